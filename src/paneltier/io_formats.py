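"""Readers/writers for the panel, variant, frequency and knowledge-base formats.

Conventions follow each format's standard: BED intervals are 0-based
half-open; variant positions are 1-based (VCF). Multi-allelic VCF records
are split into one :class:`VariantCall` per alternate allele, since every
downstream filter operates per allele.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import pysam

from .exceptions import ParseError, SchemaError, ValidationError

CAPTURE_CLASSES = ("exonic", "intronic_rearrangement")
VARIANT_CLASSES = ("SNV", "indel", "CNV_amp", "CNV_del", "fusion")
SMALL_VARIANT_CLASSES = ("SNV", "indel")
FILTER_STATUSES = (
    "PASS",
    "germline_vaf",
    "germline_popdb",
    "germline_pon",
    "artifact_strand",
    "artifact_cluster",
)
ALTERATION_MATCHERS = (
    "exact_protein_change",
    "any_amplification",
    "any_deletion",
    "any_fusion",
    "any_activating",
)
#: Evidence strength, strongest first. Used to collapse duplicate KB rows.
EVIDENCE_LEVELS = ("clinical", "preclinical", "consensus")
EVIDENCE_RANK = {level: i for i, level in enumerate(EVIDENCE_LEVELS)}


# ---------------------------------------------------------------------------
# Panel
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PanelRegion:
    """One captured target region (an exon, or an intron tiled for rearrangements)."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    gene: str
    exon_index: int
    capture_class: str = "exonic"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"region {self.chrom}:{self.start}-{self.end} has start >= end"
            )
        if self.capture_class not in CAPTURE_CLASSES:
            raise ValidationError(f"unknown capture_class {self.capture_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PanelDefinition:
    """The targeted regions of a capture panel; the coordinate frame for all stages."""

    regions: tuple[PanelRegion, ...]

    def __post_init__(self) -> None:
        if not self.regions:
            raise ValidationError("panel has no regions")
        object.__setattr__(
            self, "regions", tuple(sorted(self.regions, key=lambda r: (r.chrom, r.start)))
        )
        self._check_gene_overlaps()

    def _check_gene_overlaps(self) -> None:
        by_gene: dict[tuple[str, str], list[PanelRegion]] = {}
        for r in self.regions:
            by_gene.setdefault((r.gene, r.chrom), []).append(r)
        for (gene, _), regs in by_gene.items():
            regs = sorted(regs, key=lambda r: r.start)
            for a, b in zip(regs, regs[1:]):
                if b.start < a.end:
                    raise ValidationError(
                        f"overlapping regions in gene {gene}: "
                        f"{a.start}-{a.end} and {b.start}-{b.end}"
                    )

    @property
    def total_targeted_bases(self) -> int:
        return sum(r.length for r in self.regions)

    @property
    def exonic_bases(self) -> int:
        return sum(r.length for r in self.regions if r.capture_class == "exonic")

    @property
    def genes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for r in self.regions:
            seen.setdefault(r.gene, None)
        return tuple(seen)


def _region_from_bed_name(chrom: str, start: int, end: int, name: str) -> PanelRegion:
    gene, _, suffix = name.rpartition("_")
    if not gene:
        raise ValueError(f"region name {name!r} is not GENE_exonN or GENE_intronN")
    if suffix.startswith("exon"):
        capture = "exonic"
        idx_str = suffix[4:]
    elif suffix.startswith("intron"):
        capture = "intronic_rearrangement"
        idx_str = suffix[6:]
    else:
        raise ValueError(f"region name {name!r} is not GENE_exonN or GENE_intronN")
    try:
        exon_index = int(idx_str) if idx_str else 1
    except ValueError:
        raise ValueError(f"region name {name!r} has a non-integer exon index") from None
    return PanelRegion(chrom, start, end, gene, exon_index, capture)


def read_panel_bed(path: str | Path) -> PanelDefinition:
    """Read a 4+ column BED (name = ``GENE_exonN`` / ``GENE_intronN``) into a panel.

    Raises :class:`ParseError` naming the offending line, and
    :class:`ValidationError` for empty panels, inverted intervals, or
    overlapping regions within a gene.
    """
    regions: list[PanelRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                fields = line.split()
            if len(fields) < 4:
                raise ParseError(f"{path}: line {lineno}: expected >=4 BED columns")
            chrom, start_s, end_s, name = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            if start >= end:
                raise ValidationError(
                    f"{path}: line {lineno}: start >= end ({start} >= {end})"
                )
            try:
                regions.append(_region_from_bed_name(chrom, start, end, name))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
    if not regions:
        raise ValidationError(f"{path}: empty panel")
    return PanelDefinition(tuple(regions))


def write_panel_bed(panel: PanelDefinition, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in panel.regions:
            suffix = "exon" if r.capture_class == "exonic" else "intron"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene}_{suffix}{r.exon_index}\n")


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantCall:
    """One called small variant, gene-level CNV, or fusion.

    ``vaf`` is None for CNV/fusion records, which carry no allele fraction.
    ``filter_status`` stays PASS until a filter stage assigns a single
    reason; reasons are mutually exclusive and the first triggered wins.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str
    protein_change: str = ""
    variant_class: str = "SNV"
    vaf: float | None = None
    depth: int = 0
    strand_counts: tuple[int, int, int, int] | None = None  # ref_fwd, ref_rev, alt_fwd, alt_rev
    filter_status: str = "PASS"

    def __post_init__(self) -> None:
        if self.variant_class not in VARIANT_CLASSES:
            raise ValidationError(f"unknown variant_class {self.variant_class!r}")
        if self.filter_status not in FILTER_STATUSES:
            raise ValidationError(f"unknown filter_status {self.filter_status!r}")
        if self.vaf is not None and not 0.0 <= self.vaf <= 1.0:
            raise ValidationError(f"vaf {self.vaf} outside [0, 1]")
        if self.variant_class in SMALL_VARIANT_CLASSES and self.vaf is None:
            raise ValidationError(
                f"{self.variant_class} record at {self.chrom}:{self.pos} lacks a VAF"
            )
        if self.depth < 0:
            raise ValidationError("depth must be >= 0")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_small_variant(self) -> bool:
        return self.variant_class in SMALL_VARIANT_CLASSES

    def with_status(self, status: str) -> "VariantCall":
        return replace(self, filter_status=status)


VARIANT_TSV_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "protein_change",
    "variant_class",
    "vaf",
    "depth",
    "ref_fwd",
    "ref_rev",
    "alt_fwd",
    "alt_rev",
    "filter_status",
)


def _variants_from_tsv(path: str | Path) -> list[VariantCall]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in VARIANT_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing variant columns: {', '.join(missing)}")
    out: list[VariantCall] = []
    for row in df.itertuples(index=False):
        vaf = float(row.vaf) if row.vaf != "" else None
        if vaf is not None and not 0.0 <= vaf <= 1.0:
            raise ValidationError(f"{path}: vaf {vaf} outside [0, 1]")
        strand = None
        if all(getattr(row, c) != "" for c in ("ref_fwd", "ref_rev", "alt_fwd", "alt_rev")):
            strand = (int(row.ref_fwd), int(row.ref_rev), int(row.alt_fwd), int(row.alt_rev))
        out.append(
            VariantCall(
                chrom=row.chrom,
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                gene=row.gene,
                protein_change=row.protein_change,
                variant_class=row.variant_class,
                vaf=vaf,
                depth=int(row.depth) if row.depth != "" else 0,
                strand_counts=strand,
                filter_status=row.filter_status or "PASS",
            )
        )
    return out


def _variants_from_vcf(path: str | Path) -> list[VariantCall]:
    out: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            if not rec.samples:
                raise SchemaError(f"{path}: VCF has no sample columns")
            sample = rec.samples[0]
            dp = sample.get("DP")
            if dp is None:
                raise SchemaError(
                    f"{path}: record {rec.chrom}:{rec.pos} lacks FORMAT/DP depth"
                )
            vafs = sample.get("VAF")
            if vafs is None:
                raise SchemaError(
                    f"{path}: record {rec.chrom}:{rec.pos} lacks FORMAT/VAF"
                )
            adf = sample.get("ADF")
            adr = sample.get("ADR")
            gene = rec.info.get("GENE", "")
            pchange = rec.info.get("PCHANGE", "")
            filters = list(rec.filter.keys())
            status = filters[0] if filters else "PASS"
            alts = rec.alts or ()
            for i, alt in enumerate(alts):
                vaf = float(vafs[i])
                if not 0.0 <= vaf <= 1.0:
                    raise ValidationError(
                        f"{path}: record {rec.chrom}:{rec.pos} vaf {vaf} outside [0, 1]"
                    )
                strand = None
                if adf is not None and adr is not None:
                    strand = (int(adf[0]), int(adr[0]), int(adf[i + 1]), int(adr[i + 1]))
                vclass = "indel" if len(rec.ref) != len(alt) else "SNV"
                out.append(
                    VariantCall(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        gene=str(gene),
                        protein_change=str(pchange),
                        variant_class=vclass,
                        vaf=vaf,
                        depth=int(dp),
                        strand_counts=strand,
                        filter_status=status,
                    )
                )
    return out


def read_variant_table(path: str | Path, dialect: str = "tsv") -> list[VariantCall]:
    """Read called variants from a TSV (all classes) or a VCF subset (SNV/indel).

    The VCF dialect requires single-sample FORMAT fields DP and VAF
    (per-alt) plus optional ADF/ADR per-allele strand depths; multi-allelic
    records are split per alternate allele.
    """
    if dialect == "tsv":
        return _variants_from_tsv(path)
    if dialect == "vcf":
        return _variants_from_vcf(path)
    raise ValidationError(f"unknown variant dialect {dialect!r}")


def _variants_to_tsv(variants: list[VariantCall], path: str | Path) -> None:
    rows = []
    for v in variants:
        strand = v.strand_counts or ("", "", "", "")
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "gene": v.gene,
                "protein_change": v.protein_change,
                "variant_class": v.variant_class,
                "vaf": "" if v.vaf is None else repr(float(v.vaf)),
                "depth": v.depth,
                "ref_fwd": strand[0],
                "ref_rev": strand[1],
                "alt_fwd": strand[2],
                "alt_rev": strand[3],
                "filter_status": v.filter_status,
            }
        )
    pd.DataFrame(rows, columns=list(VARIANT_TSV_COLUMNS)).to_csv(path, sep="\t", index=False)


def _variants_to_vcf(variants: list[VariantCall], path: str | Path) -> None:
    bad = [v for v in variants if not v.is_small_variant]
    if bad:
        raise ValidationError("VCF dialect carries SNV/indel records only")
    header = pysam.VariantHeader()
    header.add_meta("source", "paneltier")
    for status in FILTER_STATUSES:
        if status != "PASS":
            header.filters.add(status, None, None, f"paneltier filter reason {status}")
    header.info.add("GENE", 1, "String", "Gene symbol")
    header.info.add("PCHANGE", 1, "String", "Protein change")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("VAF", "A", "Float", "Variant allele fraction")
    header.formats.add("ADF", "R", "Integer", "Forward-strand allelic depths")
    header.formats.add("ADR", "R", "Integer", "Reverse-strand allelic depths")
    header.add_sample("TUMOR")
    for chrom in dict.fromkeys(v.chrom for v in variants):
        maxpos = max(v.pos for v in variants if v.chrom == chrom)
        header.contigs.add(chrom, length=maxpos + 10_000)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for v in variants:
            rec = vcf.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt), filter=v.filter_status
            )
            rec.info["GENE"] = v.gene or "."
            if v.protein_change:
                rec.info["PCHANGE"] = v.protein_change
            rec.samples["TUMOR"]["DP"] = v.depth
            rec.samples["TUMOR"]["VAF"] = float(v.vaf)
            if v.strand_counts is not None:
                rf, rr, af, ar = v.strand_counts
                rec.samples["TUMOR"]["ADF"] = (rf, af)
                rec.samples["TUMOR"]["ADR"] = (rr, ar)
            vcf.write(rec)


def write_variant_table(
    variants: list[VariantCall], path: str | Path, dialect: str = "tsv"
) -> None:
    if dialect == "tsv":
        _variants_to_tsv(variants, path)
    elif dialect == "vcf":
        _variants_to_vcf(variants, path)
    else:
        raise ValidationError(f"unknown variant dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Population frequency / panel-of-normals records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrequencyRecord:
    """Population frequency and panel-of-normals recurrence for one variant.

    ``population_af`` is the maximum allele frequency across the configured
    population databases — the conservative reduction for a single >=1%
    germline rule. ``pon_count`` is the number of carrier normals among
    ``pon_size`` healthy samples.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    population_af: float = 0.0
    pon_count: int = 0
    pon_size: int = 480

    def __post_init__(self) -> None:
        if not 0.0 <= self.population_af <= 1.0:
            raise ValidationError(f"population_af {self.population_af} outside [0, 1]")
        if self.pon_count < 0 or self.pon_count > self.pon_size:
            raise ValidationError(
                f"pon_count {self.pon_count} outside [0, {self.pon_size}]"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


FREQUENCY_TSV_COLUMNS = ("chrom", "pos", "ref", "alt", "population_af", "pon_count", "pon_size")


def read_frequency_table(path: str | Path) -> list[FrequencyRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in FREQUENCY_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing frequency columns: {', '.join(missing)}")
    return [
        FrequencyRecord(
            chrom=row.chrom,
            pos=int(row.pos),
            ref=row.ref,
            alt=row.alt,
            population_af=float(row.population_af),
            pon_count=int(row.pon_count),
            pon_size=int(row.pon_size),
        )
        for row in df.itertuples(index=False)
    ]


def write_frequency_table(records: list[FrequencyRecord], path: str | Path) -> None:
    rows = [
        {
            "chrom": r.chrom,
            "pos": r.pos,
            "ref": r.ref,
            "alt": r.alt,
            "population_af": repr(float(r.population_af)),
            "pon_count": r.pon_count,
            "pon_size": r.pon_size,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(FREQUENCY_TSV_COLUMNS)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Evidence knowledge base
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EvidenceEntry:
    """One curated (gene, alteration, disease, drug) row of the knowledge base.

    ``alteration_matcher`` selects how the entry matches an alteration:
    an exact protein change (``pattern`` holds the change), any
    amplification/deletion/fusion of the gene, or any activating small
    variant. ``diagnosis_scope``, when non-empty, restricts the entry to
    the listed diagnoses — regional drug access is often
    indication-specific (an open trial for one disease does not make the
    drug available for another).
    """

    gene: str
    alteration_matcher: str
    disease: str
    evidence_level: str
    drug: str
    available_in_region: bool
    pattern: str = ""
    reference: str = ""
    diagnosis_scope: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.alteration_matcher not in ALTERATION_MATCHERS:
            raise SchemaError(f"unknown alteration_matcher {self.alteration_matcher!r}")
        if self.evidence_level not in EVIDENCE_LEVELS:
            raise SchemaError(f"unknown evidence_level {self.evidence_level!r}")
        if not self.drug:
            raise SchemaError("evidence entry lacks a drug")
        if self.alteration_matcher == "exact_protein_change" and not self.pattern:
            raise SchemaError("exact_protein_change matcher requires a pattern")
        object.__setattr__(
            self, "diagnosis_scope", tuple(d.lower() for d in self.diagnosis_scope)
        )

    @property
    def dedup_key(self) -> tuple:
        return (
            self.gene,
            self.alteration_matcher,
            self.pattern,
            self.disease.lower(),
            self.drug.lower(),
            self.diagnosis_scope,
        )


KB_TSV_COLUMNS = (
    "gene",
    "alteration_matcher",
    "pattern",
    "disease",
    "evidence_level",
    "drug",
    "available_in_region",
    "reference",
    "diagnosis_scope",
)

_BOOL_TOKENS = {"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False}


def _parse_bool(token) -> bool:
    if isinstance(token, bool):
        return token
    try:
        return _BOOL_TOKENS[str(token).strip().lower()]
    except KeyError:
        raise SchemaError(f"cannot parse boolean token {token!r}") from None


def _entry_from_mapping(row: dict) -> EvidenceEntry:
    scope = row.get("diagnosis_scope", "") or ()
    if isinstance(scope, str):
        scope = tuple(s.strip() for s in scope.split(";") if s.strip())
    return EvidenceEntry(
        gene=row["gene"],
        alteration_matcher=row["alteration_matcher"],
        pattern=row.get("pattern", "") or "",
        disease=row["disease"],
        evidence_level=row["evidence_level"],
        drug=row["drug"],
        available_in_region=_parse_bool(row["available_in_region"]),
        reference=row.get("reference", "") or "",
        diagnosis_scope=tuple(scope),
    )


def dedupe_knowledge_base(entries: list[EvidenceEntry]) -> list[EvidenceEntry]:
    """Collapse duplicate (gene, matcher, disease, drug) rows, keeping the strongest evidence."""
    best: dict[tuple, EvidenceEntry] = {}
    for entry in entries:
        prev = best.get(entry.dedup_key)
        if prev is None or EVIDENCE_RANK[entry.evidence_level] < EVIDENCE_RANK[prev.evidence_level]:
            best[entry.dedup_key] = entry
    return list(best.values())


def read_knowledge_base(path: str | Path) -> list[EvidenceEntry]:
    """Read and validate an evidence knowledge base from TSV or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            rows = json.load(fh)
        if not isinstance(rows, list):
            raise SchemaError(f"{path}: JSON knowledge base must be a list of objects")
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        required = ("gene", "alteration_matcher", "disease", "evidence_level", "drug",
                    "available_in_region")
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing KB columns: {', '.join(missing)}")
        rows = df.to_dict(orient="records")
    return dedupe_knowledge_base([_entry_from_mapping(row) for row in rows])


def write_knowledge_base(entries: list[EvidenceEntry], path: str | Path) -> None:
    path = Path(path)
    rows = [
        {
            "gene": e.gene,
            "alteration_matcher": e.alteration_matcher,
            "pattern": e.pattern,
            "disease": e.disease,
            "evidence_level": e.evidence_level,
            "drug": e.drug,
            "available_in_region": "true" if e.available_in_region else "false",
            "reference": e.reference,
            "diagnosis_scope": ";".join(e.diagnosis_scope),
        }
        for e in entries
    ]
    if path.suffix.lower() == ".json":
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=1)
    else:
        pd.DataFrame(rows, columns=list(KB_TSV_COLUMNS)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Per-exon coverage profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExonCoverageProfile:
    """Mean sequencing depth per panel exon, plus heterozygous-SNP BAFs.

    ``depths`` aligns with ``panel.regions``. ``het_snp_bafs`` holds
    (chrom, pos, baf) for germline heterozygous SNPs inside the panel;
    their deviation from 0.5 carries the allelic-imbalance signal used for
    purity estimation. ``sample_type`` selects the pattern-matched normal
    reference class (fresh-frozen vs FFPE have distinct capture biases).
    """

    panel: PanelDefinition
    depths: tuple[float, ...]
    sample_type: str = "FF"
    het_snp_bafs: tuple[tuple[str, int, float], ...] = ()

    def __post_init__(self) -> None:
        if self.sample_type not in ("FF", "FFPE"):
            raise ValidationError(f"unknown sample_type {self.sample_type!r}")
        object.__setattr__(self, "depths", tuple(float(d) for d in self.depths))
        if len(self.depths) != len(self.panel.regions):
            raise ValidationError(
                f"{len(self.depths)} depths for {len(self.panel.regions)} panel regions"
            )
        for d in self.depths:
            if not math.isfinite(d) or d < 0:
                raise ValidationError(f"exon depth {d} is not finite and >= 0")
        for _, _, baf in self.het_snp_bafs:
            if not 0.0 <= baf <= 1.0:
                raise ValidationError(f"BAF {baf} outside [0, 1]")


COVERAGE_TSV_COLUMNS = ("chrom", "start", "end", "gene", "exon_index", "mean_depth")


def read_coverage_table(
    path: str | Path,
    panel: PanelDefinition,
    sample_type: str = "FF",
    baf_path: str | Path | None = None,
) -> ExonCoverageProfile:
    """Read a per-exon coverage TSV (and optional het-SNP BAF TSV) onto a panel."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in COVERAGE_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing coverage columns: {', '.join(missing)}")
    depth_by_region = {
        (row.chrom, int(row.start), int(row.end)): float(row.mean_depth)
        for row in df.itertuples(index=False)
    }
    depths = []
    for r in panel.regions:
        key = (r.chrom, r.start, r.end)
        if key not in depth_by_region:
            raise ValidationError(f"{path}: no coverage row for panel region {key}")
        depths.append(depth_by_region[key])
    bafs: tuple[tuple[str, int, float], ...] = ()
    if baf_path is not None:
        bdf = pd.read_csv(baf_path, sep="\t", dtype=str, keep_default_na=False)
        for col in ("chrom", "pos", "baf"):
            if col not in bdf.columns:
                raise SchemaError(f"{baf_path}: BAF table missing column {col!r}")
        bafs = tuple(
            (row.chrom, int(row.pos), float(row.baf)) for row in bdf.itertuples(index=False)
        )
    return ExonCoverageProfile(panel, tuple(depths), sample_type, bafs)


def write_coverage_table(
    profile: ExonCoverageProfile, path: str | Path, baf_path: str | Path | None = None
) -> None:
    rows = [
        {
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "gene": r.gene,
            "exon_index": r.exon_index,
            "mean_depth": repr(float(d)),
        }
        for r, d in zip(profile.panel.regions, profile.depths)
    ]
    pd.DataFrame(rows, columns=list(COVERAGE_TSV_COLUMNS)).to_csv(path, sep="\t", index=False)
    if baf_path is not None:
        brows = [
            {"chrom": c, "pos": p, "baf": repr(float(b))} for c, p, b in profile.het_snp_bafs
        ]
        pd.DataFrame(brows, columns=["chrom", "pos", "baf"]).to_csv(
            baf_path, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# Hotspot table
# ---------------------------------------------------------------------------


def read_hotspot_table(path: str | Path) -> set[tuple[str, str]]:
    """Read a two-column (gene, protein_change) hotspot whitelist TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("gene", "protein_change"):
        if col not in df.columns:
            raise SchemaError(f"{path}: hotspot table missing column {col!r}")
    return {(row.gene, row.protein_change) for row in df.itertuples(index=False)}


def write_hotspot_table(hotspots: set[tuple[str, str]], path: str | Path) -> None:
    rows = [{"gene": g, "protein_change": p} for g, p in sorted(hotspots)]
    pd.DataFrame(rows, columns=["gene", "protein_change"]).to_csv(path, sep="\t", index=False)
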