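"""Synthetic panels, tumor profiles, variant tables and cohorts with known truth.

Every downstream stage (germline filtering, purity/CNV recovery, tiering,
cohort summaries) is exercised against data generated here, where purity,
copy numbers, somatic VAFs and germline status are planted and therefore
recoverable. The simulator inverts the same single-clone mixture model the
CNV caller fits:

    exon depth ~ base_depth * (p * n_T + 2 (1 - p)) / 2 * LogNormal(0, noise_sd)
    het-SNP BAF = (p * n_B + (1 - p)) / (p * n_T + 2 (1 - p)) + binomial noise

with n_B defaulting to ceil(n_T / 2). With ``noise_sd = 0`` both noise
sources are disabled so closed-form recovery is exact. FFPE samples carry a
fixed per-exon multiplicative bias vector (distinct from fresh-frozen), so
matching a tumor against the wrong reference class is detectable.

What this emulates — and what it does not: capture-panel dispersion is
reduced to one lognormal knob; there is no GC/length bias, no subclonality
(a single tumor clone at purity p), no FASTQ/BAM read level, and no clonal
evolution between timepoints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cohort_report import PatientCase
from .exceptions import ValidationError
from .io_formats import (
    EvidenceEntry,
    ExonCoverageProfile,
    FrequencyRecord,
    PanelDefinition,
    PanelRegion,
    VariantCall,
)

__all__ = [
    "SimulationTruth",
    "ExonCoverageProfile",
    "generate_panel",
    "plant_truth",
    "simulate_tumor_profile",
    "simulate_normal_profile",
    "simulate_variants",
    "synthetic_knowledge_base",
    "generate_cohort",
    "DEFAULT_DIAGNOSIS_WEIGHTS",
]

_FFPE_BIAS_SEED = 711  # fixed: the FFPE bias vector is a property of the class, not the sample


@dataclass
class SimulationTruth:
    """Planted ground truth for one simulated tumor."""

    purity: float
    cnv_events: tuple[tuple[str, float], ...] = ()  # (gene, true total copy number)
    somatic_variants: list[tuple[tuple[str, int, str, str], float]] = field(default_factory=list)
    germline_variants: list[tuple[str, int, str, str]] = field(default_factory=list)
    seed: int = 0
    minor_copies: dict[str, int] = field(default_factory=dict)  # optional n_B per gene
    hotspot_variants: list[tuple[str, int, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 < self.purity <= 1.0:
            raise ValidationError(f"purity must be in (0, 1], got {self.purity}")
        for gene, cn in self.cnv_events:
            if cn < 0:
                raise ValidationError(f"negative copy number planted for {gene}")

    def copy_number(self, gene: str) -> float:
        for g, cn in self.cnv_events:
            if g == gene:
                return cn
        return 2.0

    def minor_copy(self, gene: str) -> int:
        n_t = self.copy_number(gene)
        return self.minor_copies.get(gene, math.ceil(n_t / 2))


def generate_panel(
    n_genes: int, exons_per_gene: int, exon_length: int, seed: int = 0
) -> PanelDefinition:
    """Lay out a synthetic capture panel: non-overlapping genes on synthetic chromosomes."""
    if n_genes < 1 or exons_per_gene < 1 or exon_length < 1:
        raise ValidationError("n_genes, exons_per_gene and exon_length must be >= 1")
    rng = np.random.default_rng(seed)
    regions = []
    genes_per_chrom = 25
    cursor: dict[str, int] = {}
    for g in range(n_genes):
        gene = f"GENE{g + 1:03d}"
        chrom = f"chr{g // genes_per_chrom + 1}"
        pos = cursor.get(chrom, 1000)
        pos += int(rng.integers(500, 2000))  # intergenic gap
        for e in range(exons_per_gene):
            regions.append(PanelRegion(chrom, pos, pos + exon_length, gene, e + 1, "exonic"))
            pos += exon_length + int(rng.integers(80, 300))  # intron gap
        cursor[chrom] = pos
    return PanelDefinition(tuple(regions))


def plant_truth(
    panel: PanelDefinition,
    purity: float,
    cnv_events: dict[str, float] | None = None,
    n_somatic: int = 5,
    n_hotspot: int = 0,
    seed: int = 0,
) -> SimulationTruth:
    """Build a SimulationTruth with somatic SNVs placed in copy-neutral genes.

    Somatic true VAF follows the mixture model with one mutant copy in a
    diploid region: vaf = p / 2.
    """
    cnv_events = cnv_events or {}
    for gene in cnv_events:
        if gene not in panel.genes:
            raise ValidationError(f"planted CNV gene {gene} absent from panel")
    rng = np.random.default_rng(seed)
    neutral_regions = [
        r for r in panel.regions if r.gene not in cnv_events and r.capture_class == "exonic"
    ]
    if n_somatic > 0 and not neutral_regions:
        raise ValidationError("no copy-neutral exonic regions to place somatic variants")
    true_vaf = purity / 2.0
    somatic = []
    used: set[tuple[str, int]] = set()
    bases = ("A", "C", "G", "T")
    for _ in range(n_somatic):
        while True:
            region = neutral_regions[int(rng.integers(len(neutral_regions)))]
            pos = int(rng.integers(region.start + 1, region.end + 1))
            if (region.chrom, pos) not in used:
                used.add((region.chrom, pos))
                break
        ref = bases[int(rng.integers(4))]
        alt = bases[(bases.index(ref) + 1 + int(rng.integers(3))) % 4]
        somatic.append(((region.chrom, pos, ref, alt), true_vaf))
    truth = SimulationTruth(
        purity=purity,
        cnv_events=tuple(cnv_events.items()),
        somatic_variants=somatic,
        seed=seed,
    )
    truth.hotspot_variants = [key for key, _ in somatic[:n_hotspot]]
    return truth


def _ffpe_bias(n_exons: int) -> np.ndarray:
    rng = np.random.default_rng(_FFPE_BIAS_SEED)
    return np.exp(rng.normal(0.0, 0.3, size=n_exons))


def simulate_tumor_profile(
    panel: PanelDefinition,
    truth: SimulationTruth,
    base_depth: float = 500.0,
    noise_sd: float = 0.05,
    seed: int = 0,
    sample_type: str = "FF",
) -> ExonCoverageProfile:
    """Simulate per-exon mean depth and one het-SNP BAF per exon.

    Expected exon depth is base_depth * (p n_T + 2 (1 - p)) / 2 with
    multiplicative lognormal noise; het SNPs at exon midpoints get
    BAF = (p n_B + (1 - p)) / (p n_T + 2 (1 - p)), binomially resampled at
    the exon's depth. noise_sd = 0 disables both noise sources.
    """
    if base_depth <= 0:
        raise ValidationError("base_depth must be positive")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    for gene, _ in truth.cnv_events:
        if gene not in panel.genes:
            raise ValidationError(f"truth gene {gene} absent from panel")
    rng = np.random.default_rng(seed)
    p = truth.purity
    bias = _ffpe_bias(len(panel.regions)) if sample_type == "FFPE" else np.ones(len(panel.regions))

    depths = []
    bafs = []
    for i, region in enumerate(panel.regions):
        n_t = truth.copy_number(region.gene)
        n_b = truth.minor_copy(region.gene)
        mixture = (p * n_t + 2.0 * (1.0 - p)) / 2.0
        depth = base_depth * mixture * bias[i]
        if noise_sd > 0:
            depth *= float(np.exp(rng.normal(0.0, noise_sd)))
        depths.append(depth)
        denom = p * n_t + 2.0 * (1.0 - p)
        if denom <= 0 or region.capture_class != "exonic":
            continue  # no DNA at this locus (pure tumor, homozygous loss)
        baf = (p * n_b + (1.0 - p)) / denom
        if noise_sd > 0 and depth >= 1:
            n_reads = max(1, int(round(depth)))
            baf = float(rng.binomial(n_reads, min(max(baf, 0.0), 1.0))) / n_reads
        pos = (region.start + region.end) // 2 + 1
        bafs.append((region.chrom, pos, min(max(baf, 0.0), 1.0)))
    return ExonCoverageProfile(panel, tuple(depths), sample_type, tuple(bafs))


def simulate_normal_profile(
    panel: PanelDefinition,
    base_depth: float = 500.0,
    noise_sd: float = 0.05,
    seed: int = 0,
    sample_type: str = "FF",
) -> ExonCoverageProfile:
    """A diploid (copy-neutral, purity-irrelevant) profile for reference building."""
    truth = SimulationTruth(purity=1.0)
    return simulate_tumor_profile(panel, truth, base_depth, noise_sd, seed, sample_type)


def simulate_variants(
    panel: PanelDefinition,
    truth: SimulationTruth,
    n_germline_het: int = 30,
    pon_size: int = 480,
    seed: int = 0,
    hom_fraction: float = 0.2,
    popdb_fraction: float = 0.7,
    depth: int = 500,
) -> tuple[list[VariantCall], list[FrequencyRecord]]:
    """Materialize the truth's somatic variants plus germline contaminants.

    Somatic records carry the planted VAF, zero population frequency and an
    empty panel of normals; hotspot-flagged ones get a synthetic protein
    change recoverable via truth.hotspot_variants. Germline records are
    heterozygous (VAF near 0.5) or homozygous (VAF in [0.97, 1]) and are
    always catchable by at least one rule: a ``popdb_fraction`` subset has
    population AF >= 1% and the remainder recur in >= 3% of the panel of
    normals. Planted germline keys are appended to truth.germline_variants.
    """
    if pon_size <= 0:
        raise ValidationError("pon_size must be positive")
    rng = np.random.default_rng(seed)
    region_by_gene: dict[str, PanelRegion] = {}
    for region in panel.regions:
        region_by_gene.setdefault(region.gene, region)

    variants: list[VariantCall] = []
    freqs: list[FrequencyRecord] = []

    def strand_split(vaf: float) -> tuple[int, int, int, int]:
        alt_total = int(round(vaf * depth))
        ref_total = depth - alt_total
        alt_fwd = int(rng.binomial(alt_total, 0.5)) if alt_total else 0
        ref_fwd = int(rng.binomial(ref_total, 0.5)) if ref_total else 0
        return (ref_fwd, ref_total - ref_fwd, alt_fwd, alt_total - alt_fwd)

    def gene_at(chrom: str, pos: int) -> str:
        for region in panel.regions:
            if region.chrom == chrom and region.start < pos <= region.end:
                return region.gene
        raise ValidationError(f"position {chrom}:{pos} outside the panel")

    hotspot_keys = set(map(tuple, truth.hotspot_variants))
    for idx, (key, vaf) in enumerate(truth.somatic_variants):
        chrom, pos, ref, alt = key
        gene = gene_at(chrom, pos)
        pchange = f"p.S{idx + 1}H" if tuple(key) in hotspot_keys else f"p.S{idx + 1}X"
        variants.append(
            VariantCall(
                chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
                protein_change=pchange, variant_class="SNV", vaf=float(vaf),
                depth=depth, strand_counts=strand_split(vaf),
            )
        )
        freqs.append(FrequencyRecord(chrom, pos, ref, alt, 0.0, 0, pon_size))

    used = {tuple(key) for key, _ in truth.somatic_variants}
    exonic = [r for r in panel.regions if r.capture_class == "exonic"]
    bases = ("A", "C", "G", "T")
    n_hom = int(math.ceil(hom_fraction * n_germline_het))
    pon_min = int(math.ceil(0.03 * pon_size))
    for i in range(n_germline_het):
        while True:
            region = exonic[int(rng.integers(len(exonic)))]
            pos = int(rng.integers(region.start + 1, region.end + 1))
            ref = bases[int(rng.integers(4))]
            alt = bases[(bases.index(ref) + 1 + int(rng.integers(3))) % 4]
            if (region.chrom, pos, ref, alt) not in used:
                used.add((region.chrom, pos, ref, alt))
                break
        if i < n_hom:
            vaf = float(rng.uniform(0.97, 1.0))
        else:
            vaf = float(np.clip(rng.normal(0.5, 0.02), 0.35, 0.65))
        if rng.random() < popdb_fraction:
            pop_af, pon_count = float(rng.uniform(0.01, 0.5)), int(rng.integers(0, pon_min))
        else:
            pop_af = float(rng.uniform(0.0, 0.009))
            pon_count = int(rng.integers(pon_min, min(pon_size, pon_min * 4) + 1))
        variants.append(
            VariantCall(
                chrom=region.chrom, pos=pos, ref=ref, alt=alt, gene=region.gene,
                protein_change="", variant_class="SNV", vaf=vaf,
                depth=depth, strand_counts=strand_split(vaf),
            )
        )
        freqs.append(FrequencyRecord(region.chrom, pos, ref, alt, pop_af, pon_count, pon_size))
        truth.germline_variants.append((region.chrom, pos, ref, alt))
    return variants, freqs


#: Diagnosis mix of a relapsed/refractory pediatric solid-tumor cohort
#: (weights follow a representative 55-patient enrollment).
DEFAULT_DIAGNOSIS_WEIGHTS: dict[str, float] = {
    "neuroblastoma": 16 / 55,
    "rhabdomyosarcoma": 9 / 55,
    "medulloblastoma": 5 / 55,
    "high-grade glioma": 4 / 55,
    "ewing sarcoma": 3 / 55,
    "hepatoblastoma": 3 / 55,
    "osteosarcoma": 3 / 55,
    "alveolar soft part sarcoma": 2 / 55,
    "wilms tumor": 2 / 55,
    "other": 8 / 55,
}


def synthetic_knowledge_base(panel: PanelDefinition, n_entries: int = 6) -> list[EvidenceEntry]:
    """A small deterministic KB over the first panel genes, for end-to-end runs."""
    genes = panel.genes
    diseases = list(DEFAULT_DIAGNOSIS_WEIGHTS)
    matchers = ("any_amplification", "any_deletion", "any_activating")
    levels = ("clinical", "preclinical", "consensus")
    entries = []
    for i in range(min(n_entries, len(genes))):
        entries.append(
            EvidenceEntry(
                gene=genes[i],
                alteration_matcher=matchers[i % len(matchers)],
                disease=diseases[i % len(diseases)],
                evidence_level=levels[i % len(levels)],
                drug=f"drug-{i + 1}",
                available_in_region=(i % 3 != 2),
            )
        )
    return entries


def generate_cohort(
    n_patients: int,
    diagnosis_weights: dict[str, float] | None = None,
    actionable_fraction: float = 20 / 55,
    seed: int = 0,
    panel: PanelDefinition | None = None,
    failure_rate: float = 2 / 55,
    base_depth: float = 500.0,
    noise_sd: float = 0.05,
    fixed_purity: float | None = None,
) -> tuple[list[PatientCase], list[SimulationTruth]]:
    """Simulate a whole cohort: cases with raw variants, coverage and truth.

    A ``failure_rate`` fraction of cases (2 of every 55 by default) is
    flagged as a sequencing failure with no data; an ``actionable_fraction``
    receives an alteration matching the synthetic knowledge base.
    Deterministic for a fixed seed.
    """
    if n_patients < 1:
        raise ValidationError("n_patients must be >= 1")
    weights = DEFAULT_DIAGNOSIS_WEIGHTS if diagnosis_weights is None else diagnosis_weights
    if not weights:
        raise ValidationError("diagnosis weights must be non-empty")
    total = sum(weights.values())
    if abs(total - 1.0) > 1e-6:
        raise ValidationError(f"diagnosis weights sum to {total}, expected 1")

    rng = np.random.default_rng(seed)
    panel = panel or generate_panel(n_genes=30, exons_per_gene=4, exon_length=150, seed=seed)
    kb = synthetic_knowledge_base(panel)
    diagnoses = list(weights)
    probs = np.asarray([weights[d] for d in diagnoses])
    n_failures = int(round(failure_rate * n_patients))
    failure_ids = set(rng.choice(n_patients, size=n_failures, replace=False).tolist())
    n_actionable = int(round(actionable_fraction * n_patients))
    eligible = [i for i in range(n_patients) if i not in failure_ids]
    actionable_ids = set(
        rng.choice(eligible, size=min(n_actionable, len(eligible)), replace=False).tolist()
    )

    cases: list[PatientCase] = []
    truths: list[SimulationTruth] = []
    for i in range(n_patients):
        pid = f"P{i + 1:03d}"
        diagnosis = diagnoses[int(rng.choice(len(diagnoses), p=probs))]
        sample_type = "FFPE" if rng.random() < 34 / 55 else "FF"
        timepoint = "relapse" if rng.random() < 41 / 55 else "diagnosis"
        sex = "M" if rng.random() < 30 / 55 else "F"
        age = float(rng.uniform(0.8, 20.0))
        timeline = (int(rng.integers(2, 16)), int(rng.integers(7, 30)), int(rng.integers(0, 6)))
        case_seed = int(rng.integers(0, 2**31 - 1))
        if i in failure_ids:
            cases.append(
                PatientCase(
                    id=pid, diagnosis=diagnosis, age_years=age, sex=sex,
                    sample_timepoint=timepoint, sample_type=sample_type,
                    sequencing_success=False, timeline_days=timeline,
                )
            )
            truths.append(SimulationTruth(purity=1.0, seed=case_seed))
            continue
        purity = fixed_purity if fixed_purity is not None else float(rng.uniform(0.3, 0.9))
        cnv_events: dict[str, float] = {}
        if i in actionable_ids:
            entry = kb[int(rng.integers(len(kb)))]
            if entry.alteration_matcher == "any_amplification":
                cnv_events[entry.gene] = 8.0
            elif entry.alteration_matcher == "any_deletion":
                cnv_events[entry.gene] = 0.0
        n_somatic = max(1, int(rng.poisson(5)))
        truth = plant_truth(panel, purity, cnv_events, n_somatic=n_somatic, seed=case_seed)
        if i in actionable_ids and not cnv_events:
            # activating small variant in the KB gene
            entry_gene = next(e.gene for e in kb if e.alteration_matcher == "any_activating")
            region = next(r for r in panel.regions if r.gene == entry_gene)
            key = (region.chrom, region.start + 5, "A", "T")
            truth.somatic_variants.append((key, purity / 2.0))
        coverage = simulate_tumor_profile(
            panel, truth, base_depth=base_depth, noise_sd=noise_sd,
            seed=case_seed, sample_type=sample_type,
        )
        variants, freqs = simulate_variants(panel, truth, seed=case_seed + 1)
        cases.append(
            PatientCase(
                id=pid, diagnosis=diagnosis, age_years=age, sex=sex,
                sample_timepoint=timepoint, sample_type=sample_type,
                sequencing_success=True, variants=variants,
                frequency_records=freqs, coverage_profile=coverage,
                purity=None, timeline_days=timeline,
            )
        )
        truths.append(truth)
    return cases, truths
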