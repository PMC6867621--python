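"""Germline and artifact filtering of tumor-only variant calls, plus TMB.

Tumor-only panels cannot subtract a matched normal, so suspected germline
variants are removed by rule: (1) allele fraction >= 97% unless the variant
is a known hotspot, (2) population-database allele frequency >= 1%, and
(3) recurrence in >= 3% of a panel of healthy normals (480 by default).
Sequencing artifacts are then removed by a strand-bias exact test and a
clustered-call density filter. All thresholds are inclusive (the rules are
written with >=) and live in :class:`FilterConfig`.

Filter order is fixed and documented because each record reports a single
reason: germline rules first (vaf, then population database, then panel of
normals), then strand bias, then clustering. The hotspot exemption applies
only to the high-VAF rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from scipy import stats

from .exceptions import ValidationError
from .io_formats import FrequencyRecord, PanelDefinition, VariantCall

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the germline and artifact filters.

    vaf_germline_threshold : min allele fraction treated as homozygous-germline.
    popdb_af_threshold     : min population allele frequency treated as germline.
    pon_fraction_threshold : min carrier fraction of the panel of normals.
    pon_size               : number of normals in the panel.
    strand_bias_p_threshold: two-sided Fisher exact p below which strand bias
                             is called (together with >=90% one-strand alt reads).
    cluster_window         : window (bases) for the clustered-call filter.
    cluster_min_count      : calls within the window needed to flag a cluster.
    """

    vaf_germline_threshold: float = 0.97
    popdb_af_threshold: float = 0.01
    pon_fraction_threshold: float = 0.03
    pon_size: int = 480
    strand_bias_p_threshold: float = 0.005
    strand_bias_one_sided_fraction: float = 0.90
    cluster_window: int = 10
    cluster_min_count: int = 3
    tmb_nonsynonymous_only: bool = False

    def __post_init__(self) -> None:
        for name in ("vaf_germline_threshold", "popdb_af_threshold",
                     "pon_fraction_threshold", "strand_bias_p_threshold"):
            value = getattr(self, name)
            if not 0.0 < value <= 1.0:
                raise ValidationError(f"{name} must be in (0, 1], got {value}")
        if self.pon_size <= 0:
            raise ValidationError("pon_size must be positive")
        if self.cluster_window <= 0 or self.cluster_min_count <= 0:
            raise ValidationError("cluster window and count must be positive")


@dataclass(frozen=True)
class HotspotList:
    """Whitelist of recurrent somatic mutations exempt from the high-VAF rule."""

    entries: frozenset[tuple[str, str]] = frozenset()

    @classmethod
    def from_pairs(cls, pairs) -> "HotspotList":
        return cls(frozenset((g, p) for g, p in pairs))

    def __contains__(self, item: tuple[str, str]) -> bool:
        return item in self.entries


def is_hotspot(variant: VariantCall, hotspots: HotspotList) -> bool:
    """True iff the variant's (gene, protein_change) is whitelisted.

    CNV and fusion records are never hotspots; the exemption concerns
    point mutations whose high allele fraction could mimic germline.
    """
    if not variant.is_small_variant:
        return False
    return (variant.gene, variant.protein_change) in hotspots


def apply_germline_filters(
    variants: list[VariantCall],
    freqs: list[FrequencyRecord],
    hotspots: HotspotList | None = None,
    cfg: FilterConfig | None = None,
) -> list[VariantCall]:
    """Assign germline filter reasons to small variants; input order preserved.

    Reasons are assigned first-match-wins in the order ``germline_vaf``
    (vaf >= threshold and not a hotspot), ``germline_popdb`` (population
    AF >= threshold), ``germline_pon`` (carrier fraction >= threshold).
    Variants without a frequency record are treated as absent from the
    databases (AF 0, carrier count 0) and logged. CNV/fusion records pass
    through untouched.
    """
    cfg = cfg or FilterConfig()
    hotspots = hotspots or HotspotList()
    freq_by_key = {f.key: f for f in freqs}
    out: list[VariantCall] = []
    for v in variants:
        if not v.is_small_variant or v.filter_status != "PASS":
            out.append(v)
            continue
        freq = freq_by_key.get(v.key)
        if freq is None:
            logger.debug("no frequency record for %s:%s %s>%s; assuming novel",
                         v.chrom, v.pos, v.ref, v.alt)
            pop_af, pon_fraction = 0.0, 0.0
        else:
            pop_af = freq.population_af
            pon_fraction = freq.pon_count / freq.pon_size
        if v.vaf >= cfg.vaf_germline_threshold and not is_hotspot(v, hotspots):
            out.append(v.with_status("germline_vaf"))
        elif pop_af >= cfg.popdb_af_threshold:
            out.append(v.with_status("germline_popdb"))
        elif pon_fraction >= cfg.pon_fraction_threshold:
            out.append(v.with_status("germline_pon"))
        else:
            out.append(v)
    return out


def strand_bias_pvalue(strand_counts: tuple[int, int, int, int]) -> float:
    """Two-sided Fisher exact p for the ref/alt x fwd/rev strand table."""
    rf, rr, af, ar = strand_counts
    _, p = stats.fisher_exact([[rf, rr], [af, ar]], alternative="two-sided")
    return float(p)


def _flag_strand_bias(v: VariantCall, cfg: FilterConfig) -> bool:
    if v.strand_counts is None:
        logger.debug("no strand counts for %s:%s; skipping strand test", v.chrom, v.pos)
        return False
    rf, rr, af, ar = v.strand_counts
    alt_total = af + ar
    if alt_total == 0:
        return False
    one_sided = max(af, ar) / alt_total >= cfg.strand_bias_one_sided_fraction
    if not one_sided:
        return False
    return strand_bias_pvalue(v.strand_counts) < cfg.strand_bias_p_threshold


def apply_artifact_filters(
    variants: list[VariantCall], cfg: FilterConfig | None = None
) -> list[VariantCall]:
    """Flag strand-biased and clustered artifacts among still-PASS small variants.

    Strand bias: two-sided Fisher exact test on the 2x2 (ref/alt x fwd/rev)
    read table with p below the configured threshold AND >=90% of alt reads
    on one strand. Clustering: any set of >= ``cluster_min_count`` PASS
    calls within ``cluster_window`` bases on one chromosome is flagged
    wholesale (dense call runs are an alignment-artifact signature on
    hybrid-capture panels). Strand flags are assigned before the cluster
    scan, so a strand artifact does not also anchor a cluster.
    """
    cfg = cfg or FilterConfig()
    out: list[VariantCall] = []
    for v in variants:
        if v.is_small_variant and v.filter_status == "PASS" and _flag_strand_bias(v, cfg):
            out.append(v.with_status("artifact_strand"))
        else:
            out.append(v)

    # cluster scan over records still PASS
    by_chrom: dict[str, list[int]] = {}
    for idx, v in enumerate(out):
        if v.is_small_variant and v.filter_status == "PASS":
            by_chrom.setdefault(v.chrom, []).append(idx)
    clustered: set[int] = set()
    for indices in by_chrom.values():
        indices.sort(key=lambda i: out[i].pos)
        positions = [out[i].pos for i in indices]
        left = 0
        for right in range(len(positions)):
            while positions[right] - positions[left] > cfg.cluster_window:
                left += 1
            if right - left + 1 >= cfg.cluster_min_count:
                clustered.update(indices[left : right + 1])
    return [
        v.with_status("artifact_cluster") if i in clustered else v
        for i, v in enumerate(out)
    ]


def apply_all_filters(
    variants: list[VariantCall],
    freqs: list[FrequencyRecord],
    hotspots: HotspotList | None = None,
    cfg: FilterConfig | None = None,
) -> list[VariantCall]:
    """Germline rules followed by artifact rules; one reason per record."""
    cfg = cfg or FilterConfig()
    return apply_artifact_filters(
        apply_germline_filters(variants, freqs, hotspots, cfg), cfg
    )


def compute_tmb(
    variants: list[VariantCall],
    panel: PanelDefinition,
    nonsynonymous_only: bool = False,
) -> float:
    """Tumor mutational burden: PASS SNVs+indels per megabase of exonic target.

    CNV and fusion records are excluded. With ``nonsynonymous_only`` the
    count is restricted to variants carrying a protein change.
    """
    exonic = panel.exonic_bases
    if exonic <= 0:
        raise ValidationError("panel has no exonic bases; TMB undefined")
    count = sum(
        1
        for v in variants
        if v.is_small_variant
        and v.filter_status == "PASS"
        and (not nonsynonymous_only or v.protein_change)
    )
    return count / (exonic / 1e6)
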