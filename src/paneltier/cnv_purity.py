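"""Copy-number calling from per-exon coverage with purity adjustment.

The pipeline mirrors how hybrid-capture panels are processed in practice:

1. each sample's per-exon mean depth is normalized by its own median, so
   samples are comparable regardless of total yield;
2. the per-exon median across pattern-matched normals (same FF/FFPE class)
   serves as the reference value;
3. the tumor's normalized value is divided by the reference and log2
   transformed, giving the ratio ``r`` (diploid: r = 1);
4. tumor purity ``p`` is estimated by a grid search under the single-clone
   mixture model

       r(n_T)        = (p * n_T + 2 * (1 - p)) / 2
       BAF(n_T, n_B) = (p * major + (1 - p)) / (p * n_T + 2 * (1 - p)),
       major = max(n_B, n_T - n_B)

   matching each non-neutral gene segment to its best integer allele state
   (0 <= n_B <= n_T <= max_copy_state) and minimizing the summed squared
   residuals of coverage ratio and folded B-allele frequency;
5. the model is inverted to the purity-adjusted absolute copy number
   n_T = max(0, (2 r - 2 (1 - p)) / p), and genes are called as deletions
   (n_T < 0.7) or amplifications (n_T > 4); both boundaries are strict.

Segmentation is gene-level: the reported calls are per gene, so exon ratios
and het-SNP BAFs are aggregated within each gene before fitting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .exceptions import ValidationError
from .io_formats import (
    ExonCoverageProfile,
    PanelDefinition,
    PanelRegion,
    VariantCall,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CnvCallConfig:
    """Thresholds and search space for purity estimation and CNV calling."""

    deletion_threshold: float = 0.7
    amplification_threshold: float = 4.0
    purity_grid: tuple[float, float, float] = (0.05, 1.00, 0.01)  # min, max, step
    max_copy_state: int = 8
    neutral_log2_window: float = 0.1

    def __post_init__(self) -> None:
        if not self.deletion_threshold < 2.0 < self.amplification_threshold:
            raise ValidationError(
                "thresholds must straddle the diploid state: deletion < 2 < amplification"
            )
        lo, hi, step = self.purity_grid
        if not (0.0 < lo <= hi <= 1.0 and step > 0):
            raise ValidationError(f"invalid purity grid {self.purity_grid}")
        if self.max_copy_state < 2:
            raise ValidationError("max_copy_state must be >= 2")

    def purity_values(self) -> np.ndarray:
        lo, hi, step = self.purity_grid
        n = int(round((hi - lo) / step)) + 1
        return np.round(lo + step * np.arange(n), 10)


@dataclass(frozen=True)
class ExonRatio:
    """One exon's normalized coverage ratio against the reference."""

    region: PanelRegion
    ratio: float
    log2_ratio: float


@dataclass(frozen=True)
class GeneSegment:
    """Per-gene aggregate of exon ratios and folded het-SNP BAFs."""

    gene: str
    mean_r: float
    mean_baf: float | None  # folded: max(baf, 1 - baf), averaged; None without het SNPs
    n_exons: int
    adjusted_copy_number: float | None = None
    call: str | None = None  # deletion / neutral / amplification


@dataclass(frozen=True)
class CopyNumberProfile:
    exons: tuple[ExonRatio, ...]
    segments: tuple[GeneSegment, ...] = ()


@dataclass(frozen=True)
class ReferenceProfile:
    """Per-exon median of normalized coverage across normals of one sample class."""

    panel: PanelDefinition
    sample_type: str
    values: tuple[float, ...]
    n_normals: int

    def __post_init__(self) -> None:
        if len(self.values) != len(self.panel.regions):
            raise ValidationError("reference values misaligned with panel")
        if self.n_normals < 2:
            raise ValidationError("a reference requires >= 2 normals")

    def usable(self) -> np.ndarray:
        vals = np.asarray(self.values)
        return vals > np.finfo(float).eps


@dataclass(frozen=True)
class PuritySolution:
    """Grid-search purity estimate.

    ``neutral_scale`` is the median ratio of the copy-neutral segments used
    to re-center r before fitting; downstream adjustment must divide by it.
    When no segment deviates from neutral the fit is unidentifiable and
    purity defaults to 1.
    """

    purity: float
    fit_score: float
    identifiable: bool
    grid: tuple[tuple[float, float], ...]
    neutral_scale: float = 1.0


def normalize_coverage(profile: ExonCoverageProfile) -> np.ndarray:
    """Divide each exon's mean depth by the sample's median exon depth.

    The output has median exactly 1 for odd exon counts (within one
    interpolation step for even counts) and is invariant to rescaling all
    depths by a common factor.
    """
    depths = np.asarray(profile.depths, dtype=float)
    med = float(np.median(depths))
    if med <= 0:
        raise ValidationError("median exon depth is zero; cannot normalize coverage")
    return depths / med


def build_reference(
    normals: list[ExonCoverageProfile], sample_type: str
) -> ReferenceProfile:
    """Per-exon median of normalized coverage across >= 2 normals of one class."""
    matched = [n for n in normals if n.sample_type == sample_type]
    if len(matched) < 2:
        raise ValidationError(
            f"need >= 2 {sample_type} normals to build a reference, got {len(matched)}"
        )
    panel = matched[0].panel
    if any(n.panel != panel for n in matched):
        raise ValidationError("normals were captured on different panels")
    stacked = np.vstack([normalize_coverage(n) for n in matched])
    values = np.median(stacked, axis=0)
    n_unusable = int(np.sum(values <= np.finfo(float).eps))
    if n_unusable:
        logger.info("reference has %d unusable (zero-coverage) exons", n_unusable)
    return ReferenceProfile(panel, sample_type, tuple(values), len(matched))


def compute_ratios(
    tumor_normalized: np.ndarray, reference: ReferenceProfile
) -> CopyNumberProfile:
    """Tumor normalized value / reference value, log2 transformed, per usable exon."""
    tumor_normalized = np.asarray(tumor_normalized, dtype=float)
    if tumor_normalized.shape[0] != len(reference.panel.regions):
        raise ValidationError("tumor values misaligned with reference panel")
    usable = reference.usable()
    dropped = int(np.sum(~usable))
    if dropped:
        logger.info("dropping %d exons with unusable reference values", dropped)
    exons = []
    ref_vals = np.asarray(reference.values)
    for i, region in enumerate(reference.panel.regions):
        if not usable[i]:
            continue
        r = tumor_normalized[i] / ref_vals[i]
        log2r = math.log2(r) if r > 0 else float("-inf")
        exons.append(ExonRatio(region, float(r), float(log2r)))
    return CopyNumberProfile(tuple(exons))


def segment_by_gene(
    profile: CopyNumberProfile,
    het_bafs: tuple[tuple[str, int, float], ...] = (),
) -> tuple[GeneSegment, ...]:
    """Aggregate exon ratios into per-gene segments with folded mean BAF.

    BAFs are folded to the major allele, max(baf, 1 - baf), before
    averaging: allelic imbalance is symmetric in which parental allele is
    amplified, and folding avoids cancellation between reflected SNPs.
    """
    by_gene: dict[str, list[ExonRatio]] = {}
    for exon in profile.exons:
        by_gene.setdefault(exon.region.gene, []).append(exon)

    gene_bafs: dict[str, list[float]] = {}
    for chrom, pos, baf in het_bafs:
        for exon in profile.exons:
            reg = exon.region
            if reg.chrom == chrom and reg.start < pos <= reg.end:
                gene_bafs.setdefault(reg.gene, []).append(max(baf, 1.0 - baf))
                break

    segments = []
    for gene, exons in by_gene.items():
        mean_r = float(np.mean([e.ratio for e in exons]))
        folded = gene_bafs.get(gene)
        mean_baf = float(np.mean(folded)) if folded else None
        segments.append(GeneSegment(gene, mean_r, mean_baf, len(exons)))
    return tuple(segments)


def _allele_states(max_copy_state: int) -> tuple[np.ndarray, np.ndarray]:
    """All (n_T, major) integer allele states with 0 <= n_B <= n_T <= max."""
    n_t, major = [], []
    for nt in range(max_copy_state + 1):
        for nb in range(nt // 2, nt + 1):  # major copies; minor = nt - nb
            n_t.append(nt)
            major.append(nb)
    return np.asarray(n_t, dtype=float), np.asarray(major, dtype=float)


def model_ratio(p: float, n_t: float) -> float:
    """Expected coverage ratio of a clone at copy number n_T in a purity-p mixture."""
    return (p * n_t + 2.0 * (1.0 - p)) / 2.0


def model_baf(p: float, n_t: float, n_b: float) -> float:
    """Expected folded BAF for allele state (n_T, n_B) at purity p (major allele)."""
    major = max(n_b, n_t - n_b)
    denom = p * n_t + 2.0 * (1.0 - p)
    if denom <= 0:
        raise ValidationError("degenerate allele state: no DNA at this purity")
    return (p * major + (1.0 - p)) / denom


def estimate_purity(
    segments: tuple[GeneSegment, ...], cfg: CnvCallConfig | None = None
) -> PuritySolution:
    """Grid-search tumor purity from gene segment ratios and folded BAFs.

    Segments within the copy-neutral log2 window define the diploid
    baseline; their median ratio re-centers r (a coarse ploidy
    re-scaling). Each remaining segment is matched, at every grid purity,
    to its best integer allele state under the mixture model, and the
    purity minimizing the total squared residual wins (ties break toward
    the lowest purity). With no segment deviating from neutral the purity
    is unidentifiable and defaults to 1.
    """
    cfg = cfg or CnvCallConfig()
    if not segments:
        raise ValidationError("cannot estimate purity without segments")

    mean_rs = np.asarray([s.mean_r for s in segments], dtype=float)
    with np.errstate(divide="ignore"):
        log2r = np.where(mean_rs > 0, np.log2(np.where(mean_rs > 0, mean_rs, 1.0)), -np.inf)
    neutral_mask = np.abs(log2r) < cfg.neutral_log2_window
    if not np.any(~neutral_mask):
        scale = float(np.median(mean_rs[neutral_mask])) if np.any(neutral_mask) else 1.0
        return PuritySolution(1.0, 0.0, False, (), scale)

    scale = float(np.median(mean_rs[neutral_mask])) if np.any(neutral_mask) else 1.0
    r_rc = mean_rs / scale
    with np.errstate(divide="ignore"):
        log2_rc = np.where(r_rc > 0, np.log2(np.where(r_rc > 0, r_rc, 1.0)), -np.inf)
    fit_idx = np.nonzero(np.abs(log2_rc) >= cfg.neutral_log2_window)[0]
    if fit_idx.size == 0:
        return PuritySolution(1.0, 0.0, False, (), scale)

    n_t, major = _allele_states(cfg.max_copy_state)
    obs_r = r_rc[fit_idx]
    obs_baf = np.asarray(
        [segments[i].mean_baf if segments[i].mean_baf is not None else np.nan for i in fit_idx]
    )
    grid = []
    for p in cfg.purity_values():
        denom = p * n_t + 2.0 * (1.0 - p)
        r_model = denom / 2.0
        with np.errstate(divide="ignore", invalid="ignore"):
            baf_model = np.where(denom > 0, (p * major + (1.0 - p)) / denom, np.nan)
        # residual matrix: segments x states
        res = (obs_r[:, None] - r_model[None, :]) ** 2
        baf_res = (obs_baf[:, None] - baf_model[None, :]) ** 2
        has_baf = ~np.isnan(obs_baf)
        # states with undefined model BAF are unusable for segments with an observed BAF
        baf_res = np.where(np.isnan(baf_model)[None, :], np.inf, baf_res)
        res = res + np.where(has_baf[:, None], baf_res, 0.0)
        grid.append((float(p), float(np.sum(np.min(res, axis=1)))))
    scores = np.asarray([s for _, s in grid])
    best = int(np.argmin(scores))
    return PuritySolution(grid[best][0], grid[best][1], True, tuple(grid), scale)


def adjust_copy_number(r: float, p: float) -> float:
    """Invert the mixture model: absolute tumor copy number from ratio r at purity p.

    n_T = max(0, (2 r - 2 (1 - p)) / p); clamped at zero because a ratio
    below the pure-normal floor is noise, not negative copies.
    """
    if not 0.0 < p <= 1.0:
        raise ValidationError(f"purity must be in (0, 1], got {p}")
    return max(0.0, (2.0 * r - 2.0 * (1.0 - p)) / p)


def classify_cnv(n_t: float, cfg: CnvCallConfig | None = None) -> str:
    """deletion if n_T < deletion threshold, amplification if n_T > amplification
    threshold, otherwise neutral; both comparisons are strict."""
    cfg = cfg or CnvCallConfig()
    if n_t < 0:
        raise ValidationError("copy number must be >= 0")
    if n_t < cfg.deletion_threshold:
        return "deletion"
    if n_t > cfg.amplification_threshold:
        return "amplification"
    return "neutral"


def call_gene_cnvs(
    segments: tuple[GeneSegment, ...],
    solution: PuritySolution,
    cfg: CnvCallConfig | None = None,
) -> tuple[GeneSegment, ...]:
    """Fill adjusted copy numbers and deletion/neutral/amplification calls."""
    cfg = cfg or CnvCallConfig()
    out = []
    for seg in segments:
        n_t = adjust_copy_number(seg.mean_r / solution.neutral_scale, solution.purity)
        out.append(replace(seg, adjusted_copy_number=n_t, call=classify_cnv(n_t, cfg)))
    return tuple(out)


def cnv_variant_calls(
    segments: tuple[GeneSegment, ...], panel: PanelDefinition
) -> list[VariantCall]:
    """Emit non-neutral gene calls as CNV VariantCall records for tiering."""
    first_region = {}
    for region in panel.regions:
        first_region.setdefault(region.gene, region)
    calls = []
    for seg in segments:
        if seg.call not in ("deletion", "amplification"):
            continue
        region = first_region.get(seg.gene)
        if region is None:
            raise ValidationError(f"called gene {seg.gene} not on the panel")
        calls.append(
            VariantCall(
                chrom=region.chrom,
                pos=region.start + 1,
                ref="N",
                alt="<DEL>" if seg.call == "deletion" else "<AMP>",
                gene=seg.gene,
                variant_class="CNV_del" if seg.call == "deletion" else "CNV_amp",
                vaf=None,
                depth=0,
            )
        )
    return calls


def run_cnv_pipeline(
    tumor: ExonCoverageProfile,
    reference: ReferenceProfile,
    cfg: CnvCallConfig | None = None,
) -> tuple[CopyNumberProfile, PuritySolution]:
    """normalize -> ratio -> gene segmentation -> purity fit -> adjusted calls."""
    cfg = cfg or CnvCallConfig()
    profile = compute_ratios(normalize_coverage(tumor), reference)
    segments = segment_by_gene(profile, tumor.het_snp_bafs)
    solution = estimate_purity(segments, cfg)
    called = call_gene_cnvs(segments, solution, cfg)
    return CopyNumberProfile(profile.exons, called), solution
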