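# Methods

## Scope and data model

`paneltier` covers the interpretation stages of a targeted cancer-panel
workflow. Read alignment, duplicate marking, base recalibration and primary
SNV/indel/fusion calling are upstream concerns: the package consumes a
panel definition (BED), called variants (TSV, or a VCF subset with
single-sample `DP`/`VAF`/`ADF`/`ADR` FORMAT fields), per-exon coverage
tables, population-frequency / panel-of-normals tables, and an evidence
knowledge base (TSV/JSON). BED intervals are 0-based half-open; variant
positions are 1-based; multi-allelic VCF records are split per alternate
allele because every filter operates per allele.

## Germline and artifact filters

Tumor-only designs cannot subtract a matched normal, so germline variants
are filtered by rule. All three thresholds are inclusive (≥), and each
record reports exactly one reason, assigned first-match-wins in a fixed,
documented order:

1. **germline_vaf** — VAF ≥ 0.97, unless the (gene, protein change) pair is
   on the hotspot whitelist. The hotspot exemption applies to this rule
   only: a hotspot that is also common in a population database is still
   germline by descent, so rules 2–3 are not waived.
2. **germline_popdb** — maximum population allele frequency across the
   configured databases ≥ 0.01. Storing the *maximum* across databases is
   the conservative reduction of several sources to one ≥ 1 % rule.
3. **germline_pon** — carrier fraction of the panel of normals ≥ 0.03
   (with the default 480 normals the smallest filtered count is 15, since
   14/480 ≈ 2.9 %). Carrier counts, not allele counts, are used.

Variants with no frequency record are treated as absent from all databases
(AF 0, carrier count 0) and logged, not rejected: novelty is the expected
state of a somatic call.

Artifact filters run only on records still PASS, strand bias before
clustering so a strand artifact does not anchor a spurious cluster:

- **artifact_strand** — two-sided Fisher exact test on the 2×2
  (ref/alt × fwd/rev) table with p < 0.005 *and* ≥ 90 % of alt reads on one
  strand. The one-sidedness condition keeps well-covered sites with mild
  imbalance (where the exact test is overpowered) from being flagged.
- **artifact_cluster** — ≥ 3 PASS calls within 10 bp on one chromosome;
  all members of the run are flagged. Dense call runs are an
  alignment-artifact signature on hybrid-capture data.

Both filters stand in for site-specific heuristics that are never published
with pipelines; every knob lives in `FilterConfig` so they can be
recalibrated per assay.

**TMB** is the count of PASS SNVs+indels divided by exonic targeted
megabases; CNV and fusion records never count, intronic rearrangement
baits do not contribute to the denominator. By default all PASS small
variants count; `nonsynonymous_only` restricts to records carrying a
protein change.

## Coverage normalization, purity and copy number

Each sample's per-exon mean depth is divided by its own median exon depth
(scale-invariant; output median 1). The reference value per exon is the
median of normalized coverage across ≥ 2 normals of the matching sample
class — fresh-frozen and FFPE tissues have distinct capture-bias patterns
and are never mixed. The tumor's normalized value over the reference gives
the ratio r, log2 transformed; exons whose reference is ≤ machine epsilon
are dropped and logged.

Segmentation is gene-level: reportable CNV calls are per gene, so exon
ratios are averaged within genes, and het-SNP BAFs are folded to the major
allele, max(b, 1−b), before averaging — allelic imbalance is symmetric in
which parental allele is lost or gained, and folding prevents reflected
SNPs from cancelling.

Purity is fit by grid search under a single-clone mixture model. Segments
with |log2 r| < 0.1 define the copy-neutral baseline; their median ratio
re-centers r (a coarse ploidy re-scaling — no whole-genome-doubling search
is attempted, a documented limitation). For each grid purity
(0.05–1.00, step 0.01) every remaining segment is matched to its best
integer allele state 0 ≤ n_B ≤ n_T ≤ 8 under

    r(n_T)        = (p·n_T + 2(1−p)) / 2
    BAF(n_T, n_B) = (p·major + (1−p)) / (p·n_T + 2(1−p)),  major = max(n_B, n_T−n_B)

and the purity minimizing Σ[(r_obs − r_model)² + (BAF_obs − BAF_model)²]
(BAF term only where het SNPs exist) wins; ties break toward the lowest
purity, and states whose model BAF is undefined (no DNA) are excluded for
segments with an observed BAF. When no segment deviates from neutral the
fit is unidentifiable and purity defaults to 1 — the only value at which
the adjustment below is the identity on the re-centered ratios.

Copy number is the model inverted at the fitted purity,
n_T = max(0, (2r − 2(1−p))/p), clamped at zero because ratios below the
pure-normal floor are noise. Calls use strict thresholds on the
purity-adjusted absolute scale: deletion below 0.7 copies, amplification
above 4; the boundary values themselves are neutral. The 0.7 threshold only
makes sense on the absolute scale (it represents near-complete loss in an
impure sample), which is why adjustment precedes thresholding.

Default knobs and why: grid step 0.01 (matches the reporting precision of
purity), neutral window 0.1 in log2 (≈ ±7 % coverage, inside normal
capture dispersion), max copy state 8 (higher amplifications saturate the
classification anyway).

## Tier engine

Knowledge-base entries match on gene plus an alteration matcher (exact
protein change, any amplification/deletion/fusion, any activating small
variant). Disease context is case-insensitive string equality with an
optional synonym table — at a 20-patient reporting scale an ontology
dependency is not warranted. Entries may carry a *diagnosis scope*
restricting the diagnoses they apply to at all: regional drug access is
frequently indication-specific (an open trial in one disease does not make
the drug accessible in another), and without scoping a single KB cannot
express the same alteration being reachable in one diagnosis and not in
another. Duplicate (gene, matcher, disease, drug) rows collapse to the
strongest evidence level (clinical > preclinical > consensus).

Tier resolution: each match yields a candidate (clinical → 1a/1b,
preclinical → 2a/2b by disease identity, consensus → 3); the best
available-in-region candidate wins with its drug; if matches exist but
none is available the record is tier 4 with the best-evidence unavailable
drug; no matches is tier 5 (no drug, by construction). Alterations
co-occurring in one gene (e.g. an activating point mutation plus
amplification) form a single record with one tier label; cohort summaries
count records, collapse 1a/1b → class 1 and 2a/2b → class 2, and call a
patient actionable at best tier ≤ 4. Percentages are computed over all
enrolled patients (including sequencing failures) with one-decimal
half-up rounding, the convention of clinical cohort tables.

## Synthetic cohorts

The generator inverts exactly the models above: exon depth
base_depth · (p·n_T + 2(1−p))/2 with multiplicative lognormal noise
(σ = `noise_sd` in log space), one het SNP per exon with
BAF = (p·n_B + (1−p))/(p·n_T + 2(1−p)) (n_B defaults to ⌈n_T/2⌉),
binomially resampled at the exon's depth. With `noise_sd = 0` both noise
sources are off, so closed-form recovery is exact — the basis of the
noise-free recovery tests. FFPE samples multiply a bias vector that is a
fixed property of the class (not the sample), making reference mismatch
detectable. Somatic variants are planted at the model VAF (p/2 for one
mutant copy in a diploid region); germline variants are heterozygous
(VAF ~ N(0.5, 0.02), clipped to [0.35, 0.65]) or homozygous
(VAF ∈ [0.97, 1]), and every germline record is catchable by at least one
rule: a configurable fraction carries population AF ≥ 1 % and the rest
recur in ≥ 3 % of the panel of normals. Cohorts flag 2 of every 55 cases
(configurable) as sequencing failures and give a configurable fraction a
KB-matching alteration.

What the simulator does *not* emulate — and hence what passing tests do not
show about real data: GC/length coverage bias, subclonal populations and
clonal evolution, FFPE deamination artifacts at the read level, tri-allelic
sites, and mapping ambiguity. Recovery results on synthetic data bound the
method's behavior under its own model, not under assay physics.

## Problem sizes and verification

The test suite and the recovery experiments run on a 30-gene × 4-exon ×
150 bp panel (18 kb exonic) with five planted copy states
{0, 1, 3, 6, 8} at purities {0.2, …, 1.0}: noise-free recovery is exact at
every purity, and at `noise_sd = 0.05` gene-label accuracy over 200
seeded replicates is ≥ 95 % (measured ≈ 99.9 %). Because the synthetic
panel is three orders of magnitude smaller than a production panel,
per-Mb mutational burdens on simulated cohorts are not calibrated to
clinical ranges; TMB arithmetic is verified on constructed 0.5/1 Mb
panels instead. Filter logic is verified against a straight-line oracle on
1,000 random tables including the exact boundary values (0.97, 0.01,
15/480), and the tier ladder against a brute-force restatement over all
2¹² evidence × disease × availability match subsets.

The bundled 55-patient cohort fixes per-patient attributes (ages, sexes,
turnaround days) as plausible defaults with only their marginal counts
meaningful; cohort medians that depend on them (TMB median, mean depth,
turnaround) are illustrative, not asserted.

## Known limitations

- Single-clone model: subclonal CNVs and mixtures bias both purity and
  copy number; no confidence intervals on the grid fit.
- Ploidy handling is median re-centering only; a genome-doubled tumor with
  few neutral segments can be mis-centered.
- Low purity with even copy numbers is weakly identifiable from BAF
  (balanced states fold to 0.5); the fit then leans on coverage alone.
- Disease matching is lexical; knowledge-base curation quality directly
  bounds tiering quality.
- The VCF reader targets the package's own writer subset plus close
  variants; it is not a general VCF toolkit.
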