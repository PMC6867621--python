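"""Germline/artifact filters and TMB, checked against brute-force oracles."""

import numpy as np
import pytest
from scipy.stats import hypergeom

from paneltier.io_formats import FrequencyRecord, VariantCall
from paneltier.somatic_filter import (
    FilterConfig,
    HotspotList,
    apply_all_filters,
    apply_artifact_filters,
    apply_germline_filters,
    compute_tmb,
    is_hotspot,
    strand_bias_pvalue,
)
from paneltier.synthetic_cohort import (
    generate_panel,
    plant_truth,
    simulate_variants,
)


def snv(pos=1000, vaf=0.4, chrom="chr1", gene="G1", pchange="", depth=400,
        strand=None, status="PASS"):
    if strand is None:
        alt = int(round(vaf * depth))
        strand = ((depth - alt) // 2, depth - alt - (depth - alt) // 2,
                  alt // 2, alt - alt // 2)
    return VariantCall(chrom=chrom, pos=pos, ref="A", alt="T", gene=gene,
                       protein_change=pchange, variant_class="SNV", vaf=vaf,
                       depth=depth, strand_counts=strand, filter_status=status)


def freq(v, pop_af=0.0, pon=0, pon_size=480):
    return FrequencyRecord(v.chrom, v.pos, v.ref, v.alt, pop_af, pon, pon_size)


HOTSPOTS = HotspotList.from_pairs([("ALK", "F1174L")])


class TestHotspot:
    def test_listed_pair_is_hotspot(self):
        v = snv(gene="ALK", pchange="F1174L")
        assert is_hotspot(v, HOTSPOTS)

    def test_empty_list_never_matches(self):
        v = snv(gene="ALK", pchange="F1174L")
        assert not is_hotspot(v, HotspotList())

    def test_cnv_records_never_hotspot(self):
        cnv = VariantCall(chrom="chr1", pos=1, ref="N", alt="<AMP>", gene="ALK",
                          protein_change="F1174L", variant_class="CNV_amp")
        assert not is_hotspot(cnv, HOTSPOTS)


class TestGermlineRules:
    @pytest.mark.parametrize(
        "vaf,pop_af,pon,gene,pchange,expected",
        [
            (0.98, 0.0, 0, "G1", "", "germline_vaf"),
            (0.99, 0.0, 0, "ALK", "F1174L", "PASS"),  # hotspot rescue
            (0.40, 0.02, 0, "G1", "", "germline_popdb"),
            (0.40, 0.001, 15, "G1", "", "germline_pon"),  # 15/480 = 3.125%
            (0.40, 0.001, 14, "G1", "", "PASS"),  # 14/480 = 2.917% < 3%
            (0.97, 0.0, 0, "G1", "", "germline_vaf"),  # inclusive boundary
            (0.9699, 0.0, 0, "G1", "", "PASS"),
            (0.40, 0.01, 0, "G1", "", "germline_popdb"),  # inclusive boundary
            (0.98, 0.05, 0, "G1", "", "germline_vaf"),  # first rule wins
        ],
    )
    def test_rule_outcomes(self, vaf, pop_af, pon, gene, pchange, expected):
        v = snv(vaf=vaf, gene=gene, pchange=pchange)
        (out,) = apply_germline_filters([v], [freq(v, pop_af, pon)], HOTSPOTS)
        assert out.filter_status == expected

    def test_missing_frequency_record_treated_as_novel(self):
        v = snv(vaf=0.4)
        (out,) = apply_germline_filters([v], [], HOTSPOTS)
        assert out.filter_status == "PASS"

    def test_cnv_and_fusion_untouched(self):
        cnv = VariantCall(chrom="chr1", pos=1, ref="N", alt="<AMP>", gene="X",
                          variant_class="CNV_amp")
        assert apply_germline_filters([cnv], [], HOTSPOTS) == [cnv]

    def test_matches_bruteforce_oracle_on_random_tables(self):
        """Filter statuses agree with an independent straight-line oracle,
        including boundary values 0.97 / 0.01 / 0.03*480 and hotspot rescue."""
        cfg = FilterConfig()
        rng = np.random.default_rng(42)

        def oracle_status(v, f, hotspot):
            pop_af = f.population_af if f else 0.0
            pon_frac = (f.pon_count / f.pon_size) if f else 0.0
            if v.vaf >= 0.97 and not hotspot:
                return "germline_vaf"
            if pop_af >= 0.01:
                return "germline_popdb"
            if pon_frac >= 0.03:
                return "germline_pon"
            return "PASS"

        vaf_pool = [0.1, 0.3, 0.5, 0.9699, 0.97, 0.9701, 0.98, 1.0]
        af_pool = [0.0, 0.005, 0.0099, 0.01, 0.011, 0.2]
        pon_pool = [0, 5, 13, 14, 15, 16, 100]
        for table_i in range(1000):
            n = int(rng.integers(1, 51))
            variants, freqs, oracle = [], [], []
            for j in range(n):
                hotspot = rng.random() < 0.1
                v = snv(
                    pos=1000 + 10 * j,
                    vaf=float(vaf_pool[rng.integers(len(vaf_pool))]),
                    gene="ALK" if hotspot else "G1",
                    pchange="F1174L" if hotspot else "",
                )
                f = None
                if rng.random() < 0.9:
                    f = freq(
                        v,
                        pop_af=float(af_pool[rng.integers(len(af_pool))]),
                        pon=int(pon_pool[rng.integers(len(pon_pool))]),
                    )
                    freqs.append(f)
                variants.append(v)
                oracle.append(oracle_status(v, f, hotspot))
            out = apply_germline_filters(variants, freqs, HOTSPOTS, cfg)
            assert [v.filter_status for v in out] == oracle, f"table {table_i}"

    def test_raising_popdb_threshold_never_filters_more(self):
        rng = np.random.default_rng(7)
        variants = [snv(pos=100 * (i + 1), vaf=0.4) for i in range(30)]
        freqs = [freq(v, pop_af=float(rng.uniform(0, 0.05))) for v in variants]
        counts = []
        for thr in (0.005, 0.01, 0.02, 0.04):
            cfg = FilterConfig(popdb_af_threshold=thr)
            out = apply_germline_filters(variants, freqs, cfg=cfg)
            counts.append(sum(1 for v in out if v.filter_status != "PASS"))
        assert counts == sorted(counts, reverse=True)


class TestArtifactRules:
    def test_one_strand_alt_reads_flagged(self):
        """40 fwd / 0 rev alt reads against balanced ref reads is a strand artifact;
        the exact-test p-value is checked against hypergeometric enumeration."""
        v = snv(vaf=0.089, depth=450, strand=(200, 210, 40, 0))

        def enum_pvalue(rf, rr, af, ar):
            # condition on margins; sum probabilities of tables as or less likely
            n = rf + rr + af + ar
            row1, col1 = rf + rr, rf + af
            dist = hypergeom(n, row1, col1)
            p_obs = dist.pmf(rf)
            return sum(
                dist.pmf(k)
                for k in range(max(0, col1 - (af + ar)), min(row1, col1) + 1)
                if dist.pmf(k) <= p_obs * (1 + 1e-9)
            )

        assert strand_bias_pvalue(v.strand_counts) == pytest.approx(
            enum_pvalue(*v.strand_counts), rel=1e-6
        )
        (out,) = apply_artifact_filters([v])
        assert out.filter_status == "artifact_strand"

    def test_balanced_strands_pass(self):
        v = snv(vaf=0.095, depth=400, strand=(180, 182, 20, 18))
        (out,) = apply_artifact_filters([v])
        assert out.filter_status == "PASS"

    def test_cluster_of_three_within_window_all_flagged(self):
        vs = [snv(pos=p) for p in (100, 104, 108)]
        out = apply_artifact_filters(vs)
        assert [v.filter_status for v in out] == ["artifact_cluster"] * 3

    def test_spread_calls_not_clustered(self):
        vs = [snv(pos=p) for p in (100, 104, 120)]
        out = apply_artifact_filters(vs)
        assert all(v.filter_status == "PASS" for v in out)

    def test_germline_filtered_records_do_not_anchor_clusters(self):
        vs = [snv(pos=100, vaf=0.99), snv(pos=104), snv(pos=108)]
        freqs = [freq(v) for v in vs]
        out = apply_all_filters(vs, freqs)
        assert out[0].filter_status == "germline_vaf"
        assert out[1].filter_status == "PASS" and out[2].filter_status == "PASS"

    def test_missing_strand_counts_skips_strand_test(self):
        v = VariantCall(chrom="chr1", pos=10, ref="A", alt="T", gene="G",
                        variant_class="SNV", vaf=0.4, depth=100)
        (out,) = apply_artifact_filters([v])
        assert out.filter_status == "PASS"


class TestPartitionProperty:
    def test_every_record_kept_once_with_valid_status(self):
        panel = generate_panel(10, 3, 150, seed=5)
        truth = plant_truth(panel, 0.6, n_somatic=6, seed=5)
        variants, freqs = simulate_variants(panel, truth, n_germline_het=40, seed=5)
        out = apply_all_filters(variants, freqs)
        assert len(out) == len(variants)
        assert [v.key for v in out] == [v.key for v in variants]
        for v in out:
            if v.is_small_variant and v.filter_status == "PASS":
                assert v.vaf < 0.97 or is_hotspot(v, HOTSPOTS)

    def test_planted_somatic_sensitivity_and_germline_leakage(self):
        """On synthetic tables away from thresholds: 100% somatic sensitivity,
        0% germline leakage."""
        panel = generate_panel(20, 4, 150, seed=9)
        for seed in range(5):
            truth = plant_truth(panel, 0.7, n_somatic=8, seed=seed)
            variants, freqs = simulate_variants(panel, truth, n_germline_het=50, seed=seed)
            out = apply_all_filters(variants, freqs)
            somatic_keys = {tuple(k) for k, _ in truth.somatic_variants}
            germline_keys = {tuple(k) for k in truth.germline_variants}
            for v in out:
                if v.key in somatic_keys:
                    assert v.filter_status == "PASS"
                elif v.key in germline_keys:
                    assert v.filter_status.startswith("germline")


class TestTmb:
    def test_zero_pass_variants_is_zero(self, small_panel):
        assert compute_tmb([], small_panel) == 0.0

    def test_unit_definition(self, tmp_path):
        # 10 PASS variants over 1 Mb -> 10.0; 7 over 0.5 Mb -> 14.0
        from paneltier.io_formats import PanelDefinition, PanelRegion

        mb_panel = PanelDefinition(
            (PanelRegion("chr1", 0, 1_000_000, "G1", 1, "exonic"),)
        )
        half_panel = PanelDefinition(
            (PanelRegion("chr1", 0, 500_000, "G1", 1, "exonic"),)
        )
        ten = [snv(pos=i + 1) for i in range(0, 1000, 100)]
        assert compute_tmb(ten, mb_panel) == pytest.approx(10.0)
        assert compute_tmb(ten[:7], half_panel) == pytest.approx(14.0)

    def test_cnv_and_filtered_records_excluded(self, small_panel):
        cnv = VariantCall(chrom="chr1", pos=1, ref="N", alt="<AMP>", gene="X",
                          variant_class="CNV_amp")
        filtered = snv(status="germline_popdb")
        passing = snv(pos=2000)
        tmb = compute_tmb([cnv, filtered, passing], small_panel)
        assert tmb == pytest.approx(1 / (small_panel.exonic_bases / 1e6))

    def test_intronic_bases_do_not_count(self):
        from paneltier.exceptions import ValidationError
        from paneltier.io_formats import PanelDefinition, PanelRegion

        intronic_only = PanelDefinition(
            (PanelRegion("chr1", 0, 10_000, "G1", 1, "intronic_rearrangement"),)
        )
        with pytest.raises(ValidationError):
            compute_tmb([], intronic_only)
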