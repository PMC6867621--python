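"""Coverage normalization, purity grid fit, copy-number adjustment and calling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paneltier.cnv_purity import (
    CnvCallConfig,
    GeneSegment,
    adjust_copy_number,
    build_reference,
    classify_cnv,
    compute_ratios,
    estimate_purity,
    model_baf,
    model_ratio,
    normalize_coverage,
    run_cnv_pipeline,
    segment_by_gene,
)
from paneltier.exceptions import ValidationError
from paneltier.io_formats import ExonCoverageProfile, PanelDefinition, PanelRegion
from paneltier.synthetic_cohort import (
    generate_panel,
    plant_truth,
    simulate_normal_profile,
    simulate_tumor_profile,
)


def flat_profile(panel, depth, sample_type="FF"):
    return ExonCoverageProfile(panel, tuple([depth] * len(panel.regions)), sample_type)


def tiny_panel(n):
    return PanelDefinition(
        tuple(
            PanelRegion("chr1", 1000 * i, 1000 * i + 100, f"G{i + 1}", 1, "exonic")
            for i in range(n)
        )
    )


class TestNormalize:
    def test_flat_profile_normalizes_to_one(self):
        out = normalize_coverage(flat_profile(tiny_panel(5), 500.0))
        assert np.allclose(out, 1.0)

    def test_median_division(self):
        profile = ExonCoverageProfile(tiny_panel(3), (100.0, 200.0, 400.0))
        assert np.allclose(normalize_coverage(profile), [0.5, 1.0, 2.0])

    def test_single_exon_is_its_own_median(self):
        profile = ExonCoverageProfile(tiny_panel(1), (874.0,))
        assert np.allclose(normalize_coverage(profile), [1.0])

    def test_all_zero_profile_rejected(self):
        with pytest.raises(ValidationError):
            normalize_coverage(flat_profile(tiny_panel(4), 0.0))

    @settings(max_examples=50, derandomize=True)
    @given(
        depths=st.lists(st.floats(1.0, 1e5), min_size=1, max_size=30),
        scale=st.floats(0.01, 100.0),
    )
    def test_scale_invariance(self, depths, scale):
        panel = tiny_panel(len(depths))
        a = normalize_coverage(ExonCoverageProfile(panel, tuple(depths)))
        b = normalize_coverage(ExonCoverageProfile(panel, tuple(d * scale for d in depths)))
        assert np.allclose(a, b, rtol=1e-9)


class TestReferenceAndRatios:
    def test_identical_flat_normals_give_unit_reference(self):
        panel = tiny_panel(5)
        normals = [flat_profile(panel, 300.0) for _ in range(3)]
        ref = build_reference(normals, "FF")
        assert np.allclose(ref.values, 1.0) and ref.n_normals == 3

    def test_per_exon_median_of_three(self):
        panel = tiny_panel(3)
        base = np.array([1.0, 1.0, 1.0])
        profiles = []
        for factor in (0.8, 1.0, 1.2):
            depths = base * 300.0
            depths = depths.copy()
            depths[1] *= factor  # middle exon varies across normals
            profiles.append(ExonCoverageProfile(panel, tuple(depths)))
        ref = build_reference(profiles, "FF")
        assert ref.values[1] == pytest.approx(np.median([0.8, 1.0, 1.2]) /
                                              np.median([1.0, 0.8, 1.0]) * 0.8, rel=0.5)
        # the defining property: median across the normals' normalized values
        stacked = np.vstack([normalize_coverage(p) for p in profiles])
        assert np.allclose(ref.values, np.median(stacked, axis=0))

    def test_single_normal_rejected(self):
        with pytest.raises(ValidationError):
            build_reference([flat_profile(tiny_panel(2), 100.0)], "FF")

    def test_mismatched_sample_type_not_counted(self):
        panel = tiny_panel(2)
        normals = [flat_profile(panel, 100.0, "FF"), flat_profile(panel, 100.0, "FFPE")]
        with pytest.raises(ValidationError):
            build_reference(normals, "FF")

    def test_ratio_and_log2(self):
        panel = tiny_panel(2)
        ref = build_reference([flat_profile(panel, 100.0)] * 2, "FF")
        profile = compute_ratios(np.array([1.0, 2.0]), ref)
        assert profile.exons[0].ratio == pytest.approx(1.0)
        assert profile.exons[0].log2_ratio == pytest.approx(0.0)
        assert profile.exons[1].log2_ratio == pytest.approx(1.0)

    def test_unusable_reference_exon_dropped(self):
        panel = tiny_panel(3)
        normals = [
            ExonCoverageProfile(panel, (100.0, 0.0, 100.0)),
            ExonCoverageProfile(panel, (100.0, 0.0, 100.0)),
        ]
        ref = build_reference(normals, "FF")
        profile = compute_ratios(np.array([1.0, 1.0, 1.0]), ref)
        assert len(profile.exons) == 2
        assert all(e.region.gene != "G2" for e in profile.exons)


class TestSegmentation:
    def test_gene_mean_ratio(self):
        panel = PanelDefinition(
            (
                PanelRegion("chr1", 0, 100, "A", 1),
                PanelRegion("chr1", 200, 300, "A", 2),
            )
        )
        ref = build_reference([flat_profile(panel, 100.0)] * 2, "FF")
        profile = compute_ratios(np.array([1.9, 2.1]), ref)
        (seg,) = segment_by_gene(profile)
        assert seg.mean_r == pytest.approx(2.0) and seg.n_exons == 2

    def test_folded_baf_mean(self):
        panel = tiny_panel(1)
        ref = build_reference([flat_profile(panel, 100.0)] * 2, "FF")
        profile = compute_ratios(np.array([1.0]), ref)
        bafs = (("chr1", 50, 0.25), ("chr1", 60, 0.75))
        (seg,) = segment_by_gene(profile, bafs)
        assert seg.mean_baf == pytest.approx(0.75)

    def test_gene_without_het_snps_has_no_baf(self):
        panel = tiny_panel(1)
        ref = build_reference([flat_profile(panel, 100.0)] * 2, "FF")
        (seg,) = segment_by_gene(compute_ratios(np.array([1.0]), ref))
        assert seg.mean_baf is None


def bruteforce_purity(segments, cfg):
    """Independent double-loop grid oracle over (purity, integer allele states)."""
    import statistics

    rs = [s.mean_r for s in segments]
    neutral = [abs(math.log2(r)) < cfg.neutral_log2_window if r > 0 else False for r in rs]
    if all(neutral):
        return 1.0, False
    neutral_rs = [r for r, n in zip(rs, neutral) if n]
    scale = statistics.median(neutral_rs) if neutral_rs else 1.0
    fit_segments = [
        seg for seg in segments
        if seg.mean_r / scale <= 0 or abs(math.log2(seg.mean_r / scale)) >= cfg.neutral_log2_window
    ]
    if not fit_segments:
        return 1.0, False
    best_p, best_score = None, float("inf")
    p = cfg.purity_grid[0]
    while p <= cfg.purity_grid[1] + 1e-9:
        total = 0.0
        for seg in fit_segments:
            r = seg.mean_r / scale
            seg_best = float("inf")
            for n_t in range(cfg.max_copy_state + 1):
                for n_b in range(n_t + 1):
                    score = (r - model_ratio(p, n_t)) ** 2
                    if seg.mean_baf is not None:
                        denom = p * n_t + 2 * (1 - p)
                        if denom <= 0:
                            continue
                        score += (seg.mean_baf - model_baf(p, n_t, n_b)) ** 2
                    seg_best = min(seg_best, score)
            total += seg_best
        if total < best_score - 1e-12:
            best_score, best_p = total, p
        p = round(p + cfg.purity_grid[2], 10)
    return best_p, True


class TestPurityEstimation:
    def make_segments(self, p, events, n_neutral=10):
        segs = [
            GeneSegment(f"N{i}", 1.0, 0.5, 4) for i in range(n_neutral)
        ]
        for i, (n_t, n_b) in enumerate(events):
            r = model_ratio(p, n_t)
            baf = model_baf(p, n_t, n_b) if p * n_t + 2 * (1 - p) > 0 else None
            segs.append(GeneSegment(f"E{i}", r, baf, 4))
        return tuple(segs)

    @pytest.mark.parametrize("p", [0.2, 0.4, 0.6, 0.8, 1.0])
    def test_noise_free_recovery_within_one_grid_step(self, p):
        cfg = CnvCallConfig()
        segs = self.make_segments(p, [(0, 0), (1, 1), (3, 2), (6, 3), (8, 4)])
        sol = estimate_purity(segs, cfg)
        assert sol.identifiable
        assert abs(sol.purity - p) <= cfg.purity_grid[2] + 1e-9

    def test_all_neutral_is_unidentifiable(self):
        segs = tuple(GeneSegment(f"N{i}", 1.0, 0.5, 4) for i in range(5))
        sol = estimate_purity(segs)
        assert not sol.identifiable and sol.purity == 1.0

    def test_single_copy_loss_at_full_purity(self):
        # r = 0.5 and folded BAF = 1.0 pins purity at the top of the grid
        segs = self.make_segments(1.0, [(1, 1)])
        sol = estimate_purity(segs)
        assert sol.purity == pytest.approx(1.0)

    def test_empty_segment_list_rejected(self):
        with pytest.raises(ValidationError):
            estimate_purity(())

    @pytest.mark.parametrize("seed", range(4))
    def test_agrees_with_bruteforce_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cfg = CnvCallConfig(purity_grid=(0.1, 1.0, 0.05), max_copy_state=6)
        p_true = float(rng.choice([0.3, 0.5, 0.75]))
        events = []
        for _ in range(int(rng.integers(1, 5))):
            n_t = int(rng.integers(0, 7))
            events.append((n_t, int(rng.integers(0, n_t + 1))))
        segs = self.make_segments(p_true, events, n_neutral=int(rng.integers(1, 6)))
        sol = estimate_purity(segs, cfg)
        oracle_p, oracle_ident = bruteforce_purity(segs, cfg)
        assert sol.identifiable == oracle_ident
        if oracle_ident:
            assert sol.purity == pytest.approx(oracle_p, abs=1e-9)


class TestAdjustAndClassify:
    @pytest.mark.parametrize("p", [0.05, 0.3, 0.7, 1.0])
    def test_neutral_ratio_maps_to_two_copies(self, p):
        assert adjust_copy_number(1.0, p) == pytest.approx(2.0)

    def test_closed_form_example(self):
        assert adjust_copy_number(2.0, 0.5) == pytest.approx(6.0)

    def test_negative_copies_clamped_to_zero(self):
        assert adjust_copy_number(0.2, 0.5) == 0.0

    def test_invalid_purity_rejected(self):
        with pytest.raises(ValidationError):
            adjust_copy_number(1.0, 0.0)

    @settings(max_examples=50, derandomize=True)
    @given(p=st.floats(0.05, 1.0), r1=st.floats(0.0, 5.0), delta=st.floats(1e-6, 2.0))
    def test_strictly_increasing_in_ratio(self, p, r1, delta):
        lo, hi = adjust_copy_number(r1, p), adjust_copy_number(r1 + delta, p)
        assert hi >= lo
        if lo > 0:  # beyond the clamp the model is strictly increasing
            assert hi > lo

    def test_equals_two_r_at_full_purity(self):
        for r in (0.1, 0.7, 1.3, 4.2):
            assert adjust_copy_number(r, 1.0) == pytest.approx(2 * r)

    @pytest.mark.parametrize(
        "n_t,expected",
        [(0.69, "deletion"), (0.7, "neutral"), (2.0, "neutral"),
         (4.0, "neutral"), (4.01, "amplification")],
    )
    def test_call_boundaries_are_strict(self, n_t, expected):
        assert classify_cnv(n_t) == expected


class TestEndToEndRecovery:
    PLANTED = {"GENE001": 0.0, "GENE002": 1.0, "GENE003": 3.0,
               "GENE004": 6.0, "GENE005": 8.0}
    LABELS = {"GENE001": "deletion", "GENE002": "neutral", "GENE003": "neutral",
              "GENE004": "amplification", "GENE005": "amplification"}

    @pytest.mark.parametrize("p", [0.2, 0.4, 0.6, 0.8, 1.0])
    def test_noise_free_labels_exact(self, p, small_panel, noise_free_reference):
        truth = plant_truth(small_panel, p, self.PLANTED, n_somatic=0, seed=11)
        tumor = simulate_tumor_profile(small_panel, truth, 500, 0.0, seed=12)
        profile, sol = run_cnv_pipeline(tumor, noise_free_reference)
        assert abs(sol.purity - p) <= 0.01 + 1e-9
        calls = {s.gene: s.call for s in profile.segments}
        for gene, label in self.LABELS.items():
            assert calls[gene] == label
        for seg in profile.segments:
            if seg.gene in self.PLANTED:
                assert seg.adjusted_copy_number == pytest.approx(
                    self.PLANTED[seg.gene], abs=1e-6
                )
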