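"""Screening statistics: Z-factor, rescue normalization, hit calling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from phenoscreen.screen_stats import (
    assay_qc, call_hits, determine_mtc, group_size_zfactor, plate_capacity,
    rescue_percent, target_class_summary, z_factor,
)
from phenoscreen.synthetic_data import ScreenSpec, simulate_screen


class TestZFactor:
    def test_noiseless_limit(self):
        assert z_factor([1.0, 1.0], [0.0, 0.0]) == 1.0

    def test_textbook_evaluation(self):
        # means 100 and 0, sample SDs 10 each: Z' = 1 - 60/100 = 0.4
        pos = [90.0, 100.0, 110.0]
        neg = [-10.0, 0.0, 10.0]
        assert z_factor(pos, neg) == pytest.approx(0.4)

    def test_symmetric_in_arm_labels(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(1, 0.3, 20), rng.normal(0, 0.3, 20)
        assert z_factor(a, b) == pytest.approx(z_factor(b, a))

    def test_equal_means_undefined(self):
        assert np.isnan(z_factor([1.0, 1.0], [1.0, 1.0]))

    def test_never_exceeds_one(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = rng.normal(rng.uniform(-5, 5), rng.uniform(0.01, 2), 10)
            b = rng.normal(rng.uniform(-5, 5), rng.uniform(0.01, 2), 10)
            z = z_factor(a, b)
            assert np.isnan(z) or z <= 1.0

    @settings(derandomize=True, max_examples=25)
    @given(shift=st.floats(-50, 50), scale=st.floats(0.1, 10))
    def test_affine_invariance(self, shift, scale):
        rng = np.random.default_rng(3)
        a, b = rng.normal(2, 0.5, 16), rng.normal(0, 0.5, 16)
        z0 = z_factor(a, b)
        z1 = z_factor(scale * a + shift, scale * b + shift)
        assert z1 == pytest.approx(z0, rel=1e-9)


class TestGroupSizeZFactor:
    def test_zero_variance_arms(self):
        pos, neg = np.full(32, 5.0), np.zeros(32)
        curve = group_size_zfactor(pos, neg, [2, 4, 8], 10, seed=0)
        for size in (2, 4, 8):
            assert np.all(curve.zprime_values[size] == 1.0)

    def test_size_one_single_grouping_equals_raw(self):
        rng = np.random.default_rng(4)
        pos, neg = rng.normal(1, 0.4, 24), rng.normal(0, 0.4, 24)
        curve = group_size_zfactor(pos, neg, [1], 1, seed=0)
        assert curve.zprime_values[1][0] == pytest.approx(z_factor(pos, neg))

    def test_monotone_increase_with_group_size(self):
        """Overlapping arms: mean Z' strictly increases across sizes
        2, 4, 8, 16 (group-mean SD shrinks as 1/sqrt(size))."""
        rng = np.random.default_rng(5)
        pos = rng.normal(1.0, 0.35, 800)
        neg = rng.normal(0.0, 0.35, 800)
        assert z_factor(pos, neg) < 0
        curve = group_size_zfactor(pos, neg, [2, 4, 8, 16], 100, seed=1)
        means = [curve.mean[s] for s in (2, 4, 8, 16)]
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_matches_closed_form_at_low_noise(self):
        """Mean Z' over groupings within 10% of
        1 - 3(sd_p + sd_n)/(sqrt(g)|mean diff|)."""
        rng = np.random.default_rng(6)
        sd, delta = 5.0, 100.0
        pos = rng.normal(delta, sd, 800)
        neg = rng.normal(0.0, sd, 800)
        curve = group_size_zfactor(pos, neg, [2, 4, 8, 16], 100, seed=2)
        for g in (2, 4, 8, 16):
            closed = 1 - 3 * 2 * sd / (np.sqrt(g) * delta)
            assert curve.mean[g] == pytest.approx(closed, abs=0.1 * (1 - closed) + 0.01)

    def test_oversized_groups_skipped_with_warning(self):
        rng = np.random.default_rng(7)
        pos, neg = rng.normal(1, 0.1, 10), rng.normal(0, 0.1, 10)
        with pytest.warns(UserWarning):
            curve = group_size_zfactor(pos, neg, [2, 8], 5, seed=0)
        assert curve.group_sizes == [2]

    def test_group_of_twelve_positive_on_assay_like_arms(self, default_screen):
        """At the assay's group size the screening window is positive
        even though single-fish arms overlap."""
        tau, sib = default_screen.plate_controls["plate000"]
        rng = np.random.default_rng(8)
        # replicate-size arms: pool several plates' controls
        taus = np.concatenate([v[0] for v in
                               default_screen.plate_controls.values()])
        sibs = np.concatenate([v[1] for v in
                               default_screen.plate_controls.values()])
        assert z_factor(sibs, taus) < 0.5  # single fish: weak assay
        curve = group_size_zfactor(sibs, taus, [12], 100, seed=3)
        assert curve.mean[12] > 0


class TestRescuePercent:
    def test_tau_anchor_zero(self):
        assert rescue_percent(0.2, 0.2, 1.3) == 0.0

    def test_sibling_anchor_hundred(self):
        assert rescue_percent(1.3, 0.2, 1.3) == 100.0

    def test_midpoint_fifty(self):
        assert rescue_percent(0.75, 0.2, 1.3) == pytest.approx(50.0)

    def test_degenerate_window_rejected(self):
        with pytest.raises(ValueError):
            rescue_percent(0.5, 0.7, 0.7)

    @settings(derandomize=True, max_examples=50)
    @given(tau=st.floats(-10, 10), width=st.floats(0.01, 20),
           r=st.floats(-1, 2))
    def test_linearity_property(self, tau, width, r):
        """rescue is exactly linear in the endpoint for any window."""
        sib = tau + width
        x = tau + r * width
        assert rescue_percent(x, tau, sib) == pytest.approx(100 * r,
                                                            abs=1e-6)


class TestCallHits:
    def test_identical_rescues_no_hits(self):
        spec = ScreenSpec(n_compounds=12, planted_hits=(),
                          null_noise_sd=0.25)
        screen = simulate_screen(spec, seed=40)
        for c in screen.compounds:
            c.fish_endpoints = np.full(12, 0.5)
        result = call_hits(screen)
        assert result.library_sd >= 0
        assert result.hits == []

    def test_planted_hits_recovered(self, default_screen):
        result = call_hits(default_screen)
        assert set(result.hits) == set(default_screen.meta["planted_hits"])

    def test_hit_set_self_consistency(self, default_screen):
        """Recomputing hits from the emitted rescue table and threshold
        reproduces the hit list exactly."""
        result = call_hits(default_screen)
        recomputed = [cid for cid, r in zip(result.compound_ids,
                                            result.rescue_percent)
                      if r > result.hit_threshold]
        assert recomputed == result.hits
        assert result.hit_threshold == pytest.approx(
            result.library_mean + 3 * result.library_sd)

    def test_perfect_rescue_zero_noise_is_exactly_100(self):
        spec = ScreenSpec(n_compounds=6, planted_hits=((0, 1.0),),
                          null_noise_sd=0.0)
        screen = simulate_screen(spec, seed=41)
        result = call_hits(screen)
        assert result.rescue_percent[0] == pytest.approx(100.0)
        assert result.rescue_percent[1:] == pytest.approx(0.0)

    def test_null_hit_rate_controlled(self):
        """Mean hit count over 200 null screens consistent with the
        normal 3-SD tail."""
        counts = []
        for s in range(200):
            screen = simulate_screen(ScreenSpec(planted_hits=()),
                                     seed=5000 + s)
            counts.append(len(call_hits(screen).hits))
        expected = 147 * (1 - stats.norm.cdf(3))
        se = np.sqrt(expected / 200)  # Poisson-ish SE of the mean count
        assert np.mean(counts) <= expected + 3 * se + 0.05

    def test_too_few_compounds_rejected(self):
        screen = simulate_screen(ScreenSpec(n_compounds=2, planted_hits=()),
                                 seed=0)
        with pytest.raises(ValueError):
            call_hits(screen)


class TestTargetClassSummary:
    def test_symmetric_class_nonsignificant(self):
        rescues = [-20.0, -10.0, 0.0, 10.0, 20.0]
        out = target_class_summary(rescues, ["A"] * 5)
        assert out["A"]["mean"] == pytest.approx(0.0)
        assert out["A"]["p_value"] > 0.5

    def test_strong_positive_class_significant(self):
        rescues = [19.0, 20.0, 21.0, 20.0, 20.0]
        out = target_class_summary(rescues, ["B"] * 5)
        expected = stats.ttest_1samp(rescues, 0.0).pvalue
        assert out["B"]["p_value"] == pytest.approx(expected)
        assert out["B"]["p_value"] < 0.001

    def test_singleton_class_no_pvalue(self):
        out = target_class_summary([5.0, 1.0, 2.0], ["X", "Y", "Y"])
        assert np.isnan(out["X"]["p_value"])
        assert not np.isnan(out["Y"]["p_value"])

    def test_empty_label_excluded(self):
        with pytest.warns(UserWarning):
            out = target_class_summary([1.0, 2.0], ["", "C"])
        assert list(out) == ["C"]


class TestDetermineMTC:
    def test_tolerated_at_top(self):
        table = determine_mtc({"a": [(50.0, True)]})
        assert table.mtc_uM[0] == 50.0 and table.usable[0]

    def test_ladder_walk(self):
        obs = {"b": [(50.0, False), (25.0, False), (10.0, True)]}
        table = determine_mtc(obs)
        assert table.mtc_uM[0] == 10.0

    def test_intolerant_everywhere_flagged(self):
        obs = {"c": [(c, False) for c in (50.0, 25.0, 10.0, 5.0, 2.0,
                                          1.0, 0.5)]}
        table = determine_mtc(obs)
        assert not table.usable[0] and np.isnan(table.mtc_uM[0])

    def test_inconsistent_observations_rejected(self):
        with pytest.raises(ValueError):
            determine_mtc({"d": [(50.0, True), (25.0, False)]})

    def test_off_ladder_concentration_rejected(self):
        with pytest.raises(ValueError):
            determine_mtc({"e": [(33.0, True)]})


class TestPlateCapacity:
    def test_standard_layout(self):
        assert plate_capacity(96, 12, 2) == 6

    def test_no_room_rejected(self):
        with pytest.raises(ValueError):
            plate_capacity(96, 48, 2)

    def test_arithmetic(self):
        assert plate_capacity(96, 8, 2) == 10

    def test_indivisible_group_rejected(self):
        with pytest.raises(ValueError):
            plate_capacity(96, 10, 2)


class TestAssayQC:
    def test_inverted_window_fails(self):
        ok, reasons = assay_qc([1.0] * 12, [0.5] * 12)
        assert not ok and any("inverted" in r for r in reasons)

    def test_empty_groups_fail(self):
        ok, reasons = assay_qc([], [])
        assert not ok

    def test_simulator_plates_pass(self):
        """Plates from the default generator pass QC in >= 99/100
        seeds."""
        passes = 0
        for s in range(100):
            screen = simulate_screen(ScreenSpec(n_compounds=6,
                                                planted_hits=()),
                                     seed=7000 + s)
            tau, sib = screen.plate_controls["plate000"]
            passes += assay_qc(tau, sib)[0]
        assert passes >= 99
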