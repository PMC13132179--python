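"""Bootstrap ratio statistics, recovery-mode classification and group tests."""

import numpy as np
import pytest

from frapmorph import (
    BeamProfile,
    BootstrapRatio,
    analyze_two_beam_experiment,
    beam_area_ratio,
    bootstrap_p_vs_replicates,
    bootstrap_p_vs_value,
    classify_recovery_mode,
    compare_groups,
    ratio_test,
    tau_ratio,
)


class TestBeamAreaRatio:
    def test_printed_radii_give_published_area_ratio(self, beam_small, beam_large):
        res = beam_area_ratio(beam_large, beam_small, seed=0)
        assert res.ratio == pytest.approx((1.17 / 0.77) ** 2, abs=1e-9)
        assert res.ratio == pytest.approx(2.309, abs=1e-3)

    def test_identical_profiles_give_unit_ratio(self):
        b = BeamProfile.from_replicates("x", [1.0, 1.0, 1.0, 1.0])
        res = beam_area_ratio(b, b, seed=1)
        assert res.ratio == 1.0
        assert res.sd == pytest.approx(0.0, abs=1e-12)

    def test_bootstrap_sd_matches_delta_method(self, beams_with_replicates):
        large, small = beams_with_replicates
        res = beam_area_ratio(large, small, n_boot=2000, seed=7)
        a = np.asarray(large.omega_replicates)
        b = np.asarray(small.omega_replicates)
        # delta method for R = (mean a / mean b)^2
        sd_delta = res.ratio * 2 * np.sqrt(
            a.var(ddof=1) / (a.size * a.mean() ** 2) + b.var(ddof=1) / (b.size * b.mean() ** 2)
        )
        assert res.sd == pytest.approx(sd_delta, rel=0.30)

    def test_requires_minimum_bootstrap_size(self, beam_small, beam_large):
        with pytest.raises(ValueError):
            beam_area_ratio(beam_large, beam_small, n_boot=10)


def independent_bootstrap_oracle(a, b, n_boot, seed):
    """Re-implementation with a different resampling order (interleaved draws)."""
    rng = np.random.default_rng(seed)
    a, b = np.asarray(a, float), np.asarray(b, float)
    ratios = np.empty(n_boot)
    for i in range(n_boot):
        ra = rng.choice(a, size=a.size, replace=True).mean()
        rb = rng.choice(b, size=b.size, replace=True).mean()
        ratios[i] = ra / rb
    return a.mean() / b.mean(), ratios.std(ddof=1)


class TestTauRatio:
    def test_elementwise_scaling_gives_exact_ratio(self):
        base = np.array([0.3, 0.4, 0.5, 0.45, 0.35])
        res = tau_ratio(2.28 * base, base, seed=0)
        assert res.ratio == pytest.approx(2.28, abs=1e-12)

    def test_identity(self):
        base = [0.3, 0.4, 0.5]
        assert tau_ratio(base, base, seed=0).ratio == 1.0

    def test_against_independent_bootstrap_oracle(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.9, 0.1, 15)
        b = rng.normal(0.4, 0.05, 15)
        res = tau_ratio(a, b, n_boot=1000, seed=1)
        ratio_o, sd_o = independent_bootstrap_oracle(a, b, n_boot=1000, seed=99)
        assert res.ratio == pytest.approx(ratio_o, abs=1e-12)
        assert res.sd == pytest.approx(sd_o, rel=0.15)

    def test_deterministic_given_seed(self):
        a, b = [0.9, 1.0, 1.1, 0.95], [0.4, 0.45, 0.5, 0.42]
        r1 = tau_ratio(a, b, seed=5)
        r2 = tau_ratio(a, b, seed=5)
        assert r1.ratio == r2.ratio and r1.sd == r2.sd
        np.testing.assert_array_equal(r1.replicates, r2.replicates)

    def test_rejects_non_positive_taus(self):
        with pytest.raises(ValueError):
            tau_ratio([0.5, -0.1, 0.4], [0.3, 0.3, 0.3], seed=0)

    def test_rejects_tiny_groups(self):
        with pytest.raises(ValueError):
            tau_ratio([0.5, 0.4], [0.3, 0.3, 0.3], seed=0)


class TestRatioTests:
    def test_identical_replicates_give_p_one(self):
        reps = np.full(1000, 2.0)
        a = BootstrapRatio(2.0, 0.0, reps, 1000, 0)
        assert ratio_test(a, a) == 1.0

    def test_separated_distributions_give_tiny_p(self):
        rng = np.random.default_rng(0)
        a = BootstrapRatio(1.0, 0.01, rng.normal(1.0, 0.01, 1000), 1000, 0)
        b = BootstrapRatio(2.28, 0.01, rng.normal(2.28, 0.01, 1000), 1000, 0)
        assert ratio_test(a, b) < 1e-6
        assert bootstrap_p_vs_replicates(a, b) <= 2e-3

    def test_mismatched_n_boot_rejected(self):
        a = BootstrapRatio(1.0, 0.0, np.ones(1000), 1000, 0)
        b = BootstrapRatio(1.0, 0.0, np.ones(500), 500, 0)
        with pytest.raises(ValueError):
            ratio_test(a, b)

    def test_percentile_p_vs_value_centred(self):
        rng = np.random.default_rng(2)
        a = BootstrapRatio(1.0, 0.1, rng.normal(1.0, 0.1, 1000), 1000, 0)
        assert bootstrap_p_vs_value(a, 1.0) > 0.5
        assert bootstrap_p_vs_value(a, 2.28) == pytest.approx(1e-3, abs=1e-9)


class TestClassification:
    def test_ratio_at_beam_ratio_is_diffusion(self):
        assert classify_recovery_mode(p_vs_beam=0.8, p_vs_one=0.001) == "diffusion"

    def test_ratio_at_one_is_exchange(self):
        assert classify_recovery_mode(p_vs_beam=0.001, p_vs_one=0.7) == "exchange"

    def test_intermediate_tight_ratio_is_mixed(self):
        assert classify_recovery_mode(p_vs_beam=0.004, p_vs_one=0.004) == "mixed"

    def test_underpowered_is_indeterminate(self):
        assert classify_recovery_mode(p_vs_beam=0.5, p_vs_one=0.5) == "indeterminate"

    def test_end_to_end_mixed_call(self, beams_with_replicates):
        large, small = beams_with_replicates
        rng = np.random.default_rng(4)
        taus_small = rng.normal(0.40, 0.02, 15)
        taus_large = rng.normal(0.40 * 1.7, 0.03, 15)  # ratio 1.7: between 1 and 2.3
        res = analyze_two_beam_experiment(taus_large, taus_small, large, small, seed=11)
        assert res.mode_call == "mixed"
        assert 1.0 < res.tau_ratio < res.beam_ratio

    def test_analysis_is_bit_reproducible(self, beams_with_replicates):
        large, small = beams_with_replicates
        rng = np.random.default_rng(8)
        tl, ts = rng.normal(0.9, 0.05, 12), rng.normal(0.4, 0.03, 12)
        r1 = analyze_two_beam_experiment(tl, ts, large, small, seed=21)
        r2 = analyze_two_beam_experiment(tl, ts, large, small, seed=21)
        assert r1 == r2


class TestCompareGroups:
    def test_identical_groups_share_letter(self):
        g = {"a": [1.0, 1.1, 0.9, 1.0], "b": [1.0, 1.1, 0.9, 1.0]}
        res = compare_groups(g)
        assert res.letters["a"] == res.letters["b"] == "a"

    def test_separated_groups_get_distinct_letters(self):
        rng = np.random.default_rng(0)
        g = {"lo": rng.normal(1, 0.01, 20), "hi": rng.normal(2, 0.01, 20)}
        res = compare_groups(g)
        assert res.pairwise_p.loc["lo", "hi"] < 1e-6
        assert set(res.letters.values()) == {"a", "b"}

    def test_three_groups_two_equal_one_shifted(self):
        rng = np.random.default_rng(1)
        g = {
            "g1": rng.normal(1, 0.05, 15),
            "g2": rng.normal(1, 0.05, 15),
            "g3": rng.normal(3, 0.05, 15),
        }
        res = compare_groups(g)
        assert res.letters["g1"] == res.letters["g2"]
        assert res.letters["g3"] != res.letters["g1"]

    def test_matches_statsmodels_tukey(self):
        """Independent oracle: statsmodels' Tukey HSD on the same data."""
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(2)
        groups = {
            "a": rng.normal(1.0, 0.3, 12),
            "b": rng.normal(1.4, 0.3, 12),
            "c": rng.normal(1.5, 0.3, 12),
        }
        res = compare_groups(groups)
        vals = np.concatenate(list(groups.values()))
        labs = np.repeat(list(groups), [len(v) for v in groups.values()])
        sm = pairwise_tukeyhsd(vals, labs)
        sm_p = {
            tuple(sorted((g1, g2))): p
            for (g1, g2), p in zip(
                [(r[0], r[1]) for r in sm.summary().data[1:]], sm.pvalues
            )
        }
        for (g1, g2), p in sm_p.items():
            assert res.pairwise_p.loc[g1, g2] == pytest.approx(p, abs=1e-4)

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            compare_groups({"only": [1.0, 2.0]})
        with pytest.raises(ValueError):
            compare_groups({"a": [1.0], "b": [1.0, 2.0]})
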