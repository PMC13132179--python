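"""Closed-form and oracle checks of the Gaussian-beam recovery kernels."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from frapmorph import (
    BeamProfile,
    RecoveryParams,
    bleach_depth_from_K,
    bleach_depth_to_K,
    diffusion_recovery,
    exchange_recovery,
    mixed_recovery,
)


def mp_diffusion_series(t_over_tau: float, K: float, n_terms: int = 500) -> float:
    """Arbitrary-precision reference: 500-term alternating series via mpmath."""
    import mpmath as mp

    with mp.workdps(60):
        x = mp.mpf(1) + 2 * mp.mpf(t_over_tau)
        total = mp.mpf(0)
        for n in range(n_terms):
            total += (-mp.mpf(K)) ** n / mp.factorial(n) / (1 + n * x)
        return float(total)


class TestDiffusionKernel:
    def test_bleach_instant_matches_closed_form(self):
        # f_K(0) = (1 - e^-K)/K
        p = RecoveryParams(mode="diffusion", tau_D=1.0, K=1.0, R_f=1.0)
        assert diffusion_recovery(0.0, p) == pytest.approx((1 - math.exp(-1)), abs=1e-6)

    def test_full_recovery_limit(self):
        p = RecoveryParams(mode="diffusion", tau_D=1.0, K=1.0, R_f=1.0)
        assert diffusion_recovery(1e4, p) == pytest.approx(1.0, abs=1e-3)

    def test_low_bleach_limit_is_hyperbolic(self):
        # for K -> 0 the normalized recovery is (t/tau)/(1 + t/tau)
        p = RecoveryParams(mode="diffusion", tau_D=1.0, K=1e-4, R_f=1.0)
        f0 = diffusion_recovery(0.0, p)
        norm = (diffusion_recovery(1.0, p) - f0) / (1.0 - f0)
        assert norm == pytest.approx(0.5, abs=1e-3)

    def test_series_matches_high_precision_oracle_at_tau(self):
        p = RecoveryParams(mode="diffusion", tau_D=1.0, K=1.0, R_f=1.0)
        expected = mp_diffusion_series(1.0, 1.0)
        assert diffusion_recovery(1.0, p) == pytest.approx(expected, abs=1e-8)

    @pytest.mark.parametrize("K", [0.3, 0.7, 1.0, 1.6, 2.5])
    @pytest.mark.parametrize("t_over_tau", [0.0, 0.5, 1.0, 5.0, 100.0])
    def test_series_oracle_over_bleach_regime(self, K, t_over_tau):
        p = RecoveryParams(mode="diffusion", tau_D=1.0, K=K, R_f=1.0)
        expected = mp_diffusion_series(t_over_tau, K)
        assert diffusion_recovery(t_over_tau, p) == pytest.approx(expected, abs=1e-8)

    def test_rejects_negative_time_and_wrong_mode(self):
        p = RecoveryParams(mode="diffusion", tau_D=1.0)
        with pytest.raises(ValueError):
            diffusion_recovery(-0.1, p)
        pex = RecoveryParams(mode="exchange", tau_ex=1.0)
        with pytest.raises(ValueError):
            diffusion_recovery(1.0, pex)

    def test_deep_bleach_outside_regime_fails_loudly(self):
        with pytest.raises(ValueError, match="converge"):
            diffusion_recovery(0.5, RecoveryParams(mode="diffusion", tau_D=1.0, K=40.0))


class TestExchangeKernel:
    def test_no_recovery_at_bleach_instant(self):
        p = RecoveryParams(mode="exchange", tau_ex=0.5, K=1.0, R_f=0.9)
        assert exchange_recovery(0.0, p) == pytest.approx(bleach_depth_from_K(1.0))

    def test_one_tau_normalized_recovery(self):
        p = RecoveryParams(mode="exchange", tau_ex=0.5, K=1.0, R_f=1.0)
        f0 = bleach_depth_from_K(1.0)
        val = exchange_recovery(0.5, p)
        assert (val - f0) / (1 - f0) == pytest.approx(1 - math.exp(-1), abs=1e-12)

    def test_beam_size_independence(self):
        # identical parameters evaluated under either objective's metadata
        p = RecoveryParams(mode="exchange", tau_ex=0.5, K=1.0, R_f=0.85)
        t = np.linspace(0, 4, 50)
        np.testing.assert_array_equal(exchange_recovery(t, p), exchange_recovery(t, p))


class TestMixedKernel:
    t_grid = np.array([0.0, 0.2, 0.7, 1.5, 4.0])

    def test_alpha_zero_reduces_to_diffusion(self):
        pm = RecoveryParams(mode="mixed", tau_D=0.4, tau_ex=0.1, K=1.2, R_f=0.85, alpha=0.0)
        pd = RecoveryParams(mode="diffusion", tau_D=0.4, K=1.2, R_f=0.85)
        np.testing.assert_allclose(
            mixed_recovery(self.t_grid, pm), diffusion_recovery(self.t_grid, pd), atol=1e-12
        )

    def test_alpha_one_reduces_to_exchange(self):
        pm = RecoveryParams(mode="mixed", tau_D=0.4, tau_ex=0.1, K=1.2, R_f=0.85, alpha=1.0)
        pe = RecoveryParams(mode="exchange", tau_ex=0.1, K=1.2, R_f=0.85)
        np.testing.assert_allclose(
            mixed_recovery(self.t_grid, pm), exchange_recovery(self.t_grid, pe), atol=1e-12
        )

    def test_alpha_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            RecoveryParams(mode="mixed", tau_D=0.4, tau_ex=0.1, alpha=1.2)


class TestBleachDepthInversion:
    def test_unit_K_depth(self):
        assert bleach_depth_to_K(1 - math.exp(-1)) == pytest.approx(1.0, abs=1e-9)

    def test_shallow_bleach_limit(self):
        assert bleach_depth_to_K(0.9999) < 3e-4

    def test_half_depth(self):
        # bisection on (1 - e^-K)/K = 0.5 gives K = 1.5936...
        assert bleach_depth_to_K(0.5) == pytest.approx(1.59362426, abs=1e-6)

    @pytest.mark.parametrize("depth", [0.05, 0.3, 0.5, 0.7, 0.95])
    def test_round_trip(self, depth):
        assert bleach_depth_from_K(bleach_depth_to_K(depth)) == pytest.approx(depth, abs=1e-8)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.7])
    def test_rejects_out_of_range(self, bad):
        with pytest.raises(ValueError):
            bleach_depth_to_K(bad)


_params_strategy = st.fixed_dictionaries(
    {
        "K": st.floats(0.1, 3.0),
        "R_f": st.floats(0.0, 1.0),
        "tau": st.floats(0.05, 5.0),
        "alpha": st.floats(0.0, 1.0),
        "mode": st.sampled_from(["diffusion", "exchange", "mixed"]),
    }
)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(_params_strategy)
def test_recovery_kernels_monotone_and_bounded(kw):
    """Every kernel is non-decreasing in t and stays within the mobile-pool envelope."""
    p = RecoveryParams(
        mode=kw["mode"],
        tau_D=kw["tau"],
        tau_ex=kw["tau"] / 2,
        K=kw["K"],
        R_f=kw["R_f"],
        alpha=kw["alpha"],
    )
    t = np.linspace(0.0, 20.0 * kw["tau"], 200)
    from frapmorph import evaluate_recovery

    f = np.asarray(evaluate_recovery(t, p))
    f0 = bleach_depth_from_K(kw["K"])
    assert np.all(np.diff(f) >= -1e-9)
    assert np.all(f >= f0 - 1e-9)
    assert np.all(f <= (1 - kw["R_f"]) * f0 + kw["R_f"] + 1e-9)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.floats(1e-5, 1e-3), st.floats(0.1, 10.0))
def test_low_bleach_normalized_recovery_closed_form(K, t_over_tau):
    """In the K -> 0 limit the normalized diffusion recovery is t/(tau + t)."""
    p = RecoveryParams(mode="diffusion", tau_D=1.0, K=K, R_f=1.0)
    f0 = diffusion_recovery(0.0, p)
    norm = (diffusion_recovery(t_over_tau, p) - f0) / (1.0 - f0)
    assert norm == pytest.approx(t_over_tau / (1.0 + t_over_tau), abs=1e-3)


class TestBeamProfile:
    def test_replicate_mean_consistency_enforced(self):
        with pytest.raises(ValueError):
            BeamProfile(objective_label="x", omega=1.0, omega_replicates=(0.5, 0.6))

    def test_from_replicates_sets_mean_and_sd(self):
        b = BeamProfile.from_replicates("63x", [0.75, 0.77, 0.79])
        assert b.omega == pytest.approx(0.77)
        assert b.omega_sd == pytest.approx(np.std([0.75, 0.77, 0.79], ddof=1))
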