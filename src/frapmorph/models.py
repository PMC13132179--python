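"""Closed-form FRAP recovery models for a Gaussian monitoring/bleaching beam.

A focused laser with Gaussian intensity profile ``I(r) = I0 exp(-2 r^2 / omega^2)``
bleaches a spot of e^-2 radius ``omega`` and then monitors the return of
fluorescence.  Three recovery mechanisms are modelled:

* **lateral diffusion** within the membrane plane — the classic Gaussian-spot
  series solution, characteristic time ``tau_D = omega^2 / (4 D)``;
* **exchange** of bleached membrane-bound molecules with an unbleached
  cytoplasmic pool — a single exponential with time ``tau_ex``, independent of
  the beam size;
* a **mixed** mode, the convex combination of the two normalized kernels over
  the mobile pool.

All model curves are expressed relative to the pre-bleach fluorescence (= 1).
The dimensionless bleach parameter ``K`` sets the bleach depth through
``F(0) = (1 - exp(-K)) / K``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "BeamProfile",
    "RecoveryParams",
    "FrapCurve",
    "diffusion_recovery",
    "exchange_recovery",
    "mixed_recovery",
    "bleach_depth_to_K",
    "bleach_depth_from_K",
]

#: series truncation: stop when the next term's magnitude drops below this
_SERIES_TOL = 1e-10
#: hard cap on the number of series terms; K beyond ~5 is outside the
#: modelled bleach regime and the bound will not be reached
_SERIES_NMAX = 60


@dataclass(frozen=True)
class BeamProfile:
    """An objective's Gaussian beam: e^-2 intensity radius with replicates.

    Parameters
    ----------
    objective_label
        Free-text label, e.g. ``"40x"`` or ``"63x"``.
    omega
        Gaussian radius in micrometres.
    omega_replicates
        Optional per-measurement radii (μm) used for ratio bootstraps.
    omega_sd
        Standard deviation of the radius measurements (μm).
    """

    objective_label: str
    omega: float
    omega_replicates: tuple[float, ...] = ()
    omega_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (self.omega > 0 and math.isfinite(self.omega)):
            raise ValueError(f"omega must be positive and finite, got {self.omega}")
        if self.omega_sd < 0:
            raise ValueError("omega_sd must be non-negative")
        if self.omega_replicates:
            object.__setattr__(self, "omega_replicates", tuple(float(w) for w in self.omega_replicates))
            if any(w <= 0 for w in self.omega_replicates):
                raise ValueError("omega replicates must be positive")
            if abs(float(np.mean(self.omega_replicates)) - self.omega) > 1e-9:
                raise ValueError("omega must equal the mean of its replicates")

    @classmethod
    def from_replicates(cls, objective_label: str, replicates: Sequence[float]) -> "BeamProfile":
        reps = tuple(float(w) for w in replicates)
        return cls(
            objective_label=objective_label,
            omega=float(np.mean(reps)),
            omega_replicates=reps,
            omega_sd=float(np.std(reps, ddof=1)) if len(reps) > 1 else 0.0,
        )

    @property
    def area(self) -> float:
        """ω², the beam-area proxy used in beam-size ratios (μm²)."""
        return self.omega**2


RecoveryMode = Literal["diffusion", "exchange", "mixed"]


@dataclass(frozen=True)
class RecoveryParams:
    """Ground-truth / fitted parameters of a recovery kernel.

    ``tau_D`` is the characteristic diffusion time ω²/4D (s), ``tau_ex`` the
    characteristic membrane–cytoplasm exchange time (s), ``K`` the
    dimensionless bleach-depth parameter, ``R_f`` the mobile fraction and
    ``alpha`` the exchange weight of the mixed mode (0 = pure diffusion,
    1 = pure exchange).
    """

    mode: RecoveryMode
    tau_D: float | None = None
    tau_ex: float | None = None
    K: float = 1.0
    R_f: float = 1.0
    alpha: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("diffusion", "exchange", "mixed"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode in ("diffusion", "mixed"):
            if self.tau_D is None or self.tau_D <= 0:
                raise ValueError("tau_D must be positive for diffusion/mixed mode")
        if self.mode in ("exchange", "mixed"):
            if self.tau_ex is None or self.tau_ex <= 0:
                raise ValueError("tau_ex must be positive for exchange/mixed mode")
        if not self.K > 0:
            raise ValueError("K must be positive")
        if not 0.0 <= self.R_f <= 1.0:
            raise ValueError("R_f must lie in [0, 1]")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")


@dataclass(frozen=True)
class FrapCurve:
    """One cell's bleach-and-recovery time series with beam metadata.

    ``times`` start at t = 0 (first post-bleach sample) and are strictly
    increasing; ``intensities`` are raw fluorescence values in the same
    (arbitrary) units as ``prebleach_level``.
    """

    times: np.ndarray
    intensities: np.ndarray
    prebleach_level: float
    beam: BeamProfile
    cell_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", y)
        if t.ndim != 1 or y.ndim != 1 or t.shape != y.shape:
            raise ValueError("times and intensities must be 1-D arrays of equal length")
        if t.size < 10:
            raise ValueError("need at least 10 post-bleach samples")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not self.prebleach_level > 0:
            raise ValueError("prebleach_level must be positive")
        if np.any(y < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def normalized(self) -> np.ndarray:
        """Intensities relative to the pre-bleach level (= 1)."""
        return self.intensities / self.prebleach_level


def _as_time_array(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("time values must be finite")
    if np.any(t < 0):
        raise ValueError("time values must be non-negative")
    return t


def _diffusion_series(t_over_tau: np.ndarray, K: float) -> np.ndarray:
    """Gaussian-spot lateral-diffusion series f_K(t).

    f_K(t) = sum_{n>=0} (-K)^n / n! * 1 / (1 + n (1 + 2 t / tau_D)).

    Truncated when the next term's magnitude falls below 1e-10; raises if the
    bound is not reached within 60 terms (deep-bleach regime K >~ 5 is outside
    the modelled range).
    """
    x = 1.0 + 2.0 * t_over_tau  # >= 1
    total = np.ones_like(x)  # n = 0 term
    coef = 1.0
    for n in range(1, _SERIES_NMAX + 1):
        coef *= -K / n
        term = coef / (1.0 + n * x)
        total += term
        # |terms| decrease with x fixed; the max over t bounds the remainder
        if np.max(np.abs(term)) < _SERIES_TOL:
            return total
    raise ValueError(
        f"diffusion series did not converge to {_SERIES_TOL:g} within "
        f"{_SERIES_NMAX} terms (K={K:g} too large?)"
    )


def bleach_depth_from_K(K: float) -> float:
    """Forward map: first post-bleach fractional fluorescence F(0) = (1-e^-K)/K."""
    if not K > 0:
        raise ValueError("K must be positive")
    return float(-math.expm1(-K) / K)


def bleach_depth_to_K(depth_ratio: float) -> float:
    """Invert F(0)/F_pre = (1 - e^-K)/K for the bleach parameter K.

    ``depth_ratio`` is the fraction of fluorescence *remaining* immediately
    after the bleach pulse (e.g. a 60% bleach gives depth_ratio = 0.4).
    """
    if not 0.0 < depth_ratio < 1.0:
        raise ValueError(f"depth_ratio must lie strictly in (0, 1), got {depth_ratio}")
    # (1-e^-K)/K decreases from 1 (K->0) to 0 (K->inf)
    lo, hi = 1e-12, 1.0
    while bleach_depth_from_K(hi) > depth_ratio:
        hi *= 2.0
        if hi > 1e6:  # pragma: no cover - unreachable for depth_ratio > 0
            raise RuntimeError("bracketing failed")
    return float(brentq(lambda k: bleach_depth_from_K(k) - depth_ratio, lo, hi, xtol=1e-12))


def diffusion_recovery(t, params: RecoveryParams) -> np.ndarray:
    """Fractional fluorescence F(t) for recovery by pure lateral diffusion.

    The mobile-fraction envelope is applied as
    ``F(t) = (1 - R_f) f_K(0) + R_f f_K(t)`` so that F(0) equals the bleach
    depth and F(∞) -> (1 - R_f) f_K(0) + R_f.
    """
    if params.mode != "diffusion":
        raise ValueError("params.mode must be 'diffusion'")
    t = _as_time_array(t)
    fk = _diffusion_series(t / params.tau_D, params.K)
    f0 = bleach_depth_from_K(params.K)
    out = (1.0 - params.R_f) * f0 + params.R_f * fk
    return out if out.ndim else float(out)


def exchange_recovery(t, params: RecoveryParams) -> np.ndarray:
    """Fractional fluorescence for recovery by membrane–cytoplasm exchange.

    ``F(t) = F(0) + R_f (1 - F(0)) (1 - exp(-t/tau_ex))`` with
    ``F(0) = (1 - e^-K)/K``; independent of the beam size by construction.
    """
    if params.mode != "exchange":
        raise ValueError("params.mode must be 'exchange'")
    t = _as_time_array(t)
    f0 = bleach_depth_from_K(params.K)
    out = f0 + params.R_f * (1.0 - f0) * -np.expm1(-t / params.tau_ex)
    return out if out.ndim else float(out)


def mixed_recovery(t, params: RecoveryParams) -> np.ndarray:
    """Convex combination of the normalized exchange and diffusion kernels.

    The mobile-pool recovery is ``alpha * g_ex(t) + (1 - alpha) * g_diff(t)``
    where each kernel g is normalized to run from 0 at t = 0 to 1 at t = ∞;
    reduces exactly to :func:`diffusion_recovery` at alpha = 0 and to
    :func:`exchange_recovery` at alpha = 1.
    """
    if params.mode != "mixed":
        raise ValueError("params.mode must be 'mixed'")
    t = _as_time_array(t)
    f0 = bleach_depth_from_K(params.K)
    g_diff = (_diffusion_series(t / params.tau_D, params.K) - f0) / (1.0 - f0)
    g_ex = -np.expm1(-t / params.tau_ex)
    g = params.alpha * g_ex + (1.0 - params.alpha) * g_diff
    out = f0 + params.R_f * (1.0 - f0) * g
    return out if out.ndim else float(out)


def evaluate_recovery(t, params: RecoveryParams) -> np.ndarray:
    """Dispatch to the kernel named by ``params.mode``."""
    fn = {
        "diffusion": diffusion_recovery,
        "exchange": exchange_recovery,
        "mixed": mixed_recovery,
    }[params.mode]
    return fn(t, params)
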