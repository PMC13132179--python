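"""Seeded generators for every input the pipeline consumes.

Three families of synthetic data make the analysis verifiable without raw
microscopy:

* **two-beam FRAP experiments** — an analytic sampler that evaluates the
  closed-form recovery kernels per cell (with cell-to-cell parameter jitter
  and acquisition noise), and an independent particle-based Monte-Carlo
  simulator (2D Brownian walkers with membrane–cytoplasm exchange under a
  Gaussian bleach/detection profile) that serves as a physical oracle for the
  analytic kernels;
* **lobed pavement-cell outlines** with known ground-truth lobe counts,
  built from a cosine-perturbed radial profile;
* **fractionation blot intensities** with known true partitioning.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import yaml
from scipy.optimize import brentq

from .models import (
    BeamProfile,
    FrapCurve,
    RecoveryParams,
    bleach_depth_to_K,
    evaluate_recovery,
)
from .shape import CellShape

__all__ = [
    "DEFAULT_BEAMS",
    "SimulationConfig",
    "simulate_frap_experiment",
    "simulate_frap_particles",
    "generate_pavement_cell",
    "generate_fractionation_blot",
]

#: the two default objectives: 63x (small spot) and 40x (large spot)
DEFAULT_BEAMS = (
    BeamProfile(objective_label="63x", omega=0.77, omega_sd=0.03),
    BeamProfile(objective_label="40x", omega=1.17, omega_sd=0.05),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Ground truth and acquisition settings for a synthetic FRAP experiment.

    Physical parameters: ``D`` is the lateral diffusion coefficient (μm²/s),
    ``k_off``/``k_on`` first-order exchange rates (s⁻¹; the analytic sampler
    collapses exchange to a single τ_ex = 1/k_off, treating the cytoplasmic
    pool as infinite and instantly mixed), ``alpha`` the exchange weight of a
    mixed-mode ground truth, ``R_f`` the mobile fraction and ``bleach_depth``
    the fraction of fluorescence removed by the pulse (0.3–0.7 regime).

    Acquisition: ``dt``/``duration`` define the sampling grid (defaults
    20 ms / 8 s resolve τ in the 0.1–2 s regime implied by typical membrane
    GTPase D values and the default beam radii); ``noise_sd`` is additive Gaussian noise as a
    fraction of the pre-bleach level; ``cell_cv`` jitters each cell's
    kinetic parameter multiplicatively.
    """

    mode: Literal["diffusion", "exchange", "mixed"] = "diffusion"
    D: float = 0.3
    k_off: float = 2.0
    k_on: float = 0.0
    alpha: float = 0.5
    R_f: float = 0.85
    bleach_depth: float = 0.6
    beams: tuple[BeamProfile, ...] = DEFAULT_BEAMS
    n_cells: int = 15
    dt: float = 0.02
    duration: float = 8.0
    noise_sd: float = 0.02
    noise_model: Literal["gaussian", "poisson"] = "gaussian"
    cell_cv: float = 0.10
    prebleach_level: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("diffusion", "exchange", "mixed"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode in ("diffusion", "mixed") and not self.D > 0:
            raise ValueError("D must be positive for diffusion/mixed ground truth")
        if self.mode in ("exchange", "mixed") and not self.k_off > 0:
            raise ValueError("k_off must be positive for exchange/mixed ground truth")
        if not 0.0 < self.bleach_depth < 1.0:
            raise ValueError("bleach_depth must lie in (0, 1)")
        if not 0.0 <= self.R_f <= 1.0:
            raise ValueError("R_f must lie in [0, 1]")
        if self.noise_sd < 0 or self.cell_cv < 0:
            raise ValueError("noise_sd and cell_cv must be non-negative")
        if not (self.dt > 0 and self.duration > 0 and self.n_cells >= 1):
            raise ValueError("invalid acquisition settings")
        if self.duration < 5.0 * self.slowest_time:
            raise ValueError(
                f"duration {self.duration} s must cover >= 5x the slowest "
                f"characteristic time ({self.slowest_time:.3g} s)"
            )

    @property
    def slowest_time(self) -> float:
        """Slowest characteristic time of the configured ground truth (s)."""
        times = []
        if self.mode in ("diffusion", "mixed"):
            omega_max = max(b.omega for b in self.beams)
            times.append(omega_max**2 / (4.0 * self.D))
        if self.mode in ("exchange", "mixed"):
            times.append(1.0 / self.k_off)
        return max(times)

    @property
    def tau_ex(self) -> float:
        """Analytic-sampler exchange time, 1/k_off (s)."""
        return 1.0 / self.k_off

    def to_yaml(self) -> str:
        d = asdict(self)
        d["beams"] = [
            {"objective_label": b.objective_label, "omega": b.omega,
             "omega_replicates": list(b.omega_replicates), "omega_sd": b.omega_sd}
            for b in self.beams
        ]
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationConfig":
        d = yaml.safe_load(text)
        d["beams"] = tuple(
            BeamProfile(
                objective_label=b["objective_label"],
                omega=b["omega"],
                omega_replicates=tuple(b.get("omega_replicates", ())),
                omega_sd=b.get("omega_sd", 0.0),
            )
            for b in d["beams"]
        )
        return cls(**d)


def _cell_params(config: SimulationConfig, beam: BeamProfile, jitter: float) -> RecoveryParams:
    """Ground-truth kernel parameters for one cell at one beam."""
    K = bleach_depth_to_K(1.0 - config.bleach_depth)
    if config.mode == "diffusion":
        d_cell = config.D * jitter
        return RecoveryParams(
            mode="diffusion", tau_D=beam.omega**2 / (4.0 * d_cell), K=K, R_f=config.R_f
        )
    if config.mode == "exchange":
        return RecoveryParams(mode="exchange", tau_ex=config.tau_ex * jitter, K=K, R_f=config.R_f)
    d_cell = config.D * jitter
    return RecoveryParams(
        mode="mixed",
        tau_D=beam.omega**2 / (4.0 * d_cell),
        tau_ex=config.tau_ex * jitter,
        K=K,
        R_f=config.R_f,
        alpha=config.alpha,
    )


def simulate_frap_experiment(config: SimulationConfig) -> dict[str, list[FrapCurve]]:
    """Analytic two-beam FRAP sampler: one noisy curve per cell per beam.

    Per cell, the configured kernel is evaluated on the acquisition grid, the
    cell's kinetic parameter (D or τ_ex) is jittered multiplicatively by a
    normal factor with CV ``cell_cv``, and acquisition noise is added.
    Identical seeds give bit-identical output.  Returns curves keyed by
    objective label.
    """
    rng = np.random.default_rng(config.seed)
    t = np.arange(0.0, config.duration + config.dt / 2, config.dt)
    out: dict[str, list[FrapCurve]] = {}
    for beam in config.beams:
        curves = []
        for i in range(config.n_cells):
            jitter = 0.0
            while jitter <= 0.1:  # reject unphysical (non-positive) jitter draws
                jitter = 1.0 + config.cell_cv * rng.standard_normal()
            params = _cell_params(config, beam, jitter)
            f = np.asarray(evaluate_recovery(t, params))
            if config.noise_model == "poisson":
                counts = rng.poisson(np.maximum(f, 0.0) / max(config.noise_sd, 1e-9) ** 2)
                y = counts * config.noise_sd**2
            else:
                y = f + config.noise_sd * rng.standard_normal(f.shape)
            y = np.maximum(y, 0.0) * config.prebleach_level
            curves.append(
                FrapCurve(
                    times=t,
                    intensities=y,
                    prebleach_level=config.prebleach_level,
                    beam=beam,
                    cell_id=f"{beam.objective_label}_cell{i:03d}",
                )
            )
        out[beam.objective_label] = curves
    return out


def _solve_bleach_amplitude(weights: np.ndarray, depth: float) -> float:
    """Find b such that the weighted survival sum hits the target depth.

    The bleach pulse leaves particle i with survival probability
    exp(-b * I(r_i)); b is chosen so that the detected fluorescence drops to
    (1 - depth) of its pre-bleach value.
    """
    target = 1.0 - depth
    wsum = weights.sum()

    def drop(b: float) -> float:
        return float(np.sum(weights * np.exp(-b * weights)) / wsum) - target

    hi = 1.0
    while drop(hi) > 0:
        hi *= 2.0
        if hi > 1e4:
            raise RuntimeError("cannot reach requested bleach depth")
    return float(brentq(drop, 0.0, hi, xtol=1e-10))


def simulate_frap_particles(
    config: SimulationConfig,
    beam: BeamProfile | None = None,
    n_particles: int = 20_000,
    domain_size: float | None = None,
    n_repeats: int = 1,
) -> FrapCurve:
    """Particle-based Monte-Carlo FRAP oracle, independent of the kernels.

    2D Brownian walkers (per-axis step SD √(2·D·dt)) move on a periodic
    square domain at least 12ω across.  Membrane→cytoplasm exchange occurs
    at rate ``k_off``; a detached walker is replaced by a fresh unbleached
    walker at a uniform random position (the cytoplasmic pool is treated as
    infinite and well mixed, matching the analytic sampler's τ_ex = 1/k_off).
    The bleach pulse multiplies each walker's fluorescence weight by its
    survival probability exp(-b·I(r)) under the Gaussian profile
    I(r) = exp(-2r²/ω²), with b solved to reach the configured depth;
    detection is the Gaussian-weighted sum of membrane-resident fluorescence.
    An immobile fraction (1 - R_f) of walkers neither moves nor exchanges.

    ``n_repeats`` > 1 simulates that many independent particle fields (with
    seeds spawned from ``config.seed``) and sums their detected signals —
    the Monte-Carlo analogue of measuring several cells — which reduces the
    configuration noise by √n without any spot–spot crosstalk.
    """
    beam = beam or config.beams[0]
    if n_repeats > 1:
        children = np.random.SeedSequence(config.seed).spawn(n_repeats)
        traces = []
        prebleach = 0.0
        times = None
        for child in children:
            sub_seed = int(child.generate_state(1)[0] % (2**31))
            sub = replace(config, seed=sub_seed)
            c = simulate_frap_particles(sub, beam=beam, n_particles=n_particles,
                                        domain_size=domain_size, n_repeats=1)
            traces.append(c.intensities)
            prebleach += c.prebleach_level
            times = c.times
        return FrapCurve(
            times=times,
            intensities=np.sum(traces, axis=0),
            prebleach_level=prebleach,
            beam=beam,
            cell_id=f"particles_{beam.objective_label}_x{n_repeats}",
        )
    if n_particles < 10_000:
        raise ValueError("particle count must be at least 10,000")
    L = domain_size if domain_size is not None else 12.0 * beam.omega
    if L < 12.0 * beam.omega:
        raise ValueError(
            f"domain {L:.2f} μm too small relative to ω = {beam.omega} μm "
            "(needs >= 12ω to avoid boundary re-entry artifacts)"
        )
    rng = np.random.default_rng(config.seed)
    diffusing = config.mode in ("diffusion", "mixed")
    exchanging = config.mode in ("exchange", "mixed")
    D = config.D if diffusing else 0.0
    k_off = config.k_off if exchanging else 0.0

    pos = rng.uniform(-L / 2, L / 2, size=(n_particles, 2))
    mobile = rng.random(n_particles) < config.R_f

    def det_weights(p: np.ndarray) -> np.ndarray:
        r2 = p[:, 0] ** 2 + p[:, 1] ** 2
        return np.exp(-2.0 * r2 / beam.omega**2)

    w0 = det_weights(pos)
    prebleach = float(w0.sum())
    if config.bleach_depth > 0:
        b = _solve_bleach_amplitude(w0, config.bleach_depth)
        fluor = np.exp(-b * w0)  # survival probability as fluorescence weight
    else:
        fluor = np.ones(n_particles)

    dt = config.dt
    n_steps = int(round(config.duration / dt))
    step_sd = math.sqrt(2.0 * D * dt)
    p_off = -math.expm1(-k_off * dt)
    trace = np.empty(n_steps + 1)
    trace[0] = float(np.sum(det_weights(pos) * fluor))
    for s in range(1, n_steps + 1):
        if step_sd > 0:
            pos[mobile] += step_sd * rng.standard_normal((int(mobile.sum()), 2))
            pos = (pos + L / 2) % L - L / 2
        if p_off > 0:
            swap = mobile & (rng.random(n_particles) < p_off)
            n_swap = int(swap.sum())
            if n_swap:
                pos[swap] = rng.uniform(-L / 2, L / 2, size=(n_swap, 2))
                fluor[swap] = 1.0  # arrivals from the unbleached pool
        trace[s] = float(np.sum(det_weights(pos) * fluor))

    times = np.arange(n_steps + 1) * dt
    return FrapCurve(
        times=times,
        intensities=trace,
        prebleach_level=prebleach,
        beam=beam,
        cell_id=f"particles_{beam.objective_label}",
    )


def _smooth_periodic_noise(theta: np.ndarray, exclude: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD smooth periodic noise from low-order Fourier modes.

    The mode equal to ``exclude`` (the lobe order) is left out so roughness
    cannot systematically add or cancel lobes.
    """
    modes = [m for m in range(2, 9) if m != exclude]
    amp = rng.standard_normal(len(modes))
    phase = rng.uniform(0, 2 * math.pi, len(modes))
    eta = np.zeros_like(theta)
    for a, m, ph in zip(amp, modes, phase):
        eta += a * np.cos(m * theta + ph)
    sd = eta.std()
    return eta / sd if sd > 0 else eta


def generate_pavement_cell(
    n_lobes: int,
    amplitude: float = 0.3,
    base_radius: float = 20.0,
    roughness: float = 0.0,
    seed: int = 0,
    n_vertices: int = 360,
) -> CellShape:
    """Synthetic lobed pavement-cell outline with known lobe count.

    The boundary is the radial profile
    ``r(θ) = R (1 + amplitude·cos(n_lobes·θ) + roughness·η(θ))`` with η a
    seeded smooth periodic noise; amplitude 0 gives a circle.  The true lobe
    count is attached to the returned shape.
    """
    if n_lobes < 0:
        raise ValueError("n_lobes must be non-negative")
    if not 0.0 <= amplitude < 1.0:
        raise ValueError("amplitude must lie in [0, 1)")
    if n_vertices < 360:
        raise ValueError("need at least 360 vertices")
    rng = np.random.default_rng(seed)
    theta = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    r = 1.0 + amplitude * np.cos(n_lobes * theta)
    if roughness > 0:
        r = r + roughness * _smooth_periodic_noise(theta, n_lobes, rng)
    if np.any(r <= 0.05):
        raise ValueError("parameters produce a self-intersecting (non-star-shaped) outline")
    r = base_radius * r
    boundary = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    return CellShape(
        boundary=boundary,
        genotype_label="",
        cell_id=f"synthetic_lobes{n_lobes}_seed{seed}",
        true_lobe_count=n_lobes,
    )


def generate_fractionation_blot(
    true_fractions: Mapping[str, float],
    total_intensity: float = 1000.0,
    noise_cv: float = 0.05,
    seed: int = 0,
) -> dict[str, float]:
    """Synthetic blot intensities for a known true partitioning.

    ``true_fractions`` maps Cyt/TSM/TIM to fractions of total summing to at
    most 1.  Each band (and the total lane) gets independent multiplicative
    noise with coefficient of variation ``noise_cv``; seeded.
    """
    from .fractionation import FRACTION_KEYS

    missing = [k for k in FRACTION_KEYS if k not in true_fractions]
    if missing:
        raise ValueError(f"missing fraction keys: {missing}")
    fracs = {k: float(true_fractions[k]) for k in FRACTION_KEYS}
    if any(v < 0 for v in fracs.values()):
        raise ValueError("fractions must be non-negative")
    if sum(fracs.values()) > 1.0 + 1e-9:
        raise ValueError("fractions must sum to at most 1")
    if total_intensity <= 0 or noise_cv < 0:
        raise ValueError("total_intensity must be positive and noise_cv non-negative")
    rng = np.random.default_rng(seed)
    out = {"Tot": total_intensity * max(1.0 + noise_cv * rng.standard_normal(), 0.0)}
    for k in FRACTION_KEYS:
        out[k] = total_intensity * fracs[k] * max(1.0 + noise_cv * rng.standard_normal(), 0.0)
    return out
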