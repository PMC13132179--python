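# Methods

## Recovery models

All model curves are expressed relative to the pre-bleach fluorescence
(= 1), with t = 0 at the first post-bleach sample; the bleach pulse
(milliseconds in the emulated setup) is treated as instantaneous because it
is far shorter than any fitted τ.

**Lateral diffusion.** For a Gaussian bleach/monitoring profile
`I(r) ∝ exp(−2r²/ω²)` the recovery of a uniformly diffusing membrane
species is the alternating series

    f_K(t) = Σ_{n=0..N} (−K)ⁿ/n! · 1/(1 + n(1 + 2t/τ_D)),   τ_D = ω²/4D,

where the dimensionless bleach parameter K fixes the bleach depth via
`f_K(0) = (1 − e^−K)/K`. The series is truncated when the next term's
magnitude falls below 1e−10, with a hard cap of 60 terms; if the bound is
not reached the evaluation fails loudly rather than returning a silently
truncated value (this only happens for K ≳ 5, far deeper than the 30–70%
bleach regime the model is used in). The implementation is verified against
a 500-term arbitrary-precision summation to 1e−8 over K ∈ [0.3, 2.5] and
t/τ_D ∈ [0, 100], and against the closed-form low-bleach limit
`(t/τ_D)/(1 + t/τ_D)`.

**Exchange.** Replacement of bleached membrane-bound molecules from a large,
well-mixed cytoplasmic pool gives a single exponential,
`F(t) = F(0) + R_f(1 − F(0))(1 − e^{−t/τ_ex})`, independent of ω.

**Mixed mode.** The mobile-pool recovery is the convex combination
`α·g_ex + (1 − α)·g_diff` of the two kernels, each normalized to run from 0
to 1. The microscopic coupling between diffusion and exchange is not
modelled; the combination is chosen because it has exact degenerate limits
at α = 0 and α = 1 and reproduces the intermediate τ-ratio phenomenology
(the fitted ratio moves monotonically from the beam-area ratio toward 1 as
α grows, which the test suite checks). A partial immobile fraction enters
every kernel as `F = (1 − R_f)·F(0) + R_f·F_mobile`.

## Curve fitting

Raw intensities are divided by the pre-bleach level, and (τ, R_f, K) are
estimated by bounded least squares (scipy trust-region reflective) on the
single-τ diffusion form. Initialization is scale-free: τ₀ is the empirical
half-time between F(0) and the plateau (mean of the last 10% of samples),
R_f⁰ the plateau-based mobile fraction. Bounds: τ ∈ [dt/10, 100·t_max],
R_f ∈ [0, 1.05] (headroom for noise above the physical bound), K ∈
[1e−3, 5]. A fit that hits the iteration limit or pins τ at a bound is
flagged `converged=False` rather than raising; fits with R_f < 0.05 are
additionally flagged unusable so that essentially immobile cells do not
enter ratio statistics. Noiseless round trips recover τ_D and R_f to well
under 0.5% across D ∈ {0.1, 0.2, 0.37, 1.0} μm²/s and both beam radii.

**K policy.** By default K is co-fit with τ and R_f (`k_policy="free"`).
The alternative `"fixed_from_depth"` inverts `F(0) = (1 − e^−K)/K` from the
observed first post-bleach sample and fits only (τ, R_f); it is cheaper,
but with 2% acquisition noise the single first sample propagates into τ
(per-curve τ SD roughly doubles, ~9.5% vs ~5%, with a small downward bias,
measured on 40 simulated replicates), so the co-fit is the default and the
fixed variant is kept for sensitivity checks.

## Beam-size ratio statistics

Cells are measured with one objective each (unpaired design), so the τ
ratio is the ratio of group means, not a mean of per-cell ratios. Bootstrap
(default 1000 replicates, matching the standard practice for ratio
statistics) resamples the two groups independently with replacement,
preserving group sizes; the beam-area ratio is bootstrapped the same way
from the per-measurement radius replicates, squaring the resampled mean
radii. Whether radius and τ sets should be resampled jointly is not
determined by the emulated protocol; independent resampling is implemented.
All resampling is driven by `numpy.random.default_rng(seed)` and is
bit-reproducible.

Two significance procedures are provided. `ratio_test` is the literal
two-tailed Welch t-test between the two bootstrap replicate vectors; with
~1000 replicates this treats Monte-Carlo resamples as observations and is
strongly anti-conservative, so the default classification instead uses
bootstrap percentile p-values: against a fixed reference,
`p = 2·min(P(rep ≤ ref), P(rep ≥ ref))`; against a second bootstrapped
ratio, the same tail probability on the replicate-difference distribution.
p-values are floored at 1/n_boot. The mode call at level α (default 0.05):
*diffusion* if indistinguishable from the beam-area ratio (but distinct
from 1), *exchange* if indistinguishable from 1 (but distinct from the beam
ratio), *mixed* if distinct from both, *indeterminate* if distinct from
neither. Under a simulated pure-diffusion null (15 cells/objective, 2%
noise) the classifier returns *diffusion* in ≥ 90 of 100 seeded runs.

Group comparisons use one-way ANOVA (`scipy.stats.f_oneway`) followed by
Tukey's HSD (`scipy.stats.tukey_hsd`, whose studentized-range quantiles are
computed numerically, so any group count works; cross-checked against
statsmodels in the tests) and an insert-and-absorb compact letter display.

## Synthetic data

**Analytic sampler.** Per cell, the configured kernel is evaluated on a
dt = 20 ms grid over 8 s (resolving τ in the 0.1–2 s regime implied by
D ≈ 0.2–0.4 μm²/s at ω = 0.77–1.17 μm); defaults: 60% bleach depth (within
the emulated 50–70% range), R_f = 0.85 (middle of the typical 0.80–0.90
band), 15 cells per objective, additive Gaussian acquisition noise of 2% of
the pre-bleach level (Poisson counting noise available), and a 10%
multiplicative cell-to-cell jitter of the kinetic parameter. Exchange
collapses to a single τ_ex = 1/k_off: the cytoplasmic pool is treated as
infinite, unbleached and instantly mixed.

**Particle oracle.** An independent physical check that shares no code with
the kernels: ≥ 10⁴ Brownian walkers (per-axis step SD √(2DΔt)) on a
periodic square domain ≥ 12ω across (smaller domains are refused — bleached
walkers would re-enter the spot too quickly), first-order membrane→cytoplasm
exchange in which a detached walker is replaced by a fresh unbleached walker
at a uniform position (the same infinite-pool limit as the sampler), bleach
survival probability `exp(−b·I(r))` with b solved numerically to hit the
configured depth (the survival probability is carried as a continuous
fluorescence weight — a variance-reduction device), and Gaussian-weighted
detection of membrane-resident fluorescence. `n_repeats` sums several
independent fields (seeds spawned from the master seed) — the Monte-Carlo
analogue of measuring several cells — because the dominant error is
configuration noise (~1/√(ρπω²) relative, ρ the areal density). With
60,000 walkers × 10 fields the fitted D lands within 10% of the input over
D ∈ {0.1, 0.37, 1.0} μm²/s; residual systematics (≲2%) come from the
finite domain, where the bleached population dilutes into a finite rather
than infinite reservoir.

**Pavement cells.** Outlines are radial profiles
`r(θ) = R(1 + a·cos(nθ) + roughness·η(θ))` with η a seeded, unit-SD sum of
low-order Fourier modes excluding the lobe order n (so roughness cannot
systematically create or cancel lobes), sampled at ≥ 360 vertices;
parameter sets whose radius approaches zero (losing star-shapedness) are
refused. Defaults R = 20 μm, a = 0.3 emulate the scale and lobing of mature
leaf epidermal cells. The true lobe count travels with the shape.

**Blots.** Band intensities are `total·fraction·(1 + ε)`, ε ~ N(0, cv²)
per band including the total lane; percentage estimates are unbiased to
< 0.5 percentage points over 1000 seeded replicates at cv = 0.05.

## Morphometrics

Polygon circularity uses the shoelace area and Euclidean perimeter — exact
up to vertex discretization. Raster circularity uses pixel-count area and
the 4-direction Crofton perimeter; marching-squares contour length was
tried first and rejected (it biases a disk's perimeter ~6% high, pushing
circularity to ~0.89; the Crofton estimator stays within the 2% raster
tolerance). Circularity is scale-invariant and bounded by 1 + 0.02
(raster tolerance).

Lobes are counted as endpoints (pixels with exactly one 8-neighbour) of the
skeleton of the filled mask (polygons are rasterized at 0.1 μm/px by
default). Spurs are pruned by iterative endpoint removal for
`prune_len/pixel_size` iterations, with prune_len defaulting to 5% of the
equivalent diameter: small enough that lobes of the emulated amplitude
survive, large enough that discretization spurs on smooth outlines vanish.
A shape whose whole skeleton is consumed by pruning (a disk) reports 0; an
elongated ellipse reports its 2 skeleton tips. Masks touching the image
border are refused (the cell is truncated). Generated shapes with 3–9 lobes
and amplitude ≥ 3× the prune scale recover their ground-truth count in
≥ 95% of seeded cases. The exact pruning and connectivity conventions of
legacy skeleton plugins vary; both knobs are exposed and validated against
generator ground truth rather than against any particular plugin.

## Degenerate inputs and numerical conventions

Bleach-depth inversion uses Brent root-finding on the strictly decreasing
map K ↦ (1 − e^−K)/K with bracket growth, accurate to 1e−12 and
round-tripping to 1e−8. A curve whose first post-bleach sample is ≥ 98% of
the pre-bleach level is rejected as unbleached (a *constant* curve at a
genuinely bleached level is a valid R_f = 0 fit, not an error). Identical
groups in Tukey's HSD produce NaN pairwise p-values (zero pooled variance);
these are treated as non-significant, which merges the letters, and an
ANOVA on all-equal groups reports F = 0, p = 1. Equal-mean zero-variance
bootstrap vectors give p = 1 by convention.

## Scope and limitations

The synthetic generators emulate idealized acquisitions: no photobleaching
during monitoring, no focus drift, homoscedastic Gaussian noise, a single
diffusing species, and exchange against an infinite unbleached pool.
Passing round trips therefore demonstrate correctness of the estimators
under the stated model, not robustness to the full range of live-imaging
artifacts. Two-component and anomalous diffusion, reversible
photobleaching, 3D/volume FRAP, gel-image quantification and cell
segmentation from micrographs are out of scope. Recovery percentages in
fractionation are reported as raw sums and flagged (not renormalized) when
they fall outside plausible bounds, since losses during fractionation are
themselves informative.
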