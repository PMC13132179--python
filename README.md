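# frapmorph

Quantitative analysis of membrane-protein dynamics and its cellular
consequences, built around three workflows used in studies of plant Rho
GTPase (ROP) membrane association:

1. **FRAP beam-size analysis** — fluorescence recovery after photobleaching
   measured with two laser spot sizes distinguishes recovery by *lateral
   diffusion* within the membrane from recovery by *exchange* with the
   cytoplasmic pool.
2. **Pavement-cell morphometrics** — circularity and lobe counts of leaf
   epidermal cells, the standard readout of ROP-controlled cell polarity.
3. **Fractionation densitometry** — percentages of total protein in
   cytosolic, Triton X-100-soluble and -insoluble membrane fractions.

A seeded synthetic-data module (closed-form samplers plus an independent
particle-based Brownian-dynamics simulator) makes every stage verifiable
without raw microscopy data.

## The method

A focused laser spot with Gaussian intensity profile `I(r) = I0·exp(−2r²/ω²)`
bleaches a fraction of the fluorophores, and the return of fluorescence is
followed over time. Recovery curves are fitted with the classic
Gaussian-spot lateral-diffusion series

```
f_K(t) = Σ_{n≥0} (−K)ⁿ/n! · 1/(1 + n(1 + 2t/τ)),
F(t)   = (1 − R_f)·f_K(0) + R_f·f_K(t),
```

where `K` sets the bleach depth through `F(0) = (1 − e^−K)/K`, `τ` is the
characteristic recovery time and `R_f` the mobile fraction. For recovery by
lateral diffusion, `τ = τ_D = ω²/4D`, so τ scales with the illuminated
**area**: measuring with a small beam (63x objective, ω = 0.77 μm) and a
large beam (40x, ω = 1.17 μm) should give

```
τ(40x)/τ(63x) = ω²(40x)/ω²(63x) ≈ 2.3   (pure lateral diffusion)
τ(40x)/τ(63x) = 1                        (pure membrane–cytoplasm exchange)
```

with intermediate ratios indicating a mixed recovery mode. Both ratios get
bootstrap SDs (1000 resamples of the per-cell τ values and of the beam-radius
replicates), the τ ratio is tested against the beam-area ratio and against 1,
and the recovery mode is called from the two tests. Group comparisons of τ,
R_f or morphometric quantities use one-way ANOVA with Tukey's HSD and a
compact letter display.

Cell shape is quantified as circularity `4π·area/perimeter²` (1 for a
circle) and as the number of endpoints of the pruned morphological skeleton
of the cell mask (the lobe count).

## Worked example

```python
from frapmorph import SimulationConfig, simulated_two_beam_ratio

cfg = SimulationConfig(mode="diffusion", D=0.3, n_cells=15, seed=1)
result, fits = simulated_two_beam_ratio(cfg, analysis_seed=1)
print(f"tau ratio  {result.tau_ratio:.3f} ± {result.tau_ratio_sd:.3f}")
print(f"beam ratio {result.beam_ratio:.3f}")
print(f"mode call  {result.mode_call}")
```

prints

```
tau ratio  2.273 ± 0.097
beam ratio 2.309
mode call  diffusion
```

— a simulated membrane-anchored protein diffusing at D = 0.3 μm²/s: the
fitted τ ratio is statistically indistinguishable from the beam-area ratio,
so the analysis correctly calls recovery by lateral diffusion. The
`examples/` directory has one short script per capability (recovery kernels,
two-beam analysis, the particle-based oracle, morphometrics, densitometry),
each printing the numbers it computes and what they mean.

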