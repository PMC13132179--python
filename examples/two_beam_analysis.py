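"""Two-beam FRAP beam-size analysis on simulated genotypes.

Simulates three 15-cell-per-objective experiments — recovery by pure lateral
diffusion (a stably membrane-anchored protein), pure exchange (a weakly bound
protein cycling through the cytoplasm) and a mixed mode — fits every curve
with the single-τ model, and compares the τ(40x)/τ(63x) ratio to the
beam-area ratio ω²(40x)/ω²(63x) with bootstrap uncertainties.
"""

from frapmorph import SimulationConfig, simulated_two_beam_ratio

scenarios = {
    "membrane-anchored (pure diffusion)": SimulationConfig(
        mode="diffusion", D=0.3, n_cells=15, seed=1
    ),
    "weakly bound (pure exchange)": SimulationConfig(
        mode="exchange", k_off=2.0, n_cells=15, seed=2
    ),
    "intermediate (mixed, α=0.6)": SimulationConfig(
        mode="mixed", D=0.3, k_off=5.0, alpha=0.6, n_cells=15, seed=3
    ),
}

print(f"{'scenario':38s} {'τ ratio':>9s} {'±SD':>6s} {'beam ratio':>10s} {'mode call':>12s}")
for name, cfg in scenarios.items():
    res, fits = simulated_two_beam_ratio(cfg, analysis_seed=cfg.seed)
    print(
        f"{name:38s} {res.tau_ratio:9.3f} {res.tau_ratio_sd:6.3f} "
        f"{res.beam_ratio:10.3f} {res.mode_call:>12s}"
    )

print(
    "\nA τ ratio matching the beam-area ratio (≈2.31 for ω = 1.17/0.77 μm)"
    "\nmeans recovery scales with the bleached area — lateral diffusion."
    "\nA ratio of 1 means recovery time is beam-independent — exchange with"
    "\nthe cytoplasmic pool. Intermediate ratios indicate a mixed mode."
)
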