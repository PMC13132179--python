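"""Cross-validate the analytic recovery model with Brownian-dynamics particles.

Simulates 2D Brownian walkers under a Gaussian bleach/detection profile —
no closed-form kernel involved — fits the resulting trace with the single-τ
diffusion model, and back-computes the diffusion coefficient D = ω²/4τ.
"""

from frapmorph import DEFAULT_BEAMS, SimulationConfig, fit_recovery, simulate_frap_particles

beam = DEFAULT_BEAMS[0]  # 63x objective, ω = 0.77 μm
true_D = 0.37  # μm²/s, typical of small GTPases on the inner membrane leaflet

cfg = SimulationConfig(
    mode="diffusion", D=true_D, noise_sd=0.0, cell_cv=0.0, seed=42, beams=(beam,)
)
curve = simulate_frap_particles(cfg, beam=beam, n_particles=60_000, n_repeats=10)
fit = fit_recovery(curve)

print(f"true D          : {true_D:.3f} μm²/s")
print(f"fitted τ        : {fit.tau:.3f} s   (τ_D = ω²/4D would be {beam.omega**2/(4*true_D):.3f} s)")
print(f"back-computed D : {fit.D:.3f} μm²/s   ({100 * (fit.D / true_D - 1):+.1f}%)")
print(f"mobile fraction : {fit.R_f:.3f}   (simulated with R_f = {cfg.R_f})")
print(
    "\nThe particle simulation shares no code with the closed-form recovery"
    "\nseries, so agreement of the recovered D validates both the model and"
    "\nthe fitter against the underlying physics."
)
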