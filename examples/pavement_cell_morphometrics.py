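"""Pavement-cell morphometrics on synthetic genotype groups.

Generates groups of lobed cell outlines with known ground truth — a highly
lobed wild-type-like group and two progressively rounder groups — then
computes circularity (4π·area/perimeter²) and skeleton-endpoint lobe counts,
runs ANOVA + Tukey HSD across groups, and regresses lobe number on
circularity.
"""

import numpy as np

from frapmorph import circularity_lobe_regression, generate_pavement_cell, shape_group_stats

rng_groups = {
    "wild-type-like": dict(n_lobes=8, amplitude=0.32),
    "intermediate": dict(n_lobes=5, amplitude=0.22),
    "rounded (CA-like)": dict(n_lobes=3, amplitude=0.12),
}

# distinct seeds per group and cell
shapes = {
    name: [
        generate_pavement_cell(**kw, roughness=0.03, seed=1000 * gi + j) for j in range(12)
    ]
    for gi, (name, kw) in enumerate(rng_groups.items())
}

table, cmp_circ, cmp_lobe = shape_group_stats(shapes)
print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

pairs = list(zip(table["circularity_mean"], table["lobe_count_mean"]))
slope, intercept, r2 = circularity_lobe_regression(pairs)
print(f"\nlobe_count ~ {slope:.2f} * circularity + {intercept:.2f}   (R² = {r2:.3f})")
print(
    "\nGroups that do not share a significance letter differ at p ≤ 0.05"
    "\n(one-way ANOVA + Tukey HSD). The negative slope shows the inverse"
    "\nrelationship between circularity and lobe number: rounder cells"
    "\nhave fewer lobes, the signature of disrupted cell polarity."
)
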