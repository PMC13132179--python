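"""Densitometry arithmetic for membrane-partitioning immunoblots.

A fractionation run separates total protein (Tot) into a soluble cytoplasmic
fraction (Cyt), a Triton X-100-soluble membrane fraction (TSM) and a Triton
X-100-insoluble membrane fraction (TIM).  Band intensities from the blot are
converted into percentages of the total lane, and the summed recovery flags
losses (degradation during fractionation) or anomalies (recovery above
~110% indicates a loading or quantification problem).  Inputs are assumed
background-corrected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

__all__ = ["FRACTION_KEYS", "FractionationProfile", "fraction_percentages", "fractionation_table"]

FRACTION_KEYS = ("Cyt", "TSM", "TIM")

#: recovery above this percentage flags a loading/quantification anomaly
HIGH_RECOVERY_PCT = 110.0
#: recovery below this percentage flags protein loss during fractionation
LOW_RECOVERY_PCT = 50.0


@dataclass(frozen=True)
class FractionationProfile:
    """One lane's band intensities and derived percentages of total."""

    intensities: dict[str, float]
    percentages: dict[str, float]
    recovery_pct: float
    line_label: str = ""
    flags: tuple[str, ...] = ()


def fraction_percentages(
    intensities: Mapping[str, float], line_label: str = ""
) -> FractionationProfile:
    """Express Cyt/TSM/TIM band intensities as percentages of the total lane.

    ``recovery_pct`` is the plain sum of the three percentages; it is reported
    as-is (no renormalization) and flagged when implausibly high or low.
    """
    missing = [k for k in ("Tot", *FRACTION_KEYS) if k not in intensities]
    if missing:
        raise ValueError(f"missing fraction keys: {missing}")
    vals = {k: float(intensities[k]) for k in ("Tot", *FRACTION_KEYS)}
    if any(v < 0 for v in vals.values()):
        raise ValueError("band intensities must be non-negative")
    if vals["Tot"] == 0:
        raise ValueError("total-lane intensity must be positive")
    pct = {k: 100.0 * vals[k] / vals["Tot"] for k in FRACTION_KEYS}
    recovery = sum(pct.values())
    flags = []
    if recovery > HIGH_RECOVERY_PCT:
        flags.append("high recovery")
    if recovery < LOW_RECOVERY_PCT:
        flags.append("low recovery")
    return FractionationProfile(
        intensities=vals,
        percentages=pct,
        recovery_pct=recovery,
        line_label=line_label,
        flags=tuple(flags),
    )


def fractionation_table(profiles: list[FractionationProfile]) -> pd.DataFrame:
    """Tidy table of intensities, percentages, recovery and flags per lane."""
    rows = []
    for p in profiles:
        row = {"line_label": p.line_label, **p.intensities}
        row.update({f"{k}_pct": p.percentages[k] for k in FRACTION_KEYS})
        row["recovery_pct"] = p.recovery_pct
        row["flags"] = ";".join(p.flags)
        rows.append(row)
    return pd.DataFrame(rows)
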