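"""Flow-cytometry derived metrics: phagocytosis, proliferation, relative MFI,
apoptosis quadrant gating and co-culture uptake.

Event tables are plain DataFrames with one row per event and named channel
columns (e.g. FL1_green, FL2_red, violet).  Gates are explicit intensity
thresholds; a convenience helper derives a default gate as the 99th
percentile of a matched negative control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "default_gate",
    "percent_positive",
    "phagocytosis_percent",
    "phagocytic_activity",
    "highly_phagocytic_fraction",
    "relative_growth",
    "relative_mfi",
    "apoptosis_gating",
    "coculture_uptake_percent",
    "PhagoMetrics",
]


@dataclass
class PhagoMetrics:
    pct_phagocytic: float
    beads_per_cell: float
    pct_highly_phagocytic: float


def _require_events(events: pd.DataFrame, *channels: str) -> None:
    if len(events) == 0:
        raise ValueError("event table is empty")
    for ch in channels:
        if ch not in events.columns:
            raise KeyError(f"channel {ch!r} not in event table")


def default_gate(control: pd.DataFrame, channel: str, q: float = 0.99) -> float:
    """Positivity threshold as the q-quantile of a negative control."""
    _require_events(control, channel)
    return float(control[channel].quantile(q))


def percent_positive(events: pd.DataFrame, channel: str, threshold: float) -> float:
    _require_events(events, channel)
    return 100.0 * float((events[channel] > threshold).mean())


def phagocytosis_percent(
    sample: pd.DataFrame,
    cytod_control: pd.DataFrame,
    channel: str,
    positivity_threshold: float,
) -> float:
    """% bead-positive cells after subtracting the cytochalasin-D control, floored at 0."""
    pct = percent_positive(sample, channel, positivity_threshold) - percent_positive(
        cytod_control, channel, positivity_threshold
    )
    return max(0.0, pct)


def phagocytic_activity(cells_mfi: float, single_bead_mfi: float) -> float:
    """Beads per cell: population MFI divided by the MFI of a single bead."""
    if single_bead_mfi <= 0:
        raise ValueError("single-bead MFI must be positive")
    return cells_mfi / single_bead_mfi


def highly_phagocytic_fraction(beads_per_cell: np.ndarray | pd.Series) -> float:
    """% of cells with strictly more than 2 beads."""
    b = np.asarray(beads_per_cell, dtype=float)
    if b.size == 0:
        raise ValueError("no cells")
    return 100.0 * float((b > 2.0).mean())


def relative_growth(mfi_series: dict[float, float] | pd.Series, anchor: float = 24.0) -> pd.Series:
    """Relative growth from CFSE dilution: growth(t) = MFI(anchor) / MFI(t).

    CFSE halves each division, so inverse MFI normalized to the 24 h
    post-seeding point tracks cumulative divisions.
    """
    s = pd.Series(mfi_series, dtype=float).sort_index()
    if anchor not in s.index:
        raise ValueError(f"anchor time point {anchor} h missing from the series")
    if (s <= 0).any():
        raise ValueError("all MFI values must be positive")
    return (s[anchor] / s).rename("relative_growth")


def relative_mfi(sample: pd.DataFrame, control: pd.DataFrame, channel: str) -> float:
    """Sample MFI normalized to the control MFI on the same channel."""
    _require_events(sample, channel)
    _require_events(control, channel)
    ctrl = float(control[channel].mean())
    if ctrl <= 0:
        raise ValueError("control MFI must be positive")
    return float(sample[channel].mean()) / ctrl


def apoptosis_gating(
    events: pd.DataFrame,
    annexin_channel: str,
    pi_channel: str,
    annexin_threshold: float,
    pi_threshold: float,
) -> dict[str, float]:
    """Quadrant fractions: AnnexinV+/PI- apoptotic, double-positive late
    apoptotic, AnnexinV-/PI+ necrotic, double-negative viable.  Sums to 1.
    """
    _require_events(events, annexin_channel, pi_channel)
    av = events[annexin_channel].to_numpy() > annexin_threshold
    pi = events[pi_channel].to_numpy() > pi_threshold
    n = len(events)
    return {
        "apoptotic": float((av & ~pi).sum()) / n,
        "late_apoptotic": float((av & pi).sum()) / n,
        "necrotic": float((~av & pi).sum()) / n,
        "viable": float((~av & ~pi).sum()) / n,
    }


def coculture_uptake_percent(
    events: pd.DataFrame,
    cfse_channel: str,
    ctv_channel: str,
    cfse_gate: float,
    ctv_threshold: float,
) -> float:
    """% of CFSE-gated microglia that are CTV-positive (neuronal uptake)."""
    _require_events(events, cfse_channel, ctv_channel)
    gated = events[events[cfse_channel] > cfse_gate]
    if len(gated) == 0:
        raise ValueError("no CFSE-positive events to gate on")
    return 100.0 * float((gated[ctv_channel] > ctv_threshold).mean())
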