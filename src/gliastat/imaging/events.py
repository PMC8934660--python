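"""Phagocytic-event typing from marker flags.

Two independent classification axes over internalization events found in
microglial-neuronal co-cultures:

* apoptosis axis (CTV x cleaved caspase-3): CTV+/casp3+ events are uptake
  of apoptotic neurons; CTV+/casp3- events are uptake of healthy cells or
  their parts.
* structure axis (beta3-tubulin x DAPI): TUBB3+/DAPI+ events are neuronal
  soma; TUBB3+/DAPI- events are neurites.  TUBB3- events are excluded from
  this axis and counted separately.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

__all__ = ["PhagocyticEvent", "classify_phagocytic_events"]


@dataclass(frozen=True)
class PhagocyticEvent:
    location: tuple[float, float] | None = None
    ctv: bool = False
    caspase3: bool = False
    tubb3: bool = False
    dapi: bool = False


def classify_phagocytic_events(events: list[PhagocyticEvent]) -> dict:
    """Counts and relative frequencies on both classification axes.

    Relative frequencies sum to 1 within each axis (over classified
    events); TUBB3- events are reported under 'excluded_structure_axis'.
    """
    if not events:
        raise ValueError("no events to classify")
    apo = Counter()
    for e in events:
        if e.ctv and e.caspase3:
            apo["apoptotic_soma"] += 1
        elif e.ctv:
            apo["nonapoptotic_uptake"] += 1
        else:
            apo["ctv_negative"] += 1

    structure = Counter()
    excluded = 0
    for e in events:
        if not e.tubb3:
            excluded += 1
        elif e.dapi:
            structure["soma"] += 1
        else:
            structure["neurite"] += 1

    def freqs(counter: Counter) -> dict[str, float]:
        total = sum(counter.values())
        return {k: v / total for k, v in counter.items()} if total else {}

    return {
        "apoptosis_axis_counts": dict(apo),
        "apoptosis_axis_freq": freqs(apo),
        "structure_axis_counts": dict(structure),
        "structure_axis_freq": freqs(structure),
        "excluded_structure_axis": excluded,
    }
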