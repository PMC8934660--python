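"""Simulators for flow-cytometry event tables and qPCR Ct tables."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Population", "simulate_flow_events", "simulate_ct_table"]


@dataclass(frozen=True)
class Population:
    """One mixture component: per-channel log-normal-ish intensities.

    means/sds are per-channel normal parameters on the intensity scale
    (truncated at 0), a reasonable stand-in for gated cytometer data.
    """

    label: str
    means: dict[str, float]
    sds: dict[str, float]
    weight: float


def simulate_flow_events(
    n_events: int,
    populations: list[Population],
    seed: int = 0,
) -> pd.DataFrame:
    """Mixture of event populations with the hidden labels kept as truth.

    Returns a DataFrame with one row per event, one column per channel and
    a `truth_label` column.
    """
    if n_events < 1:
        raise ValueError("need at least one event")
    weights = np.array([p.weight for p in populations], dtype=float)
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("population weights must sum to 1")
    for p in populations:
        if any(sd < 0 for sd in p.sds.values()):
            raise ValueError(f"population {p.label!r} has a negative sd")
    channels = sorted({ch for p in populations for ch in p.means})

    rng = np.random.default_rng(seed)
    which = rng.choice(len(populations), size=n_events, p=weights)
    data = np.zeros((n_events, len(channels)))
    for i, pop in enumerate(populations):
        mask = which == i
        n = int(mask.sum())
        for j, ch in enumerate(channels):
            data[mask, j] = rng.normal(pop.means.get(ch, 0.0), pop.sds.get(ch, 0.0), size=n)
    np.maximum(data, 0.0, out=data)
    out = pd.DataFrame(data, columns=channels)
    out["truth_label"] = [populations[i].label for i in which]
    return out


def simulate_ct_table(
    genes: list[str],
    true_fold_changes: dict[str, float],
    ct_noise_sd: float = 0.0,
    n_tech_reps: int = 3,
    seed: int = 0,
    reference_gene: str = "RPS13",
    control_sample: str = "control",
    treated_sample: str = "treated",
    base_ct: float = 25.0,
    reference_ct: float = 20.0,
) -> pd.DataFrame:
    """Two-sample Ct table consistent with known fold changes.

    A fold change F in the treated sample shifts that gene's Ct by
    -log2(F) relative to control (one extra doubling of template removes
    one cycle); the reference gene is constant.  Gaussian cycle noise with
    sd `ct_noise_sd` is added per technical replicate.
    """
    if n_tech_reps < 1:
        raise ValueError("need at least one technical replicate")
    rng = np.random.default_rng(seed)
    rows = []

    def add(sample: str, gene: str, ct: float):
        for rep in range(n_tech_reps):
            rows.append(
                {
                    "sample": sample,
                    "gene": gene,
                    "replicate": rep + 1,
                    "ct": ct + rng.normal(0.0, ct_noise_sd),
                }
            )

    for sample in (control_sample, treated_sample):
        add(sample, reference_gene, reference_ct)
        for gene in genes:
            ct = base_ct
            if sample == treated_sample:
                ct -= np.log2(true_fold_changes.get(gene, 1.0))
            add(sample, gene, ct)
    return pd.DataFrame(rows)
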