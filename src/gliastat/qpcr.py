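"""Relative qPCR quantification by the 2^-ddCt method.

Technical-replicate Ct values are averaged per (sample, gene); the target
gene is normalized to a reference gene within each sample (dCt), then to
the control sample (ddCt), assuming an amplification efficiency of 2 per
cycle.  Fold change = 2^-ddCt; 2^-dCt values are also emitted since some
comparisons are made on that scale.
"""

from __future__ import annotations

import logging

import pandas as pd

__all__ = ["ddct_fold_change"]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("sample", "gene", "ct")


def ddct_fold_change(
    records: pd.DataFrame,
    reference_gene: str,
    control_sample: str,
) -> pd.DataFrame:
    """Fold changes relative to `control_sample`, normalized to `reference_gene`.

    `records` has one row per technical replicate: columns sample, gene, ct.
    Returns a frame indexed by (sample, gene) with mean_ct, delta_ct,
    delta_delta_ct, fold (2^-ddCt) and expr_2_neg_dct (2^-dCt).  Samples
    lacking the reference gene are skipped with a warning.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if (records["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")

    mean_ct = records.groupby(["sample", "gene"], sort=False)["ct"].mean()
    samples = mean_ct.index.get_level_values("sample").unique()
    if control_sample not in set(samples):
        raise ValueError(f"control sample {control_sample!r} not found")

    rows = []
    for sample in samples:
        sub = mean_ct.loc[sample]
        if reference_gene not in sub.index:
            logger.warning("sample %s lacks reference gene %s; skipped", sample, reference_gene)
            continue
        ref_ct = sub[reference_gene]
        for gene, ct in sub.items():
            if gene == reference_gene:
                continue
            rows.append({"sample": sample, "gene": gene, "mean_ct": ct, "delta_ct": ct - ref_ct})
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValueError(f"reference gene {reference_gene!r} not found in any sample")

    control_dct = out[out["sample"] == control_sample].set_index("gene")["delta_ct"]
    out["delta_delta_ct"] = out.apply(
        lambda r: r["delta_ct"] - control_dct.get(r["gene"], float("nan")), axis=1
    )
    out["fold"] = 2.0 ** (-out["delta_delta_ct"])
    out["expr_2_neg_dct"] = 2.0 ** (-out["delta_ct"])
    return out.set_index(["sample", "gene"])
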