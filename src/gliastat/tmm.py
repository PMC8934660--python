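"""Trimmed-mean-of-M-values (TMM) composition normalization for count data.

TMM estimates a per-sample scaling factor from a doubly trimmed, weighted
mean of per-gene log expression ratios against a reference sample, so that
library-size-normalized expression is comparable across samples even when a
minority of genes dominates some libraries.  Factors are rescaled so their
geometric mean is 1; sequencing depth itself is carried by the library size,
not by the factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["NormFactors", "compute_tmm_factors"]

# published TMM defaults: per-tail trims on the log-ratios (M) and abundances (A)
LOGRATIO_TRIM = 0.30
ABUNDANCE_TRIM = 0.05


@dataclass
class NormFactors:
    """Per-cell TMM factor and library size (factors have geometric mean 1)."""

    factors: pd.Series
    lib_sizes: pd.Series

    @property
    def effective_lib_sizes(self) -> pd.Series:
        return self.lib_sizes * self.factors


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float) -> float:
    """TMM factor (log2) of one sample against the reference."""
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        return 0.0
    obs, ref = obs[keep].astype(float), ref[keep].astype(float)

    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic delta-method variance of M
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)

    if np.allclose(m, m[0]):
        # all ratios equal (e.g. pure depth change): trimming is ill-posed
        return float(m[0])

    # rank-based double trim: drop floor(trim*n) genes from each tail of M and A
    n = m.size
    rank_m = np.argsort(np.argsort(m, kind="stable"), kind="stable")
    rank_a = np.argsort(np.argsort(a, kind="stable"), kind="stable")
    cut_m, cut_a = int(np.floor(LOGRATIO_TRIM * n)), int(np.floor(ABUNDANCE_TRIM * n))
    keep2 = (rank_m >= cut_m) & (rank_m < n - cut_m) & (rank_a >= cut_a) & (rank_a < n - cut_a)
    if not keep2.any() or w[keep2].sum() == 0:
        return 0.0
    # weighted by inverse variance
    inv = 1.0 / w[keep2]
    return float(np.sum(inv * m[keep2]) / np.sum(inv))


def compute_tmm_factors(counts: pd.DataFrame) -> NormFactors:
    """TMM normalization factors for a genes-by-cells count matrix.

    The reference cell is the one whose upper-quartile expression (75th
    percentile of library-size-scaled counts) is closest to the mean upper
    quartile across cells.  Raises if any cell has zero total count,
    naming the offending cell.
    """
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    if (lib <= 0).any():
        bad = counts.columns[lib <= 0][0]
        raise ValueError(f"cell {bad!r} has zero total count; TMM is undefined")

    uq = np.array([np.quantile(x[:, j][x[:, j] > 0] / lib[j], 0.75) if (x[:, j] > 0).any() else 0.0
                   for j in range(x.shape[1])])
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))

    log2f = np.array([
        _tmm_pair(x[:, j], x[:, ref_idx], lib[j], lib[ref_idx]) for j in range(x.shape[1])
    ])
    factors = 2.0 ** log2f
    factors = factors / np.exp(np.mean(np.log(factors)))  # geometric mean 1
    return NormFactors(
        factors=pd.Series(factors, index=counts.columns, name="tmm_factor"),
        lib_sizes=pd.Series(lib.astype(np.int64), index=counts.columns, name="lib_size"),
    )
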