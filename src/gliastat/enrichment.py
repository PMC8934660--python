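"""Competitive gene-set enrichment by the average t-score permutation test.

A gene set's observed statistic is the arithmetic mean of its members'
signed differential-expression t-scores.  The null is the distribution of
the same average over size-matched gene sets sampled uniformly without
replacement from the whole universe (tested-set members stay eligible),
with n = 10,000 permutations by default.  The one-sided upper-tail p-value
uses the permutation-exact (1 + exceedances) / (1 + n_perm) convention, so
it is never zero; multiplicity over the sets tested together is handled by
Bonferroni.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "PermConfig",
    "EnrichmentResult",
    "EnrichmentResults",
    "GeneSetEnrichment",
    "observed_set_score",
    "permutation_test",
    "enumerate_null_exact",
    "bonferroni_adjust",
    "dotplot_summary",
]

logger = logging.getLogger(__name__)

_ENUM_LIMIT = 10**6


@dataclass(frozen=True)
class PermConfig:
    n_perm: int = 10_000
    seed: int = 0
    alpha: float = 0.05

    def __post_init__(self):
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


@dataclass
class EnrichmentResult:
    """Permutation-test result for one gene set."""

    name: str
    size_used: int
    observed_avg_t: float
    null_mean: float
    null_sd: float
    p_raw: float
    p_bonferroni: float = math.nan
    significant: bool = False
    n_dropped: int = 0  # set members absent from the universe


def _check_universe(tscores: pd.Series) -> pd.Series:
    if tscores.index.has_duplicates:
        raise ValueError("duplicate genes in the t-score universe")
    if not np.isfinite(tscores.to_numpy()).all():
        raise ValueError("t-scores must be finite")
    return tscores


def _intersect(tscores: pd.Series, name: str, members) -> pd.Index:
    present = tscores.index.intersection(pd.Index(members))
    dropped = len(set(members)) - len(present)
    if len(present) == 0:
        raise ValueError(f"gene set {name!r} has no members in the t-score universe")
    if dropped:
        logger.info("set %s: %d members absent from the universe, dropped", name, dropped)
    return present


def observed_set_score(tscores: pd.Series, name: str, members) -> tuple[float, int]:
    """Mean t-score over the set's members present in the universe.

    Returns (observed average, post-intersection set size).
    """
    _check_universe(tscores)
    present = _intersect(tscores, name, members)
    return float(tscores.loc[present].mean()), len(present)


def _null_averages(t: np.ndarray, k: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """n_perm means of k t-scores sampled without replacement from t."""
    n = t.size
    if k == n:
        return np.full(n_perm, t.mean())
    # random-keys draw: the k smallest keys per row form a uniform subset
    keys = rng.random((n_perm, n))
    idx = np.argpartition(keys, k, axis=1)[:, :k]
    return t[idx].mean(axis=1)


def permutation_test(
    tscores: pd.Series,
    name: str,
    members,
    cfg: PermConfig = PermConfig(),
) -> EnrichmentResult:
    """Upper-tail permutation test of one gene set's average t-score."""
    _check_universe(tscores)
    present = _intersect(tscores, name, members)
    n_dropped = len(set(members)) - len(present)
    t = tscores.to_numpy(dtype=float)
    k = len(present)
    observed = float(tscores.loc[present].mean())

    if k == t.size:
        logger.warning("set %s equals the whole universe; the permutation null is degenerate", name)
        null = np.full(cfg.n_perm, t.mean())
    else:
        rng = np.random.default_rng(cfg.seed)
        null = _null_averages(t, k, cfg.n_perm, rng)

    exceed = int(np.sum(null >= observed))  # ties count as exceedances
    p_raw = (1.0 + exceed) / (1.0 + cfg.n_perm)
    return EnrichmentResult(
        name=name,
        size_used=k,
        observed_avg_t=observed,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if cfg.n_perm > 1 else 0.0,
        p_raw=p_raw,
        n_dropped=n_dropped,
    )


def enumerate_null_exact(tscores: pd.Series, set_size: int) -> tuple[np.ndarray, "ExactNull"]:
    """Complete null: averages over every size-matched subset of the universe.

    Only feasible when C(universe, set_size) <= 1e6; otherwise raises and the
    Monte-Carlo path should be used.
    """
    _check_universe(tscores)
    n = len(tscores)
    if set_size < 1 or set_size > n:
        raise ValueError("set_size must be in [1, universe size]")
    n_comb = math.comb(n, set_size)
    if n_comb > _ENUM_LIMIT:
        raise ValueError(
            f"C({n},{set_size}) = {n_comb} exceeds {_ENUM_LIMIT}; use the Monte-Carlo test"
        )
    t = tscores.to_numpy(dtype=float)
    vals = np.fromiter(
        (sum(c) / set_size for c in combinations(t, set_size)), dtype=float, count=n_comb
    )
    return vals, ExactNull(vals)


@dataclass
class ExactNull:
    values: np.ndarray

    def p_upper(self, observed: float) -> float:
        """Exact upper-tail probability P(null >= observed), ties included."""
        return float(np.mean(self.values >= observed - 1e-12))


def bonferroni_adjust(
    results: list[EnrichmentResult], alpha: float = 0.05
) -> list[EnrichmentResult]:
    """Bonferroni over the m sets tested together: p_bonf = min(1, m * p_raw)."""
    m = len(results)
    if m < 1:
        raise ValueError("need at least one result")
    for r in results:
        r.p_bonferroni = min(1.0, m * r.p_raw)
        r.significant = r.p_bonferroni < alpha
    return results


@dataclass
class EnrichmentResults:
    """Results container for a batch of gene sets tested together."""

    results: list[EnrichmentResult]
    cfg: PermConfig

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "set": r.name,
                    "size_used": r.size_used,
                    "observed_avg_t": r.observed_avg_t,
                    "null_mean": r.null_mean,
                    "null_sd": r.null_sd,
                    "p_raw": r.p_raw,
                    "p_bonferroni": r.p_bonferroni,
                    "significant": r.significant,
                }
                for r in self.results
            ]
        ).set_index("set")

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            f"Gene-set average t-score permutation test ({self.cfg.n_perm} permutations)",
            f"  sets tested: {len(df)}   Bonferroni alpha: {self.cfg.alpha}",
            f"  significant sets: {int(df['significant'].sum())}",
            df.to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)

    def bar_data(self) -> pd.DataFrame:
        """Null mean +/- 2 SD against the observed average, per set."""
        df = self.to_frame()
        out = df[["observed_avg_t", "null_mean", "null_sd"]].copy()
        out["null_lo"] = out["null_mean"] - 2 * out["null_sd"]
        out["null_hi"] = out["null_mean"] + 2 * out["null_sd"]
        return out

    def plot_bars(self, ax=None):
        """Bar chart of observed set averages over the null mean +/- 2 SD."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(1.2 + 0.6 * len(self.results), 3.2))
        bars = self.bar_data()
        x = np.arange(len(bars))
        ax.bar(x, bars["observed_avg_t"], color="#70a0c8", label="observed avg t")
        ax.errorbar(
            x,
            bars["null_mean"],
            yerr=2 * bars["null_sd"],
            fmt="_",
            color="black",
            capsize=3,
            label="null mean ± 2 SD",
        )
        ax.set_xticks(x, bars.index, rotation=45, ha="right")
        ax.set_ylabel("gene-set average t-score")
        ax.legend(frameon=False, fontsize=8)
        return ax


class GeneSetEnrichment:
    """Model-style wrapper: a t-score universe plus the gene sets to test.

    gene_sets: mapping name -> iterable of gene IDs.
    """

    def __init__(self, tscores: pd.Series, gene_sets: dict[str, list]):
        self.tscores = _check_universe(tscores.astype(float))
        if not gene_sets:
            raise ValueError("no gene sets supplied")
        self.gene_sets = gene_sets

    def fit(self, cfg: PermConfig = PermConfig()) -> EnrichmentResults:
        # each set gets a distinct child seed so p-values are reproducible
        # but draws are independent across sets
        seeds = np.random.SeedSequence(cfg.seed).spawn(len(self.gene_sets))
        results = []
        for (name, members), ss in zip(self.gene_sets.items(), seeds):
            sub_cfg = PermConfig(
                n_perm=cfg.n_perm, seed=int(ss.generate_state(1)[0] % (2**31)), alpha=cfg.alpha
            )
            results.append(permutation_test(self.tscores, name, members, sub_cfg))
        bonferroni_adjust(results, alpha=cfg.alpha)
        return EnrichmentResults(results=results, cfg=cfg)


def dotplot_summary(
    counts: pd.DataFrame,
    covariates: pd.DataFrame,
    genes: list,
) -> pd.DataFrame:
    """Per-gene, per-disease-group expression summary for dotplots.

    Expression is log1p of depth-normalized counts (counts scaled to the
    median library size), z-scored per gene across *all* cells, then
    averaged within each disease group; pct_expressed is the percentage of
    group cells with a nonzero count.  Genes with zero variance get z = 0
    and are flagged.
    """
    genes = list(genes)
    missing = [g for g in genes if g not in counts.index]
    if missing:
        raise KeyError(f"genes absent from the count matrix: {missing}")
    lib = counts.sum(axis=0).to_numpy(float)
    scale = np.median(lib)
    expr = np.log1p(counts.loc[genes].to_numpy(float) / lib[None, :] * scale)
    mean = expr.mean(axis=1, keepdims=True)
    sd = expr.std(axis=1, keepdims=True)
    flat = sd[:, 0] == 0
    z = np.where(sd > 0, (expr - mean) / np.where(sd > 0, sd, 1.0), 0.0)

    rows = []
    for group in ("Ctrl", "AT"):
        in_group = (covariates["disease.status"] == group).to_numpy()
        for i, gene in enumerate(genes):
            cnt = counts.loc[gene].to_numpy()[in_group]
            rows.append(
                {
                    "gene": gene,
                    "group": group,
                    "avg_expression_z": float(z[i, in_group].mean()),
                    "pct_expressed": 100.0 * float((cnt > 0).mean()),
                    "zero_variance": bool(flat[i]),
                }
            )
    return pd.DataFrame(rows).set_index(["gene", "group"])
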