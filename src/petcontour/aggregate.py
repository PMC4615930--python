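"""Across-pair aggregation honoring the two-surfaces-per-sectioning design.

The two cut surfaces of one sectioning position are correlated, so pairs
are clustered by sectioning position. Marginal means and robust standard
errors come from an intercept-only GEE with identity link and exchangeable
working correlation; percentile confidence intervals come from a cluster
bootstrap (resampling sectioning positions with replacement, 10,000 draws
by default). Both are reported; the bootstrap CI is the default interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["AggregateStat", "gee_mean_se", "bootstrap_ci", "summarize"]


@dataclass(frozen=True)
class AggregateStat:
    metric: str
    method: str
    parameter: float
    mean: float
    se: float  # cluster-bootstrap SE
    se_gee: float  # robust sandwich SE
    ci_low: float
    ci_high: float
    n_pairs: int
    n_clusters: int


def _clean(values, cluster_ids):
    y = np.asarray(values, dtype=float)
    g = np.asarray(cluster_ids)
    if y.shape != g.shape or y.ndim != 1:
        raise ValueError("values and cluster_ids must be equal-length 1-D")
    keep = np.isfinite(y)
    return y[keep], g[keep]


def gee_mean_se(values, cluster_ids) -> tuple[float, float]:
    """Marginal mean and robust (sandwich) SE from intercept-only GEE.

    Exchangeable working correlation; with all-singleton clusters the
    estimate is the sample mean and the SE is sqrt(sum (y - ybar)^2) / n.
    """
    y, g = _clean(values, cluster_ids)
    if len(np.unique(g)) < 2:
        raise ValueError(
            "GEE needs >= 2 clusters; use the cluster bootstrap for a single cluster"
        )
    if np.ptp(y) == 0.0:  # constant response: scale is 0, GEE is degenerate
        return float(y[0]), 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GEE(
            y,
            np.ones((len(y), 1)),
            groups=g,
            family=sm.families.Gaussian(),
            cov_struct=sm.cov_struct.Exchangeable(),
        )
        res = model.fit()
    return float(res.params[0]), float(res.bse[0])


def bootstrap_ci(
    values,
    cluster_ids,
    n_boot: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float, float]:
    """Cluster-bootstrap SE and 95% percentile CI of the mean.

    Clusters (sectioning positions) are resampled with replacement; the
    pooled mean over the resampled surfaces is recomputed each draw.
    Returns ``(se, ci_low, ci_high)``; deterministic given a seed.
    """
    y, g = _clean(values, cluster_ids)
    if len(np.unique(g)) < 2:
        raise ValueError("cluster bootstrap needs >= 2 clusters")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is very small for percentile intervals")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    clusters, inv = np.unique(g, return_inverse=True)
    sums = np.bincount(inv, weights=y, minlength=len(clusters))
    counts = np.bincount(inv, minlength=len(clusters)).astype(float)
    idx = rng.integers(0, len(clusters), size=(n_boot, len(clusters)))
    boot_means = sums[idx].sum(axis=1) / counts[idx].sum(axis=1)
    se = float(boot_means.std(ddof=1))
    lo, hi = np.percentile(boot_means, [2.5, 97.5])
    return se, float(lo), float(hi)


_METRICS = ("sensitivity", "specificity", "oe_ratio")


def summarize(
    per_pair: pd.DataFrame,
    roc_auc: pd.DataFrame | None = None,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Aggregate per-pair metrics into a study-level table.

    ``per_pair`` needs columns (section_id, cluster_id, method, parameter,
    sensitivity, specificity, oe_ratio); ``roc_auc`` needs (section_id,
    cluster_id, auc). One row per (method, parameter, metric), plus a
    pooled AUC row. Pairs with an undefined metric (e.g. no necrotic
    pixels) are dropped for that metric only.
    """
    rng = np.random.default_rng(seed)
    rows: list[AggregateStat] = []

    def add(metric, method, parameter, values, cluster_ids):
        y, g = _clean(values, cluster_ids)
        if len(y) == 0 or len(np.unique(g)) < 2:
            return
        mean, se_gee = gee_mean_se(y, g)
        se, lo, hi = bootstrap_ci(y, g, n_boot=n_boot, seed=rng)
        rows.append(
            AggregateStat(
                metric=metric,
                method=method,
                parameter=float(parameter),
                mean=mean,
                se=se,
                se_gee=se_gee,
                ci_low=lo,
                ci_high=hi,
                n_pairs=len(y),
                n_clusters=len(np.unique(g)),
            )
        )

    for (method, parameter), grp in per_pair.groupby(
        ["method", "parameter"], sort=True
    ):
        for metric in _METRICS:
            add(metric, method, parameter, grp[metric].to_numpy(), grp["cluster_id"].to_numpy())

    if roc_auc is not None and len(roc_auc):
        add("auc", "pooled", np.nan, roc_auc["auc"].to_numpy(), roc_auc["cluster_id"].to_numpy())

    return pd.DataFrame([r.__dict__ for r in rows])
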