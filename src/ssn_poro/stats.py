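"""Nonparametric group comparison for longitudinal alpha / peak-SSn cohorts.

The Kruskal-Wallis H statistic is computed with midranks and the standard tie
correction; the p-value comes from the chi-square upper tail with
``groups - 1`` degrees of freedom, or from exact enumeration of all rank
assignments for small pooled samples (N <= 10), where the chi-square
approximation is coarse.  :func:`weekly_summary` applies the pairwise test
arm-vs-arm within each week of a cohort table and attaches significance stars
at the 0.05 / 0.01 / 0.001 thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata

from .model_core import peak_ssn

__all__ = ["GroupedSamples", "KruskalResult", "kruskal_wallis", "weekly_summary", "stars"]

_EXACT_MAX_N = 10


@dataclass(frozen=True)
class GroupedSamples:
    """Two or more groups of scalar observations."""

    labels: tuple
    values: tuple  # tuple of 1-D float arrays, parallel to labels

    @classmethod
    def from_arrays(cls, groups: Sequence[Sequence[float]], labels: Optional[Sequence] = None):
        arrays = tuple(np.asarray(g, dtype=float) for g in groups)
        if len(arrays) < 2:
            raise ValueError("need at least 2 groups")
        for a in arrays:
            if a.size == 0:
                raise ValueError("each group must be nonempty")
            if not np.all(np.isfinite(a)):
                raise ValueError("group values must be finite")
        if labels is None:
            labels = tuple(range(len(arrays)))
        return cls(labels=tuple(labels), values=arrays)


def _h_statistic(pooled_ranks: np.ndarray, sizes: np.ndarray, tie_divisor: float) -> float:
    """Tie-corrected H from pooled midranks split into groups of the given sizes."""
    n = pooled_ranks.size
    h = 0.0
    start = 0
    for ni in sizes:
        mean_rank = pooled_ranks[start : start + ni].mean()
        h += ni * (mean_rank - (n + 1) / 2.0) ** 2
        start += ni
    h *= 12.0 / (n * (n + 1))
    return h / tie_divisor if tie_divisor > 0 else 0.0


def _tie_divisor(pooled: np.ndarray) -> float:
    n = pooled.size
    _, counts = np.unique(pooled, return_counts=True)
    return 1.0 - np.sum(counts.astype(float) ** 3 - counts) / (n**3 - n)


def _exact_permutation_p(ranks: np.ndarray, sizes: np.ndarray, tie_divisor: float, h_obs: float) -> float:
    """Enumerate all distinct splits of the pooled ranks into the group sizes."""
    n = ranks.size
    indices = list(range(n))

    def splits(remaining: tuple, size_idx: int):
        if size_idx == len(sizes) - 1:
            yield (remaining,)
            return
        for chosen in combinations(remaining, int(sizes[size_idx])):
            chosen_set = set(chosen)
            rest = tuple(i for i in remaining if i not in chosen_set)
            for tail in splits(rest, size_idx + 1):
                yield (chosen,) + tail

    count = 0
    total = 0
    eps = 1e-12 * max(1.0, abs(h_obs))
    for assignment in splits(tuple(indices), 0):
        perm = np.concatenate([ranks[list(g)] for g in assignment])
        h = _h_statistic(perm, sizes, tie_divisor)
        total += 1
        if h >= h_obs - eps:
            count += 1
    return count / total


@dataclass(frozen=True)
class KruskalResult:
    H: float
    df: int
    p: float
    method: str  # "chi2" or "exact"


def kruskal_wallis(g: GroupedSamples, method: str = "auto") -> KruskalResult:
    """Kruskal-Wallis rank test across the groups of ``g``.

    ``method`` is ``"chi2"`` (asymptotic), ``"exact"`` (full permutation
    enumeration, pooled N <= 10 only) or ``"auto"`` (exact when N <= 10).
    Identical values in every group give H = 0, p = 1.
    """
    sizes = np.array([a.size for a in g.values])
    pooled = np.concatenate(g.values)
    n = pooled.size
    if n < 3:
        raise ValueError("need a pooled sample of at least 3 observations")
    ranks = rankdata(pooled)  # midranks
    divisor = _tie_divisor(pooled)
    if divisor <= 0:  # all values identical
        return KruskalResult(H=0.0, df=len(sizes) - 1, p=1.0, method="degenerate")
    h = _h_statistic(ranks, sizes, divisor)
    df = len(sizes) - 1

    if method == "auto":
        method = "exact" if n <= _EXACT_MAX_N else "chi2"
    if method == "exact":
        if n > _EXACT_MAX_N:
            raise ValueError(f"exact enumeration supported only for pooled N <= {_EXACT_MAX_N}")
        p = _exact_permutation_p(ranks, sizes, divisor, h)
    elif method == "chi2":
        p = float(chi2.sf(h, df))
    else:
        raise ValueError(f"method must be 'auto', 'chi2' or 'exact', got {method!r}")
    return KruskalResult(H=float(h), df=df, p=float(p), method=method)


def stars(p: float) -> str:
    """Significance stars at the 0.05 / 0.01 / 0.001 thresholds."""
    if np.isnan(p):
        return "unavailable"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


def _holm(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = np.sum(np.isfinite(pvals))
    adj = np.full_like(pvals, np.nan)
    running = 0.0
    rank = 0
    for i in order:
        if not np.isfinite(pvals[i]):
            continue
        running = max(running, (m - rank) * pvals[i])
        adj[i] = min(running, 1.0)
        rank += 1
    return adj


def weekly_summary(
    cohort: pd.DataFrame,
    metric: str = "alpha",
    value_col: str = "alpha_observed",
    kw_method: str = "chi2",
    holm: bool = False,
) -> pd.DataFrame:
    """Per-week arm comparison of alpha or peak SSn.

    For each week present in both arms, reports the per-arm mean and standard
    deviation of the metric and the pairwise Kruskal-Wallis H, p and stars.
    ``metric="ssn_peak"`` transforms the alpha column through
    ``1 - alpha*cosech(alpha)`` before summarizing.  Weeks present in a single
    arm are marked unavailable.  ``holm=True`` applies a Holm step-down
    correction across weeks before assigning stars (off by default).
    """
    if metric not in ("alpha", "ssn_peak"):
        raise ValueError(f"metric must be 'alpha' or 'ssn_peak', got {metric!r}")
    required = {"arm", "week", value_col}
    if not required.issubset(cohort.columns):
        raise ValueError(f"cohort table must have columns {sorted(required)}")
    df = cohort.copy()
    df["_metric"] = (
        df[value_col].map(peak_ssn) if metric == "ssn_peak" else df[value_col].astype(float)
    )
    arms = sorted(df["arm"].unique())
    if len(arms) != 2:
        raise ValueError(f"weekly_summary expects exactly 2 arms, found {arms}")

    rows = []
    for week, sub in df.groupby("week", sort=True):
        row = {"week": week, "metric": metric}
        groups = []
        for arm in arms:
            vals = sub.loc[sub["arm"] == arm, "_metric"].to_numpy()
            row[f"mean_{arm}"] = vals.mean() if vals.size else np.nan
            row[f"sd_{arm}"] = vals.std(ddof=1) if vals.size > 1 else np.nan
            row[f"n_{arm}"] = vals.size
            if vals.size:
                groups.append(vals)
        if len(groups) == 2:
            res = kruskal_wallis(GroupedSamples.from_arrays(groups, labels=arms), method=kw_method)
            row["H"], row["p"] = res.H, res.p
        else:
            row["H"], row["p"] = np.nan, np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    p_for_stars = _holm(out["p"].to_numpy()) if holm else out["p"].to_numpy()
    out["stars"] = [stars(p) for p in p_for_stars]
    return out
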