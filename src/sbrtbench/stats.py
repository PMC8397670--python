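"""Cohort aggregation and rank-based group comparison.

Group summaries report median / mean / sample standard deviation per metric
per group (midpoint median for even n; n-1 denominator; std reported absent
for single-plan groups).

``kruskal_wallis`` is a from-scratch tie-corrected Kruskal-Wallis rank test:
midranks for ties, the statistic

    H = [ 12 / (N (N+1)) * sum_i n_i (rbar_i - (N+1)/2)^2 ] / C,
    C = 1 - sum_t (t^3 - t) / (N^3 - N),

and an upper-tail chi-square p-value with k-1 degrees of freedom.  For small
samples (N <= 12) an exact permutation p-value over all distinct group-label
assignments is available.

The benchmark's selective multiplicity policy: the pre-declared primary
metric (the mean PTV dose) is tested without correction; every other metric
in the tested family is Holm-Bonferroni adjusted; significance at 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

__all__ = [
    "KWResult",
    "kruskal_wallis",
    "midranks",
    "summarize",
    "holm_adjust",
    "multiplicity_policy",
]


@dataclass(frozen=True)
class KWResult:
    """Kruskal-Wallis test result (tie-corrected)."""

    H: float
    df: int
    p: float
    group_ns: tuple[int, ...]
    adjusted_p: float | None = None
    exact_p: float | None = None


def midranks(values: np.ndarray) -> np.ndarray:
    """Ranks 1..N with ties assigned their midrank (average of tied positions)."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(values.size, dtype=float)
    sorted_vals = values[order]
    i = 0
    while i < values.size:
        j = i
        while j + 1 < values.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _h_statistic(values: np.ndarray, labels: np.ndarray, n_groups: int) -> float:
    n_total = values.size
    ranks = midranks(values)
    mean_rank = 0.5 * (n_total + 1)
    h = 0.0
    for g in range(n_groups):
        sel = labels == g
        h += sel.sum() * (ranks[sel].mean() - mean_rank) ** 2
    h *= 12.0 / (n_total * (n_total + 1))
    _, counts = np.unique(values, return_counts=True)
    tie_corr = 1.0 - float(((counts**3 - counts).sum())) / (n_total**3 - n_total)
    if tie_corr <= 0:
        return 0.0  # all values identical
    return h / tie_corr


def kruskal_wallis(
    values: Sequence[float] | np.ndarray,
    groups: Sequence | np.ndarray,
    exact: bool = False,
) -> KWResult:
    """Tie-corrected Kruskal-Wallis test of k independent samples.

    Parameters
    ----------
    values, groups
        Flat observations and their group labels (any hashable labels).
    exact
        Also compute the exact permutation p-value (all distinct assignments
        of observations to groups); only permitted for N <= 12.

    If all values are identical, the documented convention is H = 0, p = 1.
    """
    values = np.asarray(values, dtype=float)
    labels_raw = np.asarray(groups)
    if values.shape != labels_raw.shape:
        raise ValueError("values and groups must have the same length")
    uniq = pd.unique(labels_raw)
    k = len(uniq)
    if k < 2:
        raise ValueError("need at least 2 groups")
    labels = np.searchsorted(np.sort(uniq.astype(str)), labels_raw.astype(str))
    group_ns = tuple(int((labels == g).sum()) for g in range(k))
    if min(group_ns) < 1 or values.size < 3:
        raise ValueError("each group needs n >= 1 and total N >= 3")

    h = _h_statistic(values, labels, k)
    df = k - 1
    p = float(chi2.sf(h, df)) if h > 0 else 1.0

    exact_p = None
    if exact:
        if values.size > 12:
            raise ValueError("exact permutation p-value only supported for N <= 12")
        exact_p = _exact_permutation_p(values, group_ns, h)
    return KWResult(H=float(h), df=df, p=p, group_ns=group_ns, exact_p=exact_p)


def _exact_permutation_p(values: np.ndarray, group_ns: tuple[int, ...], h_obs: float) -> float:
    """P(H >= H_obs) over all distinct assignments of observations to groups."""
    n = values.size
    count = 0
    total = 0
    labels = np.empty(n, dtype=int)

    def assign(remaining: tuple[int, ...], g: int) -> None:
        nonlocal count, total
        if g == len(group_ns) - 1:
            labels[list(remaining)] = g
            nonlocal_h = _h_statistic(values, labels, len(group_ns))
            total += 1
            if nonlocal_h >= h_obs - 1e-12:
                count += 1
            return
        for chosen in combinations(remaining, group_ns[g]):
            labels[list(chosen)] = g
            rest = tuple(i for i in remaining if i not in chosen)
            assign(rest, g + 1)

    assign(tuple(range(n)), 0)
    return count / total


def summarize(
    table: pd.DataFrame,
    group_by: str | Sequence[str] = "technique",
    metrics: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Median / mean / std of each metric per group.

    Returns a frame indexed by (metric, statistic) with one column per group;
    std is NaN (reported absent) for single-plan groups.
    """
    if isinstance(group_by, str):
        group_by = [group_by]
    for key in group_by:
        if key not in table.columns:
            raise KeyError(f"grouping column {key!r} not in table")
    if metrics is None:
        metrics = [
            c
            for c in table.columns
            if c not in group_by and pd.api.types.is_numeric_dtype(table[c])
        ]
    grouped = table.groupby(list(group_by), observed=True)
    sizes = grouped.size()
    if (sizes < 1).any():
        raise ValueError("empty group in summary")
    rows = []
    index = []
    for metric in metrics:
        med = grouped[metric].median()
        mean = grouped[metric].mean()
        std = grouped[metric].std(ddof=1)  # NaN for n = 1
        for stat, series in (("median", med), ("mean", mean), ("std", std)):
            rows.append(series)
            index.append((metric, stat))
    out = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(index, names=["metric", "stat"]))
    return out


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m, dtype=float)
    running_max = 0.0
    for rank, idx in enumerate(order):
        val = min(1.0, (m - rank) * p[idx])
        running_max = max(running_max, val)
        adjusted[idx] = running_max
    return adjusted


def multiplicity_policy(
    results: Mapping[str, KWResult], primary_metric: str
) -> dict[str, KWResult]:
    """Apply the selective correction policy to a family of test results.

    The primary metric's p-value is reported unadjusted; all other metrics
    are Holm-Bonferroni adjusted within the family.
    """
    if primary_metric not in results:
        raise KeyError(f"primary metric {primary_metric!r} not among results")
    others = [name for name in results if name != primary_metric]
    adjusted = holm_adjust([results[name].p for name in others]) if others else []
    out: dict[str, KWResult] = {
        primary_metric: replace(results[primary_metric], adjusted_p=results[primary_metric].p)
    }
    for name, adj in zip(others, adjusted):
        out[name] = replace(results[name], adjusted_p=float(adj))
    return out
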