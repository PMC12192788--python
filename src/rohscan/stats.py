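"""Nonparametric between-breed comparisons of per-animal run statistics.

Per-animal ROH counts and length sums are heavily tied, skewed small-integer
data, so breed contrasts use the two-sided Wilcoxon rank-sum (Mann–Whitney)
test with midranks; normality is screened with Shapiro–Wilk.  The exact
null distribution of the U statistic is computed in-package by the standard
counting recursion (applicable for small untied samples); larger or tied
samples use the normal approximation with tie and continuity corrections.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class ComparisonResult:
    statistic_name: str
    group_x: str
    group_y: str
    u_statistic: float
    rank_sum: float
    p_value: float
    n_x: int
    n_y: int
    method: str


def shapiro_wilk(sample) -> tuple[float, float]:
    """Shapiro–Wilk normality test; (W, p).  Errors on constant samples."""
    x = np.asarray(sample, dtype=float)
    if len(x) < 3:
        raise ValueError("Shapiro-Wilk requires n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant sample")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def exact_u_distribution(n_x: int, n_y: int) -> np.ndarray:
    """Null counts of the Mann–Whitney U statistic (no ties).

    ``out[u]`` is the number of the C(n_x+n_y, n_x) equally likely rank
    assignments giving U = u, built by the classical recursion
    f(m, n, u) = f(m−1, n, u−n) + f(m, n−1, u).
    """
    max_u = n_x * n_y
    # f[n][u] for current m
    prev = [np.zeros(max_u + 1) for _ in range(n_y + 1)]
    for nn in range(n_y + 1):
        prev[nn][0] = 1.0
    for m in range(1, n_x + 1):
        cur = [np.zeros(max_u + 1) for _ in range(n_y + 1)]
        cur[0][0] = 1.0
        for nn in range(1, n_y + 1):
            cur[nn][:] = cur[nn - 1][:]
            shifted = np.zeros(max_u + 1)
            if nn <= max_u:
                shifted[nn:] = prev[nn][:max_u + 1 - nn]
            else:
                shifted[:] = 0.0
            cur[nn] += shifted
        prev = cur
    return prev[n_y]


def wilcoxon_rank_sum(
    x, y, mode: str = "auto",
    statistic_name: str = "", group_x: str = "x", group_y: str = "y",
) -> ComparisonResult:
    """Two-sided Wilcoxon rank-sum test.

    mode:
      - "exact": exact p by the U null distribution (requires no ties),
      - "normal": normal approximation with tie and continuity corrections,
      - "auto": exact when n_x ≤ 10, n_y ≤ 10 and there are no ties.

    The two-sided exact p is 2·min(P(U ≤ u), P(U ≥ u)) capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    if mode not in ("exact", "normal", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    n_x, n_y = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = _midranks(combined)
    rank_sum_x = float(ranks[:n_x].sum())
    u = rank_sum_x - n_x * (n_x + 1) / 2.0
    has_ties = len(np.unique(combined)) < len(combined)

    use_exact = (mode == "exact") or (
        mode == "auto" and n_x <= 10 and n_y <= 10 and not has_ties)
    if use_exact and has_ties:
        raise ValueError("exact mode requires untied data")

    if use_exact:
        counts = exact_u_distribution(n_x, n_y)
        total = counts.sum()
        ui = int(round(u))
        p_le = counts[: ui + 1].sum() / total
        p_ge = counts[ui:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        method = "exact"
    else:
        n = n_x + n_y
        mu = n_x * n_y / 2.0
        # tie correction on the rank variance
        _, tie_counts = np.unique(combined, return_counts=True)
        tie_term = float(((tie_counts ** 3) - tie_counts).sum())
        var = n_x * n_y / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
        if var <= 0:
            p = 1.0
        else:
            z = (abs(u - mu) - 0.5) / math.sqrt(var)
            z = max(z, 0.0)
            p = min(1.0, 2.0 * sps.norm.sf(z))
        method = "normal"
    return ComparisonResult(
        statistic_name=statistic_name, group_x=group_x, group_y=group_y,
        u_statistic=float(u), rank_sum=rank_sum_x, p_value=float(p),
        n_x=n_x, n_y=n_y, method=method,
    )


def pairwise_breed_tests(
    animal_summary: pd.DataFrame,
    statistics: tuple[str, ...] = ("n_runs", "sum_length_bp"),
    mode: str = "auto",
    bonferroni: bool = True,
) -> pd.DataFrame:
    """Wilcoxon rank-sum tests for every breed pair, class, and statistic.

    ``animal_summary`` is the long-format per-animal table from
    :func:`rohscan.summaries.per_animal_summary`.  Breeds with fewer than 2
    animals are excluded with a warning.  Returns a long-format table with
    raw p-values; the optional Bonferroni column adjusts within each
    (statistic, class) family across breed pairs.
    """
    sizes = animal_summary.groupby("population")["sample_id"].nunique()
    breeds = [b for b in sizes.index if sizes[b] >= 2]
    dropped = [b for b in sizes.index if sizes[b] < 2]
    if dropped:
        warnings.warn(f"excluded breeds with <2 animals: {dropped}")
    if len(breeds) < 2:
        return pd.DataFrame(columns=[
            "statistic", "length_class", "breed_x", "breed_y",
            "u_statistic", "p_value", "p_bonferroni", "n_x", "n_y", "method",
        ])
    breeds = sorted(breeds)
    rows = []
    n_pairs = len(breeds) * (len(breeds) - 1) // 2
    for stat in statistics:
        for cls, sub in animal_summary.groupby("length_class", sort=False):
            values = {
                b: sub.loc[sub["population"] == b, stat].to_numpy(dtype=float)
                for b in breeds
            }
            for bx, by in combinations(breeds, 2):
                res = wilcoxon_rank_sum(
                    values[bx], values[by], mode=mode,
                    statistic_name=stat, group_x=bx, group_y=by,
                )
                rows.append((
                    stat, cls, bx, by, res.u_statistic, res.p_value,
                    min(1.0, res.p_value * n_pairs), res.n_x, res.n_y,
                    res.method,
                ))
    return pd.DataFrame(rows, columns=[
        "statistic", "length_class", "breed_x", "breed_y",
        "u_statistic", "p_value", "p_bonferroni", "n_x", "n_y", "method",
    ])
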