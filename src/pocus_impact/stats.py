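"""Descriptive and comparative statistics for the stratified analysis.

Provides the per-10,000-inhabitant scan rates, the stratum summaries
(mean, SD, normal-approximation 95% CI, total) used by the travel and
emissions tables, and the rural-vs-urban Mann-Whitney rank-sum test with
an exact-enumeration mode for small groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import add_rurality
from .synth import SCAN_TYPES

Z_95 = 1.959963984540054  # two-sided 97.5% normal quantile


@dataclass(frozen=True)
class SummaryStats:
    n: int
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    total: float


def stratum_summary(values: Iterable[float]) -> SummaryStats:
    """Mean, sample SD, normal-approximation 95% CI and total.

    CI = mean +/- 1.96 * sd / sqrt(n). With a single observation the SD,
    and therefore the CI width, is undefined; both bounds are NaN.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("stratum_summary requires at least one value")
    mean = float(arr.mean())
    total = float(arr.sum())
    if arr.size == 1:
        return SummaryStats(1, mean, math.nan, math.nan, math.nan, total)
    sd = float(arr.std(ddof=1))
    half = Z_95 * sd / math.sqrt(arr.size)
    return SummaryStats(int(arr.size), mean, sd, mean - half, mean + half, total)


def rate_per_10k(count: float, population: float) -> float:
    """Scans per 10,000 assigned inhabitants."""
    if population <= 0:
        raise ValueError("population must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / population * 10_000


def scan_rate_table(register: pd.DataFrame, centres: pd.DataFrame) -> pd.DataFrame:
    """Per-centre scan rates per 10^4 assigned inhabitants, by scan type.

    One row per centre plus unweighted stratum-mean rows (``rural``,
    ``urban``); columns are the scan types plus ``total``.
    """
    cent = add_rurality(centres).set_index("centre_id")
    counts = (
        register.groupby(["centre_id", "scan_type"]).size().unstack(fill_value=0)
        .reindex(columns=list(SCAN_TYPES), fill_value=0)
        .reindex(cent.index, fill_value=0)
    )
    rates = counts.div(cent["assigned_population"], axis=0) * 10_000
    rates["total"] = rates.sum(axis=1)
    rates["rurality"] = cent["rurality"]
    stratum_means = rates.groupby("rurality")[rates.columns[:-1]].mean()
    out = pd.concat([rates.drop(columns="rurality"), stratum_means])
    out.index.name = "centre_id"
    return out


@dataclass(frozen=True)
class RankSumResult:
    u_statistic: float  # U for the first group
    p_value: float
    method: str  # "exact" or "asymptotic"


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def _u_from_ranks(rank_sum_a: float, n_a: int) -> float:
    return rank_sum_a - n_a * (n_a + 1) / 2.0


def rank_sum_exact(group_a: Sequence[float], group_b: Sequence[float]) -> RankSumResult:
    """Exact two-sided Mann-Whitney test by full enumeration.

    Enumerates all C(n_a + n_b, n_a) assignments of the pooled midranks,
    so ties are handled exactly. Two-sided p-value by the doubled-tail
    convention, min(1, 2 * min(P(U <= u_obs), P(U >= u_obs))). Intended
    as the oracle for the asymptotic mode; cost grows combinatorially,
    keep groups small.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ranks = _midranks(np.concatenate([a, b]))
    n_a, n = a.size, a.size + b.size
    u_obs = _u_from_ranks(float(ranks[:n_a].sum()), n_a)
    lower = upper = total = 0
    for idx in combinations(range(n), n_a):
        u = _u_from_ranks(float(ranks[list(idx)].sum()), n_a)
        total += 1
        if u <= u_obs + 1e-12:
            lower += 1
        if u >= u_obs - 1e-12:
            upper += 1
    p = min(1.0, 2.0 * min(lower, upper) / total)
    return RankSumResult(u_obs, p, "exact")


def rank_sum_asymptotic(
    group_a: Sequence[float], group_b: Sequence[float]
) -> RankSumResult:
    """Two-sided normal approximation with tie correction and continuity
    correction (delegates to :func:`scipy.stats.mannwhitneyu`)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ranks = _midranks(np.concatenate([a, b]))
    u_obs = _u_from_ranks(float(ranks[: a.size].sum()), a.size)
    if np.ptp(np.concatenate([a, b])) == 0:  # all observations tied
        return RankSumResult(u_obs, 1.0, "asymptotic")
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return RankSumResult(float(res.statistic), float(res.pvalue), "asymptotic")


def rank_sum_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    method: str = "auto",
) -> RankSumResult:
    """Mann-Whitney U test of two independent groups (two-sided).

    ``method="auto"`` enumerates exactly when both groups have at most
    8 observations and falls back to the tie- and continuity-corrected
    normal approximation otherwise.
    """
    if method == "auto":
        method = "exact" if len(group_a) <= 8 and len(group_b) <= 8 else "asymptotic"
    if method == "exact":
        return rank_sum_exact(group_a, group_b)
    if method == "asymptotic":
        return rank_sum_asymptotic(group_a, group_b)
    raise ValueError(f"unknown method {method!r}")
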