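"""Method comparison by aligned-rank statistics.

A :class:`ResultsTable` holds balanced accuracies with one row per
observation block (data partition, possibly concatenated over N_t values and
subjects) and one column per method.  The omnibus test is the Friedman
aligned-ranks (Hodges-Lehmann) test: values are aligned by subtracting the
row mean, all n*k aligned values are ranked jointly (ties get average ranks)
and the statistic

    T = (k-1) [sum_j Rc_j^2 - (k n^2 / 4)(k n + 1)^2]
        / [k n (k n + 1)(2 k n + 1) / 6 - (1/k) sum_i Rr_i^2]

(with Rc_j the column and Rr_i the row aligned-rank sums) is referred to a
chi-square with k-1 degrees of freedom.  All-pairs post-hoc comparisons use
z = (Rbar_i - Rbar_j) / sqrt(k (k n + 1) / 6) on mean aligned ranks with the
Shaffer static step-down correction.  Mean ranks shown on critical-difference
scales use classical per-block rankings (rank 1 = best, i.e. highest
accuracy), while the hypothesis tests use aligned ranks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ResultsTable", "ComparisonSummary", "friedman_aligned",
           "pairwise_shaffer", "significance_groups", "frequency_matrix",
           "shaffer_sets"]


@dataclass
class ResultsTable:
    """Observation blocks x methods table of balanced accuracies."""

    values: np.ndarray
    methods: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (blocks x methods)")
        if self.values.shape[1] != len(self.methods):
            raise ValueError("method names must match column count")
        if len(self.methods) < 2:
            raise ValueError("need at least 2 methods")
        if np.isnan(self.values).any():
            raise ValueError("missing entries are not allowed")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ResultsTable":
        return cls(values=df.to_numpy(dtype=float),
                   methods=list(df.columns))

    @classmethod
    def concat(cls, tables: list["ResultsTable"]) -> "ResultsTable":
        """Row-stack tables (pooling across N_t values and/or subjects)."""
        methods = tables[0].methods
        for t in tables[1:]:
            if t.methods != methods:
                raise ValueError("method sets differ across tables")
        return cls(values=np.vstack([t.values for t in tables]),
                   methods=methods)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.methods)


@dataclass
class ComparisonSummary:
    methods: list[str]
    mean_rank: np.ndarray              # classical per-block mean ranks
    statistic: float
    p_value: float
    pairwise_p: np.ndarray             # Shaffer-adjusted, symmetric
    raw_pairwise_p: np.ndarray
    alpha: float
    groups: list[tuple[int, ...]] = field(default_factory=list)
    degenerate: bool = False


def _aligned_ranks(values: np.ndarray) -> np.ndarray:
    aligned = values - values.mean(axis=1, keepdims=True)
    return stats.rankdata(aligned, axis=None).reshape(values.shape)


def friedman_aligned(table: ResultsTable) -> tuple[float, float]:
    """Friedman aligned-ranks omnibus statistic and chi-square p-value.

    A table whose rows are all internally constant (no method effect can be
    ranked) is degenerate and returns (nan, 1.0).
    """
    n, k = table.n, table.k
    if n < 2:
        raise ValueError("need at least 2 blocks")
    if np.ptp(table.values, axis=1).max() == 0:
        return float("nan"), 1.0
    r = _aligned_ranks(table.values)
    col_sums = r.sum(axis=0)
    row_sums = r.sum(axis=1)
    num = (k - 1) * (np.sum(col_sums ** 2)
                     - (k * n ** 2 / 4.0) * (k * n + 1) ** 2)
    den = (k * n * (k * n + 1) * (2 * k * n + 1) / 6.0
           - np.sum(row_sums ** 2) / k)
    if den <= 0:
        return float("nan"), 1.0
    T = num / den
    return float(T), float(stats.chi2.sf(T, k - 1))


@lru_cache(maxsize=None)
def shaffer_sets(k: int) -> frozenset:
    """Possible numbers of simultaneously true pairwise hypotheses among
    k methods: S(k) = union over j of {C(j,2) + s : s in S(k-j)}, S(0)={0}."""
    if k == 0:
        return frozenset({0})
    out = set()
    for j in range(1, k + 1):
        out.update(comb(j, 2) + s for s in shaffer_sets(k - j))
    return frozenset(out)


def _shaffer_adjust(raw_p: np.ndarray, k: int) -> np.ndarray:
    """Static step-down Shaffer adjustment of the m = k(k-1)/2 raw p-values."""
    m = len(raw_p)
    s_k = sorted(shaffer_sets(k))
    order = np.argsort(raw_p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for step, idx in enumerate(order):
        tenable = m - step
        t_step = max(s for s in s_k if s <= tenable)
        running = max(running, min(1.0, t_step * raw_p[idx]))
        adj[idx] = running
    return adj


def pairwise_shaffer(table: ResultsTable, alpha: float = 0.05
                     ) -> ComparisonSummary:
    """All-pairs aligned-ranks comparison with Shaffer FWE correction."""
    n, k = table.n, table.k
    stat, p_omni = friedman_aligned(table)
    degenerate = not np.isfinite(stat)

    r_aligned = _aligned_ranks(table.values)
    col_sums = r_aligned.sum(axis=0)
    row_sums = r_aligned.sum(axis=1)
    # variance of a column-sum difference consistent with the omnibus
    # denominator D: Var(Rc_i - Rc_j) = 2 D / (k - 1), with D carrying the
    # row-sum correction of the Hodges-Lehmann statistic
    D = (k * n * (k * n + 1) * (2 * k * n + 1) / 6.0
         - np.sum(row_sums ** 2) / k)
    se = np.sqrt(max(2.0 * D / (k - 1), 0.0))
    raw = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if se > 0:
                z = (col_sums[i] - col_sums[j]) / se
                p = 2.0 * stats.norm.sf(abs(z))
            else:
                p = 1.0
            raw[i, j] = raw[j, i] = p
    iu = np.triu_indices(k, 1)
    if degenerate:
        adj_mat = np.ones((k, k))
    else:
        adj = _shaffer_adjust(raw[iu], k)
        adj_mat = np.ones((k, k))
        adj_mat[iu] = adj
        adj_mat.T[iu] = adj
    np.fill_diagonal(adj_mat, 1.0)
    np.fill_diagonal(raw, 1.0)

    # CD-display mean ranks: classical per-block ranking, rank 1 = best
    classical = stats.rankdata(-table.values, axis=1).mean(axis=0)

    summary = ComparisonSummary(
        methods=list(table.methods), mean_rank=classical,
        statistic=stat, p_value=p_omni, pairwise_p=adj_mat,
        raw_pairwise_p=raw, alpha=alpha, degenerate=degenerate)
    summary.groups = significance_groups(summary, alpha)
    return summary


def significance_groups(summary: ComparisonSummary,
                        alpha: float = 0.05) -> list[tuple[int, ...]]:
    """Critical-difference grouping: methods sorted by mean rank; maximal
    runs of consecutive methods with no significant pairwise difference."""
    k = len(summary.methods)
    order = np.argsort(summary.mean_rank, kind="stable")
    sig = summary.pairwise_p < alpha
    intervals = []
    for a in range(k):
        b = a
        while b + 1 < k and not any(
                sig[order[i], order[j]]
                for i in range(a, b + 2) for j in range(i + 1, b + 2)):
            b += 1
        intervals.append((a, b))
    groups = []
    for a, b in intervals:
        if any(a2 <= a and b <= b2 and (a2, b2) != (a, b)
               for a2, b2 in intervals):
            continue
        g = tuple(int(order[i]) for i in range(a, b + 1))
        if g not in groups:
            groups.append(g)
    return groups


def frequency_matrix(per_subject: list[ComparisonSummary]) -> pd.DataFrame:
    """Cross-subject superiority counts.

    Entry (i, j) counts subjects for which method i had a better (smaller)
    mean rank than j AND the (i, j) difference was significant at the
    summary's alpha.  Row sums = 'times better', column sums = 'times worse'.
    """
    methods = per_subject[0].methods
    for s in per_subject[1:]:
        if s.methods != methods:
            raise ValueError("method sets differ across subjects")
    k = len(methods)
    counts = np.zeros((k, k), dtype=int)
    for s in per_subject:
        sig = s.pairwise_p < s.alpha
        for i in range(k):
            for j in range(k):
                if i != j and sig[i, j] and s.mean_rank[i] < s.mean_rank[j]:
                    counts[i, j] += 1
    return pd.DataFrame(counts, index=methods, columns=methods)
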