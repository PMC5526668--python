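"""Inferential toolkit: exact r x c Fisher tests (probability-mass two-sided
criterion), 2 x 2 sample odds ratios with zero-cell markers, seeded two-sample
permutation tests, and Pearson correlation."""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

__all__ = [
    "ContingencyTable",
    "fisher_exact_rxc",
    "odds_ratio_2x2",
    "permutation_test_two_sample",
    "pearson_correlation",
]

_REL_TOL = 1.0 + 1e-7  # tolerance when comparing table probabilities


@dataclass
class ContingencyTable:
    counts: np.ndarray
    row_labels: tuple[str, ...] | None = None
    col_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or min(self.counts.shape) < 2:
            raise ValueError("contingency table must be at least 2 x 2")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.counts.sum(axis=1) == 0) or np.any(self.counts.sum(axis=0) == 0):
            raise ValueError("degenerate margin: all-zero row or column")


def _log_table_prob(table: np.ndarray, logfact_margins: float, logn: float) -> float:
    """log P(table | margins) under the multivariate hypergeometric null."""
    return logfact_margins - logn - float(gammaln(table + 1).sum())


def _enumerate_tables(row_sums, col_sums, budget):
    """Yield all non-negative integer tables with the given margins.

    Raises ``OverflowError`` once more than ``budget`` tables were generated.
    """
    r, c = len(row_sums), len(col_sums)
    table = np.zeros((r, c), dtype=np.int64)
    count = 0

    def rec(i: int, remaining_cols: np.ndarray):
        nonlocal count
        if i == r - 1:
            if np.all(remaining_cols >= 0):
                table[r - 1] = remaining_cols
                count += 1
                if count > budget:
                    raise OverflowError
                yield table
            return
        yield from fill_row(i, 0, row_sums[i], remaining_cols)

    def fill_row(i: int, j: int, left: int, remaining_cols: np.ndarray):
        if j == c - 1:
            if left <= remaining_cols[j]:
                table[i, j] = left
                remaining_cols[j] -= left
                yield from rec(i + 1, remaining_cols)
                remaining_cols[j] += left
            return
        for v in range(min(left, remaining_cols[j]) + 1):
            table[i, j] = v
            remaining_cols[j] -= v
            yield from fill_row(i, j + 1, left - v, remaining_cols)
            remaining_cols[j] += v

    yield from rec(0, np.asarray(col_sums, dtype=np.int64).copy())


def fisher_exact_rxc(
    table,
    *,
    mode: str = "auto",
    enumeration_budget: int = 2_000_000,
    mc_reps: int = 1_000_000,
    seed: int | None = None,
) -> float:
    """Two-sided Fisher exact test for an r x c table.

    Exact mode enumerates every table with the observed margins and sums the
    null probabilities of tables whose probability does not exceed the
    observed one (the probability-mass two-sided criterion, with a small
    relative tolerance). When the enumeration exceeds ``enumeration_budget``
    (or ``mode='mc'``), a seeded Monte Carlo over random tables with fixed
    margins is used and the add-one-corrected p is returned.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(np.asarray(table))
    counts = table.counts
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    n = int(counts.sum())
    logfact_margins = float(gammaln(row_sums + 1).sum() + gammaln(col_sums + 1).sum())
    logn = float(gammaln(n + 1))
    log_obs = _log_table_prob(counts, logfact_margins, logn)
    cutoff = log_obs + math.log(_REL_TOL)

    if mode not in ("auto", "exact", "mc"):
        raise ValueError(f"unknown mode {mode!r}")

    if mode in ("auto", "exact"):
        try:
            total = 0.0
            for t in _enumerate_tables(row_sums.tolist(), col_sums.tolist(),
                                       enumeration_budget if mode == "auto" else 10**18):
                lp = _log_table_prob(t, logfact_margins, logn)
                if lp <= cutoff:
                    total += math.exp(lp)
            return min(total, 1.0)
        except OverflowError:
            if mode == "exact":
                raise
    # Monte Carlo: random tables with fixed margins via random_table (Patefield)
    rng = np.random.default_rng(seed)
    sampler = sps.random_table(row_sums, col_sums, seed=rng)
    hits = 0
    chunk = 10_000
    done = 0
    while done < mc_reps:
        m = min(chunk, mc_reps - done)
        tables = sampler.rvs(size=m)
        lps = logfact_margins - logn - gammaln(tables + 1).sum(axis=(1, 2))
        hits += int(np.count_nonzero(lps <= cutoff))
        done += m
    return (hits + 1) / (mc_reps + 1)


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> float:
    """Sample odds ratio ``(a*d)/(b*c)`` with no continuity correction.

    Zero-cell semantics follow the reporting convention: 0 when the numerator
    is zero and the denominator positive, ``inf`` for the reverse, and NaN
    when both vanish. The caller chooses the orientation by ordering the
    cells (e.g. rescue-odds vs. extinction-odds).
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("counts must be non-negative")
    num, den = a * d, b * c
    if num == 0 and den == 0:
        return math.nan
    if den == 0:
        return math.inf
    return num / den


def permutation_test_two_sample(
    x,
    y,
    *,
    statistic=None,
    reps: int = 10_000,
    seed: int | None = None,
    sided: str = "two",
    exact_budget: int = 100_000,
) -> float:
    """Two-sample permutation test on the difference of group means (or a
    custom ``statistic(x, y)``).

    Full enumeration of group assignments when ``C(n, |x|)`` is within
    ``exact_budget``; otherwise seeded Monte Carlo with the add-one-corrected
    p-value ``(b + 1) / (reps + 1)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    if statistic is None:
        statistic = lambda a, b: float(np.mean(a) - np.mean(b))
    pooled = np.concatenate([x, y])
    nx, n = x.size, x.size + y.size
    obs = statistic(x, y)

    def extreme(val: float) -> bool:
        tol = 1e-12 * (1.0 + abs(obs))
        if sided == "two":
            return abs(val) >= abs(obs) - tol
        if sided == "greater":
            return val >= obs - tol
        if sided == "less":
            return val <= obs + tol
        raise ValueError(f"unknown sidedness {sided!r}")

    if math.comb(n, nx) <= exact_budget:
        hits = total = 0
        idx = np.arange(n)
        for combo in combinations(idx, nx):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            if extreme(statistic(pooled[mask], pooled[~mask])):
                hits += 1
            total += 1
        return hits / total

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(reps):
        perm = rng.permutation(pooled)
        if extreme(statistic(perm[:nx], perm[nx:])):
            hits += 1
    return (hits + 1) / (reps + 1)


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson r with the two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
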