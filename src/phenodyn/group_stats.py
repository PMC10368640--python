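"""Group comparisons: exact contingency tests with multiplicity correction,
two-tailed t tests with fold changes, and class-proportion summaries.

The 2x2 Fisher test is exact (point-probability rule).  General r x c
tables use a Monte Carlo exact test: tables are sampled from the
fixed-margin null and the p-value is the fraction whose hypergeometric
point probability does not exceed the observed one, with the standard +1
correction so the estimate is never exactly zero.  Holm step-down is the
default multiplicity correction — the method is unconditionally valid and
uniformly better than Bonferroni.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencySummary",
    "GroupComparison",
    "fisher_exact_2x2",
    "fisher_exact_rxc",
    "adjust_pvalues",
    "t_test_two_tailed",
    "proportions_summary",
]


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table."""
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float)
        if np.any(arr < 0) or np.any(arr != np.round(arr)):
            raise ValueError("table entries must be non-negative integers")
        arr = arr.astype(int)
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def _log_point_prob(tables: np.ndarray, row_sums: np.ndarray, col_sums: np.ndarray) -> np.ndarray:
    """Log hypergeometric point probability of fixed-margin tables.

    ``tables`` is (..., r, c); margins are shared.
    """
    n = row_sums.sum()
    const = gammaln(row_sums + 1).sum() + gammaln(col_sums + 1).sum() - gammaln(n + 1)
    return const - gammaln(tables + 1).sum(axis=(-2, -1))


def fisher_exact_rxc(
    table, n_mc: int = 100_000, seed: int = 0
) -> tuple[float, float]:
    """Monte Carlo exact test for an r x c table.

    Returns ``(p, mc_standard_error)``.  Null tables share the observed
    margins; for two rows they are drawn directly from the multivariate
    hypergeometric law, for more rows by random permutation of category
    labels.  ``p`` uses the (1 + hits) / (1 + n_mc) correction and is
    deterministic under ``seed``.
    """
    arr = np.asarray(table, dtype=int)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if np.any(arr < 0):
        raise ValueError("table entries must be non-negative")
    total = arr.sum()
    if total == 0:
        raise ValueError("table total must be positive")
    row_sums = arr.sum(axis=1)
    col_sums = arr.sum(axis=0)
    if np.any(row_sums == 0) or np.any(col_sums == 0):
        return 1.0, 0.0

    rng = np.random.default_rng(seed)
    obs_lp = _log_point_prob(arr, row_sums, col_sums)
    r, c = arr.shape

    if r == 2:
        first = rng.multivariate_hypergeometric(col_sums, int(row_sums[0]), size=n_mc)
        tables = np.stack([first, col_sums[None] - first], axis=1)
    else:
        labels = np.repeat(np.arange(c), col_sums)
        keys = rng.random((n_mc, total))
        perms = labels[np.argsort(keys, axis=1)]
        bounds = np.concatenate([[0], np.cumsum(row_sums)])
        tables = np.empty((n_mc, r, c), dtype=int)
        for gi in range(r):
            seg = perms[:, bounds[gi] : bounds[gi + 1]]
            for k in range(c):
                tables[:, gi, k] = (seg == k).sum(axis=1)

    lp = _log_point_prob(tables, row_sums, col_sums)
    hits = int(np.sum(lp <= obs_lp + 1e-9))
    p = (1 + hits) / (1 + n_mc)
    se = float(np.sqrt(p * (1 - p) / n_mc))
    return float(p), se


def adjust_pvalues(pvals, method: str = "holm") -> np.ndarray:
    """Holm (default) or Bonferroni adjusted p-values, clipped at 1."""
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in ("holm", "bonferroni"):
        raise ValueError(f"unknown correction {method!r}")
    return multipletests(arr, method=method)[1]


@dataclass
class GroupComparison:
    mean_x: float
    mean_y: float
    sem_x: float
    sem_y: float
    n_x: int
    n_y: int
    t_statistic: float
    p_value: float
    fold_change: float  # reference mean / test mean
    welch: bool = False
    degenerate: bool = False


def t_test_two_tailed(x, y, welch: bool = False) -> GroupComparison:
    """Two-tailed t test (Student pooled by default, Welch optional) with
    SEMs and the reference/test fold change.  ``x`` is the reference group."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    degenerate = False
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0 and np.mean(x) == np.mean(y):
        t_stat, p = 0.0, 1.0
        degenerate = True
    else:
        t_stat, p = stats.ttest_ind(x, y, equal_var=not welch)
    my = float(np.mean(y))
    return GroupComparison(
        mean_x=float(np.mean(x)),
        mean_y=my,
        sem_x=float(np.std(x, ddof=1) / np.sqrt(len(x))),
        sem_y=float(np.std(y, ddof=1) / np.sqrt(len(y))),
        n_x=len(x),
        n_y=len(y),
        t_statistic=float(t_stat),
        p_value=float(p),
        fold_change=float(np.mean(x) / my) if my != 0 else np.inf,
        welch=welch,
        degenerate=degenerate,
    )


@dataclass
class ContingencySummary:
    groups: list[str]
    categories: list
    counts: np.ndarray  # (groups, categories)
    proportions: np.ndarray
    pairs: list[tuple[str, str]]
    p_values: np.ndarray
    mc_errors: np.ndarray
    adjusted_p: np.ndarray
    correction: str = "holm"

    def __post_init__(self) -> None:
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.adjusted_p + 1e-12 < self.p_values):
            raise ValueError("adjusted p must not be below raw p")


def proportions_summary(
    labels_by_group: dict[str, "list | np.ndarray"],
    categories: list | None = None,
    correction: str = "holm",
    n_mc: int = 20_000,
    seed: int = 0,
) -> ContingencySummary:
    """Class counts and proportions per group, with all pairwise Monte
    Carlo exact tests and Holm adjustment."""
    groups = list(labels_by_group)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g, labs in labels_by_group.items():
        if len(labs) == 0:
            raise ValueError(f"group {g!r} has no cells")
    if categories is None:
        categories = sorted({l for labs in labels_by_group.values() for l in labs})
    cat_index = {cat: k for k, cat in enumerate(categories)}
    counts = np.zeros((len(groups), len(categories)), dtype=int)
    for gi, g in enumerate(groups):
        for lab in labels_by_group[g]:
            counts[gi, cat_index[lab]] += 1
    proportions = counts / counts.sum(axis=1, keepdims=True)

    pairs = list(itertools.combinations(range(len(groups)), 2))
    ss = np.random.SeedSequence(seed)
    pair_seeds = ss.generate_state(len(pairs)) % (2**31 - 1)
    pvals, errs = [], []
    for (i, j), s in zip(pairs, pair_seeds):
        sub = counts[[i, j]]
        nonzero = sub.sum(axis=0) > 0
        sub = sub[:, nonzero]
        if sub.shape[1] < 2:
            p, e = 1.0, 0.0
        else:
            p, e = fisher_exact_rxc(sub, n_mc=n_mc, seed=int(s))
        pvals.append(p)
        errs.append(e)
    adjusted = adjust_pvalues(pvals, method=correction)
    return ContingencySummary(
        groups=groups,
        categories=list(categories),
        counts=counts,
        proportions=proportions,
        pairs=[(groups[i], groups[j]) for i, j in pairs],
        p_values=np.asarray(pvals),
        mc_errors=np.asarray(errs),
        adjusted_p=np.asarray(adjusted),
        correction=correction,
    )
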