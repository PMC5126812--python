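"""Descriptive and inferential statistics for cohort comparisons.

Covers the analyses run on the three disease groups: collapsed-category
contingency tables, an exact r×c Fisher test, one-way ANOVA, Pearson
correlation / simple linear regression, per-group summaries and the
tertile split that defines the economic simulation's treatment group.

The Fisher test is exact by exhaustive enumeration of all tables with
the observed margins (two-sided p = sum of probabilities of tables no
more likely than the observed one, the convention of standard
statistical software).  A seeded Monte-Carlo fallback using the
Patefield fixed-margin sampler handles tables beyond the enumeration
budget.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import lgamma
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

from .cohort import DISEASES, Cohort
from .eq5d import DIMENSIONS, ProblemCategory, collapse_level

__all__ = [
    "ContingencyTable",
    "GroupSummary",
    "TertileSplit",
    "build_contingency",
    "contingency_from_counts",
    "fisher_exact",
    "anova_oneway",
    "fit_linear",
    "summarize",
    "split_tertiles",
]

CATEGORY_ORDER = (
    ProblemCategory.NO_SLIGHT,
    ProblemCategory.MODERATE,
    ProblemCategory.SEVERE_EXTREME,
)

# Relative tolerance for counting equally-likely tables as ties in the
# two-sided Fisher p-value.
_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """r×c table of counts with labelled rows and columns."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.row_labels),
                            columns=list(self.col_labels))


def build_contingency(cohort: Cohort, dimension: str) -> ContingencyTable:
    """Disease × collapsed-category table for one EQ-5D-5L dimension.

    Rows are the disease groups present in the cohort (in reporting
    order); columns are the three problem categories; the grand total
    equals the cohort size.
    """
    dim = dimension.upper()
    if dim not in DIMENSIONS:
        raise KeyError(f"unknown dimension {dimension!r}; expected one of {DIMENSIONS}")
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    col = dim.lower()
    diseases = tuple(d for d in DISEASES if (cohort.df.disease == d).any())
    counts = np.zeros((len(diseases), len(CATEGORY_ORDER)), dtype=int)
    cat_index = {cat: j for j, cat in enumerate(CATEGORY_ORDER)}
    for i, disease in enumerate(diseases):
        levels = cohort.df.loc[cohort.df.disease == disease, col]
        for lvl in levels:
            counts[i, cat_index[collapse_level(int(lvl))]] += 1
    return ContingencyTable(
        diseases, tuple(c.value for c in CATEGORY_ORDER), counts
    )


def contingency_from_counts(counts: pd.DataFrame, dimension: str) -> ContingencyTable:
    """Collapsed disease × category table from a per-level count table
    (columns ``dimension, disease, level, count``)."""
    dim = dimension.upper()
    sub = counts[counts.dimension == dim]
    if sub.empty:
        raise KeyError(f"no counts for dimension {dimension!r}")
    diseases = tuple(d for d in DISEASES if (sub.disease == d).any())
    table = np.zeros((len(diseases), len(CATEGORY_ORDER)), dtype=int)
    cat_index = {cat: j for j, cat in enumerate(CATEGORY_ORDER)}
    for row in sub.itertuples():
        i = diseases.index(row.disease)
        table[i, cat_index[collapse_level(int(row.level))]] += int(row.count)
    return ContingencyTable(
        diseases, tuple(c.value for c in CATEGORY_ORDER), table
    )


# ---------------------------------------------------------------------------
# Exact Fisher test


def _log_table_prob_const(rows: np.ndarray, cols: np.ndarray) -> float:
    n = rows.sum()
    return (sum(lgamma(r + 1) for r in rows)
            + sum(lgamma(c + 1) for c in cols)
            - lgamma(n + 1))


def _enumerate_pvalue(counts: np.ndarray, max_tables: int) -> float:
    """Exact two-sided p by recursive enumeration with margin pruning.

    Rows are filled one at a time; the final two rows are resolved with
    a vectorised sweep over bounded compositions, which keeps 3×3 tables
    with totals in the low hundreds well inside a few seconds.
    """
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    r, c = counts.shape
    const = _log_table_prob_const(rows, cols)
    logp_obs = const - gammaln(counts + 1).sum()
    cutoff = logp_obs + np.log1p(_TIE_RTOL)

    lg = gammaln(np.arange(int(rows.sum()) + 2) + 1.0)  # lg[k] = lgamma(k+1)

    total_p = 0.0
    visited = 0

    def compositions(m: int, bounds: np.ndarray):
        """All compositions of m into len(bounds) bounded parts (grid)."""
        axes = [np.arange(min(int(b), m) + 1) for b in bounds[:-1]]
        grid = np.meshgrid(*axes, indexing="ij") if axes else []
        if grid:
            head = np.stack([g.ravel() for g in grid], axis=1)
        else:
            head = np.zeros((1, 0), dtype=int)
        last = m - head.sum(axis=1)
        ok = (last >= 0) & (last <= int(bounds[-1]))
        return np.concatenate([head[ok], last[ok, None]], axis=1)

    def final_two_rows(colrem: np.ndarray, m1: int, logacc: float) -> None:
        # penultimate row = comps, last row = colrem - comps
        nonlocal total_p, visited
        comps = compositions(m1, colrem)
        if comps.size == 0:
            return
        visited += len(comps)
        if visited > max_tables:
            raise RuntimeError(
                "table exceeds the exact-enumeration budget; rerun "
                "fisher_exact with method='monte_carlo'"
            )
        rest = colrem[None, :] - comps
        logp = logacc - lg[comps].sum(axis=1) - lg[rest].sum(axis=1)
        sel = logp <= cutoff
        if sel.any():
            total_p += float(np.exp(logp[sel]).sum())

    def recurse(i: int, colrem: np.ndarray, logacc: float) -> None:
        if i == r - 2:
            final_two_rows(colrem, int(rows[i]), logacc)
            return
        m = int(rows[i])
        # tail capacity per column after this row
        tail = rows[i + 1:].sum()
        for comp in _bounded_compositions(m, colrem, int(tail)):
            recurse(i + 1, colrem - comp, logacc - lg[comp].sum())

    def _bounded_compositions(m: int, bounds: np.ndarray, tail: int):
        # yields integer arrays summing to m with 0 <= part_j <= bounds_j,
        # pruned so remaining column capacity can still absorb later rows
        def rec(j: int, remaining: int, prefix: list[int]):
            if j == c - 1:
                if 0 <= remaining <= bounds[j]:
                    yield np.array(prefix + [remaining], dtype=int)
                return
            hi = min(int(bounds[j]), remaining)
            lo = max(0, remaining - int(bounds[j + 1:].sum()))
            for v in range(lo, hi + 1):
                yield from rec(j + 1, remaining - v, prefix + [v])

        yield from rec(0, m, [])

    if r == 2:
        final_two_rows(cols.copy(), int(rows[0]), const)
    else:
        recurse(0, cols.copy(), const)
    return min(1.0, total_p)


def _montecarlo_pvalue(
    counts: np.ndarray, n_draws: int, rng: np.random.Generator
) -> float:
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    const = _log_table_prob_const(rows, cols)
    logp_obs = const - gammaln(counts + 1).sum()
    cutoff = logp_obs + np.log1p(_TIE_RTOL)
    sampler = sps.random_table(rows, cols)
    hits = 0
    chunk = 250_000
    done = 0
    while done < n_draws:
        k = min(chunk, n_draws - done)
        tables = sampler.rvs(k, method="patefield", random_state=rng)
        if tables.ndim == 2:
            tables = tables[None, ...]
        logp = const - gammaln(tables + 1).sum(axis=(1, 2))
        hits += int((logp <= cutoff).sum())
        done += k
    return hits / n_draws


def fisher_exact(
    table: ContingencyTable | np.ndarray,
    method: str = "enumerate",
    max_tables: int = 5_000_000,
    n_draws: int = 1_000_000,
    seed: int | np.random.Generator | None = 0,
) -> float:
    """Two-sided exact test of independence in an r×c table.

    Under the multivariate hypergeometric null with both margins fixed,
    the p-value sums the probabilities of every table whose point
    probability does not exceed the observed table's (ties included
    within a 1e-7 relative tolerance).

    Parameters
    ----------
    table
        A :class:`ContingencyTable` or a plain 2-D array of counts.
    method
        ``"enumerate"`` (exact, default) or ``"monte_carlo"`` (seeded
        Patefield resampling of fixed-margin tables, for tables beyond
        the enumeration budget).
    """
    counts = table.counts if isinstance(table, ContingencyTable) else \
        np.asarray(table, dtype=int)
    if counts.ndim != 2 or min(counts.shape) < 2:
        raise ValueError("need a 2-D table with at least 2 rows and 2 columns")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        raise ValueError("all row and column margins must be positive")

    if method == "enumerate":
        return _enumerate_pvalue(counts, max_tables)
    if method == "monte_carlo":
        rng = seed if isinstance(seed, np.random.Generator) else \
            np.random.default_rng(seed)
        return _montecarlo_pvalue(counts, n_draws, rng)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# ANOVA, regression, summaries, tertiles


def anova_oneway(*groups: Sequence[float]) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and upper-tail p-value."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 1 for a in arrays):
        raise ValueError("every group needs at least one observation")
    n_total = sum(len(a) for a in arrays)
    if n_total <= len(arrays):
        raise ValueError("total observations must exceed the number of groups")
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ssw == 0.0:
        raise ValueError("zero within-group variance everywhere: F is undefined")
    f, p = sps.f_oneway(*arrays)
    return float(f), float(p)


def fit_linear(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, float, float]:
    """Simple least-squares fit of y on x.

    Returns ``(slope, intercept, pearson_r, p_value)`` where the
    p-value is the two-sided t test on the slope.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant: slope is undefined")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue), float(res.pvalue)


@dataclass(frozen=True)
class GroupSummary:
    """Per-group descriptive summary (sample SD, n−1 denominator)."""

    group: str
    n: int
    mean: float
    sd: float
    min: float
    max: float
    sd_defined: bool = True


def summarize(cohort: Cohort, variable: str) -> list[GroupSummary]:
    """Per-disease n/mean/SD/min/max of ``utility``, ``vas`` or ``age``.

    A single-observation group reports SD 0 with ``sd_defined=False``.
    """
    if variable not in ("utility", "vas", "age"):
        raise KeyError(f"unknown variable {variable!r}")
    out = []
    for disease in DISEASES:
        sub = cohort.df.loc[cohort.df.disease == disease, variable].dropna()
        if (cohort.df.disease == disease).any() and sub.empty:
            raise ValueError(f"group {disease!r} has no values for {variable!r}")
        if sub.empty:
            continue
        values = sub.to_numpy(dtype=float)
        n = len(values)
        out.append(GroupSummary(
            group=disease,
            n=n,
            mean=float(values.mean()),
            sd=float(values.std(ddof=1)) if n > 1 else 0.0,
            min=float(values.min()),
            max=float(values.max()),
            sd_defined=n > 1,
        ))
    if not out:
        raise ValueError("cohort is empty")
    return out


@dataclass(frozen=True)
class TertileSplit:
    """Utility-ordered partition into lower/middle/upper thirds.

    The remainder of ``n mod 3`` is allocated from the lowest tertile
    upward, so 43 participants split 15/14/14 — the lowest 15 form the
    simulated treatment group.
    """

    lower: pd.DataFrame
    middle: pd.DataFrame
    upper: pd.DataFrame

    @property
    def middle_mean(self) -> float:
        """Mean utility of the middle tertile (the simulation's default
        treatment target on the original data)."""
        return float(self.middle["utility"].mean())


def split_tertiles(patients: Cohort | pd.DataFrame) -> TertileSplit:
    """Split patients into utility tertiles.

    Sorting is stable ascending by utility with ties broken by patient
    id, so the split is deterministic even with duplicated utilities.
    """
    df = patients.df if isinstance(patients, Cohort) else patients
    if not {"id", "utility"}.issubset(df.columns):
        raise ValueError("need columns 'id' and 'utility'")
    n = len(df)
    if n < 3:
        raise ValueError(f"need at least 3 patients to form tertiles, got {n}")
    ordered = df.sort_values(["utility", "id"], kind="mergesort").reset_index(drop=True)
    base, rem = divmod(n, 3)
    sizes = [base + (1 if rem >= 1 else 0), base + (1 if rem >= 2 else 0), base]
    lo = ordered.iloc[: sizes[0]]
    mid = ordered.iloc[sizes[0]: sizes[0] + sizes[1]]
    hi = ordered.iloc[sizes[0] + sizes[1]:]
    return TertileSplit(lower=lo, middle=mid, upper=hi)
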