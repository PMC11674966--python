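"""Statistical comparisons used throughout the pipeline.

Wraps the four tests the analysis needs — two-sided Fisher's exact test
on 2×2 tables, Mann–Whitney U, Wilcoxon signed-rank, and Welch's
unpaired t-test — with the small-sample conventions fixed here:

* Fisher two-sided p is the point-probability rule (sum of all tables
  with fixed margins whose probability does not exceed the observed
  table's).
* Mann–Whitney uses exact enumeration when min(n1, n2) ≤ 8 and there
  are no ties, otherwise the normal approximation with tie and
  continuity corrections.
* Wilcoxon drops zero differences, enumerates exactly for n ≤ 12
  without tied absolute differences, otherwise uses the corrected
  normal approximation.
* The unpaired t-test defaults to Welch (unequal variances); the
  pooled-variance variant is available via ``equal_var=True``.

Also provides the cell-assay summaries: the centrosome-amplification
fraction (cells with more than four centrin foci) and per-condition
chromosome-count summaries with pairwise Mann–Whitney comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TwoByTwoTable",
    "TestResult",
    "FociCountSample",
    "ChromosomeCountSample",
    "fisher_exact_two_sided",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "unpaired_t_test",
    "amplified_fraction",
    "summarize_chromosome_counts",
    "format_p",
]


@dataclass(frozen=True)
class TwoByTwoTable:
    """2×2 contingency table; rows = factor level, columns = low/high."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if int(v) != v or v < 0:
                raise ValueError(f"cell counts must be non-negative integers, got {v!r}")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table total must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass(frozen=True)
class TestResult:
    statistic: float | None
    p_value: float
    method: str
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0,1]: {self.p_value}")


@dataclass(frozen=True)
class FociCountSample:
    """Per-cell centriole (centrin focus) counts for one replicate."""

    counts: tuple[int, ...]
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if any(int(c) != c or c < 0 for c in self.counts):
            raise ValueError("focus counts must be non-negative integers")


@dataclass(frozen=True)
class ChromosomeCountSample:
    """Per-metaphase chromosome counts for one condition (clone × induction)."""

    counts: tuple[int, ...]
    condition: str

    def __post_init__(self) -> None:
        if not self.counts or any(int(c) != c or c < 1 for c in self.counts):
            raise ValueError("chromosome counts must be positive integers")


def format_p(p: float, digits: int = 4) -> str:
    """Render a p-value to 4 decimals, trimming at most trailing-zero noise
    (e.g. 0.0262, 1.0000)."""
    return f"{p:.{digits}f}"


def fisher_exact_two_sided(table: TwoByTwoTable | Sequence[Sequence[int]]) -> TestResult:
    """Two-sided Fisher's exact test (point-probability rule).

    A table with a zero margin carries no information about association;
    by convention p = 1 with a warning.
    """
    if not isinstance(table, TwoByTwoTable):
        (a, b), (c, d) = table
        table = TwoByTwoTable(int(a), int(b), int(c), int(d))
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        warnings.warn("zero margin in 2x2 table; p = 1 by convention", stacklevel=2)
        return TestResult(None, 1.0, "fisher_exact_two_sided", int(arr[0].sum()), int(arr[1].sum()))
    res = sps.fisher_exact(arr, alternative="two-sided")
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method="fisher_exact_two_sided",
        n1=int(arr[0].sum()),
        n2=int(arr[1].sum()),
    )


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> TestResult:
    """Two-sided Mann–Whitney U test.

    mode='auto' picks exact enumeration for min(n) ≤ 8 with no ties and
    the tie/continuity-corrected normal approximation otherwise;
    'exact' and 'normal' force the respective path.
    """
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("both samples must be non-empty")
    if mode == "auto":
        method = "exact" if (min(xa.size, ya.size) <= 8 and not _has_ties(xa, ya)) else "asymptotic"
    elif mode == "exact":
        method = "exact"
    elif mode == "normal":
        method = "asymptotic"
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    res = sps.mannwhitneyu(
        xa, ya, alternative="two-sided", method=method, use_continuity=True
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method=f"mann_whitney_u_{method}",
        n1=int(xa.size),
        n2=int(ya.size),
    )


def wilcoxon_signed_rank(
    pairs: Sequence[tuple[float, float]], mode: str = "auto"
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on (before, after) pairs.

    Zero differences are dropped; raises if every difference is zero.
    """
    diffs = np.asarray([float(b) - float(a) for a, b in pairs], dtype=float)
    nz = diffs[diffs != 0.0]
    if nz.size == 0:
        raise ValueError("all pairwise differences are zero; signed-rank test undefined")
    tied_abs = len(np.unique(np.abs(nz))) < nz.size
    if mode == "auto":
        method = "exact" if (nz.size <= 12 and not tied_abs) else "approx"
    elif mode == "exact":
        method = "exact"
    elif mode == "normal":
        method = "approx"
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    res = sps.wilcoxon(
        nz, zero_method="wilcox", correction=(method == "approx"),
        alternative="two-sided", method=method,
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method=f"wilcoxon_signed_rank_{method}",
        n1=int(nz.size),
        n2=int(nz.size),
    )


def unpaired_t_test(
    x: Sequence[float], y: Sequence[float], equal_var: bool = False
) -> TestResult:
    """Two-sided unpaired t-test, Welch by default.

    Two constant groups with equal means carry no evidence; p = 1 by
    convention rather than NaN.
    """
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.size < 2 or ya.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if xa.std(ddof=1) == 0.0 and ya.std(ddof=1) == 0.0:
        if xa.mean() == ya.mean():
            return TestResult(0.0, 1.0, "t_test_degenerate", int(xa.size), int(ya.size))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.ttest_ind(xa, ya, equal_var=equal_var)
    p = 1.0 if np.isnan(res.pvalue) else float(min(res.pvalue, 1.0))
    stat = 0.0 if np.isnan(res.statistic) else float(res.statistic)
    return TestResult(
        statistic=stat,
        p_value=p,
        method="t_test_pooled" if equal_var else "t_test_welch",
        n1=int(xa.size),
        n2=int(ya.size),
    )


def amplified_fraction(sample: FociCountSample | Sequence[int]) -> float:
    """Percentage of cells with more than four centrin foci.

    The boundary is strict: a cell with exactly four foci (a normal
    duplicated centrosome complement) does not count as amplified.
    """
    counts = sample.counts if isinstance(sample, FociCountSample) else tuple(sample)
    if not counts:
        raise ValueError("need at least one cell")
    return 100.0 * sum(1 for c in counts if c > 4) / len(counts)


def summarize_chromosome_counts(
    samples: Sequence[ChromosomeCountSample],
    comparisons: Sequence[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-condition medians/IQRs and pairwise Mann–Whitney comparisons.

    ``comparisons`` lists (condition_a, condition_b) pairs; by default
    every unordered pair is compared.  Unknown condition names raise.
    """
    if len(samples) < 2:
        raise ValueError("need at least two conditions to summarize")
    by_cond: dict[str, list[int]] = {}
    order: list[str] = []
    for s in samples:
        if s.condition not in by_cond:
            by_cond[s.condition] = []
            order.append(s.condition)
        by_cond[s.condition].extend(s.counts)

    rows = []
    for cond in order:
        arr = np.asarray(by_cond[cond], dtype=float)
        q1, med, q3 = np.percentile(arr, [25, 50, 75])
        rows.append(
            {"condition": cond, "n": arr.size, "median": med, "q1": q1, "q3": q3,
             "iqr": q3 - q1}
        )
    summary = pd.DataFrame(rows)

    if comparisons is None:
        comparisons = [
            (order[i], order[j]) for i in range(len(order)) for j in range(i + 1, len(order))
        ]
    comp_rows = []
    for a, b in comparisons:
        if a not in by_cond or b not in by_cond:
            missing = a if a not in by_cond else b
            raise ValueError(f"unknown condition in comparison list: {missing!r}")
        res = mann_whitney_u(by_cond[a], by_cond[b])
        comp_rows.append(
            {"condition_a": a, "condition_b": b, "U": res.statistic,
             "p_value": res.p_value, "method": res.method}
        )
    return summary, pd.DataFrame(comp_rows)
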