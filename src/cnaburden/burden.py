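"""Arm-level copy-number status calling and altered-arm burden.

The substrate is a gene × sample matrix of discrete GISTIC calls
(−2 deep deletion, −1 shallow deletion, 0 diploid, +1 gain, +2
amplification, or missing).  For each (arm, case) the fraction of
informative genes carrying a loss (−2/−1) or a gain (+1/+2) call is
compared against a threshold — two-thirds by default, inclusive — to
call the arm *deletion*, *amp_gain*, or *diploid*; an arm with no
informative genes for a case is *no_call*.  A case's burden is the
number of arms called deletion or amp_gain, and cases are split at the
cohort median of that count into CNA-high (count ≥ median) and CNA-low.

The threshold comparison is done in exact integer arithmetic
(``k * den ≥ num * n`` for threshold ``num/den``): 2/3 has no finite
binary representation, so a float comparison would misclassify exact
boundary arms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .arms import ArmMap

__all__ = [
    "VALID_CALLS",
    "GeneCopyMatrix",
    "ArmStatusTable",
    "CnaBurden",
    "CompletenessRule",
    "call_arm_status",
    "call_all_arms",
    "burden_per_case",
    "classify_cna",
    "DEFAULT_THRESHOLD",
]

VALID_CALLS = (-2, -1, 0, 1, 2)
DEFAULT_THRESHOLD = Fraction(2, 3)

DELETION = "deletion"
AMP_GAIN = "amp_gain"
DIPLOID = "diploid"
NO_CALL = "no_call"


def _as_fraction(threshold) -> Fraction:
    if isinstance(threshold, Fraction):
        frac = threshold
    elif isinstance(threshold, str):
        frac = Fraction(threshold)
    elif isinstance(threshold, float):
        # accept floats but snap to a small-denominator rational so that
        # e.g. 2/3 passed as 0.666... behaves as the exact boundary
        frac = Fraction(threshold).limit_denominator(1_000_000)
    else:
        frac = Fraction(threshold)
    if not (0 < frac <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {threshold!r}")
    return frac


@dataclass
class GeneCopyMatrix:
    """Gene × sample grid of discrete copy-number calls.

    ``calls`` is a pandas DataFrame indexed by gene_id with case_id
    columns, dtype Int8 (nullable); missing cells are pd.NA.
    """

    calls: pd.DataFrame

    def __post_init__(self) -> None:
        if self.calls.index.has_duplicates:
            dupes = self.calls.index[self.calls.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if self.calls.columns.has_duplicates:
            dupes = self.calls.columns[self.calls.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate case ids: {dupes[:5]}")
        arr = self.calls.to_numpy(dtype="float64", na_value=np.nan)
        finite = arr[~np.isnan(arr)]
        bad = finite[~np.isin(finite, VALID_CALLS)]
        if bad.size:
            raise ValueError(f"invalid copy-number call value: {bad[0]!r}")
        self.calls = self.calls.astype("Int8")

    @property
    def genes(self) -> list[str]:
        return list(self.calls.index)

    @property
    def samples(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def n_missing(self) -> int:
        return int(self.calls.isna().to_numpy().sum())


@dataclass
class ArmStatusTable:
    """Per-arm, per-case categorical status plus informative-gene counts."""

    statuses: pd.DataFrame  # arms (str index) × cases, categorical strings
    informative_gene_counts: pd.DataFrame  # same shape, int

    @property
    def arms(self) -> list[str]:
        return list(self.statuses.index)

    @property
    def samples(self) -> list[str]:
        return list(self.statuses.columns)


@dataclass
class CnaBurden:
    """Altered-arm count for one case and its CNA-high/low label."""

    case_id: str
    altered_arm_count: int
    evaluable_arm_count: int
    label: str = "unset"  # CNA_high | CNA_low | excluded | unset

    def __post_init__(self) -> None:
        if self.altered_arm_count > self.evaluable_arm_count:
            raise ValueError("altered_arm_count exceeds evaluable_arm_count")


@dataclass(frozen=True)
class CompletenessRule:
    """When a case is excluded from the median split.

    A case is excluded if more than ``max_no_call_fraction`` of the arm
    universe is no_call, or (when ``require_expression`` is set and an
    expression-availability list is supplied) the case has no matched
    expression value.
    """

    max_no_call_fraction: float = 0.5
    require_expression: bool = True


def call_arm_status(
    calls: Iterable[int | None],
    threshold=DEFAULT_THRESHOLD,
) -> str:
    """Call one (arm, case): deletion / amp_gain / diploid / no_call.

    Missing calls (None/NA/NaN) are dropped before evaluation; with no
    informative genes the result is ``no_call``.  With n informative
    genes the arm is a deletion if #{−2,−1}/n ≥ threshold, else
    amp_gain if #{+1,+2}/n ≥ threshold, else diploid; the boundary is
    inclusive and evaluated exactly.
    """
    frac = _as_fraction(threshold)
    n = k_del = k_amp = 0
    for value in calls:
        if value is None or value is pd.NA or (isinstance(value, float) and np.isnan(value)):
            continue
        iv = int(value)
        if iv != value or iv not in VALID_CALLS:
            raise ValueError(f"invalid copy-number call value: {value!r}")
        n += 1
        if iv < 0:
            k_del += 1
        elif iv > 0:
            k_amp += 1
    return _status_from_counts(k_del, k_amp, n, frac)


def _status_from_counts(k_del: int, k_amp: int, n: int, frac: Fraction) -> str:
    if n == 0:
        return NO_CALL
    num, den = frac.numerator, frac.denominator
    is_del = k_del * den >= num * n
    is_amp = k_amp * den >= num * n
    if is_del and is_amp:
        # impossible for threshold > 1/2; possible for permissive thresholds
        warnings.warn(
            f"deletion and amp_gain criteria both met at threshold {frac}; "
            "calling diploid",
            stacklevel=3,
        )
        return DIPLOID
    if is_del:
        return DELETION
    if is_amp:
        return AMP_GAIN
    return DIPLOID


def call_all_arms(
    matrix: GeneCopyMatrix,
    arm_map: ArmMap,
    threshold=DEFAULT_THRESHOLD,
) -> ArmStatusTable:
    """Call every (arm, case) of the matrix under the arm map.

    Vectorized over cases; the result is independent of gene row order.
    Raises ValueError if no gene of the matrix is mapped.
    """
    frac = _as_fraction(threshold)
    num, den = frac.numerator, frac.denominator
    arms = [str(a) for a in arm_map.arm_universe]
    samples = matrix.samples

    mapped = [g for g in matrix.genes if g in arm_map.gene_to_arm]
    if not mapped:
        raise ValueError("no gene of the copy-number matrix is mapped to any arm")

    status = pd.DataFrame(NO_CALL, index=arms, columns=samples, dtype=object)
    counts = pd.DataFrame(0, index=arms, columns=samples, dtype=int)

    values = matrix.calls.to_numpy(dtype="float64", na_value=np.nan)
    gene_index = {g: i for i, g in enumerate(matrix.genes)}
    for arm in arm_map.arm_universe:
        genes = [g for g in arm_map.genes_on(arm) if g in gene_index]
        if not genes:
            continue
        sub = values[[gene_index[g] for g in genes], :]
        informative = ~np.isnan(sub)
        n = informative.sum(axis=0)
        k_del = ((sub < 0) & informative).sum(axis=0)
        k_amp = ((sub > 0) & informative).sum(axis=0)
        is_del = k_del * den >= num * n
        is_amp = k_amp * den >= num * n
        col = np.where(
            n == 0,
            NO_CALL,
            np.where(
                is_del & is_amp,
                DIPLOID,
                np.where(is_del, DELETION, np.where(is_amp, AMP_GAIN, DIPLOID)),
            ),
        )
        if frac <= Fraction(1, 2) and np.any(is_del & is_amp & (n > 0)):
            warnings.warn(
                f"ties between deletion and amp_gain at threshold {frac}; called diploid",
                stacklevel=2,
            )
        status.loc[str(arm)] = col
        counts.loc[str(arm)] = n
    return ArmStatusTable(statuses=status, informative_gene_counts=counts)


def burden_per_case(
    table: ArmStatusTable,
    completeness: CompletenessRule | None = None,
    cases_with_expression: set[str] | Sequence[str] | None = None,
) -> list[CnaBurden]:
    """Count altered (deletion or amp_gain) and evaluable (non-no_call)
    arms per case; labels are left unset except for excluded cases.

    ``cases_with_expression`` is consulted only when the rule requires a
    matched expression value; None means "do not apply that clause".

    Arms that are no_call in every case (no mapped gene anywhere in the
    cohort) are structurally empty: they never enter a case's no_call
    fraction, so a cohort covering only part of the arm universe is not
    wholesale excluded.
    """
    rule = completeness or CompletenessRule()
    expr_set = set(cases_with_expression) if cases_with_expression is not None else None
    arr = table.statuses.to_numpy()
    structural = (arr == NO_CALL).all(axis=1)
    n_eff = int((~structural).sum())
    out: list[CnaBurden] = []
    for j, case in enumerate(table.samples):
        col = arr[:, j]
        altered = int(np.sum((col == DELETION) | (col == AMP_GAIN)))
        evaluable = int(np.sum(col != NO_CALL))
        label = "unset"
        no_call_frac = (n_eff - evaluable) / n_eff if n_eff else 1.0
        if no_call_frac > rule.max_no_call_fraction:
            label = "excluded"
        if (
            rule.require_expression
            and expr_set is not None
            and case not in expr_set
        ):
            label = "excluded"
        out.append(CnaBurden(case, altered, evaluable, label))
    return out


def classify_cna(burdens: Sequence[CnaBurden]) -> tuple[list[CnaBurden], float]:
    """Median-split the non-excluded cases into CNA-high / CNA-low.

    The median is computed over non-excluded cases only (even n: mean of
    the two central values); a case is CNA-high iff its altered-arm
    count is **greater than or equal to** the median.  Returns the
    relabelled burdens and the cutoff used.
    """
    kept = [b for b in burdens if b.label != "excluded"]
    if len(kept) < 2:
        raise ValueError("need at least 2 non-excluded cases for the median split")
    cutoff = float(np.median([b.altered_arm_count for b in kept]))
    out: list[CnaBurden] = []
    for b in burdens:
        if b.label == "excluded":
            out.append(b)
        else:
            label = "CNA_high" if b.altered_arm_count >= cutoff else "CNA_low"
            out.append(CnaBurden(b.case_id, b.altered_arm_count, b.evaluable_arm_count, label))
    return out, cutoff


def burden_frame(burdens: Sequence[CnaBurden]) -> pd.DataFrame:
    """Tabular view: case_id, altered_arms, evaluable_arms, label."""
    return pd.DataFrame(
        {
            "case_id": [b.case_id for b in burdens],
            "altered_arms": [b.altered_arm_count for b in burdens],
            "evaluable_arms": [b.evaluable_arm_count for b in burdens],
            "label": [b.label for b in burdens],
        }
    )
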