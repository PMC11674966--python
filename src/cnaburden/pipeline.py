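"""Orchestration: copy-number burden → median split → expression
association, plus the IHC and clinicopathological report arms.

``run_cna_association`` is the headline analysis: build the gene→arm
map, call every arm, count each case's altered arms, exclude incomplete
cases, median-split the rest into CNA-high/CNA-low, and compare the
designated gene's expression between the two groups with a two-sided
Mann–Whitney U test.

``run_clinicopath`` cross-tabulates each two-level clinical factor
against the low/high marker label and reports a two-sided Fisher exact
p per factor, formatted as counts with row percentages.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .arms import ArmMap, ArmUniverseConfig, GeneLocation, build_arm_map
from .burden import (
    DEFAULT_THRESHOLD,
    CompletenessRule,
    GeneCopyMatrix,
    burden_frame,
    burden_per_case,
    call_all_arms,
    classify_cna,
)
from .ihc import IhcRecord, derive_cutoff, dichotomize
from .stats import TestResult, TwoByTwoTable, fisher_exact_two_sided, mann_whitney_u

__all__ = ["AnalysisReport", "run_cna_association", "run_clinicopath", "run_ihc"]


@dataclass
class AnalysisReport:
    """Result of the burden → expression association analysis."""

    burden_table: pd.DataFrame
    median_cutoff: float
    n_high: int
    n_low: int
    n_excluded: int
    expression_test: TestResult
    median_expression_high: float
    median_expression_low: float
    provenance: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "n_cases": int(self.n_high + self.n_low + self.n_excluded),
            "n_cna_high": self.n_high,
            "n_cna_low": self.n_low,
            "n_excluded": self.n_excluded,
            "median_altered_arm_cutoff": self.median_cutoff,
            "expression_comparison": {
                "method": self.expression_test.method,
                "statistic": self.expression_test.statistic,
                "p_value": self.expression_test.p_value,
                "median_expression_cna_high": self.median_expression_high,
                "median_expression_cna_low": self.median_expression_low,
            },
            "provenance": self.provenance,
        }


def _provenance(
    threshold, rule: CompletenessRule, arm_map: ArmMap, designated_gene: str
) -> dict:
    frac = Fraction(threshold) if not isinstance(threshold, Fraction) else threshold
    return {
        "software_version": __version__,
        "arm_calling_threshold": str(frac),
        "arm_universe": [str(a) for a in arm_map.arm_universe],
        "n_genes_mapped": arm_map.n_mapped,
        "n_genes_unmapped": len(arm_map.unmapped),
        "completeness_max_no_call_fraction": rule.max_no_call_fraction,
        "completeness_require_expression": rule.require_expression,
        "median_split_rule": "CNA_high iff altered_arm_count >= cohort median",
        "ihc_high_rule": "high iff score > cutoff (score == cutoff is low)",
        "designated_gene": designated_gene,
    }


def run_cna_association(
    matrix: GeneCopyMatrix,
    expression: pd.DataFrame,
    locations: Sequence[GeneLocation] | ArmMap,
    designated_gene: str = "STIL",
    threshold=DEFAULT_THRESHOLD,
    completeness: CompletenessRule | None = None,
    arm_config: ArmUniverseConfig | None = None,
) -> AnalysisReport:
    """Full burden analysis for one cohort.

    Raises if the designated gene is absent from the expression matrix
    or if no expression column overlaps the copy-number cases.
    """
    rule = completeness or CompletenessRule()
    arm_map = (
        locations
        if isinstance(locations, ArmMap)
        else build_arm_map(locations, arm_config)
    )
    if designated_gene not in expression.index:
        raise ValueError(f"designated gene {designated_gene!r} absent from expression matrix")

    cn_cases = set(matrix.samples)
    expr_cases = set(expression.columns)
    if not (cn_cases & expr_cases):
        orphans = sorted(cn_cases)[:5]
        raise ValueError(
            f"no case id shared between copy-number and expression matrices; "
            f"copy-number cases start {orphans}"
        )

    gene_expr = expression.loc[designated_gene]
    with_expr = {c for c in matrix.samples if c in expr_cases and pd.notna(gene_expr.get(c))}

    table = call_all_arms(matrix, arm_map, threshold)
    burdens = burden_per_case(table, rule, cases_with_expression=with_expr)
    burdens, cutoff = classify_cna(burdens)

    high = [b.case_id for b in burdens if b.label == "CNA_high"]
    low = [b.case_id for b in burdens if b.label == "CNA_low"]
    n_excluded = sum(1 for b in burdens if b.label == "excluded")

    x = gene_expr[high].to_numpy(dtype=float)
    y = gene_expr[low].to_numpy(dtype=float)
    test = mann_whitney_u(x, y)

    return AnalysisReport(
        burden_table=burden_frame(burdens),
        median_cutoff=cutoff,
        n_high=len(high),
        n_low=len(low),
        n_excluded=n_excluded,
        expression_test=test,
        median_expression_high=float(np.median(x)),
        median_expression_low=float(np.median(y)),
        provenance=_provenance(threshold, rule, arm_map, designated_gene),
    )


def run_clinicopath(
    clinical: pd.DataFrame,
    factors: Sequence[str] = ("age", "sex", "smoking", "pT", "pN", "stage"),
    label_column: str = "label",
    age_cut: float = 60.0,
) -> pd.DataFrame:
    """Per-factor 2×2 cross-tabulation against the low/high label with a
    two-sided Fisher exact p.

    A numeric ``age`` column is dichotomized at ``age_cut`` (<cut vs
    ≥cut).  Factors with fewer than two observed levels are skipped with
    a warning; factors with more than two levels are skipped likewise
    (the report is strictly 2×2).
    """
    if clinical.empty:
        raise ValueError("clinical table is empty")
    if label_column not in clinical.columns:
        raise ValueError(f"clinical table lacks the {label_column!r} column")
    df = clinical.copy()
    labels = df[label_column].astype(str)
    if not set(labels.unique()).issubset({"low", "high"}):
        raise ValueError("label column must contain only 'low'/'high'")

    rows: list[dict] = []
    for factor in factors:
        if factor not in df.columns:
            warnings.warn(f"factor {factor!r} not in clinical table; skipped", stacklevel=2)
            continue
        col = df[factor]
        if factor == "age" and pd.api.types.is_numeric_dtype(col):
            col = pd.Series(
                np.where(col < age_cut, f"<{age_cut:g}", f">={age_cut:g}"),
                index=col.index,
            )
        col = col.astype(str)
        levels = sorted(col.dropna().unique())
        if len(levels) != 2:
            warnings.warn(
                f"factor {factor!r} has {len(levels)} observed level(s); "
                "need exactly 2 — skipped",
                stacklevel=2,
            )
            continue
        counts = {
            lev: (
                int(((col == lev) & (labels == "low")).sum()),
                int(((col == lev) & (labels == "high")).sum()),
            )
            for lev in levels
        }
        (a, b), (c, d) = counts[levels[0]], counts[levels[1]]
        res = fisher_exact_two_sided(TwoByTwoTable(a, b, c, d))
        for i, lev in enumerate(levels):
            n_low, n_high = counts[lev]
            total = n_low + n_high
            rows.append(
                {
                    "factor": factor,
                    "level": lev,
                    "n": total,
                    "n_low": n_low,
                    "n_high": n_high,
                    "pct_low": round(100.0 * n_low / total, 1) if total else float("nan"),
                    "pct_high": round(100.0 * n_high / total, 1) if total else float("nan"),
                    "p_value": res.p_value if i == 0 else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def run_ihc(
    records: Sequence[IhcRecord], multiplier: float = 3.0
) -> tuple[list[IhcRecord], dict]:
    """Score tumor records, derive the cutoff from normal-tissue scores,
    dichotomize the tumors, and summarize."""
    normals = [r for r in records if r.tissue == "normal"]
    tumors = [r for r in records if r.tissue == "tumor"]
    if not normals:
        raise ValueError("no normal-tissue records to derive the cutoff from")
    if not tumors:
        raise ValueError("no tumor records to dichotomize")
    cutoff = derive_cutoff([r.score for r in normals], multiplier)
    labelled, n_low, n_high = dichotomize(tumors, cutoff)
    summary = {
        "n_tumor": len(tumors),
        "n_normal": len(normals),
        "median_tumor_score": float(np.median([r.score for r in tumors])),
        "median_normal_score": cutoff.normal_median,
        "cutoff": cutoff.cutoff,
        "multiplier": cutoff.multiplier,
        "n_low": n_low,
        "n_high": n_high,
        "fraction_high": round(100.0 * n_high / len(tumors), 1),
    }
    return labelled + normals, summary


def input_checksums(paths: dict[str, Path | str]) -> dict[str, str]:
    """SHA-256 of each input file, for the provenance block."""
    out = {}
    for name, p in paths.items():
        h = hashlib.sha256()
        h.update(Path(p).read_bytes())
        out[name] = h.hexdigest()
    return out
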