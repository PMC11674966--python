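"""Immunohistochemistry scoring (H-score style) and dichotomization.

A pathologist records, per case, the percentage of cells staining at
each intensity level 0 (absent), 1 (weak), 2 (moderate), 3 (strong).
The IHC score is the intensity-weighted sum Σ i·pct[i], ranging 0–300.
Cancer cases are dichotomized at a cutoff equal to a multiplier (default
3) times the median score of non-cancerous reference tissue; a case is
*high* iff its score is strictly greater than the cutoff, so a score
exactly at the cutoff is *low*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "IntensityDistribution",
    "IhcRecord",
    "IhcCutoff",
    "compute_ihc_score",
    "derive_cutoff",
    "dichotomize",
]

PERCENT_SUM_TOL = 1e-6
INTENSITY_LEVELS = (0, 1, 2, 3)


@dataclass(frozen=True)
class IntensityDistribution:
    """Percentage of cells at each staining intensity level 0–3.

    Percentages must be non-negative and sum to 100 within 1e-6; set
    ``renormalize=True`` to rescale near-miss hand-entered totals
    instead of raising.
    """

    percent_at: tuple[float, float, float, float]

    def __init__(self, percent_at: Mapping[int, float] | Sequence[float], renormalize: bool = False):
        if isinstance(percent_at, Mapping):
            vals = [float(percent_at.get(i, 0.0)) for i in INTENSITY_LEVELS]
        else:
            vals = [float(v) for v in percent_at]
            if len(vals) != 4:
                raise ValueError("need exactly 4 percentages (levels 0-3)")
        if any(v < 0 for v in vals):
            raise ValueError(f"negative percentage in {vals}")
        total = sum(vals)
        if abs(total - 100.0) > PERCENT_SUM_TOL:
            if renormalize and total > 0:
                vals = [v * 100.0 / total for v in vals]
            else:
                raise ValueError(f"percentages sum to {total}, expected 100")
        object.__setattr__(self, "percent_at", tuple(vals))

    def score(self) -> float:
        return float(sum(i * p for i, p in zip(INTENSITY_LEVELS, self.percent_at)))


@dataclass
class IhcRecord:
    """One case's staining distribution, score, and low/high label."""

    case_id: str
    tissue: str  # "tumor" | "normal"
    distribution: IntensityDistribution
    score: float = field(default=None)  # type: ignore[assignment]
    label: str = "unset"  # low | high | unset

    def __post_init__(self) -> None:
        if self.tissue not in ("tumor", "normal"):
            raise ValueError(f"tissue must be 'tumor' or 'normal', got {self.tissue!r}")
        if self.score is None:
            self.score = self.distribution.score()


@dataclass(frozen=True)
class IhcCutoff:
    """Dichotomization cutoff = multiplier × median of reference scores."""

    normal_median: float
    multiplier: float = 3.0

    @property
    def cutoff(self) -> float:
        return self.multiplier * self.normal_median

    def __post_init__(self) -> None:
        if self.cutoff < 0:
            raise ValueError("cutoff must be non-negative")


def compute_ihc_score(distribution: IntensityDistribution | Mapping[int, float]) -> float:
    """Intensity-weighted score Σ i·pct[i] in [0, 300]."""
    if not isinstance(distribution, IntensityDistribution):
        distribution = IntensityDistribution(distribution)
    return distribution.score()


def derive_cutoff(normal_scores: Sequence[float], multiplier: float = 3.0) -> IhcCutoff:
    """Cutoff from reference (non-cancerous) tissue scores."""
    scores = [float(s) for s in normal_scores]
    if not scores:
        raise ValueError("need at least one reference score to derive a cutoff")
    return IhcCutoff(normal_median=float(np.median(scores)), multiplier=multiplier)


def dichotomize(
    records: Sequence[IhcRecord], cutoff: IhcCutoff
) -> tuple[list[IhcRecord], int, int]:
    """Label each record low/high at the cutoff (high iff score > cutoff).

    Returns (relabelled records, n_low, n_high).
    """
    out: list[IhcRecord] = []
    n_low = n_high = 0
    for rec in records:
        label = "high" if rec.score > cutoff.cutoff else "low"
        if label == "high":
            n_high += 1
        else:
            n_low += 1
        out.append(IhcRecord(rec.case_id, rec.tissue, rec.distribution, rec.score, label))
    return out, n_low, n_high
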