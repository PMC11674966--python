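"""Synthetic tumor-cohort and cell-assay generators.

The generator emulates the shape of a TCGA-style lung cohort so every
pipeline stage runs with no external download: a gene × sample matrix
of discrete copy-number calls with arm-coherent structure, a skewed
non-negative expression matrix whose designated gene is coupled to the
per-case altered-arm burden, H-score-style staining distributions, and
a clinicopathological table with a tunable odds-ratio link between
advanced stage and high marker expression.

The generative model, per tumor case: each arm of the universe is
independently altered with probability ``p_arm_alter``; an altered arm
is a deletion with probability ``del_vs_amp``, otherwise a gain.  Each
gene on an altered arm carries a call of the arm's sign (magnitude 1
or 2) with probability ``within_arm_coherence`` and is 0 otherwise;
genes on unaltered arms are 0.  Cells go missing independently with
``missing_rate``.  The designated gene's expression is log-normal with
log-mean = baseline + tumor_log_fold·is_tumor + β·(true altered-arm
count).  The first ``n_incomplete_cases`` tumor cases are emitted with
no expression value, which trips the default completeness rule.

Everything is reproducible from the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .arms import DEFAULT_ARM_UNIVERSE, ArmId, GeneLocation
from .burden import GeneCopyMatrix
from .ihc import IhcRecord, IntensityDistribution
from .stats import ChromosomeCountSample, FociCountSample

__all__ = [
    "ExpressionModel",
    "IhcModel",
    "CohortSpec",
    "CohortBundle",
    "AssayFixtureSpec",
    "generate_cohort",
    "generate_clinical",
    "generate_assay_fixtures",
    "score_to_distribution",
]


@dataclass(frozen=True)
class ExpressionModel:
    """Log-normal expression for the designated gene.

    Defaults put the non-tumor median near 39 and, combined with a
    typical altered-arm burden, the tumor median in the low hundreds —
    the order of magnitude of RSEM-normalized counts for a moderately
    expressed gene.
    """

    baseline_log_mean: float = 3.66  # ln ~39
    baseline_log_sd: float = 0.7
    tumor_log_fold: float = 1.1
    burden_coupling_beta: float = 0.05


@dataclass(frozen=True)
class IhcModel:
    """Gaussian score model on the 0–300 H-score scale."""

    normal_median_target: float = 50.0
    normal_sd: float = 15.0
    tumor_shift: float = 150.0
    tumor_sd: float = 60.0


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort (defaults: a 515-tumor,
    59-normal adenocarcinoma-shaped cohort over the 41-arm universe)."""

    n_tumor: int = 515
    n_normal: int = 59
    arm_universe: tuple[ArmId, ...] = DEFAULT_ARM_UNIVERSE
    genes_per_arm: int | Mapping[str, int] = 30
    p_arm_alter: float | Mapping[str, float] = 0.3
    del_vs_amp: float = 0.5
    within_arm_coherence: float = 0.95
    missing_rate: float = 0.01
    n_incomplete_cases: int = 3
    expression_model: ExpressionModel = field(default_factory=ExpressionModel)
    ihc_model: IhcModel = field(default_factory=IhcModel)
    designated_gene: str = "STIL"
    clinical_association_or: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumor < 2:
            raise ValueError("n_tumor must be at least 2")
        if self.n_normal < 0:
            raise ValueError("n_normal must be non-negative")
        if not (0 <= self.n_incomplete_cases <= self.n_tumor):
            raise ValueError("n_incomplete_cases must be in [0, n_tumor]")
        probs = [self.del_vs_amp, self.within_arm_coherence, self.missing_rate]
        if not isinstance(self.p_arm_alter, Mapping):
            probs.append(self.p_arm_alter)
        else:
            probs.extend(self.p_arm_alter.values())
        for p in probs:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability out of [0,1]: {p}")
        if not self.arm_universe:
            raise ValueError("arm universe is empty")

    def genes_for_arm(self, arm: ArmId) -> int:
        if isinstance(self.genes_per_arm, Mapping):
            return int(self.genes_per_arm[str(arm)])
        return int(self.genes_per_arm)

    def alter_prob(self, arm: ArmId) -> float:
        if isinstance(self.p_arm_alter, Mapping):
            return float(self.p_arm_alter[str(arm)])
        return float(self.p_arm_alter)


@dataclass
class CohortBundle:
    """All tables of one synthetic cohort, sharing one case-id set."""

    copy_matrix: GeneCopyMatrix
    expression: pd.DataFrame  # genes × samples (tumor and normal columns)
    clinical: pd.DataFrame
    ihc: list[IhcRecord]
    gene_locations: list[GeneLocation]
    truth: pd.DataFrame  # case_id, true_altered_arms, true_label, incomplete
    spec: CohortSpec

    @property
    def tumor_cases(self) -> list[str]:
        return list(self.copy_matrix.samples)


def _arm_band(arm: ArmId) -> str:
    # a plausible band label on the requested arm, e.g. "17p11"
    return f"{arm.chromosome}{arm.arm}11"


def score_to_distribution(score: float) -> IntensityDistribution:
    """Build a two-level staining distribution whose H-score equals
    ``score`` exactly (score in [0, 300])."""
    s = min(max(float(score), 0.0), 300.0)
    level = min(int(s // 100), 2)
    frac = s / 100.0 - level
    # mass split between adjacent levels: sums to 100 and the weighted
    # sum is 100·(level + frac) = s exactly
    pct = [0.0, 0.0, 0.0, 0.0]
    pct[level] = 100.0 * (1.0 - frac)
    pct[level + 1] = 100.0 * frac
    return IntensityDistribution(pct)


def generate_cohort(spec: CohortSpec) -> CohortBundle:
    """Draw one cohort bundle from the generative model (see module
    docstring); fully determined by ``spec`` including its seed."""
    rng = np.random.default_rng(spec.seed)
    arms = list(spec.arm_universe)

    gene_ids: list[str] = []
    gene_arms: list[ArmId] = []
    locations: list[GeneLocation] = []
    for arm in arms:
        for i in range(spec.genes_for_arm(arm)):
            gid = f"G{arm}_{i:03d}"
            gene_ids.append(gid)
            gene_arms.append(arm)
            locations.append(
                GeneLocation(gene_id=gid, chromosome=arm.chromosome, cytoband=_arm_band(arm))
            )

    tumor_ids = [f"T{i:04d}" for i in range(1, spec.n_tumor + 1)]
    normal_ids = [f"N{i:04d}" for i in range(1, spec.n_normal + 1)]
    n_genes = len(gene_ids)

    # --- copy-number calls (tumors only) ---
    calls = np.zeros((n_genes, spec.n_tumor), dtype=float)
    true_altered = np.zeros(spec.n_tumor, dtype=int)
    arm_slices: list[tuple[int, int]] = []
    start = 0
    for arm in arms:
        k = spec.genes_for_arm(arm)
        arm_slices.append((start, start + k))
        start += k
    for j in range(spec.n_tumor):
        for (lo, hi), arm in zip(arm_slices, arms):
            if rng.random() >= spec.alter_prob(arm):
                continue
            true_altered[j] += 1
            sign = -1 if rng.random() < spec.del_vs_amp else 1
            k = hi - lo
            coherent = rng.random(k) < spec.within_arm_coherence
            magnitude = rng.choice([1, 2], size=k, p=[0.7, 0.3])
            calls[lo:hi, j] = np.where(coherent, sign * magnitude, 0)
    if spec.missing_rate > 0:
        missing = rng.random(calls.shape) < spec.missing_rate
        calls[missing] = np.nan
    copy_df = pd.DataFrame(calls, index=gene_ids, columns=tumor_ids).astype("Int8")
    copy_matrix = GeneCopyMatrix(copy_df)

    # --- expression (designated gene + background genes) ---
    em = spec.expression_model
    incomplete = set(tumor_ids[: spec.n_incomplete_cases])
    all_cases = tumor_ids + normal_ids
    expr_genes = [spec.designated_gene] + [f"BG{i:03d}" for i in range(1, 10)]
    expr = pd.DataFrame(index=expr_genes, columns=all_cases, dtype=float)
    log_mu = np.concatenate(
        [
            em.baseline_log_mean + em.tumor_log_fold + em.burden_coupling_beta * true_altered,
            np.full(spec.n_normal, em.baseline_log_mean),
        ]
    )
    expr.loc[spec.designated_gene] = np.exp(
        rng.normal(log_mu, em.baseline_log_sd)
    )
    for g in expr_genes[1:]:
        expr.loc[g] = np.exp(
            rng.normal(em.baseline_log_mean, em.baseline_log_sd, size=len(all_cases))
        )
    expr.loc[spec.designated_gene, list(incomplete)] = np.nan

    # --- IHC ---
    im = spec.ihc_model
    ihc: list[IhcRecord] = []
    tumor_scores = np.clip(
        rng.normal(im.normal_median_target + im.tumor_shift, im.tumor_sd, spec.n_tumor),
        0.0, 300.0,
    )
    normal_scores = np.clip(
        rng.normal(im.normal_median_target, im.normal_sd, spec.n_normal), 0.0, 300.0
    )
    for cid, s in zip(tumor_ids, tumor_scores):
        ihc.append(IhcRecord(cid, "tumor", score_to_distribution(s)))
    for cid, s in zip(normal_ids, normal_scores):
        ihc.append(IhcRecord(cid, "normal", score_to_distribution(s)))

    # --- truth ---
    informative = np.array([cid not in incomplete for cid in tumor_ids])
    med = float(np.median(true_altered[informative]))
    truth = pd.DataFrame(
        {
            "case_id": tumor_ids,
            "true_altered_arms": true_altered,
            "true_label": [
                "excluded" if cid in incomplete
                else ("CNA_high" if c >= med else "CNA_low")
                for cid, c in zip(tumor_ids, true_altered)
            ],
            "incomplete": [cid in incomplete for cid in tumor_ids],
        }
    )

    # --- clinical (tumors only), linked to the IHC high/low label ---
    high = tumor_scores > 3.0 * im.normal_median_target
    clinical = generate_clinical(
        spec, spec.clinical_association_or, tumor_ids, high,
        rng=rng,
    )

    return CohortBundle(
        copy_matrix=copy_matrix,
        expression=expr,
        clinical=clinical,
        ihc=ihc,
        gene_locations=locations,
        truth=truth,
        spec=spec,
    )


def generate_clinical(
    spec: CohortSpec,
    association_or: float,
    case_ids: Sequence[str] | None = None,
    high_label: Sequence[bool] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Clinicopathological table with a tunable OR between advanced
    pathology and the high-expression label.

    For each staging factor the probability of the advanced level is
    ``p0`` for label-low cases and the OR-scaled odds for label-high
    cases; OR = 1 gives independence.
    """
    if association_or <= 0:
        raise ValueError("association_or must be positive")
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    if case_ids is None:
        case_ids = [f"T{i:04d}" for i in range(1, spec.n_tumor + 1)]
    n = len(case_ids)
    if high_label is None:
        high_label = rng.random(n) < 0.6
    high = np.asarray(high_label, dtype=bool)

    def advanced(p0: float) -> np.ndarray:
        odds0 = p0 / (1.0 - p0)
        p1 = (association_or * odds0) / (1.0 + association_or * odds0)
        p = np.where(high, p1, p0)
        return rng.random(n) < p

    age = np.clip(np.round(rng.normal(67, 9, n)), 30, 95).astype(int)
    sex = np.where(rng.random(n) < 0.6, "Male", "Female")
    smoking = np.where(rng.random(n) < 0.55, "Smoker", "Non-smoker")
    pt = np.where(advanced(0.10), "pT3/pT4", "pT1/pT2")
    pn = np.where(advanced(0.22), "pN1-pN3", "pN0")
    stage = np.where(advanced(0.16), "III/IV", "I/II")
    return pd.DataFrame(
        {
            "case_id": list(case_ids),
            "age": age,
            "sex": sex,
            "smoking": smoking,
            "pT": pt,
            "pN": pn,
            "stage": stage,
            "label": np.where(high, "high", "low"),
        }
    )


@dataclass(frozen=True)
class AssayFixtureSpec:
    """Cell-assay generator: centriole-focus counts per cell and
    chromosome counts per metaphase, per condition.

    ``conditions`` maps a condition label (clone × induction) to whether
    the induced model applies.  The chromosome baseline median of 100
    matches a near-triploid lung-carcinoma line.
    """

    conditions: Mapping[str, bool] = field(
        default_factory=lambda: {
            "Empty-1_untreated": False,
            "Empty-1_cumate": False,
            "STIL-1_untreated": False,
            "STIL-1_cumate": True,
            "STIL-2_untreated": False,
            "STIL-2_cumate": True,
        }
    )
    cells_per_condition: int = 100
    foci_baseline_p: float = 0.05
    foci_induced_p: float = 0.30
    chromosome_baseline_median: float = 100.0
    chromosome_induced_shift: float = 12.0
    chromosome_dispersion: float = 8.0
    metaphases_per_condition: int = 50
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.foci_baseline_p, self.foci_induced_p):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability out of [0,1]: {p}")
        if self.chromosome_baseline_median < 1:
            raise ValueError("baseline median must be >= 1")


def generate_assay_fixtures(
    spec: AssayFixtureSpec,
) -> tuple[dict[str, list[FociCountSample]], list[ChromosomeCountSample]]:
    """Draw foci-count replicates and chromosome-count samples per
    condition; reproducible from the seed."""
    rng = np.random.default_rng(spec.seed)
    foci: dict[str, list[FociCountSample]] = {}
    chromosomes: list[ChromosomeCountSample] = []
    for cond, induced in spec.conditions.items():
        p_amp = spec.foci_induced_p if induced else spec.foci_baseline_p
        reps: list[FociCountSample] = []
        for r in range(spec.replicates):
            amplified = rng.random(spec.cells_per_condition) < p_amp
            normal_counts = rng.choice([1, 2, 3, 4], size=spec.cells_per_condition,
                                       p=[0.05, 0.45, 0.15, 0.35])
            amp_counts = rng.integers(5, 9, size=spec.cells_per_condition)
            counts = np.where(amplified, amp_counts, normal_counts)
            reps.append(FociCountSample(tuple(int(c) for c in counts), f"{cond}_rep{r + 1}"))
        foci[cond] = reps

        shift = spec.chromosome_induced_shift if induced else 0.0
        draw = rng.normal(
            spec.chromosome_baseline_median + shift,
            spec.chromosome_dispersion,
            spec.metaphases_per_condition,
        )
        counts = np.maximum(1, np.round(draw)).astype(int)
        chromosomes.append(ChromosomeCountSample(tuple(int(c) for c in counts), cond))
    return foci, chromosomes
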