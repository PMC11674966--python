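# Methods

## The analysis

`cnaburden` quantifies a tumor's chromosomal numerical abnormality (CNA)
burden from gene-level discrete copy-number calls and tests whether that
burden is associated with the expression of a designated gene (default
symbol: *STIL*, a centriole-duplication regulator whose overexpression
drives centrosome amplification and chromosomal instability).

### Arm-level status calling

The input is a gene × sample matrix of GISTIC-style calls in
{−2, −1, 0, +1, +2}, plus a gene → chromosome-arm map. For each
(arm, case) pair, let *n* be the number of informative (non-missing)
genes on the arm, *k*₋ the number with calls in {−2, −1} and *k*₊ the
number in {+1, +2}. The arm is called

- **deletion** if *k*₋/*n* ≥ *t*,
- else **amp_gain** if *k*₊/*n* ≥ *t*,
- else **diploid**; with *n* = 0 the arm is **no_call**,

with threshold *t* = 2/3 by default, boundary inclusive. Because 2/3
has no finite binary representation, the comparison is evaluated in
integer arithmetic (3·*k* ≥ 2·*n*), so an arm with exactly two-thirds
of its genes deleted is a deletion on every platform. Deletion is
evaluated before amplification; for any *t* > 1/2 the two criteria are
mutually exclusive (*k*₋ + *k*₊ ≤ *n* < 2*t*·*n*), so the order cannot
matter. For permissive *t* ≤ 1/2 a tie is possible; it is resolved to
diploid with a warning, since such thresholds are outside the intended
use.

Missing gene calls are dropped from the denominator rather than counted
as diploid: counting them as diploid would bias arms with patchy
coverage toward diploid.

### Arm universe

The default universe holds 41 arms: 1p–22q excluding the acrocentric
p-arms (13p, 14p, 15p, 21p, 22p), plus Xp/Xq; Y is excluded. The
acrocentric p-arms carry essentially no protein-coding genes in
gene-level call tables, which would make the fractional rule vacuous
(permanent no_call) there. The full 48-arm set is available through
`ArmUniverseConfig(include_acrocentric_p=True, include_y=True)`.

Genes are assigned to arms from a cytoband string ("17p13.1" → 17p)
or explicit coordinates; BED input (0-based half-open) is converted to
the internal 1-based inclusive convention on read. A gene listed on two
different arms is an input error; a repeated consistent listing is
deduplicated. The bundled
`data/synthetic_gene_arm_map.tsv` is a synthetic stand-in mapping
(5 invented genes per arm) for exercising the pipeline; real analyses
should supply their own annotation, and arm gene counts will differ by
annotation source and genome build.

### Burden, completeness, and the median split

A case's **altered-arm count** is the number of arms called deletion or
amp_gain; its **evaluable-arm count** is the number of non-no_call arms.
Arms that are no_call in *every* case (no mapped gene anywhere in the
cohort) are structurally empty and enter neither count nor the
completeness denominator.

A case is **excluded** when more than 50% of the non-empty arm universe
is no_call for it, or when it lacks a matched expression value for the
designated gene (both clauses configurable via `CompletenessRule`).
Excluded cases take no part in the median computation.

The cohort median of the altered-arm count over non-excluded cases
(even *n*: mean of the two central values) is the cutoff: a case is
**CNA-high** iff its count is ≥ the median, **CNA-low** otherwise. The
inclusive boundary means a cohort whose counts all tie the median is
entirely CNA-high; CNA-low is empty exactly when no count falls below
the median. With discrete counts the two groups are generally unequal
in size — that is a property of the median split on ties, not a defect.

### IHC scoring

Staining is recorded as the percentage of cells at intensity 0 (absent),
1 (weak), 2 (moderate), 3 (strong); percentages must sum to 100 (strict
tolerance 10⁻⁶; an opt-in `renormalize` flag rescales hand-entered
near-misses of 99–101). The score is Σᵢ i·pctᵢ ∈ [0, 300]. The
dichotomization cutoff is 3 × the median score of non-cancerous
reference tissue (e.g. reference median 50 → cutoff 150), and a case is
**high** iff score > cutoff — strictly, so a score exactly at the cutoff
is low.

### Statistical layer

All tests are two-sided.

- **Fisher's exact test** (2×2): point-probability rule — the p-value
  sums the probabilities of all tables with the observed margins whose
  hypergeometric probability does not exceed the observed table's. A
  zero margin yields p = 1 with a warning. p-values are formatted to
  4 decimals.
- **Mann–Whitney U**: exact enumeration when min(n₁, n₂) ≤ 8 with no
  ties; otherwise the normal approximation with tie and continuity
  corrections. For tie-free samples in the exact regime the two paths
  agree within 0.02 (regression-guarded).
- **Wilcoxon signed-rank**: zero differences dropped; exact for ≤ 12
  nonzero differences without tied magnitudes, corrected normal
  approximation otherwise.
- **Unpaired t-test**: Welch (unequal variances) by default, pooled via
  `equal_var=True`. Two constant equal-mean groups give p = 1 by
  convention.

Cell-assay summaries: the **centrosome-amplification fraction** is the
percentage of cells with strictly more than four centrin foci (four is
the normal duplicated complement); chromosome-count samples are
summarized as per-condition medians and IQRs with pairwise Mann–Whitney
comparisons. No multiple-testing correction is applied anywhere — the
report is per-factor, matching how such tables are conventionally read.

## The synthetic cohort generator

Per tumor case each arm of the universe is independently altered with
probability `p_arm_alter` (default 0.3); an altered arm is a deletion
with probability `del_vs_amp` (0.5), else a gain. Each gene on an
altered arm carries a call of the arm's sign — magnitude 1 with
probability 0.7, 2 with 0.3 — with probability `within_arm_coherence`
(0.95), else 0; genes on unaltered arms are 0. Cells are erased
independently with `missing_rate` (0.01). The designated gene's
expression is log-normal with log-mean
`baseline + tumor_log_fold·1[tumor] + β·(true altered-arm count)`
(defaults 3.66 + 1.1 + 0.05·count, log-SD 0.7), putting the non-tumor
median near 39 and the tumor median in the low-to-mid hundreds, the
scale of RSEM-normalized values for this gene class. IHC scores are
Gaussian on the 0–300 scale (reference median target 50, tumor shift
+150) and converted to exact two-level intensity distributions. The
clinical table links advanced pT/pN/stage to the high-expression label
through a configurable odds ratio (default 3). Default cohort sizes are
515 tumors / 59 normals (adenocarcinoma-shaped; a squamous-shaped
501/51 cohort is one constructor call away), with
`n_incomplete_cases = 3` cases emitted without an expression value so
exclusion accounting is exercised end to end.

The generator is fully determined by its integer seed.

What it deliberately does **not** emulate: real per-chromosome
alteration frequencies, whole-genome doubling (arm alterations are
independent; a doubling process is future work), linkage between
neighbouring arms, negative-binomial expression counts (only rank-based
tests consume expression, so a log-normal marginal suffices), and tumor
ploidy. Passing tests therefore demonstrate the correctness of the
pipeline's logic under the stated generative model, not fidelity to any
real cohort's alteration landscape.

## Calibration and validation choices

- **Brute-force agreement**: burden counting is checked against an
  independent plain-Python recount on 200 random matrices of ≤ 5 arms,
  ≤ 8 genes/arm, ≤ 10 cases — exact agreement required.
- **Label recovery**: with coherence ≥ 0.9 and ≤ 5% missingness, the
  pipeline reproduces the generator's true CNA labels with ≥ 95%
  agreement over 20 seeds (100-case, 41-arm, 12-genes/arm cohorts).
  Disagreements concentrate at the median boundary, where a one-arm
  shift flips the label.
- **Null calibration**: with β = 0 the CNA-high vs CNA-low Mann–Whitney
  test rejects at α = 0.05 in 5% ± 2% of 1,000 cohorts and its p-values
  pass a Kolmogorov–Smirnov uniformity check. These runs use compact
  cohorts (60 tumors, 10 arms × 6 genes) — calibration is a property of
  the test statistic, not of cohort scale.
- Small-sample exactness of the rank tests is verified against explicit
  enumeration oracles (all C(6,3) rank splits; all 2³ sign
  assignments).

## Known limitations

- No ploidy correction: a genome-doubled tumor inflates the altered-arm
  count; the burden is a raw abnormality count, not a ploidy-adjusted
  aneuploidy score.
- The completeness criterion behind real-cohort exclusions is not
  published; the default rule (> 50% no_call arms, or missing
  expression) is explicit, configurable, and echoed into every report's
  provenance block, but other rules could exclude different cases.
- Segment-level (non-gene-level) copy-number input and genome-build
  liftover are out of scope.
- The median split ties all boundary cases into CNA-high; analyses
  sensitive to the boundary should inspect the burden table directly.
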