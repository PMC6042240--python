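# Methods

## The signature score

The package's central statistic is a per-sample, direction-weighted sum of
control-standardized expression. Given an expression matrix X (genes ×
samples, continuous intensities on whatever scale the user supplies), a
signature {(gene *i*, *k<sub>i</sub>* ∈ {+1, −1})}, and a control/case
annotation:

1. **Control reference.** Per gene, the mean and sample SD (divisor n−1) over
   control samples only. Genes with zero control SD are excluded and
   reported — the z-score is undefined there and imputation would silently
   change the statistic. If every gene is excluded, scoring aborts.
2. **Raw score.** raw(s) = Σᵢ kᵢ (xᵢₛ − meanᵢ)/sdᵢ. The score is linear in
   each gene's z-score, so it is exactly invariant to per-gene affine
   rescaling of the input (with the reference rebuilt) and exactly
   sign-flipped by negating all k.
3. **Normalization.** Subtraction of the control-group mean raw score, so
   controls average zero. Subtraction (not division) is the default because
   a summed z-score is naturally location-normalized; the raw-score mean of
   controls is an arbitrary offset, not a scale. `normalize="none"` disables
   it.

Assumptions: expression values are finite, on a roughly log-like continuous
scale (the package never transforms them; a `scale_note` tag records
provenance), and missing values are not supported — the formula has no
missing-data rule, so an unparsable or empty cell is a hard error at read
time rather than a silent NaN.

## Gene filtering

Candidate signature genes pass a conjunction filter before scoring:

- **CV > cv_min** (default 0.5), where CV = sample SD / |mean| across **all**
  samples on the input scale. All-sample CV is the common variance-filter
  convention; a control-only variant would conflate the filter with the
  differential test. Genes with zero mean have undefined CV and are dropped
  with a recorded reason.
- **BH-adjusted p < fdr_max** (default 0.05) from a per-gene two-sided
  case-vs-control test: Welch's t-test by default (standard microarray
  practice, robust to unequal group variances), with
  `test="mannwhitney"` as a rank-based alternative. The
  Benjamini–Hochberg adjustment runs over exactly the tested signature
  genes, not the whole matrix: the multiplicity burden belongs to the
  hypothesis family actually tested.

Sample SD uses divisor n−1 everywhere (CV, control reference, tests) for
internal consistency.

## Stratification

Samples are clustered on a gene panel (typically the filtered signature).
Panel genes are z-scored per gene over all samples; the inter-sample
distance is 1 − Pearson correlation of the z-scored profiles with average
linkage by default — the prevailing convention for transcriptome heatmaps —
with euclidean distance and complete/single/ward linkage available. The tree
is cut to a fixed requested number of clusters (default 3) with scipy's
`cut_tree`, which splits by merge order and therefore produces the requested
count deterministically even on tied heights. Labels are renumbered 1..k by
decreasing cluster size, ties broken by the smallest member sample id, so
identical input always yields identical labels.

Two degenerate-geometry rules: a zero-variance panel gene is dropped with a
warning (its z-score is undefined), but if the *entire* panel is constant —
e.g. all samples identical — the panel is kept as centered zero rows so the
cut is still defined and deterministic rather than a crash. Correlation
distance between constant or identical profiles is defined as 0 when the
vectors are equal and 1 otherwise.

Note that correlation distance is blind to a uniform mean shift: if every
panel gene moves in the same direction by the same amount, sample *profiles*
remain uncorrelated noise and clusters will not track diagnosis. A
direction-mixed panel (some induced, some suppressed genes) creates the
up/down pattern that correlation distance — and the familiar red/green
heatmap — actually responds to; use euclidean distance when the signal is a
uniform shift.

Cluster membership is tested against diagnosis group with a plain Pearson
chi-square on the cluster × group count table, no continuity correction,
df = (r−1)(c−1). Expected counts below 5 trigger a logged warning but do not
block the test.

## Coexpression module

The orthogonal route to a signature: Spearman-correlate every gene with an
anchor gene across all samples (average ranks for ties), keep genes with
r strictly greater than a one-sided positive threshold (default 0.5 — no
absolute value; anticorrelated genes are a different biological statement),
cap the pool at the `max_candidates` (default 400) highest-r genes with ties
broken by gene id ascending, and intersect with the union of user-selected
pathway gene sets from a GMT file. The anchor itself is excluded. A constant
anchor row is a hard error (rank correlation undefined); an empty candidate
pool is a warning and an empty module, since "nothing coexpressed at this
threshold" is a legitimate result.

## Associations and summaries

Score–score and score–covariate correlations default to Pearson (the
relationships of interest are linear trends between continuous scores), with
Spearman available; p-values come from scipy's t-approximation /
rank methods. Pairs are matched by sample id; pairs with a missing value are
dropped and counted; fewer than 3 complete pairs or a zero-variance vector
is a hard error. Two-group comparisons (e.g. limited vs diffuse disease,
early vs late duration) use the two-sided Wilcoxon–Mann–Whitney test;
categories must reduce to exactly two, either naturally or via an explicit
`groups=` pair. Cohort summaries report per-category counts with
percentages rounded to one decimal and mean ± SD for continuous fields,
with missing values as their own category. The metabolic helpers implement
HOMA-IR = glucose × insulin / 400 (glucose in mg/dL, insulin in µU/mL) and
the leptin/adiponectin ratio (undefined at zero adiponectin).

## Synthetic-data generator

A Gaussian latent-factor model: per sample, latent axis values are drawn
from a multivariate normal with unit variances and a configurable
correlation matrix (checked for positive semidefiniteness before sampling);
case samples receive a per-axis mean shift. Each gene in a named block is
`loading × latent + N(0, noise_sd)`; background genes are pure noise. A
severity covariate (MRSS-like) is generated for cases only as
`max(floor, intercept + slope × latent + noise)`.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| n_control / n_case | 22 / 70 | the reference cohort's group sizes |
| block sizes | ncor 43, pparg 30, tgfb 30, background 400 | primary signature size after filtering; plausible partner-signature sizes; background pool matching the coexpression candidate cap |
| axis correlations | ncor–pparg +0.9, ncor–tgfb −0.8, pparg–tgfb −0.72 | the two planted couplings the analysis must recover; the third pair is their product (zero partial correlation), the natural completion that keeps the matrix PSD |
| group_shift | ncor −1.0 (cases) | one latent SD — a strong but not trivially separable group effect |
| loading / noise_sd | 1.0 / 1.0 | unit signal-to-noise per gene; the block sum then has high aggregate SNR, as real signature scores do |
| mrss slope / intercept / noise / floor | −5.0 / 12.0 / 5.0 / 0 | with the −1 case shift this gives case MRSS ≈ 17 on average with SD ≈ 9, matching the reference cohort's 17 ± 10; the floor mirrors the score's 0 lower bound |
| flip_fraction | 0 per block | all genes induced by default; setting a fraction marks genes suppressed (k = −1) and negates their loadings, exercising the direction-weight machinery |
| subtype / duration probabilities | 30:5:1 diffuse:limited:overlap, 12:24 early:late | the reference cohort's composition |

When `block_sizes` is overridden, default correlations and shifts that refer
to absent axes are silently restricted to the configured axes; explicitly
passed dictionaries are validated strictly.

What the generator emulates: group structure, correlated pathway axes, a
clinically linked severity covariate, direction-mixed signatures,
reproducibility from a single seed. What it does **not** emulate: microarray
probe-level noise, intensity-dependent variance, batch effects, non-Gaussian
expression distributions, or gene–gene correlation beyond the shared latent
axis. Passing tests on this generator therefore demonstrate that the
pipeline's statistics recover planted structure of the assumed form; they do
not certify performance on raw platform data, which should be normalized
upstream.

## Numerical choices

- Sample SD divisor n−1 throughout; exact float round-trip in matrix I/O
  (`%.17g` on write, strtod-exact parse on read).
- BH via `statsmodels.stats.multitest`; tests, correlations, clustering and
  chi-square via scipy. Undefined per-gene test statistics (a gene constant
  in both groups) are assigned p = 1 rather than NaN.
- The score's oracle tolerance in tests is 1e−10 relative; affine-invariance
  checks use 1e−8 absolute to absorb rescaling round-off.
- Candidate-pool truncation and cluster renumbering use explicit,
  documented tie-breaks (gene id ascending; cluster size then smallest
  member id) so every stage is deterministic.

## Problem sizes in the reproduction script

`scripts/acceptance.py` uses the generator's default cohort (22 + 70
samples, 503 genes) averaged over 50 seeds for the correlation-recovery
quantities, 50 seeds for the severity association, 100 seeds × 200 null
genes for the FDR calibration, and a single 92-sample two-blob dataset for
the chi-square separation check; the cohort percentages are computed from
the 36-patient reference composition. These sizes give stable estimates
(Monte-Carlo SE well below the reported precision) while keeping a full run
in the seconds range.

## Known limitations

- No missing-data support in expression input (by design; see above).
- The CV filter is scale-sensitive: on already-centered data, near-zero
  means inflate CV. Users with centered input should set `cv_min=0`.
- The chi-square is asymptotic; with very small clusters the logged
  small-expected-count warning should be taken seriously.
- The coexpression module takes user-supplied gene sets at face value; it
  does not ship or reconstruct any pathway database.
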