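# fibrosig

Control-standardized gene-signature scoring and cohort stratification for
fibrosis transcriptomics.

## What problem this solves

In systemic sclerosis (SSc, scleroderma) and other fibrotic diseases, the
activity of a regulatory pathway in a skin biopsy is often summarized as a
single per-sample **signature score** computed from the expression of a
curated gene list. `fibrosig` implements that analysis end to end for
bulk expression matrices: filtering the candidate gene list, computing the
score, stratifying the cohort by hierarchical clustering, deriving an
orthogonal coexpression module around an anchor gene, and correlating scores
with other signatures and with clinical severity (the modified Rodnan skin
score, MRSS). It is aimed at translational researchers who have a
genes × samples expression table, a case/control annotation, and one or more
direction-annotated gene signatures.

## The score

For a signature with genes *i* = 1…*n* and direction weights
*k<sub>i</sub>* ∈ {+1 (induced), −1 (suppressed)}, the raw score of sample
*s* is

```
raw(s) = Σᵢ  kᵢ · ( xᵢₛ − mean_ctrl(i) ) / sd_ctrl(i)
```

where `mean_ctrl(i)` and `sd_ctrl(i)` are the mean and sample SD (divisor
n−1) of gene *i* over **control samples only**. Scores are then normalized
to the control group by subtracting the control-mean raw score, so controls
average exactly zero and a case score reads as its displacement from the
control baseline in summed z-units.

Before scoring, candidate genes pass a two-part filter: coefficient of
variation (SD/|mean| across all samples) above `cv_min` (default 0.5) **and**
Benjamini–Hochberg-adjusted case-vs-control p-value (Welch's t-test by
default) below `fdr_max` (default 0.05).

Downstream stages:

- **Stratification** — agglomerative clustering of samples on the filtered
  signature panel (1 − Pearson correlation distance, average linkage by
  default), cut to a requested number of clusters, with a Pearson chi-square
  test of cluster membership against diagnosis group.
- **Coexpression module** — Spearman correlation of every gene with an
  anchor gene; genes with r above a one-sided threshold (default 0.5, capped
  at the 400 highest) intersected with user-supplied pathway gene sets (GMT).
- **Associations** — Pearson/Spearman correlations between scores and
  covariates; two-sided Wilcoxon–Mann–Whitney comparisons across clinical
  subgroups; cohort summaries; small clinical formulas
  (HOMA-IR = glucose × insulin / 400, leptin/adiponectin ratio).
- **Synthetic data** — a latent-factor generator that plants configurable
  axis correlations, group shifts and a severity covariate, so the whole
  pipeline is testable without any external download.

## Worked example

```python
import fibrosig as fs

# a synthetic 22-control / 70-case cohort; the 43-gene primary axis carries a
# case shift and a mix of induced (k=+1) and suppressed (k=-1) genes
cfg = fs.SyntheticConfig(noise_sd=0.5, flip_fraction={"ncor": 0.4},
                         group_shift={"ncor": -1.5}, seed=42)
ds = fs.generate(cfg)

score, filt = fs.score_signature(ds.matrix, ds.annot, ds.signatures["ncor"])
assignment = fs.cluster_samples(ds.matrix, score.genes_used, n_clusters=3)
res = fs.cluster_group_chisq(assignment, ds.annot)
mrss = fs.correlate_scores(score.normalized, ds.annot["mrss"].dropna())
```

Output (printed by the snippet above plus the obvious `print` calls):

```
kept 43/43
ctrl +0.000 case -55.870
group    case  control
cluster
1          28       20
2          41        2
3           1        0
k=3: chi2=17.4 df=2 p=0.00017
vs pparg r=+0.718, vs tgfb r=-0.697
mrss r=-0.708 p=7.2e-12 n=70
```

Reading the numbers: all 43 planted signature genes survive the CV/FDR
filter; control samples average exactly 0 by construction while cases sit
far below baseline (the planted case shift is negative and amplified by the
43-gene sum); the three clusters separate cases from controls
(chi-square = 17.4, p < 0.001); the score correlates positively with the
positively-coupled second axis and negatively with the anticorrelated third
axis; and the score tracks the planted severity covariate (r = −0.71).

The same stages are available from the shell:

```bash
fibrosig simulate --out data/ --seed 42
fibrosig score --matrix data/matrix.tsv --annot data/annotations.tsv \
               --signature data/signature_ncor.tsv --out scores.tsv
fibrosig cluster --matrix data/matrix.tsv --annot data/annotations.tsv \
                 --panel panel.txt --k 3
fibrosig run --config run.yaml     # full pipeline, JSON report
```

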