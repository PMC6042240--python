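"""Signature-gene filtering and the control-standardized signature score.

The score for a sample s over a signature with genes i and directions
k_i in {+1, -1} is

    raw(s) = sum_i k_i * (x_is - mean_ctr_i) / sd_ctr_i

where mean_ctr_i and sd_ctr_i are the mean and sample SD (divisor n-1) of
gene i over control samples only. Scores are then centered on the control
group: normalized(s) = raw(s) - mean(raw over controls), so controls average
zero and a case score reads directly as displacement from the control
baseline in summed z-units.

Candidate genes are filtered before scoring: a gene is kept when its
coefficient of variation across all samples exceeds ``cv_min`` and its
Benjamini-Hochberg-adjusted case-vs-control p-value falls below ``fdr_max``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix, SignatureDefinition, case_samples, control_samples

logger = logging.getLogger(__name__)


@dataclass
class ControlReference:
    """Per-gene control-group mean and sample SD (the standardization baseline)."""

    gene_ids: list[str]
    mean_ctr: np.ndarray
    sd_ctr: np.ndarray
    excluded: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (len(self.gene_ids) == len(self.mean_ctr) == len(self.sd_ctr)):
            raise ValueError("control reference arrays misaligned")
        if np.any(self.sd_ctr <= 0):
            raise ValueError("control reference contains non-positive SDs")


@dataclass
class FilterResult:
    """Per-gene CV / p / BH-q table with the kept flag and thresholds used."""

    table: pd.DataFrame  # index gene_id; columns cv, p_value, q_value, kept
    cv_min: float
    fdr_max: float
    dropped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def kept_genes(self) -> list[str]:
        return list(self.table.index[self.table["kept"]])


@dataclass
class ScoreVector:
    """Per-sample raw and control-centered signature scores."""

    signature_name: str
    sample_ids: list[str]
    raw_score: np.ndarray
    normalized_score: np.ndarray
    control_mean_raw: float
    genes_used: list[str]
    genes_dropped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def normalized(self) -> pd.Series:
        return pd.Series(self.normalized_score, index=self.sample_ids, name=self.signature_name)

    @property
    def raw(self) -> pd.Series:
        return pd.Series(self.raw_score, index=self.sample_ids, name=f"{self.signature_name}_raw")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"raw_score": self.raw_score, "normalized_score": self.normalized_score},
            index=pd.Index(self.sample_ids, name="sample_id"),
        )
        return df


def _group_split(matrix: ExpressionMatrix, annot: pd.DataFrame) -> tuple[list[str], list[str]]:
    missing = [s for s in matrix.sample_ids if s not in annot.index]
    if missing:
        raise ValueError(f"samples in matrix absent from annotation: {missing[:5]}")
    in_matrix = set(matrix.sample_ids)
    ctr = [s for s in control_samples(annot) if s in in_matrix]
    cas = [s for s in case_samples(annot) if s in in_matrix]
    return ctr, cas


def filter_signature_genes(
    matrix: ExpressionMatrix,
    annot: pd.DataFrame,
    signature: SignatureDefinition,
    cv_min: float = 0.5,
    fdr_max: float = 0.05,
    test: str = "welch",
) -> FilterResult:
    """Apply the CV > cv_min AND BH-FDR < fdr_max filter to signature genes.

    CV is the sample SD (divisor n-1) over all samples divided by the
    absolute mean, on the input scale. The differential test compares case
    vs control per gene: Welch's two-sided t-test by default, or
    ``test="mannwhitney"`` for a rank alternative. BH adjustment runs over
    exactly the tested signature genes.

    Signature genes absent from the matrix are skipped with a log entry;
    a gene whose all-sample mean is zero has undefined CV and is dropped
    with a reason, not a hard error.
    """
    ctr, cas = _group_split(matrix, annot)
    if len(ctr) < 2 or len(cas) < 2:
        raise ValueError(
            f"need >= 2 samples per group for the filter (control={len(ctr)}, case={len(cas)})"
        )
    dropped: list[tuple[str, str]] = []
    present: list[str] = []
    for g in signature.genes:
        if g in matrix.data.index:
            present.append(g)
        else:
            dropped.append((g, "absent from matrix"))
            logger.info("filter: signature gene %r absent from matrix; skipped", g)
    if not present:
        raise ValueError("no signature genes present in the matrix")

    sub = matrix.data.loc[present]
    all_vals = sub.to_numpy()
    means = all_vals.mean(axis=1)
    sds = all_vals.std(axis=1, ddof=1)

    testable = means != 0
    for g, ok in zip(present, testable):
        if not ok:
            dropped.append((g, "undefined CV (zero mean across samples)"))
    genes = [g for g, ok in zip(present, testable) if ok]
    if not genes:
        raise ValueError("no testable signature genes (all have zero mean)")
    cv = sds[testable] / np.abs(means[testable])

    x = sub.loc[genes, cas].to_numpy()
    y = sub.loc[genes, ctr].to_numpy()
    if test == "welch":
        pvals = stats.ttest_ind(x, y, axis=1, equal_var=False).pvalue
    elif test == "mannwhitney":
        pvals = np.array(
            [stats.mannwhitneyu(xi, yi, alternative="two-sided").pvalue for xi, yi in zip(x, y)]
        )
    else:
        raise ValueError(f"unknown test {test!r} (expected 'welch' or 'mannwhitney')")
    # constant gene in both groups -> test undefined; treat as p = 1 (no evidence)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    qvals = multipletests(pvals, method="fdr_bh")[1]
    kept = (cv > cv_min) & (qvals < fdr_max)

    table = pd.DataFrame(
        {"cv": cv, "p_value": pvals, "q_value": qvals, "kept": kept},
        index=pd.Index(genes, name="gene_id"),
    )
    logger.info(
        "filter: %d/%d signature genes kept (cv > %g and q < %g); %d dropped pre-test",
        int(kept.sum()), len(signature), cv_min, fdr_max, len(dropped),
    )
    return FilterResult(table=table, cv_min=cv_min, fdr_max=fdr_max, dropped=dropped)


def build_control_reference(
    matrix: ExpressionMatrix, annot: pd.DataFrame, genes: list[str]
) -> ControlReference:
    """Per-gene mean and sample SD over control samples only.

    Genes with zero control SD are excluded and reported (the z-score is
    undefined there); if every requested gene is excluded the reference is
    unusable and a hard error is raised.
    """
    ctr, _ = _group_split(matrix, annot)
    if len(ctr) < 2:
        raise ValueError(f"need >= 2 control samples, found {len(ctr)}")
    missing = [g for g in genes if g not in matrix.data.index]
    if missing:
        raise KeyError(f"requested genes not in matrix: {missing[:5]}")
    sub = matrix.data.loc[list(genes), ctr].to_numpy()
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    excluded = [(g, "zero control SD") for g, s in zip(genes, sd) if s == 0]
    keep = sd > 0
    if not keep.any():
        raise ValueError("no scoreable genes: every gene has zero control SD")
    for g, _reason in excluded:
        logger.info("reference: gene %r excluded (zero control SD)", g)
    kept_genes = [g for g, k in zip(genes, keep) if k]
    return ControlReference(
        gene_ids=kept_genes, mean_ctr=mean[keep], sd_ctr=sd[keep], excluded=excluded
    )


def compute_signature_score(
    matrix: ExpressionMatrix,
    annot: pd.DataFrame,
    signature: SignatureDefinition,
    reference: ControlReference,
    normalize: str = "subtract",
) -> ScoreVector:
    """Direction-weighted sum of control-standardized expression per sample.

    ``normalize="subtract"`` (default) centers raw scores on the control
    mean; ``"none"`` reports raw scores unchanged in the normalized slot.
    """
    if normalize not in ("subtract", "none"):
        raise ValueError(f"unknown normalize mode {normalize!r}")
    ctr, _ = _group_split(matrix, annot)
    if not ctr:
        raise ValueError("no control samples to normalize against")
    k_map = signature.k_map
    no_k = [g for g in reference.gene_ids if g not in k_map]
    if no_k:
        raise ValueError(f"reference genes lack a direction k in the signature: {no_k[:5]}")
    missing = [g for g in reference.gene_ids if g not in matrix.data.index]
    if missing:
        raise KeyError(f"reference genes not in matrix: {missing[:5]}")
    if not reference.gene_ids:
        raise ValueError("empty retained gene set: nothing to score")

    k = np.array([k_map[g] for g in reference.gene_ids], dtype=float)
    sub = matrix.data.loc[reference.gene_ids].to_numpy()
    z = (sub - reference.mean_ctr[:, None]) / reference.sd_ctr[:, None]
    raw = (k[:, None] * z).sum(axis=0)

    samples = matrix.sample_ids
    ctr_idx = [samples.index(s) for s in ctr]
    control_mean_raw = float(raw[ctr_idx].mean())
    normalized = raw - control_mean_raw if normalize == "subtract" else raw.copy()
    return ScoreVector(
        signature_name=signature.name,
        sample_ids=samples,
        raw_score=raw,
        normalized_score=normalized,
        control_mean_raw=control_mean_raw,
        genes_used=list(reference.gene_ids),
        genes_dropped=list(reference.excluded),
    )


def score_signature(
    matrix: ExpressionMatrix,
    annot: pd.DataFrame,
    signature: SignatureDefinition,
    cv_min: float = 0.5,
    fdr_max: float = 0.05,
    apply_filter: bool = True,
    test: str = "welch",
    normalize: str = "subtract",
) -> tuple[ScoreVector, FilterResult | None]:
    """Convenience wrapper: (optional) filter -> control reference -> score."""
    filter_result = None
    genes = [g for g in signature.genes if g in matrix.data.index]
    if apply_filter:
        filter_result = filter_signature_genes(
            matrix, annot, signature, cv_min=cv_min, fdr_max=fdr_max, test=test
        )
        genes = filter_result.kept_genes
        if not genes:
            raise ValueError(
                f"signature {signature.name!r}: no genes survive the filter "
                f"(cv > {cv_min}, q < {fdr_max})"
            )
    reference = build_control_reference(matrix, annot, genes)
    score = compute_signature_score(matrix, annot, signature, reference, normalize=normalize)
    return score, filter_result
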