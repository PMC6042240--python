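"""Hierarchical stratification of samples and the cluster-vs-group chi-square.

Samples are clustered on a gene panel (z-scored per gene over all samples)
with agglomerative linkage on a configurable distance — by default
1 - Pearson correlation between sample profiles with average linkage, the
prevailing transcriptome-heatmap convention. The tree is cut to a requested
number of clusters and cluster membership is tested against the diagnosis
group with a plain Pearson chi-square (no continuity correction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import cut_tree, linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform

from .datatypes import ExpressionMatrix

logger = logging.getLogger(__name__)

VALID_DISTANCES = ("correlation", "euclidean")
VALID_LINKAGES = ("average", "complete", "single", "ward")


@dataclass
class ClusterAssignment:
    sample_ids: list[str]
    labels: np.ndarray  # 1..n_clusters, renumbered by decreasing cluster size
    n_clusters: int
    distance_name: str
    linkage_name: str
    panel_genes: list[str]

    def to_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.sample_ids, name="cluster")


@dataclass
class ContingencyResult:
    table: pd.DataFrame  # clusters x groups, integer counts
    chi_square: float
    df: int
    p_value: float


def _sample_distances(z: np.ndarray, distance: str) -> np.ndarray:
    """Condensed distance vector between sample columns of z (genes x samples)."""
    x = z.T
    if distance == "euclidean":
        return pdist(x, metric="euclidean")
    d = pdist(x, metric="correlation")
    if np.isnan(d).any():
        # constant sample profiles: correlation undefined; identical vectors
        # are distance 0, anything else maximally dissimilar (1)
        sq = squareform(d, checks=False)
        n = x.shape[0]
        for i in range(n):
            for j in range(i + 1, n):
                if np.isnan(sq[i, j]):
                    sq[i, j] = sq[j, i] = 0.0 if np.array_equal(x[i], x[j]) else 1.0
        d = squareform(sq, checks=False)
    return d


def cluster_samples(
    matrix: ExpressionMatrix,
    panel: list[str],
    n_clusters: int = 3,
    distance: str = "correlation",
    linkage: str = "average",
) -> ClusterAssignment:
    """Agglomeratively cluster samples on a gene panel into exactly n_clusters.

    Panel genes absent from the matrix or with zero variance are dropped
    with a warning (an empty panel after dropping is a hard error). Genes are
    z-scored (sample SD, divisor n-1) over all samples before distancing.
    Labels are renumbered 1..n by decreasing cluster size, ties broken by the
    smallest member sample id, so the assignment is deterministic.
    """
    if distance not in VALID_DISTANCES:
        raise ValueError(f"unknown distance {distance!r} (expected one of {VALID_DISTANCES})")
    if linkage not in VALID_LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r} (expected one of {VALID_LINKAGES})")
    if n_clusters < 1 or n_clusters > matrix.n_samples:
        raise ValueError(f"n_clusters={n_clusters} out of range for {matrix.n_samples} samples")
    if linkage == "ward" and distance != "euclidean":
        logger.warning("ward linkage assumes euclidean distance; results may be hard to interpret")

    kept: list[str] = []
    for g in panel:
        if g not in matrix.data.index:
            logger.warning("cluster: panel gene %r absent from matrix; dropped", g)
            continue
        kept.append(g)
    if not kept:
        raise ValueError("panel empty after dropping absent genes")
    sub = matrix.data.loc[kept].to_numpy()
    sd = sub.std(axis=1, ddof=1)
    zero_var = sd == 0
    if zero_var.all():
        # fully degenerate geometry (e.g. all samples identical): keep the
        # panel as centered zero rows so the cut is still defined
        logger.warning("cluster: every panel gene has zero variance; samples are indistinguishable")
        z = np.zeros_like(sub)
    else:
        for g, zv in zip(kept, zero_var):
            if zv:
                logger.warning("cluster: panel gene %r has zero variance; dropped", g)
        kept = [g for g, zv in zip(kept, zero_var) if not zv]
        sub = sub[~zero_var]
        z = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(axis=1, ddof=1, keepdims=True)

    d = _sample_distances(z, distance)
    tree = scipy_linkage(d, method=linkage)
    raw = cut_tree(tree, n_clusters=n_clusters).ravel()

    samples = matrix.sample_ids
    # renumber 1..k: largest cluster first, ties by smallest member sample id
    order = sorted(
        np.unique(raw),
        key=lambda c: (-(raw == c).sum(), min(s for s, lab in zip(samples, raw) if lab == c)),
    )
    remap = {old: new for new, old in enumerate(order, start=1)}
    labels = np.array([remap[c] for c in raw], dtype=int)
    logger.info(
        "cluster: %d samples on %d panel genes -> %d clusters (sizes %s)",
        len(samples), len(kept), n_clusters,
        np.bincount(labels)[1:].tolist(),
    )
    return ClusterAssignment(
        sample_ids=list(samples),
        labels=labels,
        n_clusters=int(labels.max()),
        distance_name=distance,
        linkage_name=linkage,
        panel_genes=kept,
    )


def cluster_group_chisq(assignment: ClusterAssignment, annot: pd.DataFrame) -> ContingencyResult:
    """Pearson chi-square (no continuity correction) on the cluster x group table."""
    missing = [s for s in assignment.sample_ids if s not in annot.index]
    if missing:
        raise ValueError(f"clustered samples absent from annotation: {missing[:5]}")
    groups = annot.loc[assignment.sample_ids, "group"]
    present = set(groups)
    if len(present) < 2:
        raise ValueError(f"need both diagnosis groups; found only {sorted(present)}")
    table = pd.crosstab(
        pd.Series(assignment.labels, index=assignment.sample_ids, name="cluster"), groups
    )
    chi2, p, df, expected = stats.chi2_contingency(table.to_numpy(), correction=False)
    if (expected < 5).any():
        logger.warning(
            "chi-square: %d expected cells < 5; asymptotic p may be rough",
            int((expected < 5).sum()),
        )
    return ContingencyResult(table=table, chi_square=float(chi2), df=int(df), p_value=float(p))


def plot_cluster_heatmap(matrix: ExpressionMatrix, assignment: ClusterAssignment, path) -> None:
    """Minimal heatmap of the z-scored panel with samples grouped by cluster."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = matrix.data.loc[assignment.panel_genes].to_numpy()
    z = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(axis=1, ddof=1, keepdims=True)
    order = np.argsort(assignment.labels, kind="stable")
    fig, ax = plt.subplots(figsize=(8, 5))
    im = ax.imshow(z[:, order], aspect="auto", cmap="RdYlGn_r", vmin=-3, vmax=3)
    boundaries = np.flatnonzero(np.diff(assignment.labels[order]))
    for b in boundaries:
        ax.axvline(b + 0.5, color="black", lw=1)
    ax.set_xlabel("samples (grouped by cluster)")
    ax.set_ylabel(f"panel genes (n={len(assignment.panel_genes)})")
    fig.colorbar(im, ax=ax, label="z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
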