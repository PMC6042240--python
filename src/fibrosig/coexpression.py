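"""Anchor-gene coexpression modules.

Given an anchor gene, every other gene is Spearman-correlated with it across
all samples; genes with r strictly above a one-sided positive threshold form
the candidate pool (capped at the top-r ``max_candidates``), and the module
is the intersection of that pool with a user-supplied pathway gene-set
collection. This is the "orthogonal" route to a signature: rather than a
curated direction-weighted gene list, take what travels with the anchor in
the data and keep the pathway-annotated part.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datatypes import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class CoexpressionModule:
    anchor_gene: str
    r_threshold: float
    candidates: list[tuple[str, float]]  # (gene_id, spearman_r), r > threshold
    module_genes: list[str]  # candidates restricted to the selected pathway sets
    pathway_sets_used: list[str] = field(default_factory=list)

    @property
    def candidate_genes(self) -> list[str]:
        return [g for g, _ in self.candidates]


def spearman_to_anchor(matrix: ExpressionMatrix, anchor: str) -> "np.ndarray":
    """Spearman r of every gene vs the anchor (average ranks for ties).

    Returns an array aligned with ``matrix.gene_ids``; the anchor's own entry
    is 1 by construction. Raises if the anchor row is constant (rank
    correlation undefined).
    """
    if anchor not in matrix.data.index:
        raise KeyError(f"anchor gene {anchor!r} not in matrix")
    values = matrix.values
    a = values[matrix.gene_ids.index(anchor)]
    if np.all(a == a[0]):
        raise ValueError(f"anchor gene {anchor!r} is constant; Spearman correlation undefined")
    ranks = np.apply_along_axis(stats.rankdata, 1, values)  # average ranks
    ar = stats.rankdata(a)
    ar_c = ar - ar.mean()
    rc = ranks - ranks.mean(axis=1, keepdims=True)
    denom = np.sqrt((rc**2).sum(axis=1) * (ar_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (rc @ ar_c) / denom
    return r  # NaN for constant genes; they can never pass a positive threshold


def derive_module(
    matrix: ExpressionMatrix,
    anchor: str,
    gene_sets: GeneSetCollection,
    set_names: list[str] | None = None,
    r_threshold: float = 0.5,
    max_candidates: int = 400,
) -> CoexpressionModule:
    """Build the anchor-coexpression module intersected with pathway sets.

    Candidates are genes (anchor excluded) with Spearman r strictly greater
    than ``r_threshold``; if more than ``max_candidates`` qualify, the
    highest-r genes are kept, ties broken by gene id ascending. An empty
    candidate pool yields an empty module with a warning, not an error.
    """
    r = spearman_to_anchor(matrix, anchor)
    names = set_names if set_names is not None else gene_sets.names
    pathway_union = gene_sets.union(names)

    cand = [
        (g, float(ri))
        for g, ri in zip(matrix.gene_ids, r)
        if g != anchor and np.isfinite(ri) and ri > r_threshold
    ]
    cand.sort(key=lambda gr: (-gr[1], gr[0]))
    if len(cand) > max_candidates:
        logger.info(
            "module: %d genes exceed r > %g; truncating to top %d by r",
            len(cand), r_threshold, max_candidates,
        )
        cand = cand[:max_candidates]
    if not cand:
        logger.warning("module: no genes coexpressed with %r at r > %g", anchor, r_threshold)
    module_genes = [g for g, _ in cand if g in pathway_union]
    logger.info(
        "module: anchor=%r candidates=%d module=%d (sets: %s)",
        anchor, len(cand), len(module_genes), ", ".join(names),
    )
    return CoexpressionModule(
        anchor_gene=anchor,
        r_threshold=r_threshold,
        candidates=cand,
        module_genes=module_genes,
        pathway_sets_used=list(names),
    )
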