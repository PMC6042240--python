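"""Core domain types: expression matrices, annotations, signatures, gene sets.

An :class:`ExpressionMatrix` is a genes-by-samples table of continuous
intensities (the input scale is recorded, never transformed internally). A
:class:`SignatureDefinition` is an ordered list of (gene, k) pairs where
k = +1 marks a gene induced by the pathway of interest and k = -1 a gene it
suppresses. Sample annotations travel as a validated pandas DataFrame
indexed by sample id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_GROUPS = ("control", "case")
VALID_SUBTYPES = ("diffuse", "limited", "overlap", "n/a")
VALID_DURATIONS = ("early", "late", "n/a")

ANNOTATION_COLUMNS = ("group", "mrss", "subtype", "duration_class")


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix with unique string identifiers.

    Parameters
    ----------
    data
        DataFrame with gene ids as index and sample ids as columns. Values
        must be finite floats; the constructor validates and copies nothing.
    scale_note
        Free-text provenance tag for the expression scale (e.g. "log2
        intensities"). The package never transforms values itself.
    """

    data: pd.DataFrame
    scale_note: str = "unspecified"

    def __post_init__(self) -> None:
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValueError("expression matrix is empty")
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "sample")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression matrix contains non-numeric values")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                "non-finite expression value at gene "
                f"{self.data.index[bad[0]]!r}, sample {self.data.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        """Row-subset preserving the requested order; genes must exist."""
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        return ExpressionMatrix(self.data.loc[list(genes)], scale_note=self.scale_note)


@dataclass
class SignatureDefinition:
    """Named gene signature: (gene_id, k) entries with k in {+1, -1}."""

    name: str
    entries: list[tuple[str, int]]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError(f"signature {self.name!r} is empty")
        _check_unique((g for g, _ in self.entries), "signature gene")
        for g, k in self.entries:
            if k not in (1, -1):
                raise ValueError(f"signature {self.name!r}: gene {g!r} has k={k}, expected +1 or -1")

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.entries]

    @property
    def k_map(self) -> dict[str, int]:
        return dict(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): name -> (description, gene list)."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, genes) in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def genes(self, name: str) -> list[str]:
        return self.sets[name][1]

    def union(self, names=None) -> set[str]:
        """Union of the selected sets (all sets if names is None)."""
        if names is None:
            names = self.names
        missing = [n for n in names if n not in self.sets]
        if missing:
            raise KeyError(f"gene sets not in collection: {missing}")
        out: set[str] = set()
        for n in names:
            out.update(self.sets[n][1])
        return out


def validate_annotations(annot: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-annotation table and return it normalized.

    The table must be indexed by unique sample ids (or carry a ``sample_id``
    column, which becomes the index) and contain a ``group`` column with
    values ``control``/``case``. Optional columns: ``mrss`` (nonnegative or
    missing), ``subtype`` and ``duration_class`` (controlled vocabularies,
    missing values mapped to ``n/a``).
    """
    annot = annot.copy()
    if "sample_id" in annot.columns:
        annot = annot.set_index("sample_id")
    annot.index = annot.index.astype(str)
    _check_unique(annot.index, "sample")
    if "group" not in annot.columns:
        raise ValueError("annotation table lacks a 'group' column")
    bad_groups = set(annot["group"]) - set(VALID_GROUPS)
    if bad_groups:
        raise ValueError(f"unknown group labels: {sorted(bad_groups)} (expected {VALID_GROUPS})")
    if "mrss" in annot.columns:
        annot["mrss"] = pd.to_numeric(annot["mrss"], errors="raise")
        if (annot["mrss"].dropna() < 0).any():
            raise ValueError("mrss must be nonnegative where present")
    for col, vocab in (("subtype", VALID_SUBTYPES), ("duration_class", VALID_DURATIONS)):
        if col in annot.columns:
            annot[col] = annot[col].fillna("n/a")
            bad = set(annot[col]) - set(vocab)
            if bad:
                raise ValueError(f"unknown {col} labels: {sorted(bad)} (expected {vocab})")
    return annot


def control_samples(annot: pd.DataFrame) -> list[str]:
    return list(annot.index[annot["group"] == "control"])


def case_samples(annot: pd.DataFrame) -> list[str]:
    return list(annot.index[annot["group"] == "case"])
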