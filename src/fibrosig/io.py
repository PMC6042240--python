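"""Readers and writers for the package's plain-text interchange formats.

Expression matrices are genes-as-rows, samples-as-columns TSV with a header
row of sample ids and gene ids in the first column. Annotations are TSV with
a ``sample_id`` column. Signatures are two-column TSV (gene, direction);
direction may be spelled ``+1``/``-1`` or ``induced``/``suppressed``. Gene
sets use the standard GMT layout (name, description, genes...).

Missing values are not supported in expression input: the score formula has
no missing-data rule, so an empty or unparsable cell is a hard error naming
its location rather than a silent NaN.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GeneSetCollection, SignatureDefinition, validate_annotations

logger = logging.getLogger(__name__)

_DIRECTION_TOKENS = {
    "+1": 1,
    "1": 1,
    "induced": 1,
    "-1": -1,
    "−1": -1,  # unicode minus
    "suppressed": -1,
}


def read_expression_matrix(path, delimiter: str = "\t", scale_note: str = "unspecified") -> ExpressionMatrix:
    """Read a genes x samples matrix from delimited text.

    Raises ``ValueError`` naming the offender on duplicate gene/sample ids,
    non-numeric or empty cells, or an empty matrix.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str, keep_default_na=False)
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ValueError(f"{path}: empty expression matrix")
    raw.index = raw.index.astype(str)
    for ids, what in ((raw.index, "gene"), (raw.columns, "sample")):
        dup = pd.Index(ids)[pd.Index(ids).duplicated()]
        if len(dup):
            raise ValueError(f"{path}: duplicate {what} id: {dup[0]!r}")
    try:
        # exact strtod round-trip; pandas' fast parser can be off by one ulp
        values = raw.to_numpy().astype(np.float64)
    except ValueError:
        for r in range(raw.shape[0]):
            for c in range(raw.shape[1]):
                try:
                    float(raw.iat[r, c])
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric cell {raw.iat[r, c]!r} at gene "
                        f"{raw.index[r]!r}, sample {raw.columns[c]!r}"
                    ) from None
        raise
    numeric = pd.DataFrame(values, index=raw.index, columns=raw.columns)
    return ExpressionMatrix(numeric, scale_note=scale_note)


def write_expression_matrix(matrix: ExpressionMatrix, path, delimiter: str = "\t") -> None:
    """Write a matrix readable back by :func:`read_expression_matrix`.

    Uses repr-precision floats so a write/read round trip reproduces values
    exactly.
    """
    df = matrix.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep=delimiter, float_format="%.17g")


def read_annotations(path, delimiter: str = "\t") -> pd.DataFrame:
    """Read and validate a sample-annotation table (TSV with sample_id column)."""
    annot = pd.read_csv(path, sep=delimiter, dtype={"sample_id": str})
    if "sample_id" not in annot.columns:
        raise ValueError(f"{path}: annotation table lacks a 'sample_id' column")
    return validate_annotations(annot)


def write_annotations(annot: pd.DataFrame, path, delimiter: str = "\t") -> None:
    out = annot.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep=delimiter)


def read_signature(path, name: str | None = None, delimiter: str = "\t") -> SignatureDefinition:
    """Read a two-column (gene, direction) signature table.

    Directions are mapped with the convention induced -> +1, suppressed -> -1;
    numeric spellings +1/-1 pass through. Unknown tokens and duplicate genes
    are hard errors. A header row ``gene<TAB>direction`` is tolerated.
    """
    path = Path(path)
    entries: list[tuple[str, int]] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter=delimiter), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns (gene, direction)")
            gene, token = row[0].strip(), row[1].strip().lower()
            if lineno == 1 and gene.lower() in ("gene", "gene_id") and token in ("direction", "k"):
                continue
            if token not in _DIRECTION_TOKENS:
                raise ValueError(f"{path}:{lineno}: unknown direction token {row[1]!r}")
            entries.append((gene, _DIRECTION_TOKENS[token]))
    if not entries:
        raise ValueError(f"{path}: signature file contains no entries")
    return SignatureDefinition(name=name or path.stem, entries=entries)


def write_signature(signature: SignatureDefinition, path, delimiter: str = "\t") -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["gene", "direction"])
        for gene, k in signature.entries:
            writer.writerow([gene, f"{k:+d}"])


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file: one set per line (name, description, genes...).

    Within-set duplicate genes are collapsed (first occurrence kept) with a
    logged warning; a line with fewer than three fields is a hard error.
    """
    path = Path(path)
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            deduped = list(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                logger.warning("%s:%d: set %r contains duplicate genes; collapsed", path, lineno, name)
            if not deduped:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no genes")
            sets[name] = (desc, deduped)
    if not sets:
        raise ValueError(f"{path}: GMT file contains no sets")
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, (desc, genes) in collection.sets.items():
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_gene_list(path) -> list[str]:
    """Read a one-gene-per-line panel file (blank lines ignored)."""
    with open(path) as fh:
        genes = [line.strip() for line in fh if line.strip()]
    if not genes:
        raise ValueError(f"{path}: gene list is empty")
    return genes
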