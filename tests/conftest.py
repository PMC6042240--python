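import numpy as np
import pandas as pd
import pytest

from fibrosig import ExpressionMatrix, SignatureDefinition, validate_annotations


def make_annot(groups: dict[str, str], **extra_cols) -> pd.DataFrame:
    df = pd.DataFrame({"group": pd.Series(groups)})
    for col, mapping in extra_cols.items():
        df[col] = pd.Series(mapping)
    df.index.name = "sample_id"
    return validate_annotations(df)


def random_dataset(rng: np.random.Generator, n_genes=None, n_samples=None):
    """Small random matrix + annotation with >=2 controls and >=2 cases."""
    n_genes = n_genes or int(rng.integers(2, 11))
    n_samples = n_samples or int(rng.integers(4, 11))
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{i}" for i in range(n_samples)]
    values = rng.normal(0, 1, size=(n_genes, n_samples)) + rng.normal(0, 2, size=(n_genes, 1))
    matrix = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))
    n_ctr = int(rng.integers(2, n_samples - 1))
    annot = make_annot({s: ("control" if i < n_ctr else "case") for i, s in enumerate(samples)})
    return matrix, annot


@pytest.fixture
def toy_scoring_data():
    """Two-gene, three-sample worked example with hand-checkable z-sums.

    g1 (k=+1): controls 1, 3 -> mean 2, sd sqrt(2); case value 4.
    g2 (k=-1): controls 0, 2 -> mean 1, sd sqrt(2); case value -1.
    Case raw score = (4-2)/sqrt(2) - (-1-1)/sqrt(2) = 2*sqrt(2).
    """
    matrix = ExpressionMatrix(
        pd.DataFrame(
            [[1.0, 3.0, 4.0], [0.0, 2.0, -1.0]],
            index=["g1", "g2"],
            columns=["c1", "c2", "p1"],
        )
    )
    annot = make_annot({"c1": "control", "c2": "control", "p1": "case"})
    signature = SignatureDefinition("toy", [("g1", 1), ("g2", -1)])
    return matrix, annot, signature
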