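"""Synthetic expression data with planted latent structure.

The generator draws, per sample, a vector of latent axis values from a
multivariate normal with a configurable correlation matrix; case samples
additionally receive a per-axis mean shift. Each named gene block loads on
its axis (gene = loading x latent + independent Gaussian noise) and a pool of
background genes is pure noise. A clinical severity covariate (MRSS-like,
floored at zero) is tied linearly to one axis for case samples only. The
defaults emulate a two-group skin-biopsy cohort (22 controls, 70 cases) with
three signature axes: a 43-gene primary axis strongly positively coupled to
a 30-gene second axis (r = +0.9) and strongly negatively coupled to a
30-gene third axis (r = -0.8), plus 400 unstructured genes.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GeneSetCollection, SignatureDefinition, validate_annotations
from .io import write_annotations, write_expression_matrix, write_gmt, write_signature

BACKGROUND = "background"


def _default_block_sizes() -> dict[str, int]:
    return {"ncor": 43, "pparg": 30, "tgfb": 30, BACKGROUND: 400}


def _default_axis_correlation() -> dict[tuple[str, str], float]:
    # pparg-tgfb set to the product of the two stated couplings (zero partial
    # correlation), the natural completion that keeps the matrix PSD
    return {("ncor", "pparg"): 0.9, ("ncor", "tgfb"): -0.8, ("pparg", "tgfb"): -0.72}


def _default_group_shift() -> dict[str, float]:
    return {"ncor": -1.0}


def _default_subtype_probs() -> dict[str, float]:
    # mirrors the reference cohort composition: 30 diffuse / 5 limited / 1 overlap
    return {"diffuse": 30 / 36, "limited": 5 / 36, "overlap": 1 / 36}


def _default_duration_probs() -> dict[str, float]:
    return {"early": 12 / 36, "late": 24 / 36}


@dataclass
class SyntheticConfig:
    """Parameters of the latent-factor generator.

    ``block_sizes`` maps axis names to gene counts; the reserved name
    ``background`` is a pure-noise pool with no latent axis. ``axis_correlation``
    holds pairwise target correlations between latent axes (unspecified pairs
    default to 0); the implied matrix must be positive semidefinite.
    ``group_shift`` adds a mean offset to case samples on the named axes.
    ``flip_fraction`` marks a fraction of each block's genes as suppressed
    (k = -1): their loadings are negated and the emitted signature records
    k = -1, so direction-weighted scoring is exercised.
    """

    n_control: int = 22
    n_case: int = 70
    block_sizes: dict[str, int] = field(default_factory=_default_block_sizes)
    axis_correlation: dict[tuple[str, str], float] | None = None
    group_shift: dict[str, float] | None = None
    loading: dict[str, float] | float = 1.0
    noise_sd: float = 1.0
    mrss_slope: float = -5.0
    mrss_intercept: float = 12.0
    mrss_noise_sd: float = 5.0
    mrss_floor: float = 0.0
    mrss_axis: str = "ncor"
    flip_fraction: dict[str, float] = field(default_factory=dict)
    subtype_probs: dict[str, float] = field(default_factory=_default_subtype_probs)
    duration_probs: dict[str, float] = field(default_factory=_default_duration_probs)
    seed: int = 0

    def __post_init__(self) -> None:
        # unspecified correlations/shifts fall back to the defaults, restricted
        # to the axes actually configured; explicit dicts are validated strictly
        axes = set(self.axes)
        if self.axis_correlation is None:
            self.axis_correlation = {
                pair: r for pair, r in _default_axis_correlation().items() if set(pair) <= axes
            }
        if self.group_shift is None:
            self.group_shift = {a: s for a, s in _default_group_shift().items() if a in axes}
        if self.mrss_axis == "ncor" and "ncor" not in axes and self.axes:
            self.mrss_axis = self.axes[0]  # default axis name absent; tie MRSS to the first axis

    @property
    def axes(self) -> list[str]:
        return [b for b in self.block_sizes if b != BACKGROUND]

    def loading_for(self, block: str) -> float:
        if isinstance(self.loading, dict):
            return float(self.loading.get(block, 1.0))
        return float(self.loading)

    def correlation_matrix(self) -> pd.DataFrame:
        axes = self.axes
        mat = pd.DataFrame(np.eye(len(axes)), index=axes, columns=axes)
        for (a, b), r in self.axis_correlation.items():
            if a not in axes or b not in axes:
                raise ValueError(f"axis_correlation names unknown axis: {(a, b)}")
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"correlation {(a, b)} = {r} outside [-1, 1]")
            mat.loc[a, b] = mat.loc[b, a] = r
        eig = np.linalg.eigvalsh(mat.to_numpy())
        if eig.min() < -1e-10:
            raise ValueError(
                f"axis correlation matrix is not positive semidefinite (min eigenvalue {eig.min():.3g})"
            )
        return mat

    def validate(self) -> None:
        if self.n_control < 1 or self.n_case < 1:
            raise ValueError("group sizes must be >= 1")
        for b, n in self.block_sizes.items():
            if n < 1:
                raise ValueError(f"block {b!r} has size {n}; must be >= 1")
        if self.noise_sd <= 0 or self.mrss_noise_sd <= 0:
            raise ValueError("noise SDs must be > 0")
        for b, f in self.flip_fraction.items():
            if b not in self.block_sizes or b == BACKGROUND:
                raise ValueError(f"flip_fraction names unknown block {b!r}")
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"flip_fraction[{b!r}] = {f} outside [0, 1]")
        if self.mrss_axis not in self.axes:
            raise ValueError(f"mrss_axis {self.mrss_axis!r} is not a configured axis")
        self.correlation_matrix()  # PSD check before any sampling


@dataclass
class SyntheticDataset:
    matrix: ExpressionMatrix
    annot: pd.DataFrame
    truth: pd.DataFrame  # samples x axes, realized latent values
    signatures: dict[str, SignatureDefinition]
    gene_sets: GeneSetCollection
    config: SyntheticConfig


def _gene_ids(block: str, n: int) -> list[str]:
    return [f"{block.upper()}_{i:04d}" for i in range(1, n + 1)]


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Draw one dataset from the latent-factor model; reproducible from config.seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    axes = config.axes
    n = config.n_control + config.n_case
    sample_ids = [f"CTRL_{i:03d}" for i in range(1, config.n_control + 1)] + [
        f"CASE_{i:03d}" for i in range(1, config.n_case + 1)
    ]
    is_case = np.array([0] * config.n_control + [1] * config.n_case, dtype=bool)

    corr = config.correlation_matrix().to_numpy()
    latent = rng.multivariate_normal(np.zeros(len(axes)), corr, size=n, method="svd")
    truth = pd.DataFrame(latent, index=sample_ids, columns=axes)
    for axis, shift in config.group_shift.items():
        if axis not in axes:
            raise ValueError(f"group_shift names unknown axis {axis!r}")
        truth.loc[is_case, axis] += shift

    rows: list[np.ndarray] = []
    gene_ids: list[str] = []
    signatures: dict[str, SignatureDefinition] = {}
    gene_sets: dict[str, tuple[str, list[str]]] = {}
    for block, size in config.block_sizes.items():
        ids = _gene_ids(block, size)
        gene_ids.extend(ids)
        noise = rng.normal(0.0, config.noise_sd, size=(size, n))
        if block == BACKGROUND:
            rows.append(noise)
            continue
        n_flip = int(round(config.flip_fraction.get(block, 0.0) * size))
        ks = np.array([1] * (size - n_flip) + [-1] * n_flip)
        load = config.loading_for(block) * ks
        rows.append(load[:, None] * truth[block].to_numpy()[None, :] + noise)
        signatures[block] = SignatureDefinition(
            name=block, entries=[(g, int(k)) for g, k in zip(ids, ks)]
        )
        gene_sets[block.upper()] = (f"synthetic {block} block", ids)

    matrix = ExpressionMatrix(
        pd.DataFrame(np.vstack(rows), index=gene_ids, columns=sample_ids),
        scale_note=f"synthetic latent-factor draw (seed={config.seed})",
    )

    mrss = np.full(n, np.nan)
    mrss_case = (
        config.mrss_intercept
        + config.mrss_slope * truth.loc[is_case, config.mrss_axis].to_numpy()
        + rng.normal(0.0, config.mrss_noise_sd, size=config.n_case)
    )
    mrss[is_case] = np.maximum(config.mrss_floor, mrss_case)

    subtype = np.array(["n/a"] * n, dtype=object)
    duration = np.array(["n/a"] * n, dtype=object)
    subtype[is_case] = rng.choice(
        list(config.subtype_probs), p=list(config.subtype_probs.values()), size=config.n_case
    )
    duration[is_case] = rng.choice(
        list(config.duration_probs), p=list(config.duration_probs.values()), size=config.n_case
    )
    annot = validate_annotations(
        pd.DataFrame(
            {
                "group": np.where(is_case, "case", "control"),
                "mrss": mrss,
                "subtype": subtype,
                "duration_class": duration,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    return SyntheticDataset(
        matrix=matrix,
        annot=annot,
        truth=truth,
        signatures=signatures,
        gene_sets=GeneSetCollection(gene_sets),
        config=config,
    )


def truth_axis_scores(dataset: SyntheticDataset, axis: str) -> pd.Series:
    """Realized latent values for one axis (the recovery target for scoring)."""
    if axis not in dataset.truth.columns:
        raise KeyError(
            f"unknown axis {axis!r}; available: {list(dataset.truth.columns)}"
        )
    return dataset.truth[axis].copy()


def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, str]:
    """Write matrix, annotations, per-block signatures, GMT and truth TSVs."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "matrix.tsv",
        "annotations": outdir / "annotations.tsv",
        "gene_sets": outdir / "blocks.gmt",
        "truth": outdir / "truth.tsv",
    }
    write_expression_matrix(dataset.matrix, paths["matrix"])
    write_annotations(dataset.annot, paths["annotations"])
    write_gmt(dataset.gene_sets, paths["gene_sets"])
    truth = dataset.truth.copy()
    truth.index.name = "sample_id"
    truth.to_csv(paths["truth"], sep="\t", float_format="%.17g")
    for name, sig in dataset.signatures.items():
        p = outdir / f"signature_{name}.tsv"
        write_signature(sig, p)
        paths[f"signature_{name}"] = p
    return {k: str(v) for k, v in paths.items()}


def with_seed(config: SyntheticConfig, seed: int) -> SyntheticConfig:
    """Copy of config with a different seed (field-safe replace)."""
    return replace(config, seed=int(seed))
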