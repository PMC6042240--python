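"""End-to-end run: filter -> score -> cluster -> associate, with a JSON report.

A run is driven by a plain YAML config (paths plus stage parameters); every
stage writes its table under the output directory and contributes to a single
machine-readable ``report.json`` that echoes the config, so any number in the
report can be regenerated from the config and inputs alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from ._version import __version__
from .associations import compare_groups, correlate_scores
from .coexpression import derive_module
from .io import read_annotations, read_expression_matrix, read_gmt, read_signature
from .scoring import score_signature
from .stratify import cluster_group_chisq, cluster_samples

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Stage failure, carrying the stage name for the abort message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    matrix: str
    annotations: str
    signatures: dict[str, str]  # name -> path; first entry is the primary score
    gmt: str | None = None
    module_sets: list[str] = field(default_factory=list)
    anchor: str | None = None
    cv_min: float = 0.5
    fdr_max: float = 0.05
    apply_filter: bool = True
    de_test: str = "welch"
    normalize: str = "subtract"
    r_threshold: float = 0.5
    max_candidates: int = 400
    n_clusters: int = 3
    distance: str = "correlation"
    linkage: str = "average"
    correlation_method: str = "pearson"
    subtype_groups: tuple[str, str] = ("limited", "diffuse")
    duration_groups: tuple[str, str] = ("early", "late")
    outdir: str = "fibrosig_run"
    scale_note: str = "unspecified"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("subtype_groups", "duration_groups"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        for label, p in (("matrix", self.matrix), ("annotations", self.annotations)):
            if not Path(p).exists():
                raise FileNotFoundError(f"{label} file not found: {p}")
        if not self.signatures:
            raise ValueError("at least one signature is required")
        for name, p in self.signatures.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"signature {name!r} file not found: {p}")
        if self.gmt is not None and not Path(self.gmt).exists():
            raise FileNotFoundError(f"GMT file not found: {self.gmt}")
        if not 0 <= self.fdr_max <= 1:
            raise ValueError(f"fdr_max={self.fdr_max} outside [0, 1]")
        if self.cv_min < 0:
            raise ValueError(f"cv_min={self.cv_min} must be >= 0")
        if self.n_clusters < 2:
            raise ValueError(f"n_clusters={self.n_clusters} must be >= 2")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - report stage context
                raise PipelineError(name, exc) from exc

        return wrapped

    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run report dict."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("fibrosig")
    root.addHandler(handler)
    if root.level > logging.INFO or root.level == logging.NOTSET:
        root.setLevel(logging.INFO)

    report: dict = {"version": __version__, "config": _jsonable(asdict(config)), "stages": {}}
    try:
        matrix, annot, signatures = _load_inputs(config)
        report["stages"]["inputs"] = {
            "n_genes": matrix.n_genes,
            "n_samples": matrix.n_samples,
            "n_control": int((annot["group"] == "control").sum()),
            "n_case": int((annot["group"] == "case").sum()),
            "signatures": {name: len(sig) for name, sig in signatures.items()},
        }

        scores, score_report = _score_stage(config, outdir, matrix, annot, signatures)
        report["stages"]["scoring"] = score_report

        primary = next(iter(signatures))
        panel = score_report[primary]["genes_used"]
        report["stages"]["stratification"] = _cluster_stage(config, outdir, matrix, annot, panel)

        if config.anchor and config.gmt:
            report["stages"]["module"] = _module_stage(config, outdir, matrix)

        report["stages"]["associations"] = _associate_stage(config, outdir, scores, annot, primary)
        report["complete"] = True
    except PipelineError:
        report["complete"] = False
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    logger.info("run complete; report at %s", outdir / "report.json")
    return report


@_stage("inputs")
def _load_inputs(config: RunConfig):
    matrix = read_expression_matrix(config.matrix, scale_note=config.scale_note)
    annot = read_annotations(config.annotations)
    signatures = {name: read_signature(p, name=name) for name, p in config.signatures.items()}
    return matrix, annot, signatures


@_stage("scoring")
def _score_stage(config: RunConfig, outdir: Path, matrix, annot, signatures):
    scores = {}
    stage_report = {}
    for name, sig in signatures.items():
        score, filt = score_signature(
            matrix,
            annot,
            sig,
            cv_min=config.cv_min,
            fdr_max=config.fdr_max,
            apply_filter=config.apply_filter,
            test=config.de_test,
            normalize=config.normalize,
        )
        scores[name] = score
        score.to_frame().to_csv(outdir / f"scores_{name}.tsv", sep="\t")
        entry = {
            "genes_in_signature": len(sig),
            "genes_used": list(score.genes_used),
            "n_genes_used": len(score.genes_used),
            "genes_dropped": [list(d) for d in score.genes_dropped],
            "control_mean_raw": score.control_mean_raw,
            "score_summary": _group_score_summary(score, annot),
        }
        if filt is not None:
            filt.table.to_csv(outdir / f"filter_{name}.tsv", sep="\t")
            entry["filter"] = {
                "cv_min": filt.cv_min,
                "fdr_max": filt.fdr_max,
                "n_tested": int(len(filt.table)),
                "n_kept": int(filt.table["kept"].sum()),
                "dropped_pre_test": [list(d) for d in filt.dropped],
            }
        stage_report[name] = entry
    return scores, stage_report


def _group_score_summary(score, annot) -> dict:
    s = score.normalized
    out = {}
    for group in ("control", "case"):
        vals = s.loc[annot.index[annot["group"] == group].intersection(s.index)]
        out[group] = {
            "n": int(len(vals)),
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        }
    return out


@_stage("stratification")
def _cluster_stage(config: RunConfig, outdir: Path, matrix, annot, panel):
    assignment = cluster_samples(
        matrix, panel, n_clusters=config.n_clusters,
        distance=config.distance, linkage=config.linkage,
    )
    assignment.to_series().to_csv(outdir / "clusters.tsv", sep="\t")
    contingency = cluster_group_chisq(assignment, annot)
    contingency.table.to_csv(outdir / "contingency.tsv", sep="\t")
    return {
        "n_clusters": assignment.n_clusters,
        "distance": assignment.distance_name,
        "linkage": assignment.linkage_name,
        "n_panel_genes": len(assignment.panel_genes),
        "cluster_sizes": assignment.to_series().value_counts().sort_index().to_dict(),
        "contingency": {str(k): v for k, v in contingency.table.to_dict().items()},
        "chi_square": contingency.chi_square,
        "df": contingency.df,
        "p_value": contingency.p_value,
    }


@_stage("module")
def _module_stage(config: RunConfig, outdir: Path, matrix):
    gene_sets = read_gmt(config.gmt)
    set_names = config.module_sets or None
    module = derive_module(
        matrix, config.anchor, gene_sets, set_names=set_names,
        r_threshold=config.r_threshold, max_candidates=config.max_candidates,
    )
    pd.DataFrame(module.candidates, columns=["gene_id", "spearman_r"]).to_csv(
        outdir / "module_candidates.tsv", sep="\t", index=False
    )
    (outdir / "module_genes.txt").write_text("\n".join(module.module_genes) + "\n")
    return {
        "anchor": module.anchor_gene,
        "r_threshold": module.r_threshold,
        "n_candidates": len(module.candidates),
        "n_module_genes": len(module.module_genes),
        "pathway_sets_used": module.pathway_sets_used,
    }


@_stage("associations")
def _associate_stage(config: RunConfig, outdir: Path, scores, annot, primary: str):
    out: dict = {"score_pairs": {}, "clinical": {}, "group_comparisons": {}}
    names = list(scores)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            res = correlate_scores(scores[a], scores[b], method=config.correlation_method)
            out["score_pairs"][f"{a}~{b}"] = _jsonable(asdict(res))
    if "mrss" in annot.columns and annot["mrss"].notna().any():
        mrss = annot["mrss"].dropna()
        for name in names:
            res = correlate_scores(
                scores[name].normalized, mrss, method=config.correlation_method
            )
            out["clinical"][f"{name}~mrss"] = _jsonable(asdict(res))
    for split_by, groups in (
        ("subtype", config.subtype_groups),
        ("duration_class", config.duration_groups),
    ):
        if split_by in annot.columns:
            try:
                res = compare_groups(scores[primary], annot, split_by, groups=groups)
                out["group_comparisons"][split_by] = _jsonable(asdict(res))
            except ValueError as exc:
                logger.warning("comparison on %r skipped: %s", split_by, exc)
                out["group_comparisons"][split_by] = {"skipped": str(exc)}
    with open(outdir / "associations.json", "w") as fh:
        json.dump(out, fh, indent=2)
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj
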