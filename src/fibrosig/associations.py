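"""Score associations, subgroup comparisons, cohort summaries, clinical formulas.

Correlations between signature scores (and between a score and a clinical
covariate such as the modified Rodnan skin score) default to Pearson, with
Spearman available; two-group score comparisons use the two-sided
Wilcoxon-Mann-Whitney test. Cohort summaries report category counts with
one-decimal percentages and mean +/- SD for continuous fields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AssociationResult:
    method: str  # "pearson" or "spearman"
    r: float
    p_value: float
    n: int  # complete pairs used
    n_dropped: int = 0  # pairs dropped for missingness


@dataclass
class GroupComparisonResult:
    group_labels: tuple[str, str]
    n_per_group: tuple[int, int]
    statistic: float
    p_value: float
    method: str = "wilcoxon-mann-whitney"


@dataclass
class CohortSummary:
    n_total: int
    categorical: dict[str, dict[str, tuple[int, float]]]  # field -> cat -> (count, pct)
    continuous: dict[str, tuple[float, float, int]]  # field -> (mean, sd, n nonmissing)


@dataclass
class MetabolicPanel:
    glucose: float
    insulin: float
    homa_ir: float
    leptin: float
    adiponectin: float
    leptin_adiponectin_ratio: float  # NaN when adiponectin == 0


def _as_series(x) -> pd.Series:
    if hasattr(x, "normalized"):  # ScoreVector
        return x.normalized
    return pd.Series(x)


def correlate_scores(x, y, method: str = "pearson") -> AssociationResult:
    """Correlate two per-sample vectors paired by sample id.

    Accepts pandas Series (index = sample id) or ScoreVector objects (their
    normalized scores are used). Pairs with a missing value in either vector
    are dropped and counted. Requires n >= 3 complete pairs and nonzero
    variance in both vectors.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    xs, ys = _as_series(x), _as_series(y)
    common = xs.index.intersection(ys.index)
    paired = pd.DataFrame({"x": xs.loc[common], "y": ys.loc[common]})
    complete = paired.dropna()
    n_dropped = len(paired) - len(complete)
    if len(complete) < 3:
        raise ValueError(f"need >= 3 complete pairs, found {len(complete)}")
    xv, yv = complete["x"].to_numpy(), complete["y"].to_numpy()
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("zero variance in one of the vectors; correlation undefined")
    if method == "pearson":
        res = stats.pearsonr(xv, yv)
    else:
        res = stats.spearmanr(xv, yv)
    return AssociationResult(
        method=method,
        r=float(res.statistic if hasattr(res, "statistic") else res[0]),
        p_value=float(res.pvalue if hasattr(res, "pvalue") else res[1]),
        n=len(complete),
        n_dropped=n_dropped,
    )


def compare_groups(
    scores,
    annot: pd.DataFrame,
    split_by: str,
    groups: tuple[str, str] | None = None,
) -> GroupComparisonResult:
    """Two-sided Wilcoxon-Mann-Whitney comparison of scores across a split.

    ``split_by`` names an annotation column (e.g. ``subtype`` or
    ``duration_class``); samples whose category is missing or ``n/a`` are
    excluded. If the column has more than two remaining categories, pass
    ``groups`` to select the pair to compare; otherwise a hard error names
    the categories found.
    """
    s = _as_series(scores)
    if split_by not in annot.columns:
        raise KeyError(f"annotation column {split_by!r} not found")
    cats = annot.loc[annot.index.intersection(s.index), split_by]
    cats = cats[cats.notna() & (cats != "n/a")]
    if groups is not None:
        cats = cats[cats.isin(groups)]
    found = sorted(cats.unique())
    if len(found) != 2:
        raise ValueError(
            f"need exactly two nonempty groups in {split_by!r}; found {found or 'none'}"
        )
    a = s.loc[cats.index[cats == found[0]]].dropna()
    b = s.loc[cats.index[cats == found[1]]].dropna()
    if len(a) == 0 or len(b) == 0:
        raise ValueError(f"empty group after dropping missing scores in {split_by!r}")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparisonResult(
        group_labels=(found[0], found[1]),
        n_per_group=(len(a), len(b)),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )


def summarize_cohort(
    annot: pd.DataFrame,
    categorical: tuple[str, ...] = ("group", "subtype", "duration_class", "sex"),
    continuous: tuple[str, ...] = ("age", "mrss"),
) -> CohortSummary:
    """Counts and one-decimal percentages per category; mean +/- SD per continuous field.

    Missing categorical values are reported as their own ``missing`` category
    so percentages always account for every row. Fields absent from the table
    are skipped silently (the annotation schema only mandates ``group``).
    """
    if len(annot) == 0:
        raise ValueError("annotation table is empty")
    n_total = len(annot)
    cat_out: dict[str, dict[str, tuple[int, float]]] = {}
    for col in categorical:
        if col not in annot.columns:
            continue
        vals = annot[col].fillna("missing")
        counts = vals.value_counts()
        cat_out[col] = {
            str(cat): (int(cnt), round(100.0 * cnt / n_total, 1)) for cat, cnt in counts.items()
        }
    cont_out: dict[str, tuple[float, float, int]] = {}
    for col in continuous:
        if col not in annot.columns:
            continue
        vals = pd.to_numeric(annot[col], errors="raise").dropna()
        if len(vals) == 0:
            continue
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        cont_out[col] = (float(vals.mean()), sd, int(len(vals)))
    return CohortSummary(n_total=n_total, categorical=cat_out, continuous=cont_out)


def compute_metabolic_panel(
    glucose: float, insulin: float, leptin: float, adiponectin: float
) -> MetabolicPanel:
    """HOMA-IR = glucose x insulin / 400 and the leptin/adiponectin ratio.

    All inputs must be nonnegative in the units supplied (HOMA-IR's /400
    constant assumes glucose in mg/dL and insulin in uU/mL). The ratio is
    undefined (NaN) when adiponectin is zero; HOMA-IR is still computed.
    """
    for name, v in (
        ("glucose", glucose), ("insulin", insulin), ("leptin", leptin), ("adiponectin", adiponectin),
    ):
        if v < 0:
            raise ValueError(f"{name} must be nonnegative, got {v}")
    homa_ir = glucose * insulin / 400.0
    ratio = leptin / adiponectin if adiponectin > 0 else math.nan
    return MetabolicPanel(
        glucose=glucose,
        insulin=insulin,
        homa_ir=homa_ir,
        leptin=leptin,
        adiponectin=adiponectin,
        leptin_adiponectin_ratio=ratio,
    )
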