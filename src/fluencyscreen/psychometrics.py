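"""Validation statistics for diagnostic screening scores.

Everything needed to validate a two-group (case/control) screening study:

- empirical ROC curves, AUC as the Mann-Whitney concordance probability,
  Youden-optimal cutoffs and confusion metrics (sensitivity, specificity,
  PPV, NPV);
- paired AUC comparison via the DeLong structural-components covariance
  estimate with a two-sided normal z test;
- Cronbach's alpha for internal consistency;
- partial Pearson correlation (residualised on covariates) and ANCOVA-style
  adjusted group comparison, both used here to adjust for age and education;
- baseline group comparisons (Student's t for continuous variables,
  Pearson chi-square for categorical ones);
- test-retest reliability as the covariate-adjusted correlation between two
  administrations.

Orientation is always explicit: a score is either higher-in-cases (the
weighted-sum risk score, age) or lower-in-cases (MMSE, total and half
scores, switching, intrusion); nothing is inferred from the data. ROC
thresholds are placed at midpoints between adjacent distinct observed
scores plus infinite endpoints, so reported cutoffs fall between observed
values, as published cutoff tables do.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Orientation",
    "DEFAULT_ORIENTATIONS",
    "ROCCurve",
    "CutoffMetrics",
    "AUCComparison",
    "ScoredCohort",
    "roc_curve",
    "auc",
    "youden_optimal_cutoff",
    "cutoff_metrics",
    "delong_auc_variance",
    "delong_compare",
    "cronbach_alpha",
    "fluency_item_matrix",
    "partial_pearson",
    "ancova_compare",
    "baseline_compare",
    "test_retest",
    "evaluate_cohort",
]

Orientation = Literal["higher", "lower"]

#: Which direction marks the case group for each standard score.
DEFAULT_ORIENTATIONS: dict[str, Orientation] = {
    "ws": "higher",
    "age": "higher",
    "mmse": "lower",
    "total": "lower",
    "first_half": "lower",
    "second_half": "lower",
    "switching": "lower",
    "intrusion": "lower",
    "clustering": "higher",
    "perseveration": "higher",
}


class DegenerateInputError(ValueError):
    """Single-class labels or otherwise degenerate statistical input."""


def _case_mask(labels: Sequence) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype == bool:
        mask = arr
    else:
        vals = set(np.unique(arr).tolist())
        if not vals <= {"case", "control"}:
            raise ValueError(
                f"labels must be boolean or 'case'/'control' (got {sorted(vals)})"
            )
        mask = arr == "case"
    if mask.all() or not mask.any():
        raise DegenerateInputError("need at least one case and one control")
    return mask


# ---------------------------------------------------------------------------
# ROC / AUC / cutoffs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ROCCurve:
    """Empirical ROC over midpoint thresholds (original score scale).

    A point's sensitivity/specificity refer to calling a subject positive
    when the oriented score is at or above the oriented threshold (i.e.
    ``score >= t`` for higher-is-case, ``score <= t`` for lower-is-case).
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    orientation: Orientation
    n_cases: int
    n_controls: int

    @property
    def auc(self) -> float:
        """Trapezoidal area under the empirical curve."""
        fpr = 1.0 - self.specificity
        order = np.lexsort((self.sensitivity, fpr))  # fpr, then sens ascending
        return float(np.trapezoid(self.sensitivity[order], fpr[order]))


@dataclass(frozen=True)
class CutoffMetrics:
    cutoff: float
    sensitivity: float
    specificity: float
    ppv: float  # NaN flags an undefined value (zero denominator)
    npv: float
    youden: float = field(default=float("nan"))

    def as_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "youden": self.youden,
        }


def roc_curve(
    scores: Sequence[float],
    labels: Sequence,
    orientation: Orientation = "higher",
) -> ROCCurve:
    """Empirical ROC curve over all midpoint thresholds plus ±inf ends."""
    s = np.asarray(scores, dtype=float)
    if np.isnan(s).any():
        raise ValueError("scores contain missing values")
    case = _case_mask(labels)
    oriented = s if orientation == "higher" else -s
    distinct = np.unique(oriented)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thr = np.concatenate(([-np.inf], mids, [np.inf]))
    pos = oriented[case]
    neg = oriented[~case]
    sens = np.array([(pos >= t).mean() for t in thr])
    spec = np.array([(neg < t).mean() for t in thr])
    if orientation == "lower":
        thr = -thr
    return ROCCurve(
        thresholds=thr,
        sensitivity=sens,
        specificity=spec,
        orientation=orientation,
        n_cases=int(case.sum()),
        n_controls=int((~case).sum()),
    )


def auc(
    scores: Sequence[float],
    labels: Sequence,
    orientation: Orientation = "higher",
) -> float:
    """AUC as the Mann-Whitney concordance probability.

    P(random case outscores random control) + 0.5 * P(tie), computed with
    midranks; identical to trapezoidal integration of the empirical curve.
    """
    s = np.asarray(scores, dtype=float)
    case = _case_mask(labels)
    oriented = s if orientation == "higher" else -s
    ranks = stats.rankdata(oriented)  # midranks
    m = int(case.sum())
    n = int((~case).sum())
    rank_sum = ranks[case].sum()
    return float((rank_sum - m * (m + 1) / 2.0) / (m * n))


def _metrics_at(curve: ROCCurve, idx: int) -> CutoffMetrics:
    sens = float(curve.sensitivity[idx])
    spec = float(curve.specificity[idx])
    return cutoff_metrics(
        sens, spec, curve.n_cases, curve.n_controls,
        cutoff=float(curve.thresholds[idx]),
    )


def youden_optimal_cutoff(curve: ROCCurve) -> CutoffMetrics:
    """Cutoff maximising Youden's J = sensitivity + specificity − 1.

    Ties are broken toward higher sensitivity, then toward the more
    liberal threshold (lower on the oriented scale).
    """
    j = curve.sensitivity + curve.specificity - 1.0
    oriented_thr = (
        curve.thresholds if curve.orientation == "higher" else -curve.thresholds
    )
    # lexicographic: max J, then max sensitivity, then min oriented threshold
    best = None
    for i in range(len(j)):
        key = (j[i], curve.sensitivity[i], -oriented_thr[i])
        if best is None or key > best[0]:
            best = (key, i)
    return _metrics_at(curve, best[1])


def cutoff_metrics(
    sensitivity: float,
    specificity: float,
    n_cases: int,
    n_controls: int,
    cutoff: float = float("nan"),
) -> CutoffMetrics:
    """Confusion metrics implied by (sensitivity, specificity) at a design.

    TP = sens*n_cases, FN = n_cases − TP, TN = spec*n_controls,
    FP = n_controls − TN; PPV = TP/(TP+FP), NPV = TN/(TN+FN). A zero
    denominator yields NaN (flagged, not thrown).
    """
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    if n_cases < 1 or n_controls < 1:
        raise ValueError("group sizes must be >= 1")
    tp = sensitivity * n_cases
    fn = n_cases - tp
    tn = specificity * n_controls
    fp = n_controls - tn
    ppv = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    npv = tn / (tn + fn) if (tn + fn) > 0 else float("nan")
    return CutoffMetrics(
        cutoff=cutoff,
        sensitivity=sensitivity,
        specificity=specificity,
        ppv=ppv,
        npv=npv,
        youden=sensitivity + specificity - 1.0,
    )


# ---------------------------------------------------------------------------
# DeLong paired AUC comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AUCComparison:
    auc_a: float
    auc_b: float
    z: float
    p: float


def _structural_components(
    scores: np.ndarray, case: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus per-subject structural components V10 (cases), V01 (controls).

    V10[i] = P(score_i > random control) + 0.5 P(tie); analogously V01.
    Computed with midranks (Sun & Xu style), O(n log n).
    """
    pos = scores[case]
    neg = scores[~case]
    m, n = len(pos), len(neg)
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    a = float((all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n))
    return a, v10, v01


def delong_auc_variance(
    scores: Sequence[float],
    labels: Sequence,
    orientation: Orientation = "higher",
) -> tuple[float, float]:
    """(AUC, variance of the AUC) from the structural components."""
    s = np.asarray(scores, dtype=float)
    case = _case_mask(labels)
    oriented = s if orientation == "higher" else -s
    a, v10, v01 = _structural_components(oriented, case)
    m, n = len(v10), len(v01)
    if m < 2 or n < 2:
        raise DegenerateInputError("need >= 2 subjects per class")
    var = float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)
    return a, var


def delong_compare(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence,
    orientation_a: Orientation = "higher",
    orientation_b: Orientation = "higher",
) -> AUCComparison:
    """Paired comparison of two AUCs measured on the same subjects.

    Uses the structural-components covariance estimate of the paired AUC
    difference and a two-sided normal z test. Degenerate zero variance
    (e.g. comparing a score with itself) yields z = 0, p = 1.
    """
    a_arr = np.asarray(scores_a, dtype=float)
    b_arr = np.asarray(scores_b, dtype=float)
    if a_arr.shape != b_arr.shape:
        raise ValueError("paired score vectors must have equal length")
    case = _case_mask(labels)
    if case.sum() < 2 or (~case).sum() < 2:
        raise DegenerateInputError("need >= 2 subjects per class")
    sa = a_arr if orientation_a == "higher" else -a_arr
    sb = b_arr if orientation_b == "higher" else -b_arr
    auc_a, v10a, v01a = _structural_components(sa, case)
    auc_b, v10b, v01b = _structural_components(sb, case)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var_diff = (
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    )
    diff = auc_a - auc_b
    if var_diff <= 0:
        z = 0.0
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / math.sqrt(var_diff)
        p = 2.0 * stats.norm.sf(abs(z))
    return AUCComparison(auc_a=auc_a, auc_b=auc_b, z=float(z), p=float(p))


# ---------------------------------------------------------------------------
# Reliability and adjusted association
# ---------------------------------------------------------------------------


def cronbach_alpha(
    item_matrix: np.ndarray | pd.DataFrame, standardized: bool = False
) -> float:
    """Cronbach's alpha over a participants x items matrix.

    Raw alpha: k/(k-1) * (1 - sum(item variances) / variance of item sums).
    Standardized alpha uses the mean inter-item correlation instead.
    Zero total variance yields NaN.
    """
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2 or x.shape[0] < 3:
        raise ValueError("need >= 3 participants and >= 2 items")
    if np.isnan(x).any():
        raise ValueError("item matrix contains missing values")
    k = x.shape[1]
    if standardized:
        corr = np.corrcoef(x, rowvar=False)
        iu = np.triu_indices(k, 1)
        rbar = float(np.mean(corr[iu]))
        return k * rbar / (1.0 + (k - 1) * rbar)
    total_var = float(np.var(x.sum(axis=1), ddof=1))
    if total_var == 0:
        return float("nan")
    item_var = float(np.var(x, axis=0, ddof=1).sum())
    return k / (k - 1.0) * (1.0 - item_var / total_var)


def fluency_item_matrix(
    transcripts,
    taxonomy,
    items: Literal["time_bins", "index_scores"] = "time_bins",
    n_bins: int = 6,
    window: float = 60.0,
) -> np.ndarray:
    """Build the participants x items matrix for internal-consistency alpha.

    The default item set is the per-time-bin correct counts (6 bins over a
    60-s window): each transcript contributes one row of n_bins counts, so
    alpha measures the consistency of the production process across the
    trial. ``items="index_scores"`` instead uses the seven index scores as
    items. Time-bin items require timed transcripts.
    """
    from .scoring import CORRECT, compute_index_scores, label_responses

    rows = []
    if items == "time_bins":
        width = window / n_bins
        for tr in transcripts:
            if not tr.timed:
                raise ValueError("time-bin items require timed transcripts")
            labeled = label_responses(tr, taxonomy)
            counts = np.zeros(n_bins)
            for l in labeled:
                if l.label == CORRECT and l.response.onset <= window:
                    b = min(int(l.response.onset // width), n_bins - 1)
                    counts[b] += 1
            rows.append(counts)
    elif items == "index_scores":
        for tr in transcripts:
            sc = compute_index_scores(tr, taxonomy, window=window)
            rows.append([sc.total, sc.first_half, sc.second_half,
                         sc.perseveration, sc.intrusion, sc.clustering,
                         sc.switching])
    else:
        raise ValueError(f"unknown item set {items!r}")
    return np.asarray(rows, dtype=float)


def _residualize(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(y)), covariates])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate matrix is rank deficient (collinearity)")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def partial_pearson(
    x: Sequence[float],
    y: Sequence[float],
    covariates: np.ndarray | pd.DataFrame | None = None,
) -> tuple[float, float]:
    """Pearson correlation of x and y after linear covariate adjustment.

    Both variables are residualised on the covariates plus an intercept;
    the p value uses the t distribution with n − k − 2 degrees of freedom
    (k = number of covariates). With no covariates this reduces exactly to
    the plain Pearson correlation.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-d and the same length")
    n = len(xa)
    if covariates is None:
        cov = np.empty((n, 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    k = cov.shape[1]
    if n <= k + 2:
        raise ValueError("need n > number of covariates + 2")
    rx = _residualize(xa, cov)
    ry = _residualize(ya, cov)
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        return float("nan"), float("nan")
    r = float(rx @ ry) / denom
    r = max(-1.0, min(1.0, r))
    df = n - k - 2
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p)


@dataclass(frozen=True)
class AncovaResult:
    f: float
    p: float
    adjusted_means: dict[str, float]
    df_num: int
    df_den: int


def ancova_compare(
    values: Sequence[float],
    group: Sequence,
    covariates: np.ndarray | pd.DataFrame | None = None,
) -> AncovaResult:
    """F test of the group term in a linear model with covariates.

    Fits values ~ intercept + case_indicator + covariates by OLS and tests
    the single-df group coefficient (F = t² of that coefficient). Adjusted
    means are the model predictions for each group at the grand covariate
    means. With no covariates, F equals the square of the pooled two-sample
    t statistic.
    """
    import statsmodels.api as sm

    y = np.asarray(values, dtype=float)
    case = _case_mask(group)
    n = len(y)
    if covariates is None:
        cov = np.empty((n, 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    design = np.column_stack([np.ones(n), case.astype(float), cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design matrix is rank deficient (collinearity)")
    fit = sm.OLS(y, design).fit()
    t_group = float(fit.tvalues[1])
    f = t_group**2
    p = float(fit.pvalues[1])
    covmeans = cov.mean(axis=0) if cov.shape[1] else np.empty(0)
    base = float(fit.params[0] + (fit.params[2:] @ covmeans if cov.shape[1] else 0.0))
    adjusted = {"control": base, "case": base + float(fit.params[1])}
    return AncovaResult(
        f=f, p=p, adjusted_means=adjusted,
        df_num=1, df_den=int(fit.df_resid),
    )


def baseline_compare(
    frame: pd.DataFrame,
    group_col: str = "group",
    continuous: Sequence[str] = (),
    categorical: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-variable baseline group comparison table.

    Continuous variables get a two-sample pooled-variance Student's t test;
    categorical ones a Pearson chi-square test on the contingency table
    (no continuity correction). A chi-square expected cell below 1 sets the
    ``warning`` flag rather than raising.
    """
    case = _case_mask(frame[group_col])
    rows = []
    for var in continuous:
        a = frame.loc[case, var].astype(float)
        b = frame.loc[~case, var].astype(float)
        t, p = stats.ttest_ind(a, b, equal_var=True)
        rows.append(
            {
                "variable": var,
                "test": "t",
                "statistic": float(t),
                "p": float(p),
                "case_mean": float(a.mean()),
                "control_mean": float(b.mean()),
                "warning": "",
            }
        )
    for var in categorical:
        table = pd.crosstab(frame[group_col], frame[var])
        chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
        warn = "expected cell < 1" if (expected < 1).any() else ""
        rows.append(
            {
                "variable": var,
                "test": "chi2",
                "statistic": float(chi2),
                "p": float(p),
                "case_mean": float("nan"),
                "control_mean": float("nan"),
                "warning": warn,
            }
        )
    return pd.DataFrame(rows)


def test_retest(
    frame: pd.DataFrame,
    score: str,
    covariates: Sequence[str] = ("age", "education_years"),
) -> tuple[float, float, int]:
    """Covariate-adjusted correlation between two administrations.

    Correlates ``<score>_1`` with ``<score>_2`` via :func:`partial_pearson`
    after listwise exclusion of participants missing either administration;
    returns (r, p, n_used).
    """
    cols = [f"{score}_1", f"{score}_2", *covariates]
    sub = frame[cols].dropna()
    n = len(sub)
    if n < 3:
        raise ValueError(f"need >= 3 complete retest pairs (got {n})")
    cov = sub[list(covariates)].to_numpy() if covariates else None
    r, p = partial_pearson(
        sub[f"{score}_1"].to_numpy(), sub[f"{score}_2"].to_numpy(), cov
    )
    return r, p, n


test_retest.__test__ = False  # a statistic, not a pytest test


# ---------------------------------------------------------------------------
# Cohort container and full evaluation report
# ---------------------------------------------------------------------------


@dataclass
class ScoredCohort:
    """Two-group cohort table with demographics and per-instrument scores.

    Columns: id, group ('case'/'control'), age, education_years, sex, mmse,
    then score columns named ``<instrument>_<score>_<administration>``,
    e.g. ``tcvft_ws_1``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"id", "group", "age", "education_years", "sex"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"cohort table lacks columns {sorted(missing)}")
        if self.frame["id"].duplicated().any():
            raise ValueError("duplicate participant ids")
        groups = set(self.frame["group"].unique())
        if not groups <= {"case", "control"}:
            raise ValueError(f"group labels must be case/control (got {groups})")

    @property
    def n_cases(self) -> int:
        return int((self.frame["group"] == "case").sum())

    @property
    def n_controls(self) -> int:
        return int((self.frame["group"] == "control").sum())

    @classmethod
    def read_csv(cls, path) -> "ScoredCohort":
        return cls(pd.read_csv(path))

    def write_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _orientation_for(column: str) -> Orientation:
    for key, orient in DEFAULT_ORIENTATIONS.items():
        if column == key or f"_{key}_" in f"_{column}":
            return orient
    base = column.rsplit("_", 2)
    if len(base) == 3 and base[1] in DEFAULT_ORIENTATIONS:
        return DEFAULT_ORIENTATIONS[base[1]]
    return "higher"


def evaluate_cohort(
    cohort: ScoredCohort,
    score_columns: Sequence[str] | None = None,
    orientations: Mapping[str, Orientation] | None = None,
    adjust_for: Sequence[str] = ("age", "education_years"),
) -> dict:
    """Full validation report for a scored two-group cohort.

    For each discriminating score: AUC with a DeLong-variance Wald CI and
    the Youden-optimal cutoff row (cutoff, sensitivity, specificity, PPV,
    NPV). Then all pairwise DeLong comparisons, covariate-adjusted group
    comparisons (ANCOVA) per score, covariate-adjusted pairwise
    correlations, and test-retest reliability for any score with two
    administrations.
    """
    df = cohort.frame
    labels = df["group"].to_numpy()
    if score_columns is None:
        score_columns = [
            c
            for c in df.columns
            if c.endswith("_1")
            and df[c].dtype.kind in "fi"
            and not df[c].isna().any()
        ]
        if "mmse" in df.columns and not df["mmse"].isna().any():
            score_columns = list(score_columns) + ["mmse"]
    covariates = df[list(adjust_for)].to_numpy() if adjust_for else None

    report: dict = {"n_cases": cohort.n_cases, "n_controls": cohort.n_controls,
                    "scores": {}, "auc_comparisons": [],
                    "adjusted_correlations": [], "reliability": {}}
    orient = {c: _orientation_for(c) for c in score_columns}
    if orientations:
        orient.update(orientations)

    for col in score_columns:
        vals = df[col].to_numpy(dtype=float)
        curve = roc_curve(vals, labels, orient[col])
        a, var = delong_auc_variance(vals, labels, orient[col])
        se = math.sqrt(var)
        best = youden_optimal_cutoff(curve)
        anc = ancova_compare(vals, labels, covariates)
        report["scores"][col] = {
            "orientation": orient[col],
            "auc": a,
            "auc_ci95": [max(0.0, a - 1.959963984540054 * se),
                         min(1.0, a + 1.959963984540054 * se)],
            "optimal_cutoff": best.as_dict(),
            "adjusted_group_comparison": {
                "F": anc.f,
                "p": anc.p,
                "adjusted_means": anc.adjusted_means,
            },
        }

    for i, ca in enumerate(score_columns):
        for cb in score_columns[i + 1:]:
            comp = delong_compare(
                df[ca].to_numpy(dtype=float),
                df[cb].to_numpy(dtype=float),
                labels,
                orient[ca],
                orient[cb],
            )
            report["auc_comparisons"].append(
                {"score_a": ca, "score_b": cb, "auc_a": comp.auc_a,
                 "auc_b": comp.auc_b, "z": comp.z, "p": comp.p}
            )
            r, p = partial_pearson(
                df[ca].to_numpy(dtype=float),
                df[cb].to_numpy(dtype=float),
                covariates,
            )
            report["adjusted_correlations"].append(
                {"score_a": ca, "score_b": cb, "r": r, "p": p}
            )

    for col in score_columns:
        if col.endswith("_1") and f"{col[:-2]}_2" in df.columns:
            base = col[:-2]
            if df[f"{base}_2"].dropna().shape[0] >= 3:
                r, p, n = test_retest(df, base, tuple(adjust_for))
                report["reliability"][base] = {"r": r, "p": p, "n": n}
    return report
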