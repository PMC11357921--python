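"""Group comparison and discrimination statistics for lesion cohorts.

Implements the statistical pipeline used to evaluate diffusion
parameters as markers of lesion grade and variant histology:

* normality-gated two-group tests (Shapiro-Wilk at 0.05 on each group;
  Student's t if both pass, Mann-Whitney U otherwise), with summaries
  formatted to match the gate (mean +/- sd vs median (IQR));
* empirical ROC analysis with the AUC computed by trapezoid (identical
  to the tie-corrected Mann-Whitney U / (n1*n2)), a DeLong-variance 95%
  CI, and the operating point maximising the Youden index
  J = sensitivity + specificity - 1;
* the paired DeLong test for comparing correlated AUCs via placement
  values;
* univariate/multivariate logistic regression to combine parameters
  (univariate Wald p < 0.05 admits a feature), the combined marker being
  the fitted linear predictor;
* :func:`run_study_analysis`, orchestrating all of the above per
  contrast over a cohort table.

Youden ties are broken toward higher sensitivity; candidate thresholds
sit midway between adjacent distinct scores (plus open extremes), so the
reported cutoff never coincides with an observed value.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "GroupComparison",
    "RocResult",
    "DelongResult",
    "LogisticResult",
    "compare_groups",
    "auc_mann_whitney",
    "roc_analysis",
    "delong_compare",
    "logistic_combine",
    "run_study_analysis",
    "report_to_tables",
]


# ---------------------------------------------------------------------------
# two-group comparison


@dataclass(frozen=True)
class GroupComparison:
    """Outcome of the normality-gated two-group test."""

    test: str  # "t-test" | "mann-whitney"
    p_value: float
    normal: bool
    summary_neg: str
    summary_pos: str
    n_neg: int
    n_pos: int


def _summaries(x: np.ndarray, normal: bool) -> str:
    if normal:
        return f"{np.mean(x):.3f} ± {np.std(x, ddof=1):.3f}"
    q1, q3 = np.percentile(x, [25, 75])
    return f"{np.median(x):.3f} ({q3 - q1:.3f})"


def compare_groups(values, labels, test: str = "auto") -> GroupComparison:
    """Shapiro-Wilk-gated Student's t or Mann-Whitney U between two groups.

    `labels` is binary; both groups need >= 3 observations.  With
    ``test="auto"`` both groups must pass Shapiro-Wilk at 0.05 for the
    t-test branch (equal-variance Student's t); otherwise the two-sided
    Mann-Whitney U is used.  ``test="t-test"`` / ``test="mann-whitney"``
    force a branch.
    """
    if test not in ("auto", "t-test", "mann-whitney"):
        raise ValueError(f"unknown test {test!r}")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(bool)
    g0, g1 = values[~labels], values[labels]
    if len(g0) < 3 or len(g1) < 3:
        raise ValueError("each group needs at least 3 observations")
    if test == "auto" and (np.ptp(g0) == 0 or np.ptp(g1) == 0):
        normal = False  # Shapiro-Wilk undefined on a constant group
    elif test == "auto":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            normal = (
                stats.shapiro(g0).pvalue > 0.05 and stats.shapiro(g1).pvalue > 0.05
            )
    else:
        normal = test == "t-test"
    if normal:
        res = stats.ttest_ind(g0, g1, equal_var=True)
        test = "t-test"
    else:
        res = stats.mannwhitneyu(g0, g1, alternative="two-sided")
        test = "mann-whitney"
    return GroupComparison(
        test=test,
        p_value=float(res.pvalue),
        normal=normal,
        summary_neg=_summaries(g0, normal),
        summary_pos=_summaries(g1, normal),
        n_neg=len(g0),
        n_pos=len(g1),
    )


# ---------------------------------------------------------------------------
# ROC / DeLong machinery


def _placements(pos: np.ndarray, neg: np.ndarray):
    """DeLong placement values: per-positive and per-negative P(pos > neg)."""
    # psi = 1 if pos > neg, 0.5 on ties, 0 otherwise
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    return cmp.mean(axis=1), cmp.mean(axis=0)  # V10 (m,), V01 (n,)


def auc_mann_whitney(scores, labels) -> float:
    """Tie-corrected Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    v10, _ = _placements(pos, neg)
    return float(v10.mean())


def _delong_variance(pos: np.ndarray, neg: np.ndarray):
    v10, v01 = _placements(pos, neg)
    auc = v10.mean()
    m, n = len(pos), len(neg)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, s10 / m + s01 / n, (v10, v01)


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC summary at the Youden-optimal operating point."""

    auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity: float  # percent
    specificity: float  # percent
    accuracy: float  # percent
    positive_high: bool
    n_pos: int
    n_neg: int

    @property
    def decision_rule(self) -> str:
        op = ">=" if self.positive_high else "<="
        return f"positive if value {op} {self.cutoff:.6g}"


def roc_analysis(scores, labels, positive_high: bool = True) -> RocResult:
    """Empirical ROC with DeLong CI and Youden-index operating point.

    `positive_high=False` states that *lower* scores indicate the
    positive class (the usual orientation for diffusion parameters, which
    fall with grade); the reported cutoff stays in the original units
    with the decision rule "value <= cutoff".
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if not (labels.any() and (~labels).any()):
        raise ValueError("both classes must be present")
    oriented = scores if positive_high else -scores
    pos, neg = oriented[labels], oriented[~labels]
    auc, var, _ = _delong_variance(pos, neg)
    se = np.sqrt(max(var, 0.0))
    ci_low = float(np.clip(auc - 1.959963984540054 * se, 0.0, 1.0))
    ci_high = float(np.clip(auc + 1.959963984540054 * se, 0.0, 1.0))

    # candidate thresholds midway between adjacent distinct oriented scores
    distinct = np.unique(oriented)
    mids = 0.5 * (distinct[:-1] + distinct[1:])
    candidates = np.concatenate([[distinct[0] - 1.0], mids, [distinct[-1] + 1.0]])
    pred = oriented[None, :] >= candidates[:, None]  # (n_thr, n)
    tp = (pred & labels[None, :]).sum(axis=1)
    tn = (~pred & ~labels[None, :]).sum(axis=1)
    sens = tp / labels.sum()
    spec = tn / (~labels).sum()
    j = sens + spec - 1.0
    best_j = j.max()
    tied = np.nonzero(j >= best_j - 1e-12)[0]
    best = tied[np.argmax(sens[tied])]
    acc = (tp[best] + tn[best]) / len(labels)
    cutoff = candidates[best] if positive_high else -candidates[best]
    return RocResult(
        auc=float(auc),
        ci_low=ci_low,
        ci_high=ci_high,
        cutoff=float(cutoff),
        sensitivity=float(100.0 * sens[best]),
        specificity=float(100.0 * spec[best]),
        accuracy=float(100.0 * acc),
        positive_high=positive_high,
        n_pos=int(labels.sum()),
        n_neg=int((~labels).sum()),
    )


@dataclass(frozen=True)
class DelongResult:
    """Paired DeLong comparison of two correlated AUCs."""

    auc_a: float
    auc_b: float
    auc_difference: float
    z: float
    p_value: float
    degenerate: bool = False


def delong_compare(scores_a, scores_b, labels) -> DelongResult:
    """Two-sided paired DeLong test for AUC(a) vs AUC(b) on the same lesions.

    Both score vectors must be oriented so that higher values indicate
    the positive class.  A degenerate comparison (zero variance of the
    AUC difference, e.g. b a monotone transform of a) is flagged with
    p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if a.shape != b.shape or a.shape != labels.shape:
        raise ValueError("scores_a, scores_b and labels must be equal-length")
    if not (labels.any() and (~labels).any()):
        raise ValueError("both classes must be present")
    pos_a, neg_a = a[labels], a[~labels]
    pos_b, neg_b = b[labels], b[~labels]
    auc_a, var_a, (v10_a, v01_a) = _delong_variance(pos_a, neg_a)
    auc_b, var_b, (v10_b, v01_b) = _delong_variance(pos_b, neg_b)
    m, n = labels.sum(), (~labels).sum()
    cov = 0.0
    if m > 1:
        cov += np.cov(v10_a, v10_b, ddof=1)[0, 1] / m
    if n > 1:
        cov += np.cov(v01_a, v01_b, ddof=1)[0, 1] / n
    var_diff = var_a + var_b - 2.0 * cov
    diff = auc_a - auc_b
    if var_diff <= 1e-16:
        return DelongResult(auc_a, auc_b, float(diff), 0.0, 1.0, degenerate=True)
    z = diff / np.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return DelongResult(float(auc_a), float(auc_b), float(diff), float(z), float(p))


# ---------------------------------------------------------------------------
# logistic combination


@dataclass
class LogisticResult:
    """Univariate screening + multivariate combination of features."""

    univariate_p: dict
    selected: list
    coefficients: dict  # multivariate, incl. intercept
    combined_score: np.ndarray
    converged: bool
    separation_flag: bool
    collinear_dropped: list


def _fit_logit(y: np.ndarray, X: np.ndarray):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, X)
        try:
            res = model.fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:
            res = model.fit(disp=0, maxiter=500, method="bfgs")
            converged = False
    return res, converged


def logistic_combine(features, labels, select_p: float = 0.05) -> LogisticResult:
    """Univariate screening then multivariate logistic combination.

    `features` is a DataFrame (or dict of vectors); each is screened by
    univariate logistic regression (Wald p on its coefficient).  Features
    with p < `select_p` enter the multivariate model; if none qualify,
    the single best feature is used so a combined score is always
    emitted.  The combined score is the multivariate linear predictor.
    Exactly collinear features are dropped (flagged) before the
    multivariate fit; perfect separation is flagged and the score comes
    from the final iterate.
    """
    feats = pd.DataFrame(features).astype(float)
    y = np.asarray(labels).astype(int)
    if len(feats) != len(y):
        raise ValueError("features and labels must be equal-length")
    if len(y) < 10:
        raise ValueError("need at least 10 lesions for logistic modelling")
    if feats.isna().any().any():
        raise ValueError("features contain missing values")

    uni_p = {}
    converged_all = True
    for name in feats.columns:
        x = feats[name].to_numpy()
        if np.ptp(x) == 0:  # constant feature carries no information
            uni_p[name] = 1.0
            continue
        X = np.column_stack([np.ones(len(y)), x])
        res, conv = _fit_logit(y, X)
        p = float(res.pvalues[1])
        uni_p[name] = p if np.isfinite(p) else 1.0
        converged_all &= conv
    informative = [n for n in feats.columns if np.ptp(feats[n].to_numpy()) > 0]
    if not informative:
        raise ValueError("all features are constant")
    selected = [n for n in informative if uni_p[n] < select_p]
    if not selected:
        selected = [min(informative, key=lambda n: uni_p[n])]

    # drop exactly collinear columns (keep first occurrence order)
    kept, dropped = [], []
    for name in selected:
        trial = feats[kept + [name]].to_numpy()
        trial = np.column_stack([np.ones(len(y)), trial])
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            kept.append(name)
        else:
            dropped.append(name)

    X = np.column_stack([np.ones(len(y)), feats[kept].to_numpy()])
    res, conv = _fit_logit(y, X)
    params = np.asarray(res.params, dtype=float)
    score = X @ params
    separation = not conv or np.max(np.abs(params)) > 1e3
    coefs = {"intercept": float(params[0])}
    coefs.update({n: float(c) for n, c in zip(kept, params[1:])})
    return LogisticResult(
        univariate_p=uni_p,
        selected=kept,
        coefficients=coefs,
        combined_score=np.asarray(score, dtype=float),
        converged=conv and converged_all,
        separation_flag=bool(separation),
        collinear_dropped=dropped,
    )


# ---------------------------------------------------------------------------
# study orchestration

PARAMETERS = ("adc", "d", "alpha", "beta")
CTRW_FEATURES = ("d", "alpha", "beta")

CONTRAST_LABELS = {
    "grade": ("grade", "high"),
    "variant": ("variant", "VH"),
}


def run_study_analysis(cohort: pd.DataFrame, contrasts=("grade", "variant")) -> dict:
    """Per-contrast group comparison + ROC for each parameter and the
    logistic CTRW combination, with a paired DeLong test of the combined
    marker against ADC.

    The cohort table must carry the label columns and the averaged
    reader values in columns 'adc', 'd', 'alpha', 'beta'.  Diffusion
    parameters enter ROC analysis with the clinical orientation (lower
    value = positive class); the combined logistic score is oriented
    positively by construction.  Returns a JSON-serialisable dict.
    """
    report = {}
    for contrast in contrasts:
        if contrast not in CONTRAST_LABELS:
            raise ValueError(f"unknown contrast {contrast!r}")
        column, positive_value = CONTRAST_LABELS[contrast]
        if column not in cohort.columns:
            raise ValueError(f"cohort lacks label column {column!r}")
        missing = [p for p in PARAMETERS if p not in cohort.columns]
        if missing:
            raise ValueError(f"cohort lacks parameter columns {missing}")
        labels = (cohort[column] == positive_value).to_numpy()
        entry = {"positive_class": positive_value, "n_pos": int(labels.sum()),
                 "n_neg": int((~labels).sum()), "parameters": {}}
        for param in PARAMETERS:
            values = cohort[param].to_numpy(dtype=float)
            comparison = compare_groups(values, labels)
            roc = roc_analysis(values, labels, positive_high=False)
            entry["parameters"][param] = {
                "comparison": asdict(comparison),
                "roc": asdict(roc),
            }
        combo = logistic_combine(cohort[list(CTRW_FEATURES)], labels)
        combo_roc = roc_analysis(combo.combined_score, labels, positive_high=True)
        adc_oriented = -cohort["adc"].to_numpy(dtype=float)
        delong = delong_compare(combo.combined_score, adc_oriented, labels)
        entry["combined"] = {
            "features": combo.selected,
            "univariate_p": combo.univariate_p,
            "coefficients": combo.coefficients,
            "separation_flag": combo.separation_flag,
            "collinear_dropped": combo.collinear_dropped,
            "roc": asdict(combo_roc),
            "delong_vs_adc": asdict(delong),
        }
        report[contrast] = entry
    return report


def report_to_tables(report: dict):
    """Flatten a study report into comparison and performance DataFrames."""
    comp_rows, perf_rows = [], []
    for contrast, entry in report.items():
        for param, block in entry["parameters"].items():
            c = block["comparison"]
            r = block["roc"]
            comp_rows.append(
                {
                    "contrast": contrast,
                    "parameter": param,
                    "negative_group": c["summary_neg"],
                    "positive_group": c["summary_pos"],
                    "test": c["test"],
                    "p_value": c["p_value"],
                }
            )
            perf_rows.append(
                {
                    "contrast": contrast,
                    "marker": param,
                    "auc": r["auc"],
                    "ci_low": r["ci_low"],
                    "ci_high": r["ci_high"],
                    "cutoff": r["cutoff"],
                    "sensitivity_pct": round(r["sensitivity"], 2),
                    "specificity_pct": round(r["specificity"], 2),
                    "accuracy_pct": round(r["accuracy"], 2),
                }
            )
        r = entry["combined"]["roc"]
        perf_rows.append(
            {
                "contrast": contrast,
                "marker": "+".join(entry["combined"]["features"]),
                "auc": r["auc"],
                "ci_low": r["ci_low"],
                "ci_high": r["ci_high"],
                "cutoff": r["cutoff"],
                "sensitivity_pct": round(r["sensitivity"], 2),
                "specificity_pct": round(r["specificity"], 2),
                "accuracy_pct": round(r["accuracy"], 2),
            }
        )
    return pd.DataFrame(comp_rows), pd.DataFrame(perf_rows)


def save_report(report: dict, path) -> None:
    """Write the study report as JSON (numpy scalars coerced)."""

    def _coerce(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        raise TypeError(f"not JSON-serialisable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_coerce)
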