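"""Diagnostic comparison of the dynamic models.

Per-parameter univariate analysis (Mann-Whitney group comparison, ROC
curve with the closest-to-(0,1) operating point, Benjamini-Hochberg
adjustment), per-model multivariable logistic models selected by
bidirectional stepwise AIC, pairwise one-sided DeLong superiority tests
between the model AUCs, and the Spearman correlation matrix of all
extracted parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ROCResult",
    "roc_analysis",
    "delong_components",
    "delong_test",
    "StepwiseResult",
    "stepwise_glm",
    "bh_adjust",
    "group_compare",
    "correlation_matrix",
    "ComparisonReport",
    "run_full_comparison",
]


def _check_labels(labels) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    return y


@dataclass(frozen=True)
class ROCResult:
    """Univariate ROC analysis of one parameter.

    ``direction`` records the orientation chosen so that AUC >= 0.5:
    'greater' means larger scores indicate the positive class.
    Sensitivity/specificity/accuracy are percentages at the cutoff
    closest to the (0, 1) corner (ties resolved toward higher
    sensitivity); the confidence interval is the DeLong-variance normal
    interval.
    """

    auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float
    direction: str


def _placements(scores: np.ndarray, y: np.ndarray):
    """DeLong placement values V10 (positives) and V01 (negatives)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    cmp = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (pos[:, None] == neg[None, :])
    return cmp.mean(axis=1), cmp.mean(axis=0)


def delong_components(scores, labels):
    """AUC and DeLong placement values for one score vector."""
    y = _check_labels(labels)
    scores = np.asarray(scores, dtype=float)
    v10, v01 = _placements(scores, y)
    return float(v10.mean()), v10, v01


def delong_variance(scores, labels) -> float:
    """DeLong variance estimate of a single empirical AUC."""
    _, v10, v01 = delong_components(scores, labels)
    m, n = v10.size, v01.size
    return float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)


def roc_analysis(scores, labels) -> ROCResult:
    """Empirical ROC analysis with the closest-to-(0,1) optimal cutoff.

    The AUC equals the all-pairs Mann-Whitney probability (ties counted
    half); the orientation is flipped when the raw AUC is below 0.5 and
    recorded in the result.
    """
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=float)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")

    auc_raw, _, _ = delong_components(s, y)
    direction = "greater" if auc_raw >= 0.5 else "less"
    oriented = s if direction == "greater" else -s

    auc, v10, v01 = delong_components(oriented, y)
    var = np.var(v10, ddof=1) / v10.size + np.var(v01, ddof=1) / v01.size if min(v10.size, v01.size) > 1 else np.nan
    half = 1.959963984540054 * np.sqrt(var) if np.isfinite(var) else np.nan
    ci = (max(0.0, auc - half), min(1.0, auc + half)) if np.isfinite(half) else (np.nan, np.nan)

    # candidate thresholds: midpoints between consecutive distinct scores,
    # plus sentinels classifying everything / nothing as positive
    u = np.unique(oriented)
    thresholds = np.concatenate([[u[0] - 1.0], 0.5 * (u[1:] + u[:-1]), [u[-1] + 1.0]])
    pos = oriented[y == 1]
    neg = oriented[y == 0]
    tpr = (pos[None, :] > thresholds[:, None]).mean(axis=1)
    fpr = (neg[None, :] > thresholds[:, None]).mean(axis=1)
    dist = np.hypot(fpr, 1.0 - tpr)
    best = np.flatnonzero(np.isclose(dist, dist.min()))
    best = best[np.argmax(tpr[best])]  # ties -> higher sensitivity
    cutoff = thresholds[best] if direction == "greater" else -thresholds[best]
    sens = 100.0 * tpr[best]
    spec = 100.0 * (1.0 - fpr[best])
    accuracy = 100.0 * ((pos > thresholds[best]).sum() + (neg <= thresholds[best]).sum()) / y.size
    return ROCResult(auc, ci[0], ci[1], float(cutoff), float(sens), float(spec), float(accuracy), direction)


def delong_test(scores_a, scores_b, labels, alternative: str = "greater") -> float:
    """One-sided paired DeLong test; default alternative AUC_A > AUC_B.

    Scores must be paired on the same subjects.  Returns the p-value; a
    zero-variance difference (e.g. identical scores) yields p = 0.5.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired score vectors must have equal length")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    y = _check_labels(labels)
    auc_a, v10_a, v01_a = delong_components(a, y)
    auc_b, v10_b, v01_b = delong_components(b, y)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        z = 0.0 if diff == 0 else np.sign(diff) * np.inf
    else:
        z = diff / np.sqrt(var)
    if alternative == "less":
        z = -z
    return float(sps.norm.sf(z))


@dataclass
class StepwiseResult:
    """Selected multivariable logistic model and its in-sample scores."""

    selected: list
    aic: float
    fitted_scores: np.ndarray
    coefficients: dict = field(default_factory=dict)
    history: list = field(default_factory=list)


_RIDGE = 1e-4  # fixed fallback penalty under perfect separation
_COEF_LIMIT = 50.0


def _fit_logit(X: pd.DataFrame, y: np.ndarray, columns) -> tuple[float, np.ndarray, dict]:
    """Binomial GLM fit for a column subset; AIC = -2 llf + 2 k.

    Perfect separation (diverging coefficients or failed convergence)
    falls back to a small fixed ridge penalty so the stepwise search
    stays deterministic; the AIC is then computed from the unpenalised
    log-likelihood at the penalised coefficients.
    """
    design = sm.add_constant(X[list(columns)], has_constant="add")
    model = sm.GLM(y, design, family=sm.families.Binomial())
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(maxiter=200)
        ok = np.all(np.isfinite(res.params)) and np.max(np.abs(res.params.to_numpy())) < _COEF_LIMIT
    except Exception:
        ok = False
    if not ok:
        res = model.fit_regularized(alpha=_RIDGE, L1_wt=0.0, maxiter=500)
    params = np.asarray(res.params, dtype=float)
    llf = float(model.loglike(params))
    aic = -2.0 * llf + 2.0 * params.size
    scores = np.asarray(model.predict(params), dtype=float)
    coef = dict(zip(design.columns, params))
    return aic, scores, coef


def stepwise_glm(predictors: pd.DataFrame, labels) -> StepwiseResult:
    """Bidirectional stepwise AIC selection of a binomial GLM.

    Starts from the intercept-only model; at each step the single add or
    drop move that most reduces the AIC is applied, stopping when no
    move reduces it.  Candidate fits that fail are skipped.
    """
    y = _check_labels(labels)
    X = pd.DataFrame(predictors)
    if len(X) != y.size:
        raise ValueError("predictor table and labels must have equal length")
    if y.size <= X.shape[1]:
        raise ValueError("need more subjects than candidate predictors")

    current: list = []
    aic, scores, coef = _fit_logit(X, y, current)
    history = [(tuple(current), aic)]
    while True:
        moves = []
        for col in X.columns:
            trial = current + [col] if col not in current else [c for c in current if c != col]
            try:
                trial_aic, trial_scores, trial_coef = _fit_logit(X, y, trial)
            except Exception:
                continue
            moves.append((trial_aic, trial, trial_scores, trial_coef))
        if not moves:
            break
        moves.sort(key=lambda m: (m[0], len(m[1])))
        best_aic, best_cols, best_scores, best_coef = moves[0]
        if best_aic < aic - 1e-10:
            current, aic, scores, coef = list(best_cols), best_aic, best_scores, best_coef
            history.append((tuple(current), aic))
        else:
            break
    return StepwiseResult(selected=current, aic=aic, fitted_scores=scores, coefficients=coef, history=history)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def group_compare(values, labels, kind: str = "mann_whitney") -> float:
    """Two-sided group comparison p-value.

    ``mann_whitney``: exact when the pooled sample is small (n <= 20) and
    tie-free, normal approximation otherwise.  ``chi_squared``: 2 x c
    contingency chi-squared for categorical values.
    """
    y = _check_labels(labels)
    values = np.asarray(values)
    g0, g1 = values[y == 0], values[y == 1]
    if g0.size == 0 or g1.size == 0:
        raise ValueError("both groups must be non-empty")
    if kind == "mann_whitney":
        has_ties = np.unique(values.astype(float)).size < values.size
        method = "exact" if (values.size <= 20 and not has_ties) else "asymptotic"
        return float(sps.mannwhitneyu(g1, g0, alternative="two-sided", method=method).pvalue)
    if kind == "chi_squared":
        table = pd.crosstab(y, values)
        return float(sps.chi2_contingency(table.to_numpy(), correction=False).pvalue)
    raise ValueError(f"unknown comparison kind {kind!r}")


def correlation_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rank correlations of all parameter columns.

    Constant columns have undefined rank correlation and are reported as
    missing values.
    """
    df = pd.DataFrame(table)
    if len(df) < 3:
        raise ValueError("need at least 3 subjects")
    if df.isna().any().any():
        raise ValueError("parameter table contains missing values")
    with np.errstate(invalid="ignore"):
        corr = df.corr(method="spearman")
    constant = df.nunique() <= 1
    corr.loc[constant, :] = np.nan
    corr.loc[:, constant] = np.nan
    return corr


# parameter -> dynamic-model grouping of the univariate analysis
MODEL_PARAMS = {
    "SQ": ["ttp", "slope"],
    "SQ Fit": ["a1", "a2", "p", "q", "A", "B"],
    "Ref SQ": ["ttp_ratio", "slope_ratio"],
    "Logan": ["ved", "int_logan"],
    "Ref Logan": ["dvr", "rrt"],
    "2TCM": ["K1", "k2", "k3", "k4", "Ki", "Vb"],
}


@dataclass
class ComparisonReport:
    """Structured output of the full multi-model comparison."""

    univariate: pd.DataFrame  # per-parameter MW p, BH-adjusted p, ROC stats
    model_aucs: pd.DataFrame  # per-model stepwise AUC + CI + selected params
    delong_p: pd.DataFrame  # one-sided superiority p-values, row beats column
    delong_p_adjusted: pd.DataFrame
    spearman: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "univariate": self.univariate.to_dict(orient="index"),
            "model_aucs": self.model_aucs.to_dict(orient="index"),
            "delong_p": self.delong_p.to_dict(orient="index"),
            "delong_p_adjusted": self.delong_p_adjusted.to_dict(orient="index"),
            "spearman": self.spearman.to_dict(orient="index"),
        }


def run_full_comparison(
    parameters: pd.DataFrame,
    labels,
    model_params: dict | None = None,
) -> ComparisonReport:
    """Univariate + multivariable comparison of the six dynamic models.

    ``parameters`` holds one row per subject and one column per extracted
    parameter; ``labels`` is the binary IDH status (1 = mutant).
    """
    model_params = model_params or MODEL_PARAMS
    y = _check_labels(labels)
    missing = [p for cols in model_params.values() for p in cols if p not in parameters.columns]
    if missing:
        raise ValueError(f"parameter table is missing columns: {missing}")

    rows = {}
    for model, cols in model_params.items():
        for p in cols:
            roc = roc_analysis(parameters[p].to_numpy(), y)
            rows[p] = {
                "model": model,
                "p_value": group_compare(parameters[p].to_numpy(), y),
                "auc": roc.auc,
                "auc_ci_low": roc.ci_low,
                "auc_ci_high": roc.ci_high,
                "cutoff": roc.cutoff,
                "sensitivity_pct": roc.sensitivity,
                "specificity_pct": roc.specificity,
                "accuracy_pct": roc.accuracy,
                "direction": roc.direction,
            }
    univariate = pd.DataFrame(rows).T
    univariate["p_value_bh"] = bh_adjust(univariate["p_value"].to_numpy(dtype=float))

    model_rows = {}
    model_scores = {}
    for model, cols in model_params.items():
        sel = stepwise_glm(parameters[cols], y)
        scores = sel.fitted_scores
        if len(sel.selected) == 0:
            # intercept-only: constant scores, AUC degenerates to 0.5
            model_rows[model] = {
                "auc": 0.5, "auc_ci_low": np.nan, "auc_ci_high": np.nan,
                "selected": "", "aic": sel.aic,
            }
        else:
            roc = roc_analysis(scores, y)
            model_rows[model] = {
                "auc": roc.auc, "auc_ci_low": roc.ci_low, "auc_ci_high": roc.ci_high,
                "selected": ";".join(sel.selected), "aic": sel.aic,
            }
        model_scores[model] = scores
    model_aucs = pd.DataFrame(model_rows).T

    names = list(model_params)
    pmat = pd.DataFrame(np.nan, index=names, columns=names)
    for a in names:
        for b in names:
            if a == b:
                continue
            pmat.loc[a, b] = delong_test(model_scores[a], model_scores[b], y, alternative="greater")
    off = ~np.eye(len(names), dtype=bool)
    adj = pmat.copy()
    adj.values[off] = bh_adjust(pmat.values[off])

    spearman = correlation_matrix(parameters[[p for cols in model_params.values() for p in cols]])
    return ComparisonReport(univariate, model_aucs, pmat, adj, spearman)
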