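"""Statistical evaluation of the risk models on a case/control cohort.

ROC/AUC with a DeLong confidence interval for continuous scores; a
threshold-sweep AUC for the categorical combined classifier (a joint
threshold applied to both the clinical and genetic 5-year scores, with
carriers always elevated); two-sample t tests; covariate-adjusted logistic
association; odds ratio and predictive values from a 2x2 table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionTable",
    "RocResult",
    "roc_auc",
    "combined_risk_auc",
    "group_compare_ttest",
    "adjusted_association",
    "odds_ratio",
    "ppv_npv",
]


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 table of combined-risk category against case/control status."""

    elevated_cases: int
    average_cases: int
    elevated_controls: int
    average_controls: int

    def __post_init__(self) -> None:
        for v in (self.elevated_cases, self.average_cases,
                  self.elevated_controls, self.average_controls):
            if v < 0:
                raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class RocResult:
    auc: float
    points: np.ndarray  # (n, 2) columns FPR, TPR, sorted by FPR
    ci95: Optional[tuple[float, float]] = None


def _validate_labels(labels: np.ndarray) -> None:
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError("need at least one case and one control")


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_ci(scores: np.ndarray, labels: np.ndarray, auc: float) -> tuple[float, float]:
    """DeLong variance of the empirical AUC; 95% Wald interval clipped to [0,1]."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    # structural components (Sun & Xu 2014 fast DeLong)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    return (max(0.0, auc - half), min(1.0, auc + half))


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """Empirical ROC and AUC (ties count half) with a DeLong 95% CI.

    ``labels`` are 1 for cases, 0 for controls.  The AUC equals the
    Mann-Whitney concordance probability.
    """
    from sklearn.metrics import roc_curve

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _validate_labels(labels)
    fpr, tpr, _ = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(auc=auc, points=np.column_stack([fpr, tpr]),
                     ci95=_delong_ci(scores, labels, auc))


def combined_risk_auc(
    clinical: Sequence[float],
    genetic: Sequence[float],
    carrier: Sequence[bool],
    labels: Sequence[int],
) -> RocResult:
    """Threshold-sweep AUC of the categorical combined classifier.

    Candidate thresholds are the midpoints between consecutive distinct
    values of the pooled clinical and genetic scores, plus -inf/+inf
    sentinels.  At each threshold ``t`` a subject is elevated iff
    ``clinical >= t`` or ``genetic >= t`` or carrier; the
    sensitivity/specificity pairs, anchored at (0,0) and (1,1), are
    integrated by the trapezoidal rule.
    """
    clin = np.asarray(clinical, dtype=float)
    gen = np.asarray(genetic, dtype=float)
    car = np.asarray(carrier, dtype=bool)
    labels = np.asarray(labels, dtype=int)
    if not (len(clin) == len(gen) == len(car) == len(labels)):
        raise ValueError("input vectors must be aligned")
    _validate_labels(labels)

    pooled = np.unique(np.concatenate([clin, gen]))
    thresholds = np.concatenate(
        [[-np.inf], (pooled[:-1] + pooled[1:]) / 2.0, [np.inf]]
    )
    n_case = int(labels.sum())
    n_ctrl = int(len(labels) - n_case)
    pts = {(0.0, 0.0), (1.0, 1.0)}
    for t in thresholds:
        elevated = (clin >= t) | (gen >= t) | car
        sens = float(np.sum(elevated & (labels == 1))) / n_case
        fpr = float(np.sum(elevated & (labels == 0))) / n_ctrl
        pts.add((fpr, sens))
    points = np.array(sorted(pts))
    auc = float(np.trapezoid(points[:, 1], points[:, 0]))
    return RocResult(auc=auc, points=points)


def group_compare_ttest(
    scores: Sequence[float], labels: Sequence[int], equal_var: bool = True
) -> dict:
    """Two-sample t test of a score between cases and controls.

    Pooled-variance by default (``equal_var=False`` gives Welch).  Returns
    the statistic, two-sided p and per-group summaries.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    if len(cases) < 2 or len(controls) < 2:
        raise ValueError("need at least 2 subjects per group")
    if np.var(cases) == 0 and np.var(controls) == 0 and cases.mean() == controls.mean():
        return {
            "t": 0.0, "p": 1.0,
            "case_mean": float(cases.mean()), "case_sd": 0.0, "n_cases": len(cases),
            "control_mean": float(controls.mean()), "control_sd": 0.0,
            "n_controls": len(controls),
        }
    t, p = stats.ttest_ind(cases, controls, equal_var=equal_var)
    return {
        "t": float(t),
        "p": float(p),
        "case_mean": float(cases.mean()),
        "case_sd": float(cases.std(ddof=1)),
        "n_cases": int(len(cases)),
        "control_mean": float(controls.mean()),
        "control_sd": float(controls.std(ddof=1)),
        "n_controls": int(len(controls)),
    }


def adjusted_association(
    outcome: Sequence[int],
    exposure: Sequence[float],
    age: Sequence[float],
    ethnicity: Sequence[int],
) -> dict:
    """Logistic regression of case status on a score, controlling for age
    and an ethnicity indicator.  Returns the exposure log-odds estimate,
    its SE and the two-sided Wald p-value.

    Constant covariates are dropped with a warning; perfect separation
    raises.
    """
    import statsmodels.api as sm

    y = np.asarray(outcome, dtype=float)
    cols = {"exposure": np.asarray(exposure, dtype=float)}
    for name, v in (("age", np.asarray(age, dtype=float)),
                    ("ethnicity", np.asarray(ethnicity, dtype=float))):
        if np.ptp(v) == 0:
            warnings.warn(f"covariate {name} is constant; dropped", stacklevel=2)
        else:
            cols[name] = v
    X = sm.add_constant(np.column_stack(list(cols.values())), has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
            fit = sm.Logit(y, X).fit(disp=0)
    except (sm.tools.sm_exceptions.PerfectSeparationError,
            sm.tools.sm_exceptions.PerfectSeparationWarning) as exc:
        raise ValueError("perfect separation in logistic fit") from exc
    return {
        "log_odds": float(fit.params[1]),
        "se": float(fit.bse[1]),
        "wald_p": float(fit.pvalues[1]),
        "covariates_used": list(cols.keys())[1:],
    }


def odds_ratio(table: ConfusionTable) -> dict:
    """Association between combined-risk category and case status.

    Headline estimate is the Wald cross-product ``(a*d)/(b*c)`` with a
    log-scale 95% CI (0.5 continuity correction on a zero cell, flagged);
    a conditional-MLE (median-unbiased-style) estimate is reported as a
    secondary output.
    """
    a = table.elevated_cases
    b = table.average_cases
    c = table.elevated_controls
    d = table.average_controls
    corrected = 0 in (a, b, c, d)
    aa, bb, cc, dd = (v + 0.5 if corrected else v for v in (a, b, c, d))
    wald = (aa * dd) / (bb * cc)
    se_log = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    z = 1.959963984540054
    ci = (float(np.exp(np.log(wald) - z * se_log)), float(np.exp(np.log(wald) + z * se_log)))
    res = stats.contingency.odds_ratio([[a, b], [c, d]], kind="conditional")
    return {
        "or_wald": float(wald),
        "ci95": ci,
        "or_conditional_mle": float(res.statistic),
        "continuity_corrected": corrected,
    }


def ppv_npv(table: ConfusionTable) -> tuple[float, float]:
    """Positive and negative predictive value of the elevated call, in
    percent rounded to 2 decimals."""
    denom_ppv = table.elevated_cases + table.elevated_controls
    denom_npv = table.average_controls + table.average_cases
    if denom_ppv == 0 or denom_npv == 0:
        raise ZeroDivisionError("degenerate margins: PPV/NPV undefined")
    ppv = 100.0 * table.elevated_cases / denom_ppv
    npv = 100.0 * table.average_controls / denom_npv
    return round(ppv, 2), round(npv, 2)
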