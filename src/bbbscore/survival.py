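"""Outcome analytics: median split, Kaplan-Meier, log-rank, Cox, ROC.

Survival inputs are right-censored (time in days, event 1 = death observed,
0 = censored).  Conventions: median-split ties go to the "high" group; Cox
models use the Efron tie correction with Wald confidence intervals and
p-values; the time-dependent ROC uses the cumulative-case / dynamic-control
definition with Kaplan-Meier-based weighting and a horizon defaulting to the
cohort's median observed survival time.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

logger = logging.getLogger(__name__)


@dataclass
class KMCurve:
    """Product-limit survival estimate: event-time grid, S(t), at-risk counts."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value of S at time t (right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CoxFit:
    """Per-covariate coefficients, hazard ratios, Wald CIs and p-values."""

    table: pd.DataFrame  # term, coef, se, hr, ci_low, ci_high, p_value
    log_likelihood: float

    def coef(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "coef"])

    def se(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "se"])


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


def _check_survival(time, event) -> tuple[np.ndarray, np.ndarray]:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.shape != event.shape:
        raise ValueError("time and event must have identical shape")
    if not np.isfinite(time).all() or (time <= 0).any():
        raise ValueError("survival times must be finite and positive")
    if not np.isin(event, [0, 1]).all():
        raise ValueError("event indicator must be 0 or 1")
    return time, event.astype(int)


def dichotomize_median(scores) -> np.ndarray:
    """Split a score vector at its median into "low"/"high" labels.

    Values >= median are "high" (ties go high, keeping the rule
    deterministic); a constant vector cannot be split and is an error.
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) < 2:
        raise ValueError("need at least two samples to dichotomize")
    if np.ptp(scores) == 0:
        raise ValueError("all scores identical; median split is degenerate")
    med = np.median(scores)
    return np.where(scores >= med, "high", "low")


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimate.

    Censored-only times reduce the risk set without a step.  A cohort with
    no events yields a constant curve at 1 with a warning rather than an
    error (it is a valid, if uninformative, estimate).
    """
    time, event = _check_survival(time, event)
    if event.sum() == 0:
        logger.warning("no events observed; survival curve is constant 1")
    kmf = KaplanMeierFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kmf.fit(time, event)
    # drop the t=0 anchor row; keep observed time grid
    sf = kmf.survival_function_.iloc[1:]
    ev = kmf.event_table.iloc[1:]
    return KMCurve(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
        at_risk=ev["at_risk"].to_numpy(dtype=int),
    )


def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    time, event = _check_survival(time, event)
    group = np.asarray(group)
    levels = pd.unique(group)
    if len(levels) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {len(levels)}")
    a = group == levels[0]
    res = _ll_logrank(time[a], time[~a], event[a], event[~a])
    return float(res.test_statistic), float(res.p_value)


def cox_fit(
    time, event, covariates: pd.DataFrame, ties: str = "efron"
) -> CoxFit:
    """Cox proportional-hazards fit (Efron ties, Wald inference).

    ``covariates`` is a samples-by-terms numeric DataFrame; constant
    covariates and non-convergence (including separation) are errors.
    Supports univariate and multivariate use.
    """
    time, event = _check_survival(time, event)
    if ties != "efron":
        raise ValueError("only the Efron tie correction is supported")
    cov = covariates.astype(float)
    if len(cov) != len(time):
        raise ValueError("covariate rows must match number of subjects")
    if len(cov) <= cov.shape[1]:
        raise ValueError("need more subjects than covariates")
    const = [c for c in cov.columns if cov[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant covariate(s): {const!r}")
    df = cov.copy()
    df["_time"] = time
    df["_event"] = event
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                df,
                duration_col="_time",
                event_col="_event",
                fit_options={"precision": 1e-12, "max_steps": 500},
            )
    except ConvergenceError as exc:
        raise RuntimeError(f"Cox model failed to converge: {exc}") from exc
    s = cph.summary
    table = pd.DataFrame(
        {
            "term": s.index,
            "coef": s["coef"].to_numpy(),
            "se": s["se(coef)"].to_numpy(),
            "hr": np.exp(s["coef"].to_numpy()),
            "ci_low": np.exp(s["coef"].to_numpy() - 1.96 * s["se(coef)"].to_numpy()),
            "ci_high": np.exp(s["coef"].to_numpy() + 1.96 * s["se(coef)"].to_numpy()),
            "p_value": s["p"].to_numpy(),
        }
    ).reset_index(drop=True)
    return CoxFit(table, float(cph.log_likelihood_))


def median_survival_time(time, event) -> float:
    """Median observed follow-up time (default time-dependent ROC horizon)."""
    time, _ = _check_survival(time, event)
    return float(np.median(time))


def td_roc(marker, time, event, t_star: float) -> ROCResult:
    """Cumulative-case / dynamic-control time-dependent ROC at horizon t*.

    Cases are subjects with an event by t*, controls those surviving past
    t*; censoring is handled by Kaplan-Meier estimates within marker strata:
    for each threshold c,

        sens(c) = [1 - S_{M>c}(t*)] * P(M>c) / [1 - S(t*)]
        spec(c) = 1 - S_{M>c}(t*) * P(M>c) / S(t*)

    with S the overall and S_{M>c} the conditional Kaplan-Meier survival.
    AUC is the trapezoid over the resulting curve.  With no censoring before
    t* this reduces exactly to the Mann-Whitney AUC of the binary
    event-by-t* outcome.
    """
    marker = np.asarray(marker, dtype=float)
    time, event = _check_survival(time, event)
    if marker.shape != time.shape:
        raise ValueError("marker and survival vectors must align")
    overall = km_estimate(time, event)
    s_all = overall.survival_at(t_star)
    if s_all >= 1.0:
        raise ValueError("no events by the requested horizon")
    if s_all <= 0.0:
        raise ValueError("no survivors past the requested horizon")
    n = len(marker)
    thresholds = np.concatenate(([-np.inf], np.unique(marker)))
    sens = np.empty_like(thresholds)
    spec = np.empty_like(thresholds)
    for i, c in enumerate(thresholds):
        above = marker > c
        p_above = above.mean()
        if p_above == 0:
            s_cond = 1.0
        else:
            s_cond = km_estimate(time[above], event[above]).survival_at(t_star)
        sens[i] = (1.0 - s_cond) * p_above / (1.0 - s_all)
        spec[i] = 1.0 - s_cond * p_above / s_all
    fpr = 1.0 - spec
    # descending thresholds trace the ROC path from (0,0) to (1,1); the
    # nested risk sets make it monotone up to floating-point dust and the
    # known mild non-monotonicity of the conditional-KM estimator, both
    # cleaned up by a cumulative maximum before the trapezoid
    path_fpr = np.maximum.accumulate(np.clip(fpr[::-1], 0.0, 1.0))
    path_sens = np.maximum.accumulate(np.clip(sens[::-1], 0.0, 1.0))
    area = float(np.trapezoid(path_sens, path_fpr))
    return ROCResult(thresholds, sens, spec, area)


def roc_auc(marker, labels) -> ROCResult:
    """Classical ROC of a continuous marker against binary labels.

    AUC equals the Mann-Whitney U statistic scaled to [0, 1], with tied
    marker values contributing 1/2.
    """
    marker = np.asarray(marker, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {len(classes)}")
    y = (labels == classes[1]).astype(int)
    fpr, tpr, thr = _sk_roc_curve(y, marker)
    return ROCResult(thr, tpr, 1.0 - fpr, float(_sk_auc(fpr, tpr)))
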