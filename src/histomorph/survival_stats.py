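"""Survival analysis: Kaplan-Meier / log-rank, multivariable Cox models,
Cox-derived risk scores with median/tertile stratification, Fisher exact and
McNemar tests.

Recurrence-free survival (RFS) semantics: time from diagnosis to recurrence
or death, whichever occurs first, censored at last follow-up.  All tests are
two-sided.  Cox models use Efron tie handling (lifelines).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps

__all__ = [
    "KMCurve",
    "km_curve",
    "km_logrank",
    "cox_multivariable",
    "RiskModel",
    "cox_risk_scores",
    "stratify",
    "fisher_exact_2x2",
    "mcnemar",
    "COX_REFERENCE_LEVELS",
]


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit estimate for one group."""

    event_times: np.ndarray     # observed event times (steps of the estimate)
    survival: np.ndarray        # S(t) at each event time
    at_risk: np.ndarray         # number at risk just before each event time
    group: str = ""

    def median(self) -> float:
        """Smallest event time with S(t) <= 0.5 (NaN if never reached)."""
        below = self.survival <= 0.5
        return float(self.event_times[below][0]) if below.any() else np.nan


def km_curve(times, events, group: str = "") -> KMCurve:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    ev_times = np.unique(times[events])
    surv = kmf.survival_function_at_times(ev_times).to_numpy()
    at_risk = np.array([(times >= t).sum() for t in ev_times], dtype=float)
    return KMCurve(event_times=ev_times, survival=surv, at_risk=at_risk, group=group)


def km_logrank(times, events, groups) -> tuple[dict[str, KMCurve], float, float]:
    """KM curves per group plus the standard log-rank chi-square and p-value
    (df = number of groups - 1)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("log-rank needs at least 2 groups")
    curves = {}
    for lab in labels:
        sel = groups == lab
        if not sel.any():
            raise ValueError(f"empty group {lab!r}")
        curves[str(lab)] = km_curve(times[sel], events[sel], group=str(lab))
    if events.sum() == 0:
        return curves, 0.0, 1.0
    res = multivariate_logrank_test(times, groups, events)
    return curves, float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Multivariable Cox
# ---------------------------------------------------------------------------

#: default reference levels for the standard covariate set
COX_REFERENCE_LEVELS = {
    "gender": "F",
    "t_stage": "T1",
    "n_stage": "N0",
    "classifier_call": False,   # predicted non-recurrence
}


def cox_multivariable(
    table: pd.DataFrame,
    times,
    events,
    covariates: dict[str, object] | None = None,
) -> pd.DataFrame:
    """Multivariable Cox proportional-hazards fit (Efron ties).

    ``covariates`` maps column name -> reference level; each covariate is
    dummy-coded as an indicator of not-the-reference.  Constant covariates
    are dropped with a warning.  Returns a DataFrame indexed by covariate
    with columns hr, ci_low, ci_high, p, coef.
    """
    covariates = covariates or COX_REFERENCE_LEVELS
    df = pd.DataFrame({
        "time": np.asarray(times, dtype=float),
        "event": np.asarray(events, dtype=bool).astype(int),
    })
    kept = []
    for col, ref in covariates.items():
        ind = (table[col].to_numpy() != ref).astype(float)
        if ind.min() == ind.max():
            warnings.warn(f"covariate {col} is constant: dropped")
            continue
        df[col] = ind
        kept.append(col)
    if not kept:
        raise ValueError("no usable covariates")
    if df["event"].sum() < len(kept):
        raise ValueError("fewer events than covariates")

    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    if cph.params_.abs().max() > 10:
        warnings.warn("possible separation: |coef| > 10")
    summary = cph.summary
    return pd.DataFrame({
        "hr": np.exp(summary["coef"]),
        "ci_low": np.exp(summary["coef lower 95%"]),
        "ci_high": np.exp(summary["coef upper 95%"]),
        "p": summary["p"],
        "coef": summary["coef"],
    })


# ---------------------------------------------------------------------------
# Cox risk scores and stratification
# ---------------------------------------------------------------------------

@dataclass
class RiskModel:
    """Cox coefficients over the selected features plus per-patient linear
    predictors and the cutpoints used for 2- and 3-group stratification."""

    features: list[str]
    coefs: np.ndarray
    feature_means: np.ndarray
    feature_scales: np.ndarray
    scores: np.ndarray
    median: float
    tertiles: tuple[float, float]
    groups2: np.ndarray = field(default_factory=lambda: np.array([]))
    groups3: np.ndarray = field(default_factory=lambda: np.array([]))
    degenerate: bool = False

    def score(self, table: pd.DataFrame) -> np.ndarray:
        X = table[self.features].to_numpy(dtype=float)
        return ((X - self.feature_means) / self.feature_scales) @ self.coefs


def stratify(scores: np.ndarray, cutpoints) -> np.ndarray:
    """Group index per score: group g iff cutpoints[g-1] < score <= cutpoints[g]."""
    return np.searchsorted(np.asarray(cutpoints, dtype=float), scores, side="left")


def cox_risk_scores(
    table: pd.DataFrame,
    features: list[str],
    times,
    events,
    penalizer: float = 0.0,
) -> RiskModel:
    """Fit a Cox model on standardised selected features; the risk score of a
    patient is the linear predictor (weighted feature sum).  Median and
    tertile (1/3 and 2/3 sample quantile) cutpoints are computed on this
    dataset, per the per-cohort cutpoint convention.
    """
    n = len(table)
    if n < 3:
        raise ValueError("need at least 3 patients for tertile stratification")
    X = table[features].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in selected feature columns")
    means = X.mean(axis=0)
    raw_scales = X.std(ddof=0, axis=0)
    scales = np.where(raw_scales == 0, 1.0, raw_scales)
    Xs = (X - means) / scales

    usable = [f for f, s in zip(features, raw_scales) if s > 0]
    coefs = np.zeros(len(features))
    if usable:
        df = pd.DataFrame(Xs[:, [features.index(f) for f in usable]], columns=usable)
        df["time"] = np.asarray(times, dtype=float)
        df["event"] = np.asarray(events, dtype=bool).astype(int)
        cph = CoxPHFitter(penalizer=penalizer)
        cph.fit(df, duration_col="time", event_col="event")
        for f in usable:
            coefs[features.index(f)] = cph.params_[f]
    else:
        warnings.warn("all selected features constant: Cox coefficients are 0")

    scores = Xs @ coefs
    degenerate = bool(np.ptp(scores) == 0)
    if degenerate:
        warnings.warn("all risk scores identical: stratification is degenerate")
    median = float(np.median(scores))
    q1, q2 = np.quantile(scores, [1.0 / 3.0, 2.0 / 3.0])
    groups2 = (scores > median).astype(int)
    groups3 = stratify(scores, (q1, q2))
    return RiskModel(
        features=list(features),
        coefs=coefs,
        feature_means=means,
        feature_scales=scales,
        scores=scores,
        median=median,
        tertiles=(float(q1), float(q2)),
        groups2=groups2,
        groups3=groups3,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Exact tests
# ---------------------------------------------------------------------------

def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]]: the sum of the
    probabilities of all tables with the observed margins whose probability
    does not exceed the observed table's."""
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("counts must be nonnegative integers")
    if min(a + b, c + d, a + c, b + d) == 0:
        warnings.warn("zero margin: Fisher p = 1 by convention")
        return 1.0
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def mcnemar(calls_a, calls_b, truth) -> float:
    """Exact two-sided McNemar test of two paired classifiers.

    Discordant pairs: b = (A correct, B wrong), c = (A wrong, B correct);
    p = two-sided exact binomial on min(b, c) of b + c fair-coin trials.
    b = c = 0 yields p = 1.
    """
    a_ok = np.asarray(calls_a).astype(bool) == np.asarray(truth).astype(bool)
    b_ok = np.asarray(calls_b).astype(bool) == np.asarray(truth).astype(bool)
    if len(a_ok) != len(b_ok):
        raise ValueError("paired call vectors must have equal length")
    b = int((a_ok & ~b_ok).sum())
    c = int((~a_ok & b_ok).sum())
    if b + c == 0:
        return 1.0
    return float(sps.binomtest(min(b, c), b + c, 0.5, alternative="two-sided").pvalue)
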