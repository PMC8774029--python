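"""Kaplan–Meier estimation, log-rank tests, and Cox proportional-hazards fits.

Reporting conventions: survival is summarised as the 5-year (60-month)
estimate ± Greenwood standard error; Cox models report the hazard ratio
with a 95% Wald confidence interval and a two-sided p-value; ties are
handled by Efron's method (the lifelines default).  Time is in months
throughout.  No multiplicity correction is applied to log-rank p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "Endpoint",
    "SurvivalEstimate",
    "CoxResult",
    "CoxTerm",
    "km_estimate",
    "logrank_test",
    "cox_fit",
]

FIVE_YEARS = 60.0


class Endpoint(str, Enum):
    OS = "OS"
    EFS = "EFS"


@dataclass
class SurvivalEstimate:
    """Product-limit curve with its 5-year summary."""

    timeline: np.ndarray
    survival: np.ndarray
    se: np.ndarray
    rate_5y: float
    se_5y: float
    n: int

    def at(self, t: float) -> float:
        """Step-function value at time t (last value carried forward)."""
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        return float(self.survival[max(idx, 0)])


@dataclass(frozen=True)
class CoxTerm:
    name: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class CoxResult:
    terms: list[CoxTerm]
    n: int
    n_events: int
    endpoint: Endpoint = Endpoint.OS
    converged: bool = True

    def term(self, name: str) -> CoxTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


def km_estimate(times, events, horizon: float = FIVE_YEARS
                ) -> SurvivalEstimate:
    """Kaplan–Meier product-limit estimate with Greenwood standard errors.

    The summary rate is the step value at ``horizon`` months (last value
    carried forward when no event falls on the horizon).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival input")
    if times.shape != events.shape:
        raise ValueError("times and events differ in length")
    if (times < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"].to_numpy()
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    # Greenwood: Var S(t) = S(t)^2 * sum_{t_i<=t} d_i / (n_i (n_i - d_i)).
    d = table["observed"].to_numpy(dtype=float)
    n = table["at_risk"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = np.where((n > d) & (n > 0), d / (n * (n - d)), 0.0)
    cum = np.cumsum(inc)
    se = surv * np.sqrt(cum)
    est = SurvivalEstimate(timeline=timeline, survival=surv, se=se,
                           rate_5y=0.0, se_5y=0.0, n=int(times.size))
    idx = np.searchsorted(timeline, horizon, side="right") - 1
    idx = max(idx, 0)
    est.rate_5y = float(surv[idx])
    est.se_5y = float(se[idx])
    return est


def logrank_test(groups) -> float:
    """Two-sided log-rank p-value comparing two or more groups.

    ``groups`` is a sequence of ``(times, events)`` pairs, each non-empty.
    """
    if len(groups) < 2:
        raise ValueError("log-rank needs at least two groups")
    times, events, labels = [], [], []
    for i, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=int)
        if t.size == 0:
            raise ValueError(f"group {i} has zero subjects")
        times.append(t)
        events.append(e)
        labels.append(np.full(t.size, i))
    res = multivariate_logrank_test(np.concatenate(times),
                                    np.concatenate(labels),
                                    np.concatenate(events))
    return float(res.p_value)


def cox_fit(features: pd.DataFrame, times, events,
            term_names: list[str] | None = None,
            endpoint: Endpoint | str = Endpoint.OS) -> CoxResult:
    """Cox proportional-hazards fit (Efron ties, 95% Wald intervals).

    ``features`` holds binary or numeric covariates, one column per term;
    rows with any missing covariate or endpoint are dropped (complete
    case).  A covariate that is constant after filtering is degenerate and
    raises a ``ValueError`` naming the term; non-convergence returns a
    result flagged ``converged=False`` rather than raising.
    """
    endpoint = Endpoint(endpoint)
    features = pd.DataFrame(features).copy()
    if term_names is None:
        term_names = list(features.columns)
    features = features[term_names]
    df = features.astype(float)
    df["_time"] = np.asarray(times, dtype=float)
    df["_event"] = np.asarray(events, dtype=float)
    df = df.dropna()
    if df.empty:
        raise ValueError("no complete cases for Cox fit")
    for name in term_names:
        if df[name].nunique() < 2:
            raise ValueError(f"degenerate covariate {name!r}: "
                             "constant after complete-case filtering")
    dup = df[term_names].T.duplicated()
    if dup.any():
        dupes = [n for n, flag in zip(term_names, dup) if flag]
        raise ValueError(f"collinear covariate(s) duplicating another "
                         f"term: {dupes}")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="_time", event_col="_event")
    except ConvergenceError:
        return CoxResult(terms=[], n=len(df),
                         n_events=int(df["_event"].sum()),
                         endpoint=endpoint, converged=False)
    summary = cph.summary
    terms = [CoxTerm(name=str(ix),
                     hazard_ratio=float(row["exp(coef)"]),
                     ci_low=float(row["exp(coef) lower 95%"]),
                     ci_high=float(row["exp(coef) upper 95%"]),
                     p_value=float(row["p"]))
             for ix, row in summary.iterrows()]
    return CoxResult(terms=terms, n=len(df),
                     n_events=int(df["_event"].sum()), endpoint=endpoint)
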