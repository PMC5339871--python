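"""Survival contrast of radiogenomic subgroups.

Kaplan-Meier product-limit estimation, the two-group log-rank test and
univariate Cox proportional-hazards regression (Efron tie handling), backed
by lifelines.  Survival data travel as a DataFrame indexed by sample id with
columns ``time`` (months, > 0), ``event`` (1 = death/progression, 0 =
censored) and optionally ``group``.

Group summaries report both the censoring-naive mean +/- SD of the observed
times (a common reporting style, labelled as such because censored times
bias it) and the proper Kaplan-Meier median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "KaplanMeierEstimate",
    "CoxFit",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "summarize_groups",
]


def _check(data: pd.DataFrame) -> pd.DataFrame:
    if not {"time", "event"}.issubset(data.columns):
        raise ValueError("survival data needs 'time' and 'event' columns")
    t = data["time"].to_numpy(dtype=float)
    e = data["event"].to_numpy()
    if np.any(~np.isfinite(t)) or np.any(t <= 0):
        raise ValueError("survival times must be positive and finite")
    if not set(np.unique(e)).issubset({0, 1}):
        raise ValueError("event flags must be binary (0 = censored, 1 = event)")
    return data


@dataclass(frozen=True)
class KaplanMeierEstimate:
    """Product-limit step function and its median."""

    table: pd.DataFrame  # time, at_risk, events, survival (distinct event times)
    median: float | None  # earliest t with S(t) <= 0.5; None if never reached

    def survival_at(self, t: float) -> float:
        past = self.table[self.table["time"] <= t]
        return 1.0 if past.empty else float(past["survival"].iloc[-1])


def km_estimate(data: pd.DataFrame) -> KaplanMeierEstimate:
    """Kaplan-Meier estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i).

    With no censoring this equals the empirical survival function.  The
    median is the earliest time at which S drops to 0.5 or below, reported
    as ``None`` when the curve never reaches 0.5 (heavy censoring).
    """
    data = _check(data)
    if data["event"].sum() < 1:
        warnings.warn("all observations censored: survival curve stays at 1", stacklevel=2)
    kmf = KaplanMeierFitter()
    kmf.fit(data["time"], event_observed=data["event"])
    ev = kmf.event_table
    event_rows = ev[ev["observed"] > 0]
    surv = kmf.survival_function_["KM_estimate"]
    table = pd.DataFrame(
        {
            "time": event_rows.index.to_numpy(dtype=float),
            "at_risk": ev.loc[event_rows.index, "at_risk"].to_numpy(dtype=int),
            "events": event_rows["observed"].to_numpy(dtype=int),
            "survival": surv.loc[event_rows.index].to_numpy(dtype=float),
        }
    ).reset_index(drop=True)
    med = kmf.median_survival_time_
    median = None if np.isinf(med) else float(med)
    return KaplanMeierEstimate(table=table, median=median)


def logrank_test(data: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p).

    The statistic compares observed versus hypergeometric-expected events in
    one group at each distinct event time, with 1 degree of freedom.
    """
    data = _check(data)
    if "group" not in data.columns:
        raise ValueError("log-rank test needs a 'group' column")
    groups = data["group"].unique()
    if len(groups) != 2:
        raise ValueError(f"log-rank comparison needs exactly 2 groups, got {len(groups)}")
    if data["event"].sum() < 1:
        raise ValueError("log-rank test needs at least one event")
    a = data[data["group"] == groups[0]]
    b = data[data["group"] == groups[1]]
    res = _ll_logrank(a["time"], b["time"], event_observed_A=a["event"], event_observed_B=b["event"])
    return float(res.test_statistic), float(res.p_value)


@dataclass(frozen=True)
class CoxFit:
    """Univariate Cox proportional-hazards fit summary."""

    log_hr: float
    se: float
    p: float
    converged: bool

    @property
    def hr(self) -> float:
        return float(np.exp(self.log_hr))

    def confidence_interval(self, z: float = 1.959963984540054) -> tuple[float, float]:
        """HR confidence interval (default 95%)."""
        return (
            float(np.exp(self.log_hr - z * self.se)),
            float(np.exp(self.log_hr + z * self.se)),
        )


def cox_fit(data: pd.DataFrame, covariate) -> CoxFit:
    """Cox partial-likelihood fit of one covariate (Efron tie handling).

    Monotone likelihoods (perfect separation) are reported with
    ``converged=False`` and a lightly ridge-stabilised finite estimate
    instead of a diverging one.
    """
    data = _check(data)
    if isinstance(covariate, pd.Series):
        x = covariate.reindex(data.index).astype(float)
        if x.isna().any():
            raise ValueError("covariate missing for some samples")
    else:
        x = pd.Series(np.asarray(covariate, dtype=float), index=data.index)
    if x.nunique() < 2:
        raise ValueError("covariate is constant: hazard ratio undefined")
    if int(data["event"].sum()) < 2:
        raise ValueError("need >= 2 events for a Cox fit")
    frame = pd.DataFrame({"time": data["time"], "event": data["event"], "x": x})
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph = CoxPHFitter()
            cph.fit(frame, duration_col="time", event_col="event")
        except ConvergenceError:
            converged = False
            cph = CoxPHFitter(penalizer=0.1)
            cph.fit(frame, duration_col="time", event_col="event")
            warnings.warn(
                "monotone Cox partial likelihood (perfect separation); "
                "estimate ridge-stabilised and flagged non-converged",
                stacklevel=2,
            )
    for w in caught:
        if issubclass(w.category, ConvergenceWarning):
            converged = False
    if not converged and abs(float(cph.params_["x"])) > 10:
        # monotone likelihood: the MLE runs away; report a ridge-stabilised value
        cph = CoxPHFitter(penalizer=0.1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(frame, duration_col="time", event_col="event")
        warnings.warn(
            "diverging Cox estimate (likely perfect separation); "
            "ridge-stabilised value reported and flagged non-converged",
            stacklevel=2,
        )
    return CoxFit(
        log_hr=float(cph.params_["x"]),
        se=float(cph.standard_errors_["x"]),
        p=float(cph.summary.loc["x", "p"]),
        converged=converged,
    )


def summarize_groups(data: pd.DataFrame) -> pd.DataFrame:
    """Per-group n, censoring-naive mean/SD of observed times, and KM median.

    The mean/SD deliberately ignore censoring (a descriptive convention);
    ``km_median`` is the statistically proper location estimate.  Empty
    groups are excluded with a warning; singleton groups report SD as NaN.
    """
    data = _check(data)
    if "group" not in data.columns:
        raise ValueError("summaries need a 'group' column")
    rows = []
    for g, sub in data.groupby("group", sort=True):
        if sub.empty:
            warnings.warn(f"group {g!r} is empty; excluded", stacklevel=2)
            continue
        km = km_estimate(sub) if sub["event"].sum() >= 1 else None
        rows.append(
            {
                "group": g,
                "n": len(sub),
                "mean_time": float(sub["time"].mean()),
                "sd_time": float(sub["time"].std(ddof=1)) if len(sub) > 1 else np.nan,
                "km_median": km.median if km is not None and km.median is not None else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("group")
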