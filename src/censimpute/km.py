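"""Product-limit (Kaplan-Meier) estimation and the imputation curve set.

Three curves summarise how imputation changes the estimated survival
experience: the KM estimate of the initial censored data, the KM estimate
using the event records only ("omitting censored"), and the complete-data
KM estimate after the censored times have been replaced by their
posterior-predictive summaries (the Bayesian-augmented curve).  Records
censored exactly at an event time are counted as still at risk for that
event (events precede censorings at ties).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import SurvivalDataset
from .imputation import ImputationResult

__all__ = ["KMCurve", "km_estimate", "build_curve_set", "CurveSet"]


@dataclass
class KMCurve:
    """A product-limit step function."""

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("event times must be strictly increasing")
        s = self.survival
        if np.any(s < -1e-12) or np.any(s > 1 + 1e-12) or np.any(np.diff(s) > 1e-12):
            raise ValueError("survival probabilities must be non-increasing in [0, 1]")

    def evaluate(self, t) -> np.ndarray:
        """Step-function value S(t); 1 before the first event."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        s = np.concatenate(([1.0], self.survival))
        return s[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "events": self.events,
            }
        )


def km_estimate(data: SurvivalDataset) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    S(t) = prod_{t_j <= t} (1 - d_j / n_j) over distinct event times t_j
    with d_j events and n_j at risk.
    """
    t = data.time
    e = data.event
    if e.sum() == 0:
        warnings.warn("all records are censored; KM curve is constant at 1")
        return KMCurve(np.empty(0), np.empty(0), np.empty(0, int), np.empty(0, int))
    order = np.lexsort((1 - e, t))  # time ascending, events before censorings
    t_sorted, e_sorted = t[order], e[order]
    n = len(data)
    event_times = np.unique(t_sorted[e_sorted == 1])
    at_risk = np.empty(event_times.size, dtype=int)
    d = np.empty(event_times.size, dtype=int)
    for j, tj in enumerate(event_times):
        at_risk[j] = int(np.sum(t >= tj))
        d[j] = int(np.sum((t == tj) & (e == 1)))
    surv = np.cumprod(1.0 - d / at_risk)
    return KMCurve(event_times, surv, at_risk, d)


@dataclass
class CurveSet:
    """The three comparison curves plus the per-censor draw band."""

    initial: KMCurve  # KM on the censored data
    omit_censored: KMCurve  # KM on event records only
    ba: KMCurve  # complete-data KM after imputation
    band: pd.DataFrame  # per censored record: c, draw quantiles, mean, median

    def curves(self) -> dict[str, KMCurve]:
        return {"initial": self.initial, "omit_censored": self.omit_censored, "ba": self.ba}


def build_curve_set(initial: SurvivalDataset, imputed: ImputationResult) -> CurveSet:
    """Construct the comparison curves from a dataset and its imputation.

    The Bayesian-augmented curve treats every imputed time as an exact
    event, so it is a complete-data product-limit curve reaching zero.
    """
    if imputed.original is not initial and not np.array_equal(
        imputed.original.time, initial.time
    ):
        raise ValueError("imputation result was not derived from this dataset")
    km_initial = km_estimate(initial)
    ev = initial.event == 1
    if ev.any():
        omit = SurvivalDataset(initial.time[ev], initial.event[ev],
                               None if initial.covariate is None else initial.covariate[ev])
        km_omit = km_estimate(omit)
    else:
        km_omit = km_estimate(initial)
    aug = imputed.augmented
    complete = SurvivalDataset(aug.time, np.ones(len(aug), dtype=int),
                               None if aug.covariate is None else aug.covariate)
    km_ba = km_estimate(complete)

    if imputed.draws.size:
        q = np.quantile(imputed.draws, [0.025, 0.25, 0.5, 0.75, 0.975], axis=1)
        band = pd.DataFrame(
            {
                "censor_time": initial.time[imputed.censored_indices],
                "q2.5": q[0],
                "q25": q[1],
                "q50": q[2],
                "q75": q[3],
                "q97.5": q[4],
                "mean": imputed.means,
                "median": imputed.medians,
            }
        )
    else:
        band = pd.DataFrame(
            columns=["censor_time", "q2.5", "q25", "q50", "q75", "q97.5", "mean", "median"]
        )
    return CurveSet(km_initial, km_omit, km_ba, band)
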