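"""Cox proportional-hazards models of post-imaging disease incidence.

Predictors are the covariate set plus kidney volume and the first k PC scores
of the S2S distances; left and right kidneys are modelled separately.  Ties
use the Efron approximation; 95% CIs are Wald, exp(beta +/- 1.96 SE);
significance across outcomes/kidneys/predictors is controlled with BH-FDR.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from .spm import bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "HazardEstimate",
    "fit_cox",
    "censor_and_assemble",
    "fdr_across_tests",
    "hazard_table",
]

DAYS_PER_YEAR = 365.25


@dataclass
class HazardEstimate:
    predictor: str
    hr: float
    ci_low: float
    ci_high: float
    p: float
    log_hr: float
    se: float
    p_fdr: float | None = None
    outcome: str | None = None
    kidney: str | None = None
    flagged: bool = False

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.hr <= self.ci_high):
            raise ValueError("CI must bracket the hazard ratio")

    def format(self) -> str:
        return f"HR: {self.hr:.2f}, 95% CI: {self.ci_low:.2f}–{self.ci_high:.2f}"


def fit_cox(
    records: pd.DataFrame,
    predictor_set: list[str],
    time_col: str = "time",
    event_col: str = "event",
    standardise_continuous: bool = True,
    outcome: str | None = None,
    kidney: str | None = None,
) -> list[HazardEstimate]:
    """Cox partial-likelihood fit (Efron ties) for the named predictors.

    Continuous predictors (more than two distinct values) are standardised to
    unit SD by default, so hazard ratios are per SD — matching the
    standardised units of the vertex-wise regression.  Separation or
    convergence trouble yields a flagged estimate rather than silence.
    """
    df = records[[time_col, event_col] + list(predictor_set)].copy()
    if df[event_col].sum() < 1:
        raise ValueError("need at least one event")
    if (df[time_col] <= 0).any():
        raise ValueError("times must be positive")
    for c in predictor_set:
        x = df[c].to_numpy(float)
        if np.ptp(x) == 0:
            raise ValueError(f"constant predictor {c!r}")
        if standardise_continuous and len(np.unique(x)) > 2:
            df[c] = (x - x.mean()) / x.std()
    cph = CoxPHFitter(baseline_estimation_method="breslow")
    flagged = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col=time_col, event_col=event_col)
    except ConvergenceError as err:
        raise RuntimeError(f"Cox model failed to converge: {err}") from err
    summary = cph.summary
    out = []
    for name in predictor_set:
        row = summary.loc[name]
        se = float(row["se(coef)"])
        if se > 100:  # near-separation: absurd SE
            flagged = True
            logger.warning("possible separation for predictor %s (SE=%.3g)", name, se)
        out.append(
            HazardEstimate(
                predictor=name,
                hr=float(np.exp(row["coef"])),
                ci_low=float(np.exp(row["coef"] - 1.96 * se)),
                ci_high=float(np.exp(row["coef"] + 1.96 * se)),
                p=float(row["p"]),
                log_hr=float(row["coef"]),
                se=se,
                outcome=outcome,
                kidney=kidney,
                flagged=flagged,
            )
        )
    return out


def censor_and_assemble(
    event_dates,
    baseline_dates,
    end_of_followup,
    death_dates=None,
    subject_ids=None,
) -> pd.DataFrame:
    """Build (time, event) pairs: time runs from baseline to the earliest of
    event, death, or administrative end of follow-up; the event indicator is 1
    only when the outcome itself comes first.

    Dates may be datetimes (converted to years via 365.25 days) or plain
    numbers in years.  Missing event/death dates mean "did not occur".
    """
    base = pd.Series(baseline_dates)
    ev = pd.Series(event_dates).reindex(base.index)
    death = pd.Series(death_dates).reindex(base.index) if death_dates is not None \
        else pd.Series(np.nan, index=base.index)
    end = pd.Series(end_of_followup) if np.ndim(end_of_followup) else \
        pd.Series(end_of_followup, index=base.index)

    def to_years(s: pd.Series) -> pd.Series:
        if pd.api.types.is_datetime64_any_dtype(s):
            origin = pd.Timestamp("2000-01-01")
            return (s - origin).dt.total_seconds() / (DAYS_PER_YEAR * 86400.0)
        return s.astype(float)

    base_y, ev_y, death_y, end_y = map(to_years, (base, ev, death, end))
    stop = pd.concat([ev_y, death_y, end_y], axis=1).min(axis=1)
    event = (ev_y.notna() & (ev_y <= death_y.fillna(np.inf)) & (ev_y <= end_y)).astype(int)
    time = stop - base_y
    if (time <= 0).any():
        raise ValueError(
            "non-positive follow-up time; prevalent cases (event before baseline) "
            "must be excluded upstream"
        )
    out = pd.DataFrame({"time": time, "event": event})
    if subject_ids is not None:
        out.insert(0, "subject_id", list(subject_ids))
    return out


def fdr_across_tests(estimates: list[HazardEstimate], alpha: float = 0.05) -> list[HazardEstimate]:
    """BH-FDR across the collected tests (all predictors x outcomes x kidneys
    in one run form the family); annotates ``p_fdr`` in place and returns the
    list."""
    if not estimates:
        return estimates
    adj = bh_fdr(np.array([e.p for e in estimates]))
    for e, q in zip(estimates, adj):
        e.p_fdr = float(q)
    return estimates


def hazard_table(estimates: list[HazardEstimate]) -> pd.DataFrame:
    """Tidy forest-plot-ready table of hazard estimates."""
    return pd.DataFrame(
        [
            {
                "outcome": e.outcome,
                "kidney": e.kidney,
                "predictor": e.predictor,
                "hr": e.hr,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "p": e.p,
                "p_fdr": e.p_fdr,
                "flagged": e.flagged,
            }
            for e in estimates
        ]
    )
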