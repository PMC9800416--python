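"""Relapse-free survival: Kaplan-Meier, log-rank, Cox, and the 6-month endpoint.

Times are in months.  Administrative censoring at a horizon H replaces
time with min(time, H) and keeps the event indicator only when the
original event time is <= H; an event at exactly the horizon counts as
within the horizon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

from ._errors import AnalysisError, DataValidationError
from .stats import chi_square_test

logger = logging.getLogger(__name__)

RFS6M_HORIZON = 6.0


def _check(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("time", "event"):
        if col not in df.columns:
            raise DataValidationError(f"survival table missing column {col!r}")
    if df.empty:
        raise DataValidationError("empty survival table")
    t = df["time"].to_numpy(dtype=float)
    if not np.isfinite(t).all() or (t <= 0).any():
        raise DataValidationError("survival times must be finite and > 0")
    out = df.copy()
    out["event"] = out["event"].astype(bool)
    return out


def censor_at(df: pd.DataFrame, horizon: float) -> pd.DataFrame:
    """Administrative censoring at ``horizon`` months (event at the horizon
    still counts)."""
    df = _check(df)
    out = df.copy()
    out["event"] = df["event"] & (df["time"].to_numpy(dtype=float) <= horizon)
    out["time"] = np.minimum(df["time"].to_numpy(dtype=float), horizon)
    return out


def km_curve(df: pd.DataFrame) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns a step-function table (time, survival, at_risk) starting at
    S(0) = 1; ``df`` needs columns time (> 0) and event (bool).
    """
    df = _check(df)
    kmf = KaplanMeierFitter()
    kmf.fit(df["time"], event_observed=df["event"])
    surv = kmf.survival_function_["KM_estimate"]
    at_risk = kmf.event_table["at_risk"].reindex(surv.index)
    at_risk = at_risk.ffill().fillna(len(df)).astype(int)
    out = pd.DataFrame(
        {"time": surv.index.to_numpy(dtype=float),
         "survival": surv.to_numpy(dtype=float),
         "at_risk": at_risk.to_numpy()}
    )
    if out.loc[0, "time"] != 0.0:
        out = pd.concat(
            [pd.DataFrame({"time": [0.0], "survival": [1.0], "at_risk": [len(df)]}),
             out],
            ignore_index=True,
        )
    return out


def log_rank(df1: pd.DataFrame, df2: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p)."""
    df1, df2 = _check(df1), _check(df2)
    if not (df1["event"].any() or df2["event"].any()):
        raise AnalysisError("log-rank undefined: no events in either group")
    res = logrank_test(df1["time"], df2["time"],
                       event_observed_A=df1["event"], event_observed_B=df2["event"])
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxResult:
    hazard_ratio: float
    ci95: tuple[float, float]
    p_value: float
    coef: float

    def summary(self) -> dict:
        return {
            "hazard_ratio": self.hazard_ratio,
            "ci95_low": self.ci95[0],
            "ci95_high": self.ci95[1],
            "p_value": self.p_value,
        }


def cox_univariate(df: pd.DataFrame, covariate: str) -> CoxResult:
    """Univariate Cox proportional-hazards fit on a binary covariate.

    Breslow tie handling; Wald 95% CI on the hazard ratio.  A covariate
    level with zero events makes the partial likelihood monotone and is
    reported as an error.
    """
    df = _check(df)
    if covariate not in df.columns:
        raise DataValidationError(f"covariate {covariate!r} missing")
    x = df[covariate].to_numpy()
    levels = np.unique(x)
    if levels.size != 2:
        raise DataValidationError(
            f"covariate {covariate!r} must be binary, has levels {levels.tolist()}"
        )
    for lev in levels:
        if not df.loc[x == lev, "event"].any():
            raise AnalysisError(
                f"no events in covariate level {lev!r}: monotone likelihood"
            )
    data = pd.DataFrame(
        {"time": df["time"].astype(float),
         "event": df["event"].astype(int),
         covariate: (x == levels[1]).astype(float) if x.dtype == object else
                    df[covariate].astype(float)}
    )
    cph = CoxPHFitter()
    cph.fit(data, duration_col="time", event_col="event")
    coef = float(cph.params_[covariate])
    lo, hi = cph.confidence_intervals_.loc[covariate]
    return CoxResult(
        hazard_ratio=float(np.exp(coef)),
        ci95=(float(np.exp(lo)), float(np.exp(hi))),
        p_value=float(cph.summary.loc[covariate, "p"]),
        coef=coef,
    )


@dataclass
class Rfs6mResult:
    censored: pd.DataFrame
    counts: pd.DataFrame       # early-relapse (yes/no) x group
    statistic: float
    p_value: float


def rfs6m(df: pd.DataFrame, group_col: str = "group",
          horizon: float = RFS6M_HORIZON) -> Rfs6mResult:
    """Six-month relapse-free-survival endpoint.

    Censors administratively at ``horizon`` (default 6 months; an event
    at exactly 6.0 counts as early relapse) and tests the early-relapse
    rate against the group label by chi-square.
    """
    df = _check(df)
    if group_col not in df.columns:
        raise DataValidationError(f"group column {group_col!r} missing")
    cens = censor_at(df, horizon)
    early = np.where(cens["event"], "yes", "no")
    counts = pd.crosstab(pd.Series(early, name="early_relapse"), cens[group_col])
    counts = counts.reindex(index=["yes", "no"], fill_value=0)
    try:
        stat, _, p = chi_square_test(counts.to_numpy())
    except (AnalysisError, DataValidationError):
        # single group, or all-yes/all-no: no association testable
        logger.warning("early-relapse table degenerate; chi-square skipped")
        stat, p = 0.0, float("nan")
    return Rfs6mResult(censored=cens, counts=counts, statistic=stat, p_value=p)
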