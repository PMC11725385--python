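"""Kaplan–Meier survival analysis for interval-monitored coral early life stages.

Individuals (larvae in well plates, settled juveniles) are checked at
scheduled monitoring visits; an individual absent at visit *t* but present
at the previous visit is scored dead at *t* (right endpoint of the
monitoring interval). The product-limit estimator and a two-group log-rank
test operate on the resulting right-censored event times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

__all__ = ["SurvivalRecord", "KMCurve", "km_estimator", "logrank_test"]


@dataclass(frozen=True)
class SurvivalRecord:
    """One monitored individual: event (death) or censoring time in days."""

    individual_id: str
    stage: str
    treatment: str
    family: str
    time: float
    event: int

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("time must be >= 0")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve.

    ``times`` are the distinct observed times (events and censorings),
    ``survival`` the KM estimate S(t) just after each time. ``median`` is
    the smallest time with S(t) <= 0.5, or NaN when survival never drops
    that far. ``ci_lower``/``ci_upper`` are 95% log-log (Greenwood)
    intervals, reported for information.
    """

    times: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray
    n_censored: np.ndarray
    survival: np.ndarray
    median: float
    ci_lower: np.ndarray = field(repr=False)
    ci_upper: np.ndarray = field(repr=False)

    @property
    def median_defined(self) -> bool:
        return np.isfinite(self.median)

    def survival_at(self, t: float) -> float:
        """S(t): step function, right-continuous."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.survival[idx])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "n_risk": self.n_risk,
                "n_event": self.n_event,
                "n_censored": self.n_censored,
                "survival": self.survival,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            }
        )


def records_to_frame(records: list[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "individual_id": [r.individual_id for r in records],
            "stage": [r.stage for r in records],
            "treatment": [r.treatment for r in records],
            "family": [r.family for r in records],
            "time_days": [r.time for r in records],
            "event": [r.event for r in records],
        }
    )


def km_estimator(records: list[SurvivalRecord]) -> KMCurve:
    """Fit the Kaplan–Meier product-limit estimator.

    S(t) = prod over event times t_i <= t of (1 - d_i / n_i); censored
    individuals leave the risk set after their censoring time. The median
    is the smallest observed time with S(t) <= 0.5 (NaN if never reached).
    """
    if not records:
        raise ValueError("no survival records")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events, alpha=0.05)
    tab = kmf.event_table.copy()
    tab = tab[tab.index > 0] if (tab.index[0] == 0 and tab.iloc[0].removed == 0) else tab
    t = tab.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[t, "KM_estimate"].to_numpy()
    ci = kmf.confidence_interval_
    lo = np.interp(t, ci.index.to_numpy(), ci.iloc[:, 0].to_numpy())
    hi = np.interp(t, ci.index.to_numpy(), ci.iloc[:, 1].to_numpy())
    median = float(kmf.median_survival_time_)
    if not np.isfinite(median):
        median = float("nan")
    return KMCurve(
        times=t,
        n_risk=tab["at_risk"].to_numpy(dtype=int),
        n_event=tab["observed"].to_numpy(dtype=int),
        n_censored=tab["censored"].to_numpy(dtype=int),
        survival=surv,
        median=median,
        ci_lower=lo,
        ci_upper=hi,
    )


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    p_value: float
    observed: np.ndarray = field(repr=False)  # group-1 events per event time
    expected: np.ndarray = field(repr=False)  # group-1 hypergeometric expectation
    variance: np.ndarray = field(repr=False)
    event_times: np.ndarray = field(repr=False)
    permutation_p: float | None = None


def logrank_test(
    records: list[SurvivalRecord],
    group_label: str = "treatment",
    n_perm: int | None = None,
    seed: int | None = None,
) -> LogrankResult:
    """Two-group log-rank test with hypergeometric variance.

    At each distinct event time t_j, the observed group-1 events O_j are
    compared with the expectation E_j = d_j * n_1j / n_j under the null of
    a common hazard; the chi-square statistic is
    (sum O - sum E)^2 / sum V with V_j the hypergeometric variance, tested
    on 1 df. Optionally a permutation p-value (group labels permuted,
    +1 convention) is computed alongside, reproducible under ``seed``.
    """
    df = records_to_frame(records)
    groups = sorted(df[group_label].unique())
    if len(groups) != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {groups}")
    g1 = (df[group_label] == groups[0]).to_numpy()
    time = df["time_days"].to_numpy(dtype=float)
    event = df["event"].to_numpy(dtype=int)
    if event.sum() == 0:
        raise ValueError("no events in either group")

    stat, obs, exp, var, etimes = _logrank_stat(time, event, g1, return_terms=True)
    p = float(stats.chi2.sf(stat, df=1))
    perm_p = None
    if n_perm:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(g1)
            s = _logrank_stat(time, event, perm)
            if s >= stat - 1e-12:
                count += 1
        perm_p = (count + 1) / (n_perm + 1)
    return LogrankResult(
        statistic=float(stat),
        p_value=p,
        observed=obs,
        expected=exp,
        variance=var,
        event_times=etimes,
        permutation_p=perm_p,
    )


def _logrank_stat(time, event, g1, return_terms: bool = False):
    etimes = np.unique(time[event == 1])
    obs = np.empty(len(etimes))
    exp = np.empty(len(etimes))
    var = np.empty(len(etimes))
    for j, t in enumerate(etimes):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        dying = (time == t) & (event == 1)
        d = dying.sum()
        d1 = (dying & g1).sum()
        obs[j] = d1
        exp[j] = d * n1 / n
        var[j] = (d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)) if n > 1 else 0.0
    v = var.sum()
    stat = (obs.sum() - exp.sum()) ** 2 / v if v > 0 else 0.0
    if return_terms:
        return stat, obs, exp, var, etimes
    return stat
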