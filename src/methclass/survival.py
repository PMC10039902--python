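"""Kaplan-Meier estimation and the log-rank comparison across groups.

The product-limit estimator is computed over distinct event times with
the standard tie convention: subjects censored at time t remain at risk
for the event at t.  Greenwood's formula gives the standard error, and
the 95% confidence interval uses the log transform
``exp(log S +/- z * se(log S))`` clipped to [0, 1].

The k-sample log-rank statistic is the quadratic form of observed-minus
-expected event counts against their hypergeometric covariance over the
pooled event times, with k - 1 degrees of freedom.  A comparison without
any events returns p = 1 with a warning flag rather than failing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

Z_95 = 1.959963984540054


def km_estimate(time, event) -> pd.DataFrame:
    """Kaplan-Meier step function of one group.

    Returns one row per distinct event time: ``time, n_risk, n_event,
    survival, se, ci_lower, ci_upper``.  S(0) = 1 and the function is
    right-continuous; with no events it stays 1 throughout.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(time) == 0:
        raise ValueError("at least one record is required")
    if (time <= 0).any():
        raise ValueError("survival times must be positive")
    event_times = np.unique(time[event == 1])
    rows = []
    survival = 1.0
    greenwood = 0.0  # running sum d / (n (n - d))
    for t in event_times:
        n_risk = int((time >= t).sum())
        n_event = int(((time == t) & (event == 1)).sum())
        survival *= 1.0 - n_event / n_risk
        se = np.nan
        ci_lower, ci_upper = (np.nan, np.nan)
        if n_risk > n_event:
            greenwood += n_event / (n_risk * (n_risk - n_event))
        if survival > 0:
            se = survival * np.sqrt(greenwood)
            half = Z_95 * np.sqrt(greenwood)
            ci_lower = float(np.clip(survival * np.exp(-half), 0.0, 1.0))
            ci_upper = float(np.clip(survival * np.exp(half), 0.0, 1.0))
        else:
            se, ci_lower, ci_upper = 0.0, 0.0, 0.0
        rows.append(
            {"time": t, "n_risk": n_risk, "n_event": n_event,
             "survival": survival, "se": se, "ci_lower": ci_lower, "ci_upper": ci_upper}
        )
    return pd.DataFrame(rows, columns=["time", "n_risk", "n_event", "survival", "se", "ci_lower", "ci_upper"])


def km_survival_at(km: pd.DataFrame, t: float) -> float:
    """S(t) from a km_estimate table (right-continuous step lookup)."""
    past = km[km["time"] <= t]
    return 1.0 if past.empty else float(past["survival"].iloc[-1])


def km_median(km: pd.DataFrame) -> float:
    """Median survival time: first event time with S(t) <= 0.5 (inf if never)."""
    below = km[km["survival"] <= 0.5]
    return float(below["time"].iloc[0]) if len(below) else np.inf


@dataclass
class LogrankResult:
    statistic: float
    df: int
    p: float
    no_events: bool = False


def logrank_test(groups: list[tuple]) -> LogrankResult:
    """K-sample log-rank test.

    ``groups`` is a list of ``(time, event)`` pairs of arrays, one per
    group (each with >= 1 subject).  With no events anywhere the test is
    undefined and p = 1 is returned with ``no_events=True``.
    """
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    times = [np.asarray(t, dtype=float) for t, _ in groups]
    events = [np.asarray(e, dtype=int) for _, e in groups]
    for t in times:
        if len(t) == 0:
            raise ValueError("every group needs at least one subject")
        if (t <= 0).any():
            raise ValueError("survival times must be positive")
    k = len(groups)
    all_event_times = np.unique(np.concatenate([t[e == 1] for t, e in zip(times, events)]))
    if len(all_event_times) == 0:
        return LogrankResult(statistic=0.0, df=k - 1, p=1.0, no_events=True)

    observed = np.zeros(k)
    expected = np.zeros(k)
    cov = np.zeros((k, k))
    for t in all_event_times:
        n_i = np.array([float((ti >= t).sum()) for ti in times])
        d_i = np.array([float(((ti == t) & (ei == 1)).sum()) for ti, ei in zip(times, events)])
        n, d = n_i.sum(), d_i.sum()
        if n == 0 or d == 0:
            continue
        observed += d_i
        expected += d * n_i / n
        if n > 1:
            frac = n_i / n
            factor = d * (n - d) / (n - 1)
            cov += factor * (np.diag(frac) - np.outer(frac, frac))
    u = (observed - expected)[: k - 1]
    v = cov[: k - 1, : k - 1]
    statistic = float(u @ np.linalg.pinv(v) @ u)
    p = float(stats.chi2.sf(statistic, k - 1))
    return LogrankResult(statistic=statistic, df=k - 1, p=p)


def survival_groups_from_samples(samples: pd.DataFrame, group_col: str,
                                 time_col: str = "pfs_time_months",
                                 event_col: str = "pfs_event") -> dict[str, tuple]:
    """Split a sample sheet into per-group (time, event) arrays."""
    return {
        str(label): (sub[time_col].to_numpy(dtype=float), sub[event_col].to_numpy(dtype=int))
        for label, sub in samples.groupby(group_col, sort=False)
    }


def write_km_table(km: pd.DataFrame, path) -> None:
    """Write a Kaplan-Meier step function as TSV."""
    km.to_csv(path, sep="\t", index=False)
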