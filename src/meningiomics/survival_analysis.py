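"""Survival comparison between tumour subgroups.

Kaplan-Meier product-limit estimation, the log-rank (Mantel-Cox) test and
the Mantel-Haenszel hazard ratio exp((O-E)/V) with a log-scale normal 95%
confidence interval — the standard output reported for the C1-vs-C2
prognosis split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class HazardRatioEstimate:
    """Mantel-Haenszel hazard ratio for group1 vs the other group."""

    hr: float
    ci_low: float
    ci_high: float
    chi2: float
    p: float
    o1: float
    e1: float
    v: float

    def __post_init__(self) -> None:
        assert self.ci_low <= self.hr <= self.ci_high
        assert self.hr > 0


def _as_frame(records) -> pd.DataFrame:
    df = pd.DataFrame(records)
    required = {"sample", "time", "event", "group"}
    if not required.issubset(df.columns):
        raise ValueError(f"survival records need columns {sorted(required)}")
    if (df["time"] < 0).any():
        raise ValueError("negative survival time")
    df = df.copy()
    df["event"] = df["event"].astype(bool)
    return df


def km_estimate(records, group: str | None = None) -> pd.DataFrame:
    """Kaplan-Meier product-limit curve.

    Returns a step table with one row per distinct event time: ``time``,
    ``at_risk``, ``events``, ``survival``. Censored subjects leave the risk
    set without producing a step (left-continuous convention: a subject
    censored at an event time is still at risk there).
    """
    df = _as_frame(records)
    if group is not None:
        df = df[df["group"] == group]
    if len(df) == 0:
        raise ValueError("no records in requested group")
    t = df["time"].to_numpy(float)
    e = df["event"].to_numpy(bool)
    event_times = np.unique(t[e])
    rows = []
    surv = 1.0
    for tj in event_times:
        n_risk = int((t >= tj).sum())
        d = int(((t == tj) & e).sum())
        surv *= 1.0 - d / n_risk
        rows.append({"time": tj, "at_risk": n_risk, "events": d, "survival": surv})
    return pd.DataFrame(rows, columns=["time", "at_risk", "events", "survival"])


def logrank_table(records, group1: str):
    """O1, E1, V from the per-event-time hypergeometric 2x2 tables.

    Ties contribute with multiplicity d_j via the standard variance
    n1 n2 d (n - d) / (n^2 (n - 1)).
    """
    df = _as_frame(records)
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    if group1 not in groups:
        raise ValueError(f"group1={group1!r} not present")
    t = df["time"].to_numpy(float)
    e = df["event"].to_numpy(bool)
    g1 = (df["group"] == group1).to_numpy()
    if not e.any():
        raise ValueError("at least one event required")
    o1 = e1 = v = 0.0
    for tj in np.unique(t[e]):
        at_risk = t >= tj
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = ((t == tj) & e).sum()
        d1 = ((t == tj) & e & g1).sum()
        o1 += d1
        e1 += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return float(o1), float(e1), float(v)


def logrank_test(records, group1: str | None = None) -> tuple[float, float]:
    """Log-rank (Mantel-Cox) chi-square and p-value on 1 df."""
    df = _as_frame(records)
    if group1 is None:
        group1 = sorted(df["group"].unique())[0]
    o1, e1, v = logrank_table(df, group1)
    if v <= 0:
        return 0.0, 1.0
    chi2 = (o1 - e1) ** 2 / v
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def mh_hazard_ratio(records, group1: str) -> HazardRatioEstimate:
    """Mantel-Haenszel hazard ratio exp((O1-E1)/V) with normal log-scale CI.

    group1 is the numerator group (C1 in the pipeline), so HR > 1 means
    worse survival in group1.
    """
    o1, e1, v = logrank_table(records, group1)
    if v <= 0:
        raise ZeroDivisionError("zero log-rank variance; hazard ratio undefined")
    log_hr = (o1 - e1) / v
    half = 1.96 / np.sqrt(v)
    chi2 = (o1 - e1) ** 2 / v
    return HazardRatioEstimate(
        hr=float(np.exp(log_hr)),
        ci_low=float(np.exp(log_hr - half)),
        ci_high=float(np.exp(log_hr + half)),
        chi2=float(chi2),
        p=float(stats.chi2.sf(chi2, df=1)),
        o1=o1,
        e1=e1,
        v=v,
    )
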