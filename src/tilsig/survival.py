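"""Kaplan-Meier estimation, log-rank tests and related survival utilities.

The two-group log-rank test reports the Mantel-Haenszel hazard ratio
exp((O−E)/V) with CI exp((O−E)/V ± 1.96/√V) — the "log-rank HR" of
classical clinical software — rather than a proportional-hazards fit.
Five-year disease-free survival is computed as a binary proportion among
evaluable patients so it can feed Fisher's exact comparisons directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "LogRankResult",
    "TrendResult",
    "FiveYearDFS",
    "DichotomizationRule",
    "records_frame",
    "km_estimate",
    "logrank_test",
    "logrank_trend",
    "five_year_dfs",
    "dichotomize",
    "read_survival_csv",
]

Z_95 = 1.959964


@dataclass(frozen=True)
class SurvivalRecord:
    sample_id: str
    time: float  # months
    event: int  # 1 = event, 0 = censored
    group: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time < 0:
            raise ValueError("time must be finite and non-negative")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


def records_frame(records) -> pd.DataFrame:
    """Normalize input (DataFrame or SurvivalRecord list) to a frame with
    columns sample_id, time_months, event, group."""
    if isinstance(records, pd.DataFrame):
        frame = records.copy()
        if "time_months" not in frame.columns and "time" in frame.columns:
            frame = frame.rename(columns={"time": "time_months"})
        required = {"time_months", "event"}
        if not required <= set(frame.columns):
            raise ValueError(f"records need columns {sorted(required)}")
        if "sample_id" not in frame.columns:
            frame["sample_id"] = [f"r{i}" for i in range(len(frame))]
        if "group" not in frame.columns:
            frame["group"] = ""
    else:
        frame = pd.DataFrame(
            [
                {
                    "sample_id": r.sample_id,
                    "time_months": r.time,
                    "event": r.event,
                    "group": r.group,
                }
                for r in records
            ]
        )
    if len(frame) == 0:
        raise ValueError("no survival records")
    times = frame["time_months"].to_numpy(dtype=float)
    if not np.isfinite(times).all() or (times < 0).any():
        raise ValueError("times must be finite and non-negative")
    return frame


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate: survival after each distinct event time."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def survival_at(self, t: float) -> float:
        mask = self.times <= t
        return float(self.survival[mask][-1]) if mask.any() else 1.0

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "time": self.times,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
            }
        ).to_csv(path, sep="\t", index=False)


def km_estimate(records) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Subjects censored exactly at an event time are still at risk for that
    event (events-before-censoring convention).
    """
    frame = records_frame(records)
    times = frame["time_months"].to_numpy(dtype=float)
    events = frame["event"].to_numpy(dtype=int)
    event_times = np.unique(times[events == 1])
    survival = []
    at_risk = []
    d_counts = []
    s = 1.0
    for t in event_times:
        n_t = int((times >= t).sum())
        d_t = int(((times == t) & (events == 1)).sum())
        s *= 1 - d_t / n_t
        survival.append(s)
        at_risk.append(n_t)
        d_counts.append(d_t)
    return KMCurve(
        times=np.asarray(event_times, dtype=float),
        survival=np.asarray(survival, dtype=float),
        at_risk=np.asarray(at_risk, dtype=int),
        events=np.asarray(d_counts, dtype=int),
    )


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    p_two_sided: float
    observed: dict[str, float]
    expected: dict[str, float]
    hazard_ratio: float
    hr_ci_low: float
    hr_ci_high: float
    groups: tuple[str, str]


def _oe_table(frame: pd.DataFrame, group_levels: list[str]):
    """Per-event-time observed/expected/variance bookkeeping shared by the
    two-group test and the trend test."""
    times = frame["time_months"].to_numpy(dtype=float)
    events = frame["event"].to_numpy(dtype=int)
    group_idx = frame["group"].map({g: i for i, g in enumerate(group_levels)}).to_numpy()
    event_times = np.unique(times[events == 1])
    G = len(group_levels)
    O = np.zeros(G)
    E = np.zeros(G)
    # full multivariate hypergeometric covariance of per-group event counts
    V = np.zeros((G, G))
    for t in event_times:
        risk = times >= t
        n = int(risk.sum())
        d = int(((times == t) & (events == 1)).sum())
        if n <= 1:
            continue
        n_g = np.array([(risk & (group_idx == g)).sum() for g in range(G)], dtype=float)
        d_g = np.array(
            [((times == t) & (events == 1) & (group_idx == g)).sum() for g in range(G)],
            dtype=float,
        )
        p_g = n_g / n
        O += d_g
        E += d * p_g
        factor = d * (n - d) / (n - 1)
        V += factor * (np.diag(p_g) - np.outer(p_g, p_g))
    return O, E, V


def logrank_test(records, groups: tuple[str, str] | None = None) -> LogRankResult:
    """Two-group log-rank test with the Mantel-Haenszel hazard ratio of
    the first group relative to the second."""
    frame = records_frame(records)
    levels = list(groups) if groups is not None else sorted(frame["group"].unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    frame = frame[frame["group"].isin(levels)]
    for g in levels:
        sub = frame[frame["group"] == g]
        if len(sub) == 0 or sub["time_months"].sum() == 0:
            raise ValueError(f"group {g!r} has no at-risk time")
    O, E, V = _oe_table(frame, levels)
    v = float(V[0, 0])
    if v == 0:
        chi2, hr, lo, hi = 0.0, 1.0, float("nan"), float("nan")
    else:
        diff = float(O[0] - E[0])
        chi2 = diff**2 / v
        hr = float(np.exp(diff / v))
        lo = float(np.exp(diff / v - Z_95 / np.sqrt(v)))
        hi = float(np.exp(diff / v + Z_95 / np.sqrt(v)))
    return LogRankResult(
        chi_square=chi2,
        p_two_sided=float(sps.chi2.sf(chi2, df=1)) if v else 1.0,
        observed={g: float(O[i]) for i, g in enumerate(levels)},
        expected={g: float(E[i]) for i, g in enumerate(levels)},
        hazard_ratio=hr,
        hr_ci_low=lo,
        hr_ci_high=hi,
        groups=tuple(levels),
    )


@dataclass(frozen=True)
class TrendResult:
    chi_square: float
    p_two_sided: float
    scores: dict[str, float]
    statistic: float  # Σ_g s_g (O_g − E_g)
    variance: float


def logrank_trend(records, scores: dict[str, float]) -> TrendResult:
    """Log-rank test for trend across ordered groups with numeric scores
    (e.g. none = 0, CMF = 1, anthracycline = 2)."""
    if len(scores) < 2:
        raise ValueError("need at least 2 ordered groups")
    values = np.asarray(list(scores.values()), dtype=float)
    if np.ptp(values) == 0:
        raise ValueError("all trend scores are equal")
    frame = records_frame(records)
    levels = list(scores)
    frame = frame[frame["group"].isin(levels)]
    O, E, V = _oe_table(frame, levels)
    s = np.asarray([scores[g] for g in levels], dtype=float)
    z = float(s @ (O - E))
    var = float(s @ V @ s)
    chi2 = z**2 / var if var > 0 else 0.0
    return TrendResult(
        chi_square=chi2,
        p_two_sided=float(sps.chi2.sf(chi2, df=1)) if var > 0 else 1.0,
        scores=dict(scores),
        statistic=z,
        variance=var,
    )


@dataclass(frozen=True)
class FiveYearDFS:
    proportion: float
    event_free: int
    evaluable: int
    excluded_censored_early: int


def five_year_dfs(records, horizon_months: float = 60.0) -> FiveYearDFS:
    """Event-free proportion at 5 years among evaluable patients.

    Evaluable = event before the horizon, or followed at least to the
    horizon; patients censored earlier are excluded (and counted).
    Events after the horizon count as event-free.
    """
    frame = records_frame(records)
    times = frame["time_months"].to_numpy(dtype=float)
    events = frame["event"].to_numpy(dtype=int)
    event_before = (events == 1) & (times < horizon_months)
    followed = times >= horizon_months
    evaluable = event_before | followed
    n_eval = int(evaluable.sum())
    if n_eval == 0:
        raise ValueError("zero evaluable patients at the 5-year horizon")
    event_free = int((followed & evaluable).sum())
    return FiveYearDFS(
        proportion=event_free / n_eval,
        event_free=event_free,
        evaluable=n_eval,
        excluded_censored_early=int((~evaluable).sum()),
    )


@dataclass(frozen=True)
class DichotomizationRule:
    """Cut-point rule for marker values.

    median: high = value strictly above the median (ties at the cut go
    low).  upper_quartile: high = value at or above Q3 ("upper quartile
    or higher"), type-7 quartiles.
    """

    statistic: str = "median"

    def __post_init__(self) -> None:
        if self.statistic not in ("median", "upper_quartile"):
            raise ValueError("statistic must be 'median' or 'upper_quartile'")


def dichotomize(
    values: pd.Series | dict, rule: DichotomizationRule | str = "median"
) -> tuple[pd.Series, float]:
    """Split marker values into high/low labels; returns (labels, cut value)."""
    if isinstance(rule, str):
        rule = DichotomizationRule(rule)
    values = pd.Series(dict(values) if not isinstance(values, pd.Series) else values)
    values = values.dropna()
    arr = values.to_numpy(dtype=float)
    if len(np.unique(arr)) < 2:
        raise ValueError("all marker values identical; cannot dichotomize")
    if rule.statistic == "median":
        cut = float(np.median(arr))
        high = values > cut
    else:
        cut = float(np.percentile(arr, 75, method="linear"))
        high = values >= cut
    labels = high.map({True: "high", False: "low"})
    if labels.nunique() < 2:
        raise ValueError("dichotomization produced an empty group")
    return labels, cut


def read_survival_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"sample_id": str, "group": str})
    return records_frame(frame)
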