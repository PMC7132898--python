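"""Counting-process primitives shared by all two-sample survival tests.

Everything downstream (weighted logrank statistics, supremum tests, RMST
permutation tests) reduces a two-arm trial to the risk table: at each distinct
event time, the numbers at risk and the numbers of events, split by arm.  This
module builds that table, the Kaplan-Meier product-limit estimate with its
left limits, and the restricted mean survival time (RMST) with a
Greenwood-type variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalDataset",
    "RiskTable",
    "KMCurve",
    "RMSTValue",
    "build_risk_table",
    "km_estimate",
    "rmst",
]


@dataclass(frozen=True)
class SurvivalDataset:
    """Per-subject records of a two-arm trial.

    Parameters
    ----------
    time : array of positive floats
        Observed time (event or censoring), in a consistent unit.
    event : array of 0/1
        1 = event observed, 0 = right-censored.
    arm : array of 0/1
        0 = control, 1 = research arm.
    """

    time: np.ndarray
    event: np.ndarray
    arm: np.ndarray

    def __post_init__(self):
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event)
        arm = np.asarray(self.arm)
        if time.ndim != 1 or event.shape != time.shape or arm.shape != time.shape:
            raise ValueError("time, event, arm must be equal-length 1-d arrays")
        if time.size == 0:
            raise ValueError("empty dataset")
        if not np.all(np.isfinite(time)) or np.any(time <= 0):
            raise ValueError("all times must be positive and finite")
        for name, a in (("event", event), ("arm", arm)):
            if not np.isin(a, (0, 1)).all():
                raise ValueError(f"{name} must be coded 0/1")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event.astype(np.int8))
        object.__setattr__(self, "arm", arm.astype(np.int8))

    @property
    def n(self) -> int:
        return self.time.size

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def arm_mask(self, a: int) -> np.ndarray:
        return self.arm == a

    def swap_arms(self) -> "SurvivalDataset":
        """Relabel the arms (0 <-> 1); useful for symmetry checks."""
        return SurvivalDataset(self.time, self.event, 1 - self.arm)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.time, "event": self.event, "arm": self.arm}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SurvivalDataset":
        return cls(
            df["time"].to_numpy(), df["event"].to_numpy(), df["arm"].to_numpy()
        )


@dataclass(frozen=True)
class RiskTable:
    """At-risk and event counts at each distinct event time.

    ``time`` is strictly increasing.  ``n``/``n1`` are total / research-arm
    numbers at risk just before each time; ``d``/``d1`` the corresponding
    event counts.  Censorings tied with an event time are counted as at risk
    at that time (censoring ordered after events at equal times).
    """

    time: np.ndarray
    n: np.ndarray
    n1: np.ndarray
    d: np.ndarray
    d1: np.ndarray

    @property
    def n0(self) -> np.ndarray:
        return self.n - self.n1

    @property
    def d0(self) -> np.ndarray:
        return self.d - self.d1

    @property
    def n_times(self) -> int:
        return self.time.size

    @property
    def total_events(self) -> int:
        return int(self.d.sum())

    def hypergeometric_variance(self) -> np.ndarray:
        """Conditional variance of d1 at each event time.

        v_j = d_j (n_j - d_j) n1_j n0_j / (n_j^2 (n_j - 1)), with the
        n_j = 1 term set to 0.
        """
        n, d = self.n.astype(float), self.d.astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            v = d * (n - d) * self.n1 * self.n0 / (n * n * (n - 1.0))
        v[self.n <= 1] = 0.0
        return v


def build_risk_table(data: SurvivalDataset) -> RiskTable:
    """Reduce a dataset to its risk table (the rank-test sufficient statistic)."""
    if data.n_events == 0:
        raise ValueError("no events")
    if data.arm.min() == data.arm.max():
        raise ValueError("need two arms")
    ev = data.event == 1
    times = np.unique(data.time[ev])
    # at risk at t_j: time >= t_j.  Sorted subject times allow searchsorted counts.
    order = np.sort(data.time)
    n = data.n - np.searchsorted(order, times, side="left")
    order1 = np.sort(data.time[data.arm == 1])
    n1 = order1.size - np.searchsorted(order1, times, side="left")
    # events per distinct time, total and arm 1
    idx = np.searchsorted(times, data.time[ev])
    d = np.bincount(idx, minlength=times.size)
    d1 = np.bincount(idx, weights=data.arm[ev], minlength=times.size).astype(int)
    return RiskTable(times, n.astype(int), n1.astype(int), d.astype(int), d1)


@dataclass(frozen=True)
class KMCurve:
    """Kaplan-Meier step estimate with left limits at each event time.

    ``surv[j]`` is S(t_j) (the value just after the j-th event time) and
    ``left[j]`` = S(t_j - 0).  ``n_at_risk``/``n_events`` are the counts used
    at each step, retained for Greenwood-type variances.  ``max_follow_up`` is
    the largest observed time in the scope (event or censoring).
    """

    times: np.ndarray
    surv: np.ndarray
    left: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    max_follow_up: float

    @property
    def s_min(self) -> float:
        """Minimum of the left estimate S(t-0) over event times."""
        return float(self.left.min())

    def survival_at(self, t) -> np.ndarray:
        """Evaluate the step function S(t) (right-continuous)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        padded = np.concatenate(([1.0], self.surv))
        return padded[idx]


def km_estimate(data: SurvivalDataset, scope: str = "pooled") -> KMCurve:
    """Product-limit estimate on the pooled sample or a single arm.

    ``scope`` is ``"pooled"``, ``"arm0"`` or ``"arm1"``.
    """
    if scope == "pooled":
        sub = data
    elif scope in ("arm0", "arm1"):
        m = data.arm_mask(int(scope[-1]))
        if not m.any():
            raise ValueError(f"empty scope {scope!r}")
        sub = SurvivalDataset(data.time[m], data.event[m], np.zeros(m.sum()))
    else:
        raise ValueError(f"unknown scope {scope!r}")
    ev = sub.event == 1
    if not ev.any():
        raise ValueError(f"no events in scope {scope!r}")
    times = np.unique(sub.time[ev])
    order = np.sort(sub.time)
    n = sub.n - np.searchsorted(order, times, side="left")
    idx = np.searchsorted(times, sub.time[ev])
    d = np.bincount(idx, minlength=times.size)
    surv = np.cumprod(1.0 - d / n)
    left = np.concatenate(([1.0], surv[:-1]))
    return KMCurve(times, surv, left, n.astype(int), d.astype(int),
                   float(sub.time.max()))


@dataclass(frozen=True)
class RMSTValue:
    """Restricted mean survival time up to ``t_star`` with its variance."""

    t_star: float
    estimate: float
    variance: float


def rmst(km: KMCurve, t_star: float) -> RMSTValue:
    """Area under the KM step function on [0, t*], with Greenwood variance.

    Var = sum_{t_j <= t*} A_j^2 d_j / (n_j (n_j - d_j)), A_j the area under S
    from t_j to t*.  Steps with n_j = d_j (risk set exhausted by events)
    contribute 0 to the variance.
    """
    t_star = float(t_star)
    if t_star <= 0:
        raise ValueError("t* must be positive")
    if t_star > km.max_follow_up:
        raise ValueError("t* exceeds follow-up")
    t = km.times
    # widths of the constant segments of S that fall inside [0, t*]
    nxt = np.concatenate((t[1:], [np.inf]))
    widths = np.clip(np.minimum(nxt, t_star) - t, 0.0, None)
    area = min(t[0], t_star) + float(np.dot(km.surv, widths))
    # A_j = integral of S from t_j to t*: reverse cumulative sum of segment areas
    seg = km.surv * widths
    a = np.cumsum(seg[::-1])[::-1]
    n = km.n_at_risk.astype(float)
    d = km.n_events.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = a * a * d / (n * (n - d))
    terms[(n == d) | (t > t_star)] = 0.0
    return RMSTValue(t_star, area, float(terms.sum()))
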