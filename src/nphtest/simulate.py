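"""Two-arm trial simulator with a piecewise-constant hazard-ratio effect.

The control arm follows a configurable baseline distribution (exponential,
Weibull, log-logistic, or a restricted-cubic-spline model of the log
cumulative hazard against log time).  The research arm follows a hazard
ratio HR(t) that is constant before and after a single change point t*:

    H1(t) = hr_before * H0(t)                                   t <= t*
    H1(t) = hr_before * H0(t*) + hr_after * (H0(t) - H0(t*))    t >  t*

Early effect: hr_before < 1, hr_after = 1 (the effect wears off at t*).
Late effect:  hr_before = 1, hr_after < 1 (the effect kicks in at t*);
t* = 0 reduces to proportional hazards.  Censoring is independent of arm,
by default uniform over an accrual + administrative follow-up window.

Two built-in presets emulate the study conditions: a low-event-rate control
distribution with survival ~0.9 at maximum follow-up, and a high-event-rate
one with survival ~0.1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .core import SurvivalDataset

__all__ = [
    "ControlDistribution",
    "Exponential",
    "Weibull",
    "LogLogistic",
    "SplineLogCumHazard",
    "PiecewiseHREffect",
    "UniformCensoring",
    "survival_research_arm",
    "research_cumhaz",
    "sample_trial",
    "low_event_rate_preset",
    "high_event_rate_preset",
    "make_lowrate_highrate_presets",
    "preset_effect",
    "PRESET_STEP_HRS",
]


class ControlDistribution:
    """Baseline event-time distribution, specified by its cumulative hazard."""

    family = "abstract"

    def cumhaz(self, t):
        raise NotImplementedError

    def hazard(self, t):
        """Hazard function; numerically differentiated unless overridden."""
        t = np.asarray(t, dtype=float)
        h = np.maximum(1e-6, 1e-6 * t)
        lo = np.maximum(t - h, 1e-12)
        return (self.cumhaz(t + h) - self.cumhaz(lo)) / (t + h - lo)

    def survival(self, t):
        return np.exp(-self.cumhaz(t))

    def inv_cumhaz(self, u):
        """Solve H0(t) = u for t; closed form where available."""
        u = np.asarray(u, dtype=float)
        return np.vectorize(self._inv_scalar)(u)

    def _inv_scalar(self, u):
        if u <= 0:
            return 0.0
        hi = 1.0
        while self.cumhaz(hi) < u:
            hi *= 2.0
            if hi > 1e12:
                raise ValueError("cumulative hazard never reaches target")
        return brentq(lambda t: self.cumhaz(t) - u, 0.0, hi, xtol=1e-12,
                      rtol=1e-10)

    @staticmethod
    def from_config(cfg: dict) -> "ControlDistribution":
        cfg = dict(cfg)
        family = cfg.pop("family")
        cls = {
            "exponential": Exponential,
            "weibull": Weibull,
            "loglogistic": LogLogistic,
            "spline": SplineLogCumHazard,
        }[family]
        return cls(**cfg)


@dataclass
class Exponential(ControlDistribution):
    rate: float
    family = "exponential"

    def cumhaz(self, t):
        return self.rate * np.asarray(t, dtype=float)

    def hazard(self, t):
        return np.full_like(np.asarray(t, dtype=float), self.rate)

    def inv_cumhaz(self, u):
        return np.asarray(u, dtype=float) / self.rate


@dataclass
class Weibull(ControlDistribution):
    shape: float
    scale: float
    family = "weibull"

    def cumhaz(self, t):
        return (np.asarray(t, dtype=float) / self.scale) ** self.shape

    def hazard(self, t):
        t = np.asarray(t, dtype=float)
        return self.shape / self.scale * (t / self.scale) ** (self.shape - 1.0)

    def inv_cumhaz(self, u):
        return self.scale * np.asarray(u, dtype=float) ** (1.0 / self.shape)


@dataclass
class LogLogistic(ControlDistribution):
    shape: float
    scale: float
    family = "loglogistic"

    def cumhaz(self, t):
        return np.log1p((np.asarray(t, dtype=float) / self.scale) ** self.shape)

    def hazard(self, t):
        t = np.asarray(t, dtype=float)
        x = (t / self.scale) ** self.shape
        return self.shape / self.scale * (t / self.scale) ** (self.shape - 1) / (1 + x)

    def inv_cumhaz(self, u):
        return self.scale * np.expm1(np.asarray(u, dtype=float)) ** (1.0 / self.shape)


def _rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted cubic spline basis (natural spline, truncated-power form).

    Columns: 1, x, and m-2 curvature terms that are linear beyond the
    boundary knots; scaled by the knot span for conditioning.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    k = np.asarray(knots, dtype=float)
    m = k.size
    if m < 3:
        raise ValueError("need at least 3 knots")
    span2 = (k[-1] - k[0]) ** 2
    cols = [np.ones_like(x), x]
    denom = k[-1] - k[-2]

    def cube(v):
        return np.maximum(v, 0.0) ** 3

    for j in range(m - 2):
        term = (
            cube(x - k[j])
            - cube(x - k[-2]) * (k[-1] - k[j]) / denom
            + cube(x - k[-1]) * (k[-2] - k[j]) / denom
        )
        cols.append(term / span2)
    return np.column_stack(cols)


class SplineLogCumHazard(ControlDistribution):
    """log H0(t) modelled as a restricted cubic spline in log t.

    ``coefs`` has length ``len(knots)`` (intercept, linear, curvature terms);
    knots are on the log-time scale.  Coefficients are user-supplied (for
    example from an external flexible-parametric fit); monotonicity of the
    implied cumulative hazard is validated on a grid at construction.
    """

    family = "spline"

    def __init__(self, coefs, knots):
        self.coefs = np.asarray(coefs, dtype=float)
        self.knots = np.asarray(knots, dtype=float)
        if self.coefs.size != self.knots.size:
            raise ValueError("need one coefficient per basis column "
                             "(intercept, linear, len(knots)-2 curvature)")
        grid = np.exp(np.linspace(self.knots[0] - 2, self.knots[-1] + 2, 400))
        h = self.cumhaz(grid)
        if np.any(np.diff(h) < -1e-10):
            raise ValueError("spline coefficients give a non-monotone "
                             "cumulative hazard")

    def cumhaz(self, t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t, dtype=float)
        pos = t > 0
        logt = np.log(t[pos])
        out[pos] = np.exp(_rcs_basis(logt, self.knots) @ self.coefs)
        return out


@dataclass(frozen=True)
class PiecewiseHREffect:
    """Step-function hazard ratio with a single change point.

    ``kind`` is ``early`` (hr_before < 1, hr_after = 1), ``late``
    (hr_before = 1, hr_after < 1), ``ph`` (constant) or ``null`` (both 1).
    """

    kind: str
    hr_before: float
    hr_after: float
    t_star: float = 0.0

    def __post_init__(self):
        if self.hr_before <= 0 or self.hr_after <= 0 or self.t_star < 0:
            raise ValueError("hazard ratios must be positive, t* >= 0")
        ok = {
            "early": self.hr_before < 1 and self.hr_after == 1,
            "late": self.hr_before == 1 and self.hr_after < 1,
            "ph": self.hr_before == self.hr_after,
            "null": self.hr_before == 1 and self.hr_after == 1,
        }
        if self.kind not in ok:
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if not ok[self.kind]:
            raise ValueError(f"hazard ratios inconsistent with {self.kind!r} effect")

    @classmethod
    def early(cls, hr: float, t_star: float):
        return cls("early", hr, 1.0, t_star)

    @classmethod
    def late(cls, hr: float, t_star: float):
        return cls("late", 1.0, hr, t_star)

    @classmethod
    def ph(cls, hr: float):
        return cls("ph", hr, hr, 0.0)

    @classmethod
    def null(cls):
        return cls("null", 1.0, 1.0, 0.0)

    def hr_at(self, t):
        t = np.asarray(t, dtype=float)
        return np.where(t <= self.t_star, self.hr_before, self.hr_after)


def research_cumhaz(dist: ControlDistribution, eff: PiecewiseHREffect, t):
    """Cumulative hazard of the research arm under the step-HR effect."""
    t = np.asarray(t, dtype=float)
    h0 = dist.cumhaz(t)
    h0_star = float(dist.cumhaz(eff.t_star)) if eff.t_star > 0 else 0.0
    return np.where(
        t <= eff.t_star,
        eff.hr_before * h0,
        eff.hr_before * h0_star + eff.hr_after * (h0 - h0_star),
    )


def survival_research_arm(dist: ControlDistribution, eff: PiecewiseHREffect, t):
    """Survival function of the research arm, S1(t) = exp(-H1(t))."""
    return np.exp(-research_cumhaz(dist, eff, t))


def _sample_research_times(dist, eff, u):
    """Invert H1 against exponential deviates -log(u)."""
    e = -np.log(u)
    h_star = float(dist.cumhaz(eff.t_star)) if eff.t_star > 0 else 0.0
    thresh = eff.hr_before * h_star
    before = e <= thresh
    target = np.where(
        before, e / eff.hr_before, h_star + (e - thresh) / eff.hr_after
    )
    return dist.inv_cumhaz(target)


@dataclass(frozen=True)
class UniformCensoring:
    """Censoring time uniform on [low, high]: staggered uniform accrual over
    a window of length high - low with an administrative horizon at high."""

    low: float
    high: float

    def __post_init__(self):
        if not 0 < self.low <= self.high:
            raise ValueError("need 0 < low <= high")

    def draw(self, size, rng):
        return rng.uniform(self.low, self.high, size)

    def survival(self, t):
        t = np.asarray(t, dtype=float)
        with np.errstate(invalid="ignore"):
            s = np.clip((self.high - t) / (self.high - self.low), 0.0, 1.0)
        return np.where(t <= self.low, 1.0, np.where(t >= self.high, 0.0, s))

    @property
    def horizon(self) -> float:
        return self.high

    @staticmethod
    def from_config(cfg: dict) -> "UniformCensoring":
        cfg = dict(cfg)
        family = cfg.pop("family", "uniform")
        if family != "uniform":
            raise ValueError(f"unknown censoring family {family!r}")
        return UniformCensoring(**cfg)


def sample_trial(
    n: int,
    dist: ControlDistribution,
    eff: PiecewiseHREffect,
    cens: UniformCensoring,
    seed=None,
    rng: np.random.Generator | None = None,
) -> SurvivalDataset:
    """Simulate one 1:1 randomized trial of ``n`` subjects (n even, >= 4)."""
    if n < 4 or n % 2:
        raise ValueError("n must be an even integer >= 4")
    if rng is None:
        rng = np.random.default_rng(seed)
    half = n // 2
    t0 = dist.inv_cumhaz(-np.log(rng.uniform(size=half)))
    t1 = _sample_research_times(dist, eff, rng.uniform(size=half))
    c = cens.draw(n, rng)
    event_time = np.concatenate((t0, t1))
    arm = np.repeat([0, 1], half)
    time = np.minimum(event_time, c)
    event = (event_time <= c).astype(int)
    time = np.maximum(time, 1e-12)  # guard against numerically zero times
    return SurvivalDataset(time, event, arm)


# ---------------------------------------------------------------------------
# presets emulating the low / high event-rate study conditions
# ---------------------------------------------------------------------------

#: Step hazard ratios for the built-in scenario grid, by (effect, event rate).
PRESET_STEP_HRS = {
    ("early", "low"): 0.3,
    ("early", "high"): 0.5,
    ("late", "low"): 0.3,
    ("late", "high"): 0.5,
}


def low_event_rate_preset():
    """Control survival ~0.9 at the 5-year horizon; accrual over 2 years.

    Exponential baseline calibrated so S0(5) = 0.9; censoring uniform on
    [3, 5] years (administrative censoring dominates).
    """
    rate = -np.log(0.9) / 5.0
    return Exponential(rate), UniformCensoring(3.0, 5.0)


def high_event_rate_preset():
    """Control survival ~0.1 at the 3-year horizon; accrual over 1 year.

    Weibull baseline (shape 1.3, mildly increasing hazard) calibrated so
    S0(3) = 0.1; censoring uniform on [2, 3] years.
    """
    shape = 1.3
    scale = 3.0 / (-np.log(0.1)) ** (1.0 / shape)
    return Weibull(shape, scale), UniformCensoring(2.0, 3.0)


def make_lowrate_highrate_presets():
    """Both built-in (distribution, censoring) pairs, keyed by event rate."""
    return {"low": low_event_rate_preset(), "high": high_event_rate_preset()}


def preset_effect(kind: str, event_rate: str, t_star: float = 0.0) -> PiecewiseHREffect:
    """Scenario-grid effect for an event-rate preset.

    Early effects: HR 0.3 (low rate) or 0.5 (high rate) before t*, then 1.
    Late effects: HR 1 before t*, then 0.3 / 0.5.  ``ph`` uses HR 0.75;
    ``null`` ignores the rate.
    """
    if kind == "null":
        return PiecewiseHREffect.null()
    if kind == "ph":
        return PiecewiseHREffect.ph(0.75)
    hr = PRESET_STEP_HRS[(kind, event_rate)]
    if kind == "early":
        return PiecewiseHREffect.early(hr, t_star)
    return PiecewiseHREffect.late(hr, t_star)
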