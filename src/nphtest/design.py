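"""Trial design utilities: required events, sample-size calibration, and the
information fraction.

Sample sizes are benchmarked to the logrank test: the Schoenfeld
required-events formula gives a starting point (using the event-weighted
average log hazard ratio when the effect is non-proportional), and a short
simulation search then adjusts n until the simulated logrank power matches
the target within one percentage point.

The information fraction IF(t*) is the probability, among control-arm events
that are observed at all (i.e. not censored), of occurring before t*.  It
places a change point on a scale that is invariant to the time units and is
the natural x-axis for power comparisons of early/late effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.integrate import quad
from scipy.optimize import brentq

from .simulate import (
    ControlDistribution,
    PiecewiseHREffect,
    UniformCensoring,
    sample_trial,
)
from .statistics import logrank_test

__all__ = [
    "DesignSpec",
    "InformationFraction",
    "SampleSizeResult",
    "required_events_schoenfeld",
    "expected_event_probability",
    "average_log_hr",
    "simulate_logrank_power",
    "calibrate_sample_size",
    "information_fraction",
    "solve_tstar_for_if",
    "DEFAULT_IF_GRIDS",
]

#: Target information fractions (%/100) for the built-in scenario grids,
#: by (effect kind, event-rate preset): seven change points per cell, the
#: late grids starting at 0 (pure proportional hazards).
DEFAULT_IF_GRIDS = {
    ("early", "low"): (0.40, 0.49, 0.56, 0.68, 0.75, 0.87, 0.95),
    ("late", "low"): (0.0, 0.16, 0.28, 0.40, 0.53, 0.64, 0.75),
    ("early", "high"): (0.45, 0.57, 0.69, 0.77, 0.85, 0.91, 0.96),
    ("late", "high"): (0.0, 0.12, 0.27, 0.45, 0.57, 0.69, 0.77),
}


@dataclass(frozen=True)
class DesignSpec:
    """Design inputs for a 1:1 trial powered on the logrank test."""

    effect: PiecewiseHREffect
    dist: ControlDistribution
    cens: UniformCensoring
    alpha: float = 0.05
    power: float = 0.9

    def __post_init__(self):
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("alpha and power must lie in (0, 1)")


@dataclass(frozen=True)
class InformationFraction:
    t_star: float
    value: float


@dataclass(frozen=True)
class SampleSizeResult:
    n: int
    achieved_power: float
    expected_events: float
    evaluations: tuple = field(default_factory=tuple)

    def __int__(self):
        return self.n


def required_events_schoenfeld(hr: float, alpha: float = 0.05,
                               power: float = 0.9) -> int:
    """Schoenfeld's required total events for a 1:1 logrank design.

    e = ceil( 4 (z_{1-alpha/2} + z_power)^2 / (ln hr)^2 ).
    """
    if hr == 1:
        raise ValueError("no effect (hr = 1)")
    if not 0 < hr:
        raise ValueError("hr must be positive")
    z = stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)
    return int(np.ceil(4.0 * z * z / np.log(hr) ** 2))


def _event_density(dist, eff, t):
    """Density of observed research-arm (or control if eff None) events."""
    t = np.asarray(t, dtype=float)
    if eff is None:
        return dist.hazard(t) * dist.survival(t)
    from .simulate import survival_research_arm

    return eff.hr_at(t) * dist.hazard(t) * survival_research_arm(dist, eff, t)


def expected_event_probability(
    dist: ControlDistribution,
    cens: UniformCensoring,
    eff: PiecewiseHREffect | None = None,
) -> float:
    """P(event observed before censoring) for one arm, by numeric integration."""
    pts = [0.0, cens.low, cens.high]
    if eff is not None and 0 < eff.t_star < cens.high:
        pts.append(eff.t_star)
    pts = sorted(set(pts))
    total = 0.0
    for a, b in zip(pts[:-1], pts[1:]):
        total += quad(
            lambda u: _event_density(dist, eff, u) * cens.survival(u),
            a, b, limit=200,
        )[0]
    return float(total)


def average_log_hr(spec: DesignSpec) -> float:
    """Event-weighted average log HR under the alternative.

    ln HRbar = sum_j p_j ln HR(t_j) in continuous form, with p_j the expected
    fraction of observed events (both arms pooled) at time t_j.
    """
    eff, dist, cens = spec.effect, spec.dist, spec.cens

    def dens(u):
        return 0.5 * (
            _event_density(dist, None, u) + _event_density(dist, eff, u)
        ) * cens.survival(u)

    pts = sorted({0.0, cens.low, cens.high} | (
        {eff.t_star} if 0 < eff.t_star < cens.high else set()
    ))
    num = den = 0.0
    for a, b in zip(pts[:-1], pts[1:]):
        num += quad(lambda u: np.log(eff.hr_at(u)) * dens(u), a, b, limit=200)[0]
        den += quad(dens, a, b, limit=200)[0]
    if den <= 0:
        raise ValueError("no expected events under the design")
    return num / den


def simulate_logrank_power(
    n: int,
    spec: DesignSpec,
    replicates: int,
    rng: np.random.Generator,
) -> float:
    """Empirical logrank rejection rate at alpha (two-sided) over replicates."""
    hits = 0
    for _ in range(replicates):
        data = sample_trial(n, spec.dist, spec.effect, spec.cens, rng=rng)
        try:
            p = logrank_test(data).p_value
        except ValueError:
            continue
        hits += p < spec.alpha
    return hits / replicates


def calibrate_sample_size(
    spec: DesignSpec,
    reps: int = 1000,
    seed=None,
    rng: np.random.Generator | None = None,
    tol: float = 0.01,
) -> SampleSizeResult:
    """Find n (even) giving simulated logrank power within ``tol`` of target.

    Starts from the Schoenfeld formula applied to the event-weighted average
    log HR, inflated by the expected event probability, then adjusts n
    multiplicatively on the normal-approximation scale and finishes with a
    local search, each step evaluated by simulation with ``reps`` replicates.
    """
    if reps < 500:
        raise ValueError("reps must be at least 500")
    if spec.effect.kind == "null":
        raise ValueError("no effect: power cannot be pegged under the null")
    if rng is None:
        rng = np.random.default_rng(seed)
    loghr = average_log_hr(spec)
    if loghr == 0:
        raise ValueError("average log HR is zero: target unreachable")
    z_a = stats.norm.ppf(1 - spec.alpha / 2)
    z_b = stats.norm.ppf(spec.power)
    events = 4.0 * (z_a + z_b) ** 2 / loghr**2
    p_event = 0.5 * (
        expected_event_probability(spec.dist, spec.cens, None)
        + expected_event_probability(spec.dist, spec.cens, spec.effect)
    )
    n = _even(events / p_event)
    evals = []
    for _ in range(8):
        power = simulate_logrank_power(n, spec, reps, rng)
        evals.append((n, power))
        if abs(power - spec.power) <= tol:
            return SampleSizeResult(n, power, n * p_event, tuple(evals))
        # rescale required events on the normal-approximation scale
        z_hat = stats.norm.ppf(np.clip(power, 1e-4, 1 - 1e-4))
        shrink = ((z_a + z_b) / max(z_a + z_hat, 0.3)) ** 2
        n_new = _even(n * np.clip(shrink, 0.5, 2.0))
        if n_new == n:
            n_new = n + 2 if power < spec.power else max(4, n - 2)
        n = n_new
    raise ValueError(
        "sample-size calibration did not reach the target power; "
        f"evaluations: {evals}"
    )


def _even(x: float) -> int:
    n = int(np.ceil(x))
    return max(4, n + (n % 2))


def information_fraction(
    dist: ControlDistribution,
    cens: UniformCensoring,
    t_star: float,
) -> InformationFraction:
    """Fraction of observed control-arm events occurring before t*."""
    if t_star < 0:
        raise ValueError("t* must be non-negative")
    total = expected_event_probability(dist, cens, None)
    if t_star == 0:
        return InformationFraction(0.0, 0.0)
    if t_star >= cens.high:
        return InformationFraction(t_star, 1.0)
    pts = sorted({0.0, min(t_star, cens.low), t_star} | (
        {cens.low} if cens.low < t_star else set()
    ))
    part = 0.0
    for a, b in zip(pts[:-1], pts[1:]):
        part += quad(
            lambda u: _event_density(dist, None, u) * cens.survival(u),
            a, b, limit=200,
        )[0]
    return InformationFraction(t_star, float(part / total))


def solve_tstar_for_if(
    dist: ControlDistribution,
    cens: UniformCensoring,
    target_if: float,
    tol: float = 1e-4,
) -> float:
    """Invert the information fraction: find t* with IF(t*) = target."""
    if not 0 <= target_if < 1:
        raise ValueError("target IF must lie in [0, 1)")
    if target_if == 0:
        return 0.0

    def f(t):
        return information_fraction(dist, cens, t).value - target_if

    hi = cens.high
    t = brentq(f, 1e-9, hi, xtol=tol * 1e-2)
    return float(t)
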