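"""Simulation study driver: empirical size/power, benchmarks and deficits.

A scenario fixes the data-generating process (control distribution,
censoring, effect, sample size); `estimate_rejection_rate` simulates
replicate trials, applies the requested tests, and returns per-test
rejection rates with exact binomial confidence intervals and the mean
observed control-arm information fraction.  `summarize_deficits` compares
each test against the per-scenario benchmark (the best test's power) and
averages the shortfall by effect type and event rate; a test is flagged
acceptable when its mean deficit across event rates stays below 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .core import SurvivalDataset
from .simulate import (
    ControlDistribution,
    PiecewiseHREffect,
    UniformCensoring,
    sample_trial,
)
from .statistics import TEST_NAMES, run_tests

__all__ = [
    "Scenario",
    "SizePowerResult",
    "DeficitSummary",
    "estimate_rejection_rate",
    "summarize_deficits",
    "plot_power_vs_if",
]


@dataclass(frozen=True)
class Scenario:
    """One cell of the simulation study."""

    scenario_id: str
    dist: ControlDistribution
    cens: UniformCensoring
    effect: PiecewiseHREffect
    n: int
    event_rate: str = "custom"  # "low" | "high" | "custom", used for grouping


@dataclass(frozen=True)
class SizePowerResult:
    """Empirical rejection rates for one scenario."""

    scenario_id: str
    effect_kind: str
    event_rate: str
    t_star: float
    replicates: int
    counts: dict
    rates: dict
    ci: dict
    mean_if: float

    def to_rows(self) -> pd.DataFrame:
        rows = [
            {
                "scenario": self.scenario_id,
                "effect": self.effect_kind,
                "event_rate": self.event_rate,
                "t_star": self.t_star,
                "test": t,
                "rejections": self.counts[t],
                "replicates": self.replicates,
                "rate": self.rates[t],
                "ci_lo": self.ci[t][0],
                "ci_hi": self.ci[t][1],
                "mean_IF": self.mean_if,
            }
            for t in self.rates
        ]
        return pd.DataFrame(rows)


def _observed_if(data: SurvivalDataset, t_star: float) -> float:
    """Share of observed control-arm events falling before t*."""
    ctrl = (data.arm == 0) & (data.event == 1)
    total = int(ctrl.sum())
    if total == 0:
        return np.nan
    return float(np.sum(data.time[ctrl] < t_star)) / total


def estimate_rejection_rate(
    scenario: Scenario,
    tests=TEST_NAMES,
    replicates: int = 1000,
    alpha: float = 0.05,
    seed=None,
    rng: np.random.Generator | None = None,
    permutations: int = 500,
    max_error_fraction: float = 0.01,
) -> SizePowerResult:
    """Simulate replicate trials and estimate each test's rejection rate.

    Identical seeds give identical results.  If any test errors on more than
    ``max_error_fraction`` of replicates the scenario is considered
    degenerate and the run aborts with a diagnostic.
    """
    if replicates < 100:
        raise ValueError("need at least 100 replicates")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    tests = list(tests)
    if rng is None:
        rng = np.random.default_rng(seed)
    counts = {t: 0 for t in tests}
    errors = {t: 0 for t in tests}
    ifs = []
    # one deterministic substream per replicate, so replicate k's data does
    # not depend on how much randomness earlier replicates consumed
    child_seeds = rng.integers(2**31, size=replicates)
    for k in range(replicates):
        child = np.random.default_rng(child_seeds[k])
        data = sample_trial(
            scenario.n, scenario.dist, scenario.effect, scenario.cens, rng=child
        )
        ifs.append(_observed_if(data, scenario.effect.t_star))
        try:
            results = run_tests(
                data, tests, permutations=permutations, rng=child
            )
        except (ValueError, RuntimeError):
            # whole-replicate failure (e.g. no events): charge every test
            for t in tests:
                errors[t] += 1
            results = {}
        for t, res in results.items():
            counts[t] += res.p_value < alpha
    for t in tests:
        if errors[t] > max_error_fraction * replicates:
            raise RuntimeError(
                f"degenerate scenario {scenario.scenario_id!r}: test {t!r} "
                f"failed on {errors[t]}/{replicates} replicates"
            )
    denom = {t: replicates - errors[t] for t in tests}
    rates = {t: counts[t] / denom[t] for t in tests}
    ci = {
        t: tuple(proportion_confint(counts[t], denom[t], 0.05, method="beta"))
        for t in tests
    }
    return SizePowerResult(
        scenario.scenario_id,
        scenario.effect.kind,
        scenario.event_rate,
        scenario.effect.t_star,
        replicates,
        counts,
        rates,
        ci,
        float(np.nanmean(ifs)),
    )


def pooled_null_size(
    event_rate: str = "low",
    sizes=(1400, 2200, 3400),
    replicates_total: int = 5000,
    tests=TEST_NAMES,
    alpha: float = 0.05,
    seed=None,
    permutations: int = 500,
) -> dict:
    """Empirical size from identical-arm simulations pooled over sample sizes.

    Splits ``replicates_total`` as evenly as possible across the sample
    sizes, simulates identical arms from the chosen event-rate preset, and
    pools rejection counts.  Returns pooled rates, counts, Clopper-Pearson
    CIs and the per-size results.
    """
    from .simulate import make_lowrate_highrate_presets

    dist, cens = make_lowrate_highrate_presets()[event_rate]
    rng = np.random.default_rng(seed)
    base, extra = divmod(replicates_total, len(sizes))
    per_size = [base + (i < extra) for i in range(len(sizes))]
    results = []
    for n, reps in zip(sizes, per_size):
        sc = Scenario(
            f"null-{event_rate}-n{n}", dist, cens,
            PiecewiseHREffect.null(), n, event_rate,
        )
        results.append(
            estimate_rejection_rate(
                sc, tests, replicates=reps, alpha=alpha, rng=rng,
                permutations=permutations,
            )
        )
    counts = {t: sum(r.counts[t] for r in results) for t in tests}
    total = sum(r.replicates for r in results)
    rates = {t: counts[t] / total for t in tests}
    ci = {
        t: tuple(proportion_confint(counts[t], total, 0.05, method="beta"))
        for t in tests
    }
    return {
        "rates": rates,
        "counts": counts,
        "replicates": total,
        "ci": ci,
        "per_size": results,
    }


@dataclass(frozen=True)
class DeficitSummary:
    """Benchmark powers and per-test deficits across scenarios.

    ``benchmark`` maps scenario id -> best empirical power; ``deficits`` is a
    tidy frame (scenario, effect, event_rate, test, power, benchmark,
    deficit); ``mean_deficits`` averages per (effect, test) over event rates
    and scenarios; ``acceptable`` flags tests with mean deficit < 0.05 for a
    given effect type.  Proportional-hazards scenarios (late effects with
    t* = 0) are grouped under effect ``ph`` and excluded from the late-effect
    means.
    """

    benchmark: dict
    deficits: pd.DataFrame
    mean_deficits: pd.DataFrame
    acceptable: dict


def summarize_deficits(results, acceptability_threshold: float = 0.05) -> DeficitSummary:
    results = list(results)
    if not results:
        raise ValueError("no results")
    test_sets = {frozenset(r.rates) for r in results}
    if len(test_sets) != 1:
        raise ValueError("every scenario must report the same test set")
    rows = []
    benchmark = {}
    for r in results:
        best = max(r.rates.values())
        benchmark[r.scenario_id] = best
        effect = r.effect_kind
        if effect == "late" and r.t_star == 0:
            effect = "ph"  # late effect with t*=0 is proportional hazards
        for t, rate in r.rates.items():
            rows.append(
                {
                    "scenario": r.scenario_id,
                    "effect": effect,
                    "event_rate": r.event_rate,
                    "test": t,
                    "power": rate,
                    "benchmark": best,
                    "deficit": best - rate,
                }
            )
    deficits = pd.DataFrame(rows)
    mean_deficits = (
        deficits.groupby(["effect", "test"], as_index=False)["deficit"].mean()
    )
    acceptable = {
        (row["effect"], row["test"]): row["deficit"] < acceptability_threshold
        for _, row in mean_deficits.iterrows()
    }
    return DeficitSummary(benchmark, deficits, mean_deficits, acceptable)


def plot_power_vs_if(results, tests=None, ax=None):
    """Power against mean observed control-arm IF, one line per test."""
    import matplotlib.pyplot as plt

    results = sorted(results, key=lambda r: r.mean_if)
    tests = tests or list(results[0].rates)
    if ax is None:
        _, ax = plt.subplots()
    x = [r.mean_if for r in results]
    for t in tests:
        ax.plot(x, [r.rates[t] for r in results], marker="o", label=t)
    ax.set_xlabel("mean control-arm information fraction")
    ax.set_ylabel("empirical power")
    ax.legend()
    return ax
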