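"""Nine two-sample tests for time-to-event outcomes.

The family covers the standard logrank test (LR), Fleming-Harrington weighted
logrank tests targeting early (LRE) and late (LRL) treatment effects, the
supremum logrank test (SupLR), and four composite tests built from several
components: the joint Cox + proportional-hazards test (J), the combined
Cox + RMST permutation test (C), the weighted combined test (WC, the LRL
statistic in place of the Cox component), and the versatile weighted logrank
tests (VWLR and its modified form VWLR2) that take the maximum of three
correlated weighted logrank Z statistics.

All p-values are two-sided.  Composite permutation tests are reproducible
given a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._cox import cox_fit_binary, cox_score_chi2, grambsch_therneau_chi2
from ._mvnbox import symmetric_box_probability
from ._perm import RelabelingEngine
from .core import (
    KMCurve,
    RiskTable,
    SurvivalDataset,
    build_risk_table,
    km_estimate,
)

__all__ = [
    "TestResult",
    "fh_weights",
    "vwlr2_weights",
    "weighted_logrank",
    "sup_brownian_pvalue",
    "sup_logrank",
    "joint_test",
    "combined_test",
    "weighted_combined_test",
    "versatile_test",
    "logrank_test",
    "TEST_NAMES",
    "run_tests",
]

TEST_NAMES = (
    "lr", "lre", "lrl", "suplr", "joint", "combined", "wc", "vwlr", "vwlr2",
)


@dataclass
class TestResult:
    """Outcome of one hypothesis test.

    ``null_dist`` tags the reference distribution: ``normal``, ``chi2(k)``,
    ``sup-brownian``, ``max-trivariate-normal`` or ``permutation``.
    """

    name: str
    statistic: float
    null_dist: str
    p_value: float
    df: int | None = None
    details: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


# ---------------------------------------------------------------------------
# weights and the shared weighted-logrank engine
# ---------------------------------------------------------------------------

def fh_weights(km: KMCurve, scheme: str) -> np.ndarray:
    """Fleming-Harrington weights from the pooled KM left limits.

    ``lr`` -> 1 (FH(0,0)); ``early`` -> S(t-0) (FH(1,0));
    ``late`` -> 1 - S(t-0) (FH(0,1)).
    """
    if scheme == "lr":
        return np.ones_like(km.left)
    if scheme == "early":
        return km.left.copy()
    if scheme == "late":
        return 1.0 - km.left
    raise ValueError(f"unknown weight scheme {scheme!r}")


def vwlr2_weights(km: KMCurve) -> np.ndarray:
    """Rescaled early weights w = max{0.001, [S(t-0) - S_min] / (1 - S_min)}.

    The rescaling stretches the early weights onto (almost) the full [0.001, 1]
    interval, so that with a low event rate — where S(t-0) stays near 1 and
    plain FH(1,0) weights barely differ from the logrank — the early component
    retains contrast.  As S_min -> 0 the weights tend to S(t-0) pointwise.
    """
    s_min = km.s_min
    if s_min >= 1.0:
        # all left limits equal 1 (single event time): the rescaled weight at
        # S(t-0) = 1 is 1 by continuity (numerator equals denominator)
        return np.ones_like(km.left)
    w = (km.left - s_min) / (1.0 - s_min)
    return np.maximum(0.001, w)


def weighted_logrank(
    table: RiskTable, weights: np.ndarray | None = None, name: str = "wlr"
) -> TestResult:
    """Weighted logrank test with per-event-time weights.

    U = sum_j w_j (d1_j - d_j n1_j / n_j), V = sum_j w_j^2 v_j with v_j the
    hypergeometric variance; Z = U / sqrt(V) referred to N(0, 1).
    """
    w = np.ones(table.n_times) if weights is None else np.asarray(weights, float)
    if w.shape != table.time.shape:
        raise ValueError("weight vector length must equal number of event times")
    if np.any(w < 0) or not np.any(w > 0):
        raise ValueError("weights must be non-negative and not all zero")
    u = float(np.dot(w, table.d1 - table.d * table.n1 / table.n))
    v = float(np.dot(w * w, table.hypergeometric_variance()))
    if v <= 0:
        raise ValueError("degenerate variance")
    z = u / np.sqrt(v)
    p = 2.0 * stats.norm.sf(abs(z))
    return TestResult(name, z, "normal", p, details={"U": u, "V": v})


def logrank_test(data: SurvivalDataset) -> TestResult:
    """Standard (unweighted) logrank test."""
    return weighted_logrank(build_risk_table(data), None, name="lr")


# ---------------------------------------------------------------------------
# supremum logrank
# ---------------------------------------------------------------------------

def sup_brownian_pvalue(b: float, tol: float = 1e-12) -> float:
    """P(sup_{0<=s<=1} |B(s)| >= b) for standard Brownian motion.

    Alternating series 4 * sum_{k>=0} (-1)^k [1 - Phi((2k+1) b)], truncated
    when a term drops below ``tol``; the partial sums bracket the limit.
    """
    if b < 0:
        raise ValueError("b must be non-negative")
    if b < 1e-8:
        return 1.0
    total, k = 0.0, 0
    while True:
        term = 4.0 * stats.norm.sf((2 * k + 1) * b)
        if term < tol or k > 100_000:
            break
        total += term if k % 2 == 0 else -term
        k += 1
    return float(min(1.0, max(0.0, total)))


def sup_logrank(table: RiskTable) -> TestResult:
    """Supremum logrank test.

    The logrank score process is restricted to each event time in turn; the
    maximal absolute partial sum, standardized by the full-information
    variance, is referred to the supremum of |Brownian motion| on [0, 1].
    Because the supremum is taken over the discrete set of observed event
    times the test is slightly conservative.
    """
    inc = table.d1 - table.d * table.n1 / table.n
    v_total = float(table.hypergeometric_variance().sum())
    if v_total <= 0:
        raise ValueError("degenerate variance")
    partial = np.cumsum(inc)
    b = float(np.max(np.abs(partial)) / np.sqrt(v_total))
    return TestResult(
        "suplr", b, "sup-brownian", sup_brownian_pvalue(b),
        details={"argmax_time": float(table.time[np.argmax(np.abs(partial))])},
    )


# ---------------------------------------------------------------------------
# joint test
# ---------------------------------------------------------------------------

def joint_test(
    data: SurvivalDataset,
    transform: str = "identity",
    cox_component: str = "score",
) -> TestResult:
    """Joint test: Cox chi-square + Grambsch-Therneau chi-square, 2 df.

    The Cox component tests the arm effect (score test by default, or the
    likelihood ratio); the Grambsch-Therneau component tests non-proportional
    hazards via scaled Schoenfeld residuals regressed on transformed event
    times (``identity``, ``km`` or ``rank``).  Under proportional hazards the
    two components are asymptotically independent, so their sum is referred
    to chi-square with 2 df.
    """
    table = build_risk_table(data)
    if table.total_events < 2:
        raise ValueError("joint test needs at least two events")
    beta = cox_fit_binary(table)
    if cox_component == "score":
        chi2_cox = cox_score_chi2(table)
    elif cox_component == "lr":
        chi2_cox = _cox_lr_chi2(table, beta)
    else:
        raise ValueError(f"unknown cox_component {cox_component!r}")
    km = km_estimate(data, "pooled") if transform == "km" else None
    chi2_gt = grambsch_therneau_chi2(table, beta, transform, km)
    j = chi2_cox + chi2_gt
    return TestResult(
        "joint", j, "chi2(2)", float(stats.chi2.sf(j, 2)), df=2,
        details={"chi2_cox": chi2_cox, "chi2_gt": chi2_gt, "beta": beta},
    )


def _cox_lr_chi2(table: RiskTable, beta: float) -> float:
    def loglik(b):
        return float(
            b * table.d1.sum()
            - np.dot(table.d, np.log(table.n1 * np.exp(b) + table.n0))
        )

    return 2.0 * (loglik(beta) - loglik(0.0))


# ---------------------------------------------------------------------------
# combined / weighted combined permutation tests
# ---------------------------------------------------------------------------

def default_rmst_grid(data: SurvivalDataset) -> np.ndarray:
    """Event-time quantiles {0.25, 0.5, 0.75, 1.0}, clipped to both arms'
    follow-up so every RMST truncation time is evaluable in either arm."""
    table = build_risk_table(data)
    q = np.quantile(table.time, [0.25, 0.5, 0.75, 1.0])
    cap = min(
        data.time[data.arm == 0].max(), data.time[data.arm == 1].max()
    )
    return np.unique(np.minimum(q, cap))


def _combined_core(
    data: SurvivalDataset,
    grid,
    permutations: int,
    rng: np.random.Generator,
    exact: bool,
    which: tuple,
) -> dict:
    if grid is None:
        grid = default_rmst_grid(data)
    grid = np.atleast_1d(np.asarray(grid, float))
    if grid.size == 0:
        raise ValueError("empty RMST grid")
    for a in (0, 1):
        cap = data.time[data.arm == a].max()
        if np.any(grid > cap + 1e-12):
            raise ValueError("grid t* exceeds follow-up of arm %d" % a)
    km = km_estimate(data, "pooled")
    table = build_risk_table(data)
    lrl_w = fh_weights(km, "late")
    # truncation times with degenerate observed RMST variance are dropped
    engine = RelabelingEngine(data, grid)
    obs = engine.statistics(engine.observed_labels(), lrl_w)
    z2 = obs["z2_rmst"][:, 0]
    keep = np.ones(grid.size, dtype=bool)
    for i in range(grid.size):
        if z2[i] == 0.0 and grid[i] < engine.tvals[0]:
            keep[i] = False
    if not keep.all():
        warnings.warn("dropping degenerate RMST grid points", stacklevel=3)
        grid = grid[keep]
        if grid.size == 0:
            raise ValueError("all RMST grid points precede the first event")
        engine = RelabelingEngine(data, grid)
        obs = engine.statistics(engine.observed_labels(), lrl_w)

    if exact:
        labels = engine.exhaustive_labels()
    else:
        if permutations < 100:
            raise ValueError("need at least 100 permutations")
        labels = engine.random_labels(permutations, rng)
    perm = engine.statistics(labels, lrl_w)

    out = {}
    comp = {"combined": "chi2_cox", "wc": "chi2_lrl"}
    for name in which:
        key = comp[name]
        m_obs = max(obs[key][0], obs["max_z2"][0])
        m_perm = np.maximum(perm[key], perm["max_z2"])
        if exact:
            p = float(np.mean(m_perm >= m_obs - 1e-12))
            tag = "permutation-exact"
            count = int(np.sum(m_perm >= m_obs - 1e-12))
        else:
            count = int(np.sum(m_perm >= m_obs - 1e-12))
            p = (1.0 + count) / (labels.shape[1] + 1.0)
            tag = "permutation"
        out[name] = TestResult(
            name, float(m_obs), tag, p,
            details={
                "component_chi2": float(obs[key][0]),
                "max_rmst_z2": float(obs["max_z2"][0]),
                "grid": grid.tolist(),
                "permutations": labels.shape[1],
                "exceedances": count,
            },
        )
    return out


def combined_test(
    data: SurvivalDataset,
    grid=None,
    permutations: int = 1000,
    seed=None,
    rng: np.random.Generator | None = None,
    exact: bool = False,
) -> TestResult:
    """Combined test: max(Cox score chi2, max_t* z_RMST(t*)^2), permutation null.

    z_RMST(t*) is the standardized difference in restricted mean survival
    time between the arms at truncation time t*, maximized over a small
    predefined grid.  The maximum of the Cox and RMST components is referred
    to its joint permutation distribution under arm relabeling, which keeps
    the finite-sample size exact under exchangeability.  With random
    permutations the p-value uses the (1 + count) / (B + 1) estimator;
    ``exact=True`` enumerates all label assignments instead (small n only).
    """
    rng = _resolve_rng(rng, seed)
    return _combined_core(data, grid, permutations, rng, exact, ("combined",))[
        "combined"
    ]


def weighted_combined_test(
    data: SurvivalDataset,
    grid=None,
    permutations: int = 1000,
    seed=None,
    rng: np.random.Generator | None = None,
    exact: bool = False,
) -> TestResult:
    """Weighted combined test: the Cox component of the combined test is
    replaced by the late-effect weighted logrank (FH(0,1)) chi-square."""
    rng = _resolve_rng(rng, seed)
    return _combined_core(data, grid, permutations, rng, exact, ("wc",))["wc"]


def _resolve_rng(rng, seed) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# versatile weighted logrank tests
# ---------------------------------------------------------------------------

def _max_abs_normal_pvalue(z_max: float, corr: np.ndarray) -> float:
    """P(max_i |N_i| >= z_max) for a centred MVN with correlation ``corr``."""
    return 1.0 - symmetric_box_probability(z_max, corr)


def versatile_test(
    table: RiskTable,
    km: KMCurve,
    variant: str = "vwlr",
) -> TestResult:
    """Versatile weighted logrank test: max |Z| over three weight schemes.

    Components: unweighted (logrank), an early-effect weighting — FH(1,0) for
    ``vwlr``, the rescaled early weights for ``vwlr2`` — and FH(0,1).  The
    null distribution of max |Z| is evaluated as a trivariate-normal box
    probability with the estimated correlation matrix
    rho_ab = sum_j w_aj w_bj v_j / sqrt(sum w_aj^2 v_j * sum w_bj^2 v_j).
    """
    if variant == "vwlr":
        early = km.left.copy()
    elif variant == "vwlr2":
        early = vwlr2_weights(km)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    schemes = [np.ones_like(km.left), early, 1.0 - km.left]
    labels = ["lr", "early", "late"]
    v = table.hypergeometric_variance()
    zs, ws, kept = [], [], []
    for w, lab in zip(schemes, labels):
        vv = float(np.dot(w * w, v))
        if vv <= 0:
            warnings.warn(f"dropping zero-variance component {lab}", stacklevel=2)
            continue
        u = float(np.dot(w, table.d1 - table.d * table.n1 / table.n))
        zs.append(u / np.sqrt(vv))
        ws.append(w)
        kept.append(lab)
    if not zs:
        raise ValueError("all components degenerate")
    k = len(zs)
    corr = np.eye(k)
    for a in range(k):
        for b in range(a + 1, k):
            num = float(np.dot(ws[a] * ws[b], v))
            den = np.sqrt(np.dot(ws[a] ** 2, v) * np.dot(ws[b] ** 2, v))
            corr[a, b] = corr[b, a] = num / den
    z_max = float(np.max(np.abs(zs)))
    p = _max_abs_normal_pvalue(z_max, corr)
    return TestResult(
        variant, z_max, "max-trivariate-normal", p,
        details={"z_components": dict(zip(kept, map(float, zs))),
                 "correlation": corr},
    )


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------

def run_tests(
    data: SurvivalDataset,
    names=TEST_NAMES,
    permutations: int = 1000,
    grid=None,
    transform: str = "identity",
    seed=None,
    rng: np.random.Generator | None = None,
) -> dict:
    """Run several tests on one dataset, sharing intermediate computations.

    The risk table and pooled KM curve are built once; when both combined
    tests are requested they share a single permutation pass.  Returns a dict
    mapping test name to :class:`TestResult`.
    """
    names = list(names)
    unknown = set(names) - set(TEST_NAMES)
    if unknown:
        raise ValueError(f"unknown tests: {sorted(unknown)}")
    rng = _resolve_rng(rng, seed)
    table = build_risk_table(data)
    km = km_estimate(data, "pooled")
    out = {}
    for name in names:
        if name == "lr":
            out[name] = weighted_logrank(table, fh_weights(km, "lr"), "lr")
        elif name == "lre":
            out[name] = weighted_logrank(table, fh_weights(km, "early"), "lre")
        elif name == "lrl":
            out[name] = weighted_logrank(table, fh_weights(km, "late"), "lrl")
        elif name == "suplr":
            out[name] = sup_logrank(table)
        elif name == "joint":
            out[name] = joint_test(data, transform=transform)
        elif name in ("vwlr", "vwlr2"):
            out[name] = versatile_test(table, km, name)
    both = [n for n in ("combined", "wc") if n in names]
    if both:
        out.update(
            _combined_core(data, grid, permutations, rng, False, tuple(both))
        )
    return {n: out[n] for n in names}
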