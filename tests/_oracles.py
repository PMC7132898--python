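"""Independent brute-force oracles used by the test suite.

Everything here is written as naive per-subject / per-event-time loops, kept
deliberately separate from the package's vectorized implementations.
"""

import numpy as np


def risk_table_by_enumeration(time, event, arm):
    """Risk table rows by exhaustively scanning subjects at each event time."""
    time, event, arm = map(np.asarray, (time, event, arm))
    rows = []
    for t in sorted(set(time[event == 1])):
        at_risk = [i for i in range(len(time)) if time[i] >= t]
        rows.append(
            dict(
                t=t,
                n=len(at_risk),
                n1=sum(arm[i] for i in at_risk),
                d=sum(1 for i in at_risk if time[i] == t and event[i] == 1),
                d1=sum(arm[i] for i in at_risk if time[i] == t and event[i] == 1),
            )
        )
    return rows


def km_by_product_limit(time, event):
    """(times, survival) of the product-limit estimate, naive loops."""
    time, event = map(np.asarray, (time, event))
    out_t, out_s = [], []
    s = 1.0
    for t in sorted(set(time[event == 1])):
        n = int(np.sum(time >= t))
        d = int(np.sum((time == t) & (event == 1)))
        s *= 1.0 - d / n
        out_t.append(t)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


def weighted_logrank_by_summation(time, event, arm, weights_at):
    """U and V by per-event-time hypergeometric summation.

    ``weights_at`` maps each distinct event time to its weight.
    """
    u = v = 0.0
    for row in risk_table_by_enumeration(time, event, arm):
        w = weights_at[row["t"]]
        n, n1, d, d1 = row["n"], row["n1"], row["d"], row["d1"]
        u += w * (d1 - d * n1 / n)
        if n > 1:
            v += w * w * d * (n - d) * n1 * (n - n1) / (n * n * (n - 1))
    return u, v


def rmst_by_numeric_integration(km_times, km_surv, t_star, m=200_000):
    """Area under the KM step function by midpoint rule on a fine grid."""
    grid = np.linspace(0, t_star, m + 1)
    mid = 0.5 * (grid[:-1] + grid[1:])
    idx = np.searchsorted(km_times, mid, side="right")
    s = np.concatenate(([1.0], km_surv))[idx]
    return float(np.sum(s) * t_star / m)


def sup_brownian_mc(b, n_paths=1_000_000, n_steps=1024, seed=0, chunk=20_000):
    """Monte-Carlo P(sup |B| >= b) via random-walk approximation on [0, 1]."""
    rng = np.random.default_rng(seed)
    hits = 0
    done = 0
    while done < n_paths:
        k = min(chunk, n_paths - done)
        steps = rng.standard_normal((k, n_steps)) / np.sqrt(n_steps)
        m = np.max(np.abs(np.cumsum(steps, axis=1)), axis=1)
        hits += int(np.sum(m >= b))
        done += k
    return hits / n_paths


def max_abs_trivariate_mc(z, corr, n_draws=1_000_000, seed=0):
    """Monte-Carlo P(max_i |N_i| >= z) for MVN(0, corr)."""
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(corr + 1e-12 * np.eye(corr.shape[0]))
    x = rng.standard_normal((n_draws, corr.shape[0])) @ L.T
    return float(np.mean(np.max(np.abs(x), axis=1) >= z))


def combined_statistic_naive(time, event, arm, grid):
    """max(Cox score chi2, max RMST z^2) from scalar building blocks."""
    from nphtest.core import SurvivalDataset, build_risk_table, km_estimate, rmst
    from nphtest._cox import cox_score_chi2

    data = SurvivalDataset(time, event, arm)
    chi2 = cox_score_chi2(build_risk_table(data))
    best = 0.0
    for t_star in grid:
        r1 = _rmst_flat(data, 1, t_star)
        r0 = _rmst_flat(data, 0, t_star)
        var = r1[1] + r0[1]
        if var > 0:
            best = max(best, (r1[0] - r0[0]) ** 2 / var)
    return max(chi2, best)


def _rmst_flat(data, a, t_star):
    """Arm RMST with flat extension beyond the arm's last observation."""
    from nphtest.core import SurvivalDataset, km_estimate, rmst

    m = data.arm == a
    sub = SurvivalDataset(data.time[m], data.event[m], np.zeros(int(m.sum())))
    if sub.event.sum() == 0:
        return t_star, 0.0
    km = km_estimate(sub, "pooled")
    km = km.__class__(
        km.times, km.surv, km.left, km.n_at_risk, km.n_events,
        max(km.max_follow_up, t_star),
    )
    r = rmst(km, t_star)
    return r.estimate, r.variance
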