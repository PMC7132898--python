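"""One-covariate Cox partial likelihood machinery for the joint test.

The only covariate ever needed here is the binary arm indicator, so the
partial likelihood (Breslow handling of ties) collapses onto the risk table:
at event time t_j the risk set contains n1_j exposed and n0_j unexposed
subjects and the within-risk-set covariate mean at coefficient beta is
xbar_j = n1_j e^beta / (n1_j e^beta + n0_j).
"""

from __future__ import annotations

import numpy as np

from .core import KMCurve, RiskTable

__all__ = [
    "cox_score_chi2",
    "cox_fit_binary",
    "grambsch_therneau_chi2",
    "CoxConvergenceError",
]


class CoxConvergenceError(RuntimeError):
    """Raised when the one-parameter Cox fit does not converge."""


def _xbar(table: RiskTable, beta: float) -> np.ndarray:
    e = np.exp(beta)
    return table.n1 * e / (table.n1 * e + table.n0)


def cox_score_chi2(table: RiskTable) -> float:
    """Score (Rao) chi-square at beta=0 for the arm indicator, 1 df.

    U(0) is the logrank numerator; the information uses the Breslow
    (binomial, no finite-population correction) variance.
    """
    xbar = table.n1 / table.n
    u = float(np.sum(table.d1 - table.d * xbar))
    info = float(np.sum(table.d * xbar * (1.0 - xbar)))
    if info <= 0:
        raise ValueError("degenerate variance")
    return u * u / info


def cox_fit_binary(table: RiskTable, tol: float = 1e-10, max_iter: int = 50) -> float:
    """Newton-Raphson MLE of the log hazard ratio (Breslow ties).

    Raises :class:`CoxConvergenceError` on monotone likelihood (all events in
    one arm) or failure to converge.
    """
    d1 = int(table.d1.sum())
    d = int(table.d.sum())
    if d1 == 0 or d1 == d:
        raise CoxConvergenceError(
            "monotone partial likelihood: all events in one arm"
        )
    beta = 0.0
    for _ in range(max_iter):
        xbar = _xbar(table, beta)
        score = float(np.sum(table.d1 - table.d * xbar))
        info = float(np.sum(table.d * xbar * (1.0 - xbar)))
        if info <= 0:
            raise CoxConvergenceError("vanishing information")
        step = score / info
        beta += np.clip(step, -2.0, 2.0)  # damped; likelihood is concave
        if abs(beta) > 50:
            raise CoxConvergenceError("diverging coefficient")
        if abs(step) < tol:
            return beta
    raise CoxConvergenceError("Newton iteration did not converge")


def _transform_times(table: RiskTable, km: KMCurve | None, transform: str) -> np.ndarray:
    """Per-event-time transform g(t_j) used by the Grambsch-Therneau test."""
    if transform == "identity":
        return table.time.astype(float)
    if transform == "rank":
        return np.arange(1.0, table.n_times + 1.0)
    if transform == "km":
        if km is None:
            raise ValueError("km transform needs the pooled KM curve")
        return 1.0 - km.survival_at(table.time)
    raise ValueError(f"unknown transform {transform!r}")


def grambsch_therneau_chi2(
    table: RiskTable,
    beta: float,
    transform: str = "identity",
    km: KMCurve | None = None,
) -> float:
    """Global Grambsch-Therneau test of proportional hazards, 1 df.

    With per-event Schoenfeld residuals r_k = x_k - xbar(t_k), transformed
    event times g_k, and Vbar the mean per-event information at beta-hat,

        T = [sum_k (g_k - gbar) r_k]^2 / [Vbar * sum_k (g_k - gbar)^2],

    the score test for a linear time interaction assuming approximately
    constant per-event information.  Tied events at t_j contribute d1_j
    residuals (1 - xbar_j) and (d_j - d1_j) residuals (0 - xbar_j), so all
    sums collapse to per-event-time form.
    """
    d_tot = float(table.d.sum())
    g = _transform_times(table, km, transform)
    gbar = float(np.dot(table.d, g)) / d_tot
    xbar = _xbar(table, beta)
    # sum over events of (g_k - gbar) r_k and of (g_k - gbar)^2
    sr = float(np.dot(g - gbar, table.d1 - table.d * xbar))
    sg2 = float(np.dot(table.d, (g - gbar) ** 2))
    vbar = float(np.dot(table.d, xbar * (1.0 - xbar))) / d_tot
    if sg2 <= 0 or vbar <= 0:
        raise ValueError("degenerate Grambsch-Therneau denominator")
    return sr * sr / (vbar * sg2)
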