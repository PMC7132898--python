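"""Vectorized relabeling engine for the combined permutation tests.

The combined (C) and weighted combined (WC) tests refer the maximum of a
chi-square component and the maximal squared standardized RMST difference to
a permutation null obtained by relabeling arms.  Only the arm labels change
under relabeling: the pooled event times, total at-risk counts n_j and total
event counts d_j are fixed.  This lets all B relabelings be evaluated at once
with column-parallel cumulative sums: per column, n1_j and d1_j follow from
segment sums of the label vector ordered by time, and the per-arm
Kaplan-Meier curves / RMSTs follow from cumulative products on the shared
pooled event-time grid.

Evaluating the per-arm product-limit estimate on the pooled grid is exact:
times where an arm has no event contribute a factor 1 and a zero variance
term.  Beyond an arm's last observation its curve is extended flat, the usual
convention for RMST grids that may exceed a relabeled arm's follow-up.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .core import SurvivalDataset

__all__ = ["RelabelingEngine"]


class RelabelingEngine:
    """Precomputes time-ordered structure; evaluates statistics per relabeling."""

    def __init__(self, data: SurvivalDataset, grid: np.ndarray):
        order = np.argsort(data.time, kind="stable")
        self.time_s = data.time[order]
        self.event_s = data.event[order]
        self.arm_s = data.arm[order].astype(np.int64)
        self.n = data.n
        self.m1 = int(data.arm.sum())
        self.grid = np.asarray(grid, dtype=float)

        ev = self.event_s == 1
        self.tvals = np.unique(self.time_s[ev])
        r = self.tvals.size
        # first sorted index with time >= t_j: subjects from there on are at risk
        self.risk_idx = np.searchsorted(self.time_s, self.tvals, side="left")
        self.n_at = self.n - self.risk_idx
        self.ev_rows = np.flatnonzero(ev)
        grp = np.searchsorted(self.tvals, self.time_s[self.ev_rows])
        self.grp_starts = np.searchsorted(grp, np.arange(r))
        self.d = np.bincount(grp, minlength=r).astype(np.int64)
        # segment geometry for RMST at each grid point
        nxt = np.concatenate((self.tvals[1:], [np.inf]))
        self.widths = [
            np.clip(np.minimum(nxt, t) - self.tvals, 0.0, None) for t in self.grid
        ]
        self.head = [min(self.tvals[0], t) for t in self.grid]

    # -- label matrices ----------------------------------------------------
    def observed_labels(self) -> np.ndarray:
        return self.arm_s[:, None].copy()

    def random_labels(self, b: int, rng: np.random.Generator) -> np.ndarray:
        lab = np.tile(self.arm_s[:, None], (1, b))
        return rng.permuted(lab, axis=0)

    def exhaustive_labels(self) -> np.ndarray:
        """All distinct assignments of m1 research labels to the n subjects."""
        from math import comb

        if comb(self.n, self.m1) > 200_000:
            raise ValueError("too many label assignments to enumerate")
        cols = []
        for pos in combinations(range(self.n), self.m1):
            col = np.zeros(self.n, dtype=np.int64)
            col[list(pos)] = 1
            cols.append(col)
        return np.stack(cols, axis=1)

    # -- core counts -------------------------------------------------------
    def _counts(self, labels: np.ndarray):
        """n1_j, d1_j (r x B) for each label column."""
        seg = np.add.reduceat(labels, self.risk_idx, axis=0)
        # reduceat needs strictly handled duplicate starts: risk_idx is strictly
        # increasing because each distinct event time has at least one subject.
        before = np.cumsum(seg, axis=0) - seg  # labels with risk_idx[0]<=i<risk_idx[j]
        head = labels[: self.risk_idx[0], :].sum(axis=0) if self.risk_idx[0] else 0
        n1 = self.m1 - head - before
        d1 = np.add.reduceat(labels[self.ev_rows, :], self.grp_starts, axis=0)
        return n1.astype(float), d1.astype(float)

    @staticmethod
    def _arm_km_areas(da, na, head, wcol):
        """RMST and Greenwood variance per column for one arm's counts."""
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(da > 0, 1.0 - da / na, 1.0)
        s = np.cumprod(f, axis=0)
        seg = s * wcol
        a = np.cumsum(seg[::-1], axis=0)[::-1]
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = a * a * da / (na * (na - da))
        terms[(da <= 0) | (na <= da)] = 0.0
        return head + seg.sum(axis=0), terms.sum(axis=0)

    def _rmst_z2(self, n1, d1):
        """Squared standardized RMST differences, (len(grid) x B)."""
        n = self.n_at[:, None].astype(float)
        d = self.d[:, None].astype(float)
        out = []
        for head, w in zip(self.head, self.widths):
            wcol = w[:, None]
            r1, v1 = self._arm_km_areas(d1, n1, head, wcol)
            r0, v0 = self._arm_km_areas(d - d1, n - n1, head, wcol)
            diff = r1 - r0
            var = v1 + v0
            with np.errstate(divide="ignore", invalid="ignore"):
                z2 = np.where(var > 0, diff * diff / var, 0.0)
            out.append(z2)
        return np.stack(out, axis=0)

    def _wlr_chi2(self, n1, d1, w):
        """Weighted logrank chi-square per column for weight vector w (r,)."""
        n = self.n_at[:, None].astype(float)
        d = self.d[:, None].astype(float)
        wcol = w[:, None]
        u = (wcol * (d1 - d * n1 / n)).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            v = d * (n - d) * n1 * (n - n1) / (n * n * (n - 1.0))
        v[self.n_at <= 1] = 0.0
        vtot = (wcol * wcol * v).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = np.where(vtot > 0, u * u / vtot, 0.0)
        return chi2

    def statistics(self, labels: np.ndarray, lrl_weights: np.ndarray):
        """Per-column components: logrank chi2, LRL chi2, max RMST z^2."""
        n1, d1 = self._counts(labels)
        ones = np.ones(self.tvals.size)
        chi2_lr = self._wlr_chi2(n1, d1, ones)
        chi2_lrl = self._wlr_chi2(n1, d1, lrl_weights)
        z2 = self._rmst_z2(n1, d1)
        return {
            "chi2_cox": chi2_lr,
            "chi2_lrl": chi2_lrl,
            "z2_rmst": z2,
            "max_z2": z2.max(axis=0),
        }
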