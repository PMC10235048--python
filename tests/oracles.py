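"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the package's optimizer/hull code paths: the grid
searches evaluate the posterior on dense lattices, and the LP dip oracle
solves the exact "nearest unimodal cdf in sup norm" program per candidate
mode position with scipy's linear-programming backend.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


def _biv_logpost_grid(A, B, levels, k, n, prior_sd):
    # shape (len(A), len(B)); vectorized over the dEV levels
    eta = B[None, :, None] * (A[:, None, None] + levels[None, None, :])
    ll = -(k * np.logaddexp(0.0, -eta) + (n - k) * np.logaddexp(0.0, eta)).sum(axis=2)
    prior = -0.5 * (A[:, None] ** 2 + B[None, :] ** 2) / prior_sd ** 2
    return ll + prior


def grid_map_bivariate(choices, prior_sd: float = 5.0, span: float = 10.0,
                       coarse: float = 0.05, fine: float = 0.01,
                       refine_margin: float = 2.0) -> tuple[float, float]:
    """Argmax of the bivariate log posterior on a dense (a, b) lattice.

    A 0.05 coarse pass over [-span, span]^2 locates every near-optimal cell
    (within ``refine_margin`` log units); the bounding box of those cells is
    then evaluated at the full 0.01 resolution, and a final 0.001 pass
    around the 0.01 argmax resolves quantization along the soft (a, b)
    trade-off direction.  Posterior basins at 126 trials are far wider than
    the coarse step, so this finds the same optimum as a complete dense
    lattice.
    """
    levels = choices.levels
    k, n = choices.k_per_level, choices.n_per_level
    A = np.round(np.arange(-span, span + coarse / 2, coarse), 10)
    B = A.copy()
    lp = _biv_logpost_grid(A, B, levels, k, n, prior_sd)
    mask = lp >= lp.max() - refine_margin
    ia, ib = np.where(mask)
    a_lo, a_hi = A[ia.min()] - coarse, A[ia.max()] + coarse
    b_lo, b_hi = B[ib.min()] - coarse, B[ib.max()] + coarse
    Af = np.round(np.arange(max(a_lo, -span), min(a_hi, span) + fine / 2, fine), 10)
    Bf = np.round(np.arange(max(b_lo, -span), min(b_hi, span) + fine / 2, fine), 10)
    best_val, best_ab = -np.inf, (0.0, 0.0)
    chunk = max(1, int(4e6 / (len(Bf) * len(levels))))
    for s in range(0, len(Af), chunk):
        sub = _biv_logpost_grid(Af[s:s + chunk], Bf, levels, k, n, prior_sd)
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] > best_val:
            best_val = float(sub[i, j])
            best_ab = (float(Af[s + i]), float(Bf[j]))
    a0, b0 = best_ab
    Au = np.round(np.arange(a0 - 0.08, a0 + 0.08 + 5e-4, 0.001), 10)
    Bu = np.round(np.arange(b0 - 0.08, b0 + 0.08 + 5e-4, 0.001), 10)
    sub = _biv_logpost_grid(Au, Bu, levels, k, n, prior_sd)
    i, j = np.unravel_index(np.argmax(sub), sub.shape)
    return float(Au[i]), float(Bu[j])


def grid_map_univariate(choices, prior_sd: float = 5.0, span: float = 30.0,
                        step: float = 0.001) -> float:
    """Argmax of the univariate log posterior on a dense 1-D lattice."""
    C = np.arange(-span, span + step / 2, step)
    k, n = choices.k, choices.n
    ll = -(k * np.logaddexp(0.0, -C) + (n - k) * np.logaddexp(0.0, C))
    lp = ll - 0.5 * C ** 2 / prior_sd ** 2
    return float(C[np.argmax(lp)])


def lp_dip(values) -> float:
    """Exact dip via linear programming over all mode positions.

    Minimizes d subject to the existence of a cdf that is convex before and
    concave after the mode (an atom permitted at a data-point mode) and
    stays within d of the ecdf everywhere.
    """
    v = np.sort(np.asarray(values, dtype=float))
    x, counts = np.unique(v, return_counts=True)
    n = counts.sum()
    K = len(x)
    if K == 1:
        return 0.0
    F = np.cumsum(counts) / n
    Fm1 = np.concatenate(([0.0], F[:-1]))

    def solve(mode_kind: str, m: int) -> float:
        # variables: g_0..g_{K-1}, [ell (left limit at an atom mode)], d
        has_ell = mode_kind == "point"
        nv = K + (1 if has_ell else 0) + 1
        ell = K                       # index of the left-limit variable
        di = nv - 1                   # index of d
        A_ub: list[np.ndarray] = []
        b_ub: list[float] = []

        def band(idx, lo_val, hi_val):
            row = np.zeros(nv); row[idx] = -1; row[di] = -1
            A_ub.append(row); b_ub.append(-lo_val)
            row = np.zeros(nv); row[idx] = 1; row[di] = -1
            A_ub.append(row); b_ub.append(hi_val)

        for idx in range(K):
            if has_ell and idx == m:
                band(idx, F[idx], F[idx])   # the atom's top: |g_m - F_m| <= d
            else:
                band(idx, F[idx], Fm1[idx])
        if has_ell:
            band(ell, Fm1[m], Fm1[m])       # left limit: |ell - F(x_m^-)| <= d
            if m >= 1:                      # monotone into and out of the jump
                row = np.zeros(nv); row[m - 1] = 1; row[ell] = -1
                A_ub.append(row); b_ub.append(0.0)
            row = np.zeros(nv); row[ell] = 1; row[m] = -1
            A_ub.append(row); b_ub.append(0.0)
        for idx in range(K - 1):            # monotone
            row = np.zeros(nv); row[idx] = 1; row[idx + 1] = -1
            A_ub.append(row); b_ub.append(0.0)
        row = np.zeros(nv); row[0] = -1; A_ub.append(row); b_ub.append(0.0)
        row = np.zeros(nv); row[K - 1] = 1; A_ub.append(row); b_ub.append(1.0)

        def curvature(entries, sign):
            # entries: list of (variable index, x position)
            for t in range(len(entries) - 2):
                (v1, x1), (v2, x2), (v3, x3) = entries[t], entries[t + 1], entries[t + 2]
                d1, d2 = x2 - x1, x3 - x2
                row = np.zeros(nv)
                row[v1] += -sign / d1
                row[v2] += sign / d1 + sign / d2
                row[v3] += -sign / d2
                A_ub.append(row); b_ub.append(0.0)

        left = [(idx, x[idx]) for idx in range(m)]
        if has_ell:
            left = left + [(ell, x[m])]     # the left limit ends the convex piece
        curvature(left, 1.0)                # convex left of the mode
        curvature([(idx, x[idx]) for idx in range(m, K)], -1.0)  # concave after
        c = np.zeros(nv); c[di] = 1.0
        res = linprog(c, A_ub=np.array(A_ub), b_ub=np.array(b_ub),
                      bounds=[(None, None)] * (nv - 1) + [(0, None)], method="highs")
        return float(res.fun) if res.success else np.inf

    best = min(solve("segment", m) for m in range(K + 1))
    best = min(best, min(solve("point", m) for m in range(K)))
    return best
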