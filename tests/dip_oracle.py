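"""Exact small-n oracle for the dip statistic.

The dip of an empirical CDF F_n is the smallest half-width d such that some
continuous unimodal CDF G (convex up to its mode, concave after) stays within
d of F_n everywhere.  For a fixed mode location — at a sample point, or
strictly between two adjacent ones — feasibility is a linear program in the
values of G at the unique sample points:

* band constraints at interval endpoints (sufficient, G being monotone);
* convexity of the slopes left of the mode, concavity right of it;
* when the mode lies strictly between points k-1 and k, the bridging chord
  must rise at least as fast as both neighbouring segments (the function
  accelerates then decelerates inside the bridge);
* virtual anchor points far out on both sides pin G to 0 and 1, encoding the
  CDF limits.

Minimising d over all mode placements gives the exact dip.  Independent of
the greatest-convex-minorant / least-concave-majorant algorithm it is used to
verify; practical for n up to a few dozen.
"""

import numpy as np
from scipy.optimize import linprog


def _solve(u, chi, clo, k, mode_at_point):
    """LP for one mode placement; returns optimal d or inf if infeasible.

    Variables: g_-1 (left anchor), g_0..g_{m-1}, g_m (right anchor), d.
    ``k``: first index of the concave piece; with ``mode_at_point`` the point
    k belongs to both pieces, otherwise the mode lies in (u[k-1], u[k]).
    """
    m = len(u)
    width = (u[-1] - u[0]) * 1e4 + 1.0
    xs = np.concatenate([[u[0] - width], u, [u[-1] + width]])
    nv = m + 3  # anchors + points + d
    D = m + 2   # index of d variable

    a_ub, b_ub = [], []

    def le(coefs, rhs):  # sum coefs <= rhs
        r = np.zeros(nv)
        for idx, c in coefs:
            r[idx] += c  # accumulate: slope rows share their middle variable
        # normalise to unit max-norm so tie-broken (eps-scale) slope rows are
        # enforced at the same feasibility tolerance as band rows
        s = np.max(np.abs(r))
        a_ub.append(r / s)
        b_ub.append(rhs / s)

    # monotone over anchors + points (indices 0..m+1 in xs order)
    for j in range(m + 1):
        le([(j, 1.0), (j + 1, -1.0)], 0.0)
    # band constraints at sample points (variable j+1 is point j)
    for j in range(m):
        le([(j + 1, -1.0), (D, -1.0)], -chi[j])   # g_j >= chi_j - d
        le([(j + 1, 1.0), (D, -1.0)], clo[j])     # g_j <= clo_j + d

    def slope_pair(i):  # variable indices for segment xs[i] -> xs[i+1]
        return i, i + 1, xs[i + 1] - xs[i]

    def convex(i):  # slope(i-1 -> i) <= slope(i -> i+1), xs-indexed
        a0, a1, dl = slope_pair(i - 1)
        b0, b1, dr = slope_pair(i)
        # (g_a1-g_a0)/dl - (g_b1-g_b0)/dr <= 0  (scaled by dl*dr > 0)
        le([(a0, -dr), (a1, dr), (b0, dl), (b1, -dl)], 0.0)

    def concave(i):
        a0, a1, dl = slope_pair(i - 1)
        b0, b1, dr = slope_pair(i)
        le([(a0, dr), (a1, -dr), (b0, -dl), (b1, dl)], 0.0)

    # xs index of the first concave interior point / last convex interior point
    left_end = k + 1 if mode_at_point else k      # last xs-point of convex piece
    right_start = k + 1                            # first xs-point of concave piece
    for i in range(1, left_end):       # interior kinks of the convex piece
        convex(i)
    for i in range(right_start + 1, m + 1):  # interior kinks of the concave piece
        concave(i)
    if not mode_at_point:
        # bridge chord xs[k] -> xs[k+1] must outrun both adjacent segments
        convex(left_end)     # slope(k-1->k) <= chord slope
        concave(right_start)  # chord slope >= slope(k+1->k+2)... expressed below
        # note: convex(left_end) compares segment (left_end-1) with the chord;
        # concave(right_start) compares the chord with segment right_start.

    c = np.zeros(nv)
    c[D] = 1.0
    bounds = [(0.0, 0.0)] + [(0.0, 1.0)] * m + [(1.0, 1.0)] + [(0.0, None)]
    res = linprog(c, A_ub=np.array(a_ub), b_ub=np.array(b_ub), bounds=bounds,
                  method="highs")
    return res.fun if res.success else np.inf


def dip_lp(values: np.ndarray, tie_eps: float = 1e-6) -> float:
    """Exact dip by LP enumeration over mode placements.

    Tied observations are separated by an infinitesimal offset (``tie_eps``
    times the data range), matching the limit the hull-based algorithm
    computes; for tied samples the result is accurate to O(tie_eps).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n < 2 or x[0] == x[-1]:
        return 0.0
    rng = x[-1] - x[0]
    # break ties: add k*eps to the k-th member of each tie group
    u = x.copy()
    start = 0
    for j in range(1, n + 1):
        if j == n or x[j] != x[start]:
            if j - start > 1:
                u[start:j] += rng * tie_eps * np.arange(j - start)
            start = j
    chi = np.arange(1, n + 1) / n             # F_n on [u_j, u_{j+1})
    clo = np.arange(0, n) / n                 # F_n just left of u_j

    best = np.inf
    for k in range(n):
        best = min(best, _solve(u, chi, clo, k, True))
    for k in range(1, n):
        best = min(best, _solve(u, chi, clo, k, False))
    return float(best)
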