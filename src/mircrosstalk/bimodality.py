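"""Bimodality detection for single-cell expression distributions.

Near the titration threshold, strong miRNA repression splits the population
into distinct high- and low-expression states.  The primary statistic is
Hartigan & Hartigan's dip — the smallest sup-norm distance between the
empirical CDF and the class of unimodal CDFs — with a Monte-Carlo p-value
calibrated on the uniform null, which is the least favourable unimodal
distribution.  A KDE mode count (Silverman bandwidth) is reported as a
cross-check; the verdict combines both.

The dip statistic is computed by the greatest-convex-minorant /
least-concave-majorant interval-shrinking algorithm; the test suite verifies
it against an exact small-n oracle that minimises the sup-distance over
unimodal CDFs by linear programming.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

__all__ = ["BimodalityReport", "dip_statistic", "dip_pvalue",
           "kde_mode_count", "bimodality_test"]


@dataclass(frozen=True)
class BimodalityReport:
    statistic: float
    p_value: float
    n_modes: int
    verdict: bool
    level: float
    n: int


@njit(cache=True)
def _dip(x):
    """Dip statistic of a sorted sample (ascending, len >= 2, not constant).

    Works in scaled units of 2n*dip throughout; the minimum attainable dip is
    1/(2n).  Indices are 0-based; ``mn``/``mj`` hold the greatest-convex-
    minorant predecessor and least-concave-majorant successor of each point.
    """
    n = x.shape[0]

    mn = np.zeros(n, dtype=np.int64)
    for j in range(1, n):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 0 or (x[j] - x[mnj]) * (mnj - mnmnj) < (x[mnj] - x[mnmnj]) * (j - mnj):
                break
            mn[j] = mnmnj

    mj = np.zeros(n, dtype=np.int64)
    mj[n - 1] = n - 1
    for k in range(n - 2, -1, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            mjmjk = mj[mjk]
            if mjk == n - 1 or (x[k] - x[mjk]) * (mjk - mjmjk) < (x[mjk] - x[mjmjk]) * (k - mjk):
                break
            mj[k] = mjmjk

    low = 0
    high = n - 1
    dip = 1.0  # scaled: 2n * (1/(2n))

    gcm = np.zeros(n + 1, dtype=np.int64)
    lcm = np.zeros(n + 1, dtype=np.int64)

    while True:
        # change points of the GCM from high down to low, and LCM upward
        gcm[0] = high
        l_gcm = 1
        while gcm[l_gcm - 1] > low:
            gcm[l_gcm] = mn[gcm[l_gcm - 1]]
            l_gcm += 1
        lcm[0] = low
        l_lcm = 1
        while lcm[l_lcm - 1] < high:
            lcm[l_lcm] = mj[lcm[l_lcm - 1]]
            l_lcm += 1

        ix = l_gcm - 2
        iv = 1
        ig = l_gcm - 1
        ih = l_lcm - 1
        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            while True:
                gcm_ix = gcm[ix]
                lcm_iv = lcm[iv]
                if gcm_ix > lcm_iv:
                    # largest gap with the LCM point below the current GCM arc
                    gcm_i1 = gcm[ix + 1]
                    den = x[gcm_ix] - x[gcm_i1]
                    if den > 0.0:
                        dx = (lcm_iv - gcm_i1 + 1) - (x[lcm_iv] - x[gcm_i1]) * (gcm_ix - gcm_i1) / den
                    else:
                        dx = -1.0  # vertical arc from ties: no interior gap
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    # largest gap with the GCM point above the current LCM arc
                    lcm_i1 = lcm[iv - 1]
                    den = x[lcm_iv] - x[lcm_i1]
                    if den > 0.0:
                        dx = (x[gcm_ix] - x[lcm_i1]) * (lcm_iv - lcm_i1) / den - (gcm_ix - lcm_i1 - 1)
                    else:
                        dx = -1.0
                    ix -= 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 0:
                    ix = 0
                if iv > l_lcm - 1:
                    iv = l_lcm - 1
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0
        if d < dip:
            break

        # dip within the modal interval: deviation of F above the GCM arcs
        dip_l = 0.0
        for j in range(ig, l_gcm - 1):
            max_t = 1.0
            jb = gcm[j + 1]
            je = gcm[j]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (x[jj] - x[jb]) * c
                    if max_t < t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t

        # ... and of F below the LCM arcs
        dip_u = 0.0
        for j in range(ih, l_lcm - 1):
            max_t = 1.0
            jb = lcm[j]
            je = lcm[j + 1]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (x[jj] - x[jb]) * c - (jj - jb - 1)
                    if max_t < t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t

        dipnew = dip_l if dip_l > dip_u else dip_u
        if dip < dipnew:
            dip = dipnew
        if low == gcm[ig] and high == lcm[ih]:
            break
        low = gcm[ig]
        high = lcm[ih]

    return dip / (2.0 * n)


def dip_statistic(values: np.ndarray) -> float:
    """Hartigan dip statistic of a 1-D sample (ties allowed).

    Returns 0 for constant samples; otherwise a value in [1/(2n), 1/4].
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n < 1:
        raise ValueError("empty sample")
    if n == 1 or x[0] == x[-1]:
        return 0.0
    return float(_dip(x))


@njit(cache=True)
def _null_dips(n, n_boot, seed):
    np.random.seed(seed)
    out = np.empty(n_boot)
    for b in range(n_boot):
        u = np.sort(np.random.random(n))
        out[b] = _dip(u)
    return out


def dip_pvalue(values: np.ndarray, n_boot: int = 500, seed: int = 0,
               dither: bool = True) -> tuple[float, float]:
    """Dip statistic and its Monte-Carlo p-value under the uniform null.

    The uniform null calibrates the dip for continuous data; tied samples
    (molecule counts) inflate the statistic through their atoms alone.  With
    ``dither`` (default), tied samples are therefore spread by seeded one-
    sided uniform noise, x + U[0, h) with h the smallest observed spacing —
    the standard continuity randomisation for counts, which removes every
    atom while leaving genuine two-mode structure intact.

    p = (1 + #{null dips >= observed}) / (1 + n_boot), the add-one estimator,
    so p is never exactly 0.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2 or x.min() == x.max():
        return 0.0, 1.0
    rng = np.random.default_rng(seed)
    if dither and len(np.unique(x)) < n:
        gaps = np.diff(np.unique(x))
        h = gaps.min() if len(gaps) else 1.0
        x = x + rng.uniform(0.0, h, size=n)
    stat = dip_statistic(x)
    if stat == 0.0:
        return 0.0, 1.0
    null = _null_dips(n, n_boot, int(rng.integers(1, 2**31 - 1)))
    p = (1.0 + float(np.sum(null >= stat))) / (1.0 + n_boot)
    return stat, p


def kde_mode_count(values: np.ndarray, grid_size: int = 512,
                   prominence_frac: float = 0.05,
                   transform: str = "log1p") -> int:
    """Number of modes of a Gaussian KDE with Silverman's bandwidth.

    Non-negative expression data are examined on a log1p axis by default —
    the scale on which cytometry histograms are read and on which the high/low
    phenotypes of a titrating reporter separate; pass ``transform="linear"``
    to disable.  Peaks with prominence below ``prominence_frac`` of the
    density maximum are ignored so sampling ripples do not register as modes.
    """
    x = np.asarray(values, dtype=float)
    if transform == "log1p" and x.min() >= 0:
        x = np.log1p(x)
    if x.std() == 0:
        return 1
    kde = gaussian_kde(x, bw_method="silverman")
    lo, hi = x.min(), x.max()
    pad = 0.1 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, grid_size)
    dens = kde(grid)
    peaks, _ = find_peaks(dens, prominence=prominence_frac * dens.max())
    return max(1, len(peaks))


def bimodality_test(values: np.ndarray, level: float = 0.01,
                    n_boot: int = 500, seed: int = 0,
                    min_n: int = 500, transform: str = "log1p") -> BimodalityReport:
    """Dip test with KDE cross-check.

    Non-negative expression values are examined on the log1p axis (after
    dithering tied counts on the raw scale): the high/low phenotypes of a
    titrating reporter separate on the logarithmic scale on which expression
    histograms are conventionally read, while the linear-scale density of the
    off-state is a monotone tail.  Pass ``transform="linear"`` to test the
    raw values.

    The dip test is primary: the verdict is bimodal when its Monte-Carlo
    p-value falls below ``level``.  The KDE mode count is reported alongside
    as a descriptive cross-check (with few cells the KDE oversmooths heavily
    unbalanced mixtures that the dip still resolves).  Constant samples are
    unimodal with p = 1.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} values, got {len(x)}")
    if transform == "log1p" and len(x) and x.min() >= 0:
        rng = np.random.default_rng(seed + 1)
        y = x
        if x.max() > x.min() and len(np.unique(x)) < len(x):
            gaps = np.diff(np.unique(x))
            h = gaps.min()
            y = x + rng.uniform(0.0, h, size=len(x))
        stat, p = dip_pvalue(np.log1p(y), n_boot=n_boot, seed=seed,
                             dither=False)
    else:
        stat, p = dip_pvalue(x, n_boot=n_boot, seed=seed)
    modes = kde_mode_count(x)
    return BimodalityReport(
        statistic=float(stat),
        p_value=float(p),
        n_modes=int(modes),
        verdict=bool(p < level),
        level=float(level),
        n=len(x),
    )
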