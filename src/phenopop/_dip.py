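"""Hartigan & Hartigan dip statistic.

The dip of a sample is the maximum distance between its empirical CDF and
the nearest unimodal CDF.  It is computed by the classic iteration over
candidate modal intervals: fit the greatest convex minorant (GCM) of the
empirical CDF to the left of the current modal interval and the least
concave majorant (LCM) to the right, measure the largest discrepancy, and
shrink the interval until it stabilises.

The kernel works in "event count" units (empirical CDF steps of 1) and the
result is divided by 2n at the end, so the smallest attainable value is
1/(2n), reached by perfectly unimodal (e.g. constant) samples.

The hot loop is JIT-compiled with numba; p-values for the dip test are
Monte-Carlo (see :func:`phenopop.flow.dip_test`) and spend essentially all
their time in this kernel.
"""

from __future__ import annotations

import numpy as np


def _dip_sorted(x):  # pragma: no cover - compiled; exercised via dip_stat
    n = x.shape[0]
    if n < 2 or x[n - 1] == x[0]:
        return 1.0 / (2.0 * n)

    low = 0
    high = n - 1
    dip = 1.0  # count units; /(2n) on return

    mn = np.empty(n, dtype=np.int64)
    mj = np.empty(n, dtype=np.int64)
    gcm = np.empty(n + 1, dtype=np.int64)
    lcm = np.empty(n + 1, dtype=np.int64)

    while True:
        # GCM touch-point predecessors on [low, high]
        mn[low] = low
        for j in range(low + 1, high + 1):
            mn[j] = j - 1
            while True:
                mnj = mn[j]
                mnmnj = mn[mnj]
                if mnj == low or (
                    (x[j] - x[mnj]) * (mnj - mnmnj)
                    < (x[mnj] - x[mnmnj]) * (j - mnj)
                ):
                    break
                mn[j] = mnmnj
        # LCM touch-point successors on [low, high]
        mj[high] = high
        for k in range(high - 1, low - 1, -1):
            mj[k] = k + 1
            while True:
                mjk = mj[k]
                mjmjk = mj[mjk]
                if mjk == high or (
                    (x[k] - x[mjk]) * (mjk - mjmjk)
                    < (x[mjk] - x[mjmjk]) * (k - mjk)
                ):
                    break
                mj[k] = mjmjk

        # gcm[0..l_gcm] runs high -> low, lcm[0..l_lcm] runs low -> high
        i = 0
        gcm[0] = high
        while gcm[i] > low:
            gcm[i + 1] = mn[gcm[i]]
            i += 1
        l_gcm = i
        ix = l_gcm - 1
        ig = l_gcm

        i = 0
        lcm[0] = low
        while lcm[i] < high:
            lcm[i + 1] = mj[lcm[i]]
            i += 1
        l_lcm = i
        iv = 1
        ih = l_lcm

        # largest distance between the GCM and the LCM on [low, high]
        d = 0.0
        if l_gcm != 1 or l_lcm != 1:
            while True:
                gcm_ix = gcm[ix]
                lcm_iv = lcm[iv]
                if gcm_ix > lcm_iv:
                    # LCM touch point lies under the GCM chord
                    gcm_i1 = gcm[ix + 1]
                    dx = (lcm_iv - gcm_i1 + 1) - (
                        (x[lcm_iv] - x[gcm_i1])
                        * (gcm_ix - gcm_i1)
                        / (x[gcm_ix] - x[gcm_i1])
                    )
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    # GCM touch point lies above the LCM chord
                    lcm_i1 = lcm[iv - 1]
                    dx = (
                        (x[gcm_ix] - x[lcm_i1])
                        * (lcm_iv - lcm_i1)
                        / (x[lcm_iv] - x[lcm_i1])
                    ) - (gcm_ix - lcm_i1 - 1)
                    ix -= 1
                    if dx > d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 0:
                    ix = 0
                if iv > l_lcm:
                    iv = l_lcm
                if gcm[ix] == lcm[iv]:
                    break

        if d < dip:
            break

        # dip of the empirical CDF against the GCM on [low, gcm[ig]]
        dip_l = 0.0
        for j in range(ig, l_gcm):
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

        # dip of the empirical CDF against the LCM on [lcm[ih], high]
        dip_u = 0.0
        for j in range(ih, l_lcm):
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
        low = gcm[ig]
        high = lcm[ih]

    return dip / (2.0 * n)


def _dip_many_sorted(xs):  # pragma: no cover - compiled
    m = xs.shape[0]
    out = np.empty(m, dtype=np.float64)
    for i in range(m):
        out[i] = _dip_sorted(xs[i])
    return out


try:  # compile the kernels; the pure-Python path is a functional fallback
    from numba import njit

    _dip_sorted = njit(cache=False)(_dip_sorted)
    _dip_many_sorted = njit(cache=False)(_dip_many_sorted)
except ImportError:  # pragma: no cover
    pass


def dip_stat(x: np.ndarray) -> float:
    """Dip statistic of a 1-D sample (sorting handled here).

    Parameters
    ----------
    x
        Sample values; must be finite and contain at least one point.

    Returns
    -------
    float
        The dip, in [1/(2n), 1/4].
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("dip requires a non-empty 1-D sample")
    if not np.all(np.isfinite(x)):
        raise ValueError("dip requires finite sample values")
    return float(_dip_sorted(np.sort(x)))


def dip_stat_many(rows: np.ndarray) -> np.ndarray:
    """Dip statistic of each row of a 2-D array (used for Monte-Carlo nulls)."""
    rows = np.sort(np.asarray(rows, dtype=np.float64), axis=1)
    return np.asarray(_dip_many_sorted(np.ascontiguousarray(rows)))
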