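"""Numba inner loops for the per-signal hot paths.

The 600-trial pipeline evaluates sample entropy on ~3.4e4 signals of
1000 samples; the O(N^2) pair count is the dominant cost and lives here.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def sampen_counts_m2(x: np.ndarray, r: float) -> tuple[int, int]:
    """Fast path for embedding dimension m = 2.

    Iterates over template lags d = j - i; per lag the coordinate-wise
    tolerance tests are precomputed in one vectorisable pass, which avoids
    the branchy early-exit of the generic pair loop. Count-identical to
    sampen_counts(x, 2, r).
    """
    n = x.shape[0]
    b = 0
    a = 0
    c = np.empty(n, dtype=np.bool_)
    for d in range(1, n - 2):
        ub = n - 2 - d  # number of valid template starts at this lag
        if ub <= 0:
            break
        for t in range(ub + 2):
            c[t] = abs(x[t] - x[t + d]) <= r
        for i in range(ub):
            if c[i] and c[i + 1]:
                b += 1
                if c[i + 2]:
                    a += 1
    return a, b


@njit(cache=True)
def sampen_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Template-match pair counts (B at length m, A at length m+1).

    Counts unordered pairs i < j over the N - m templates
    x[i:i+m], using the Chebyshev distance and tolerance r.
    A pair matching at length m is extended by one sample to test
    the length-(m+1) match, so A <= B by construction.
    """
    n = x.shape[0]
    n_templates = n - m
    b = 0
    a = 0
    for i in range(n_templates - 1):
        for j in range(i + 1, n_templates):
            match = True
            for k in range(m):
                if abs(x[i + k] - x[j + k]) > r:
                    match = False
                    break
            if match:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return a, b


@njit(cache=True)
def local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Interior strict local extrema with plateau collapsing.

    A plateau of equal samples flanked by opposite slopes yields a single
    extremum at the plateau midpoint (rounded down). Endpoints are never
    extrema. Returns (indices, kinds) with kind +1 for maxima, -1 minima.
    """
    n = x.shape[0]
    idx = np.empty(n, dtype=np.int64)
    kind = np.empty(n, dtype=np.int64)
    count = 0
    prev_sign = 0  # sign of the last nonzero slope seen
    prev_pos = -1  # index of that slope (x[prev_pos] -> x[prev_pos+1])
    for i in range(n - 1):
        d = x[i + 1] - x[i]
        if d == 0.0:
            continue
        s = 1 if d > 0.0 else -1
        if prev_sign != 0 and s != prev_sign:
            # plateau spans x[prev_pos+1 .. i], all equal
            idx[count] = (prev_pos + 1 + i) // 2
            kind[count] = prev_sign  # rising->falling = max
            count += 1
        prev_sign = s
        prev_pos = i
    return idx[:count], kind[:count]


@njit(cache=True)
def itd_baseline_knots(
    tau: np.ndarray, xv: np.ndarray, alpha: float
) -> np.ndarray:
    """Baseline knot values at the extrema positions.

    tau/xv include the virtual boundary knots (first and last sample);
    the boundary knots keep the signal value, interior knots follow the
    alpha-contraction toward the chord of their neighbours.
    """
    nk = tau.shape[0]
    lk = np.empty(nk, dtype=np.float64)
    lk[0] = xv[0]
    lk[nk - 1] = xv[nk - 1]
    for j in range(1, nk - 1):
        chord = xv[j - 1] + (
            (tau[j] - tau[j - 1]) / (tau[j + 1] - tau[j - 1])
        ) * (xv[j + 1] - xv[j - 1])
        lk[j] = alpha * chord + (1.0 - alpha) * xv[j]
    return lk


@njit(cache=True)
def itd_baseline_fill(
    x: np.ndarray, tau: np.ndarray, xv: np.ndarray, lk: np.ndarray
) -> np.ndarray:
    """Piecewise baseline between knots.

    On each segment (tau_k, tau_{k+1}] the baseline is the affine image of
    the (monotone) signal onto [L_k, L_{k+1}]; a flat segment, where the
    signal contraction denominator vanishes, falls back to linear
    interpolation in time.
    """
    n = x.shape[0]
    out = np.empty(n, dtype=np.float64)
    out[0] = lk[0]
    for k in range(tau.shape[0] - 1):
        t0 = tau[k]
        t1 = tau[k + 1]
        dx = xv[k + 1] - xv[k]
        if abs(dx) > 1e-12:
            scale = (lk[k + 1] - lk[k]) / dx
            for t in range(t0 + 1, t1 + 1):
                out[t] = lk[k] + scale * (x[t] - xv[k])
        else:
            dt = t1 - t0
            for t in range(t0 + 1, t1 + 1):
                out[t] = lk[k] + (lk[k + 1] - lk[k]) * (t - t0) / dt
    return out
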