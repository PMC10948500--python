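"""Intrinsic time-scale decomposition (ITD).

ITD iteratively splits a signal X_t into a piecewise-defined low-frequency
baseline L_t and a high-frequency proper rotation component (PRC)
H_t = X_t - L_t. The baseline is built between successive local extrema
tau_k: its knot value at each interior extremum is an alpha-contraction of
the extremum toward the chord joining its two neighbours,

    L_{k+1} = alpha * [X_k + ((tau_{k+1}-tau_k)/(tau_{k+2}-tau_k))
                       * (X_{k+2}-X_k)] + (1-alpha) * X_{k+1},

with 0 < alpha < 1 (alpha = 1/2 by default), and between knots L_t is the
affine image of the (monotone) signal segment onto the knot interval.
Iterating on successive baselines yields ordered PRCs from highest to
lowest frequency plus a final monotonic trend, with exact additive
reconstruction: X = sum_j H^(j) + L^(D).

The baseline is only defined between extrema, so virtual extrema carrying
the signal values are pinned at the first and last samples; this keeps the
decomposition exact at the boundaries. Iteration stops when the current
baseline has fewer than ``min_extrema`` interior extrema (it is then the
monotonic trend) or when ``max_components`` PRCs have been extracted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import itd_baseline_fill, itd_baseline_knots, local_extrema

__all__ = [
    "ITDParams",
    "ExtremaList",
    "ITDLevel",
    "ITDDecomposition",
    "find_local_extrema",
    "compute_baseline",
    "itd_step",
    "itd_decompose",
    "reconstruct",
    "prc_energy_spectrum",
]


@dataclass(frozen=True)
class ITDParams:
    """Decomposition controls.

    alpha : baseline contraction factor in (0, 1); 0.5 is the customary
        choice and the default.
    max_components : hard cap on the number of PRCs extracted.
    min_extrema : minimum number of interior extrema a signal needs for
        another decomposition level; below it the signal is treated as the
        final monotonic trend.
    """

    alpha: float = 0.5
    max_components: int = 10
    min_extrema: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            # alpha = 0 is allowed only through compute_baseline directly
            # (degenerate: the PRC vanishes at interior knots).
            raise ValueError(f"alpha must lie in (0, 1); got {self.alpha}")
        if self.max_components < 1:
            raise ValueError("max_components must be >= 1")
        if self.min_extrema < 1:
            raise ValueError("min_extrema must be >= 1")


@dataclass(frozen=True)
class ExtremaList:
    """Interior strict local extrema of a signal.

    ``indices`` are strictly increasing 0-based positions tau_k, ``values``
    the signal values there, and ``kinds`` +1/-1 flags for maxima/minima,
    which strictly alternate.
    """

    indices: np.ndarray
    values: np.ndarray
    kinds: np.ndarray

    def __len__(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class ITDLevel:
    """One decomposition level: input = baseline + prc, elementwise."""

    baseline: np.ndarray
    prc: np.ndarray
    terminal: bool


@dataclass(frozen=True)
class ITDDecomposition:
    """Ordered PRCs (highest frequency first) plus the final baseline."""

    prcs: list[np.ndarray]
    final_baseline: np.ndarray
    params: ITDParams = field(default_factory=ITDParams)

    @property
    def n_components(self) -> int:
        return len(self.prcs)


def _validate_signal(x, min_len: int = 2) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError(f"signal must be 1-D; got shape {x.shape}")
    if x.size < min_len:
        raise ValueError(f"signal must have at least {min_len} samples; got {x.size}")
    return x


def find_local_extrema(signal) -> ExtremaList:
    """All interior strict local extrema of a signal.

    Plateaus of equal samples flanked by opposite slopes yield a single
    extremum at the plateau midpoint (rounded down); endpoints are never
    extrema.
    """
    x = _validate_signal(signal, min_len=3)
    idx, kinds = local_extrema(x)
    return ExtremaList(indices=idx, values=x[idx], kinds=kinds)


def compute_baseline(signal, extrema: ExtremaList, alpha: float = 0.5) -> np.ndarray:
    """Piecewise ITD baseline over the full signal support.

    Knot values at the interior extrema follow the alpha-contraction toward
    the neighbour chord; virtual boundary knots at the first and last sample
    keep the signal values there. Between knots the baseline is the affine
    image of the monotone signal segment (a near-flat segment, where the
    contraction denominator is below 1e-12, degrades to linear interpolation
    of its knots). Requires at least 3 extrema.
    """
    x = _validate_signal(signal, min_len=3)
    if len(extrema) < 3:
        raise ValueError(
            f"baseline needs >= 3 interior extrema; got {len(extrema)} "
            "(terminal decomposition level)"
        )
    if not 0.0 <= alpha < 1.0:
        raise ValueError(f"alpha must lie in [0, 1); got {alpha}")
    tau = extrema.indices
    if tau[0] != 0:
        tau = np.concatenate(([0], tau))
    if tau[-1] != x.size - 1:
        tau = np.concatenate((tau, [x.size - 1]))
    xv = x[tau]
    knots = itd_baseline_knots(tau, xv, float(alpha))
    return itd_baseline_fill(x, tau, xv, knots)


def itd_step(signal, params: ITDParams | None = None) -> ITDLevel:
    """Extract one (baseline, PRC) pair.

    When the signal has fewer than ``min_extrema`` interior extrema it is
    already the monotonic trend: the level is flagged terminal with the
    signal as its own baseline and a zero PRC.
    """
    params = params or ITDParams()
    x = _validate_signal(signal, min_len=2)
    if x.size >= 3:
        extrema = find_local_extrema(x)
    else:
        extrema = None
    if extrema is None or len(extrema) < params.min_extrema:
        return ITDLevel(baseline=x.copy(), prc=np.zeros_like(x), terminal=True)
    baseline = compute_baseline(x, extrema, params.alpha)
    return ITDLevel(baseline=baseline, prc=x - baseline, terminal=False)


def itd_decompose(signal, params: ITDParams | None = None) -> ITDDecomposition:
    """Full ITD of a signal into PRCs plus a final monotonic baseline."""
    params = params or ITDParams()
    x = _validate_signal(signal, min_len=2)
    if not np.isfinite(x).all():
        raise ValueError("signal contains non-finite samples")
    prcs: list[np.ndarray] = []
    current = x
    while len(prcs) < params.max_components:
        level = itd_step(current, params)
        if level.terminal:
            break
        prcs.append(level.prc)
        current = level.baseline
    return ITDDecomposition(prcs=prcs, final_baseline=current.copy(), params=params)


def reconstruct(decomp: ITDDecomposition) -> np.ndarray:
    """Elementwise sum of all PRCs and the final baseline."""
    out = decomp.final_baseline.copy()
    for prc in decomp.prcs:
        out += prc
    return out


def prc_energy_spectrum(prc):
    """Periodogram of a PRC, for component-selection diagnostics.

    Thin wrapper over :func:`itdeeg.features.periodogram_psd`; PRC1 shows
    the highest spectral content and successive PRCs shift downward.
    """
    from .features import periodogram_psd

    return periodogram_psd(prc)


def get_prcs(decomp: ITDDecomposition, n: int) -> tuple[np.ndarray, bool]:
    """First ``n`` PRCs stacked as (n, N); zero-pads when the decomposition
    is shallower than requested. Returns (array, padded_flag)."""
    size = decomp.final_baseline.size
    out = np.zeros((n, size))
    avail = min(n, decomp.n_components)
    for j in range(avail):
        out[j] = decomp.prcs[j]
    return out, avail < n
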