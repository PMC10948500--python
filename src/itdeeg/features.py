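"""Per-signal features and trial-level feature matrices.

Ten features are computed per signal (a raw EEG channel or one of its
proper rotation components):

* mean value,
* total spectral power  S_T = sum_k S(w_k)  from the full two-sided
  periodogram  S(w_k) = |DFT(x)[k]|^2 / N,  w_k = 2*pi*k/N  (rad/sample),
* spectral moments  M_p = sum_k w_k^p S(w_k),  p = 1..4,
* Hjorth activity (sample variance), mobility (SD of the first difference
  over SD of the signal) and complexity (mobility of the first difference
  over mobility of the signal),
* Richman-Moorman sample entropy  -ln(A/B)  with Chebyshev distance,
  tolerance r * SD, self-matches excluded.

A trial's feature vector concatenates these over channels and the chosen
component selection (single PRCs, PRC combinations, or the raw EEG signal),
channel-major with a fixed feature-kind order, giving
10 * n_channels * n_components columns.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import itd as _itd
from ._kernels import sampen_counts, sampen_counts_m2
from .epochs import EpochSet

__all__ = [
    "FEATURE_KINDS",
    "PRC_SELECTIONS",
    "EntropyParams",
    "SpectralDensity",
    "FeatureMatrix",
    "UndefinedFeatureError",
    "mean_value",
    "periodogram_psd",
    "total_power",
    "spectral_moment",
    "hjorth_activity",
    "hjorth_mobility",
    "hjorth_complexity",
    "sample_entropy",
    "signal_features",
    "extract_trial_features",
    "build_feature_matrix",
    "subset_selection",
]

FEATURE_KINDS = (
    "mean",
    "power",
    "M1",
    "M2",
    "M3",
    "M4",
    "activity",
    "mobility",
    "complexity",
    "sampen",
)

# Component selections: the first three PRCs singly and in combination,
# plus the raw EEG channel without decomposition.
PRC_SELECTIONS: dict[str, tuple[str, ...]] = {
    "PRC1": ("PRC1",),
    "PRC2": ("PRC2",),
    "PRC3": ("PRC3",),
    "PRCs1-2": ("PRC1", "PRC2"),
    "PRCs1-3": ("PRC1", "PRC3"),
    "PRCs2-3": ("PRC2", "PRC3"),
    "PRCs1-to-3": ("PRC1", "PRC2", "PRC3"),
    "EEG": ("EEG",),
}


class UndefinedFeatureError(ValueError):
    """A feature is undefined for this input (e.g. zero-variance signal)."""


@dataclass(frozen=True)
class EntropyParams:
    """Sample-entropy controls: embedding dimension m and tolerance r as a
    fraction of the signal standard deviation."""

    m: int = 2
    r: float = 0.2

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.r <= 0:
            raise ValueError("tolerance fraction r must be > 0")


@dataclass(frozen=True)
class SpectralDensity:
    """Two-sided periodogram: w_k = 2*pi*k/N in radians/sample and the
    non-negative density S(w_k), k = 0..N-1."""

    frequencies: np.ndarray
    density: np.ndarray


def _as_1d(x, min_len: int = 1) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError(f"signal must be 1-D; got shape {x.shape}")
    if x.size < min_len:
        raise ValueError(f"signal must have at least {min_len} samples; got {x.size}")
    return x


def mean_value(signal) -> float:
    """Arithmetic mean of the samples."""
    return float(np.mean(_as_1d(signal, 1)))


def periodogram_psd(signal, one_sided: bool = False) -> SpectralDensity:
    """Full two-sided periodogram S(w_k) = |DFT(x)[k]|^2 / N.

    Rectangular window, no detrending, all N bins; with this normalisation
    sum_k S(w_k) equals sum_n x[n]^2 (Parseval). ``one_sided=True`` folds
    the spectrum onto 0..pi (doubling the interior bins); the default
    two-sided form is what the feature sums use.
    """
    x = _as_1d(signal, 2)
    n = x.size
    spec = np.abs(np.fft.fft(x)) ** 2 / n
    w = 2.0 * np.pi * np.arange(n) / n
    if one_sided:
        half = n // 2 + 1
        folded = spec[:half].copy()
        folded[1 : (n + 1) // 2] *= 2.0
        return SpectralDensity(frequencies=w[:half], density=folded)
    return SpectralDensity(frequencies=w, density=spec)


def total_power(signal) -> float:
    """Total spectral power S_T: the periodogram summed over all N bins."""
    return float(periodogram_psd(signal).density.sum())


def spectral_moment(signal, order: int) -> float:
    """Spectral moment M_p = sum_k w_k^p S(w_k), p in 1..4."""
    if order not in (1, 2, 3, 4):
        raise ValueError(f"moment order must be in 1..4; got {order}")
    sd = periodogram_psd(signal)
    return float(np.sum(sd.frequencies**order * sd.density))


def _act(x: np.ndarray) -> float:
    return float(np.var(x, ddof=1))


def hjorth_activity(signal, autocorr: bool = False) -> float:
    """Hjorth activity: the sample variance (N-1 denominator)."""
    x = _as_1d(signal, 2)
    if autocorr:
        x = _autocorrelation(x)
    return _act(x)


def _autocorrelation(x: np.ndarray) -> np.ndarray:
    # biased autocorrelation sequence at lags 0..N-1
    n = x.size
    return np.correlate(x, x, mode="full")[n - 1 :] / n


def hjorth_mobility(signal, autocorr: bool = False) -> float:
    """Hjorth mobility: SD of the first difference over SD of the signal.

    The first difference stands in for the derivative; the sampling
    interval cancels in the ratio.
    """
    x = _as_1d(signal, 3)
    if autocorr:
        x = _autocorrelation(x)
    a = _act(x)
    if a <= 0.0:
        raise UndefinedFeatureError("mobility undefined: zero activity")
    return float(np.sqrt(_act(np.diff(x)) / a))


def hjorth_complexity(signal, autocorr: bool = False) -> float:
    """Hjorth complexity: mobility of the first difference over mobility of
    the signal; ~1 for a pure sinusoid, larger for broadband signals."""
    x = _as_1d(signal, 4)
    if autocorr:
        x = _autocorrelation(x)
    a = _act(x)
    if a <= 0.0:
        raise UndefinedFeatureError("complexity undefined: zero activity")
    d = np.diff(x)
    ad = _act(d)
    if ad <= 0.0:
        raise UndefinedFeatureError("complexity undefined: zero mobility")
    return float(np.sqrt(_act(np.diff(d)) / ad) / np.sqrt(ad / a))


def sample_entropy(signal, params: EntropyParams | None = None) -> float:
    """Richman-Moorman sample entropy -ln(A/B).

    B counts unordered template pairs of length m within Chebyshev distance
    r * SD(signal); A counts the same pairs extended to length m + 1.
    Self-matches are excluded. A constant signal returns 0 (every template
    matches at both lengths); zero matches at length m + 1 return +inf.
    """
    params = params or EntropyParams()
    x = _as_1d(signal, params.m + 2)
    if not np.isfinite(x).all():
        raise ValueError("signal contains non-finite samples")
    sd = float(np.std(x))
    if sd == 0.0:
        return 0.0
    r = params.r * sd
    if params.m == 2:
        a, b = sampen_counts_m2(x, r)
    else:
        a, b = sampen_counts(x, params.m, r)
    if b == 0 or a == 0:
        return float("inf")
    return float(-np.log(a / b))


def signal_features(
    x: np.ndarray, entropy_params: EntropyParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """The ten features of one signal, plus per-feature undefined flags.

    Undefined features (mobility/complexity of a zero-variance signal,
    infinite sample entropy) are emitted as 0 with their flag set, so a
    degenerate channel never aborts a matrix build.
    """
    x = _as_1d(x, 4)
    vals = np.zeros(len(FEATURE_KINDS))
    flags = np.zeros(len(FEATURE_KINDS), dtype=bool)
    n = x.size
    spec = np.abs(np.fft.fft(x)) ** 2 / n
    w = 2.0 * np.pi * np.arange(n) / n
    vals[0] = x.mean()
    vals[1] = spec.sum()
    for p in (1, 2, 3, 4):
        vals[1 + p] = np.sum(w**p * spec)
    act = _act(x)
    vals[6] = act
    if act > 0.0:
        d = np.diff(x)
        ad = _act(d)
        mob = np.sqrt(ad / act)
        vals[7] = mob
        if ad > 0.0:
            vals[8] = np.sqrt(_act(np.diff(d)) / ad) / mob
        else:
            flags[8] = True
    else:
        flags[7] = True
        flags[8] = True
    se = sample_entropy(x, entropy_params)
    if np.isfinite(se):
        vals[9] = se
    else:
        flags[9] = True
    return vals, flags


@dataclass
class FeatureMatrix:
    """Trials x named features with class labels.

    Columns are named ``<channel>|<component>|<kind>`` in deterministic
    channel-major order. ``flags`` marks cells whose feature was undefined
    and emitted as 0; ``row_flags`` marks trials whose decomposition was
    shallower than the selection required (missing PRCs zero-padded).
    """

    values: pd.DataFrame
    labels: np.ndarray
    selection: str
    flags: np.ndarray
    row_flags: np.ndarray
    subject_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.values) != len(self.labels):
            raise ValueError("labels length must match row count")
        if self.subject_ids is None:
            self.subject_ids = np.ones(len(self.labels), dtype=np.int64)

    @property
    def n_trials(self) -> int:
        return len(self.values)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)

    def take(self, index: np.ndarray) -> "FeatureMatrix":
        index = np.asarray(index)
        return FeatureMatrix(
            values=self.values.iloc[index].reset_index(drop=True),
            labels=self.labels[index],
            selection=self.selection,
            flags=self.flags[index],
            row_flags=self.row_flags[index],
            subject_ids=self.subject_ids[index],
        )

    def to_tsv(self, path) -> None:
        """Tab-delimited round-trip format: label column then feature
        columns named channel|component|kind."""
        df = self.values.copy()
        df.insert(0, "label", self.labels)
        df.insert(1, "subject", self.subject_ids)
        with open(path, "w") as fh:
            fh.write(f"# selection={self.selection}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "FeatureMatrix":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("# selection="):
                raise ValueError("feature table missing selection header line")
            selection = header.strip().split("=", 1)[1]
            df = pd.read_csv(_io.StringIO(fh.read()), sep="\t")
        labels = df.pop("label").to_numpy(dtype=np.int64)
        subjects = df.pop("subject").to_numpy(dtype=np.int64)
        n, f = df.shape
        return cls(
            values=df,
            labels=labels,
            selection=selection,
            flags=np.zeros((n, f), dtype=bool),
            row_flags=np.zeros(n, dtype=bool),
            subject_ids=subjects,
        )


def _column_names(
    channel_names: list[str], components: tuple[str, ...]
) -> list[str]:
    return [
        f"{ch}|{comp}|{kind}"
        for ch in channel_names
        for comp in components
        for kind in FEATURE_KINDS
    ]


def extract_trial_features(
    trial: np.ndarray,
    selection: str,
    itd_params: _itd.ITDParams | None = None,
    entropy_params: EntropyParams | None = None,
    channel_names: list[str] | None = None,
) -> tuple[np.ndarray, list[str], np.ndarray, bool]:
    """Feature vector of one trial (channels x samples).

    For the ``EEG`` selection the ten features are computed on each raw
    channel; otherwise each channel is ITD-decomposed and the features are
    computed on each selected PRC. Returns (values, names, flags,
    row_flag); row_flag is set when any channel yielded fewer PRCs than the
    selection needs (missing components are zero signals).
    """
    if selection not in PRC_SELECTIONS:
        raise ValueError(
            f"unknown selection {selection!r}; choose from {sorted(PRC_SELECTIONS)}"
        )
    trial = np.asarray(trial, dtype=np.float64)
    if trial.ndim != 2:
        raise ValueError("trial must be 2-D (channels, samples)")
    components = PRC_SELECTIONS[selection]
    n_ch = trial.shape[0]
    channel_names = channel_names or _default_names(n_ch)
    itd_params = itd_params or _itd.ITDParams()
    nk = len(FEATURE_KINDS)
    values = np.empty(n_ch * len(components) * nk)
    flags = np.zeros_like(values, dtype=bool)
    row_flag = False
    pos = 0
    if components == ("EEG",):
        for ch in range(n_ch):
            v, f = signal_features(trial[ch], entropy_params)
            values[pos : pos + nk] = v
            flags[pos : pos + nk] = f
            pos += nk
    else:
        need = max(int(c[3:]) for c in components)  # highest PRC index used
        for ch in range(n_ch):
            decomp = _itd.itd_decompose(trial[ch], itd_params)
            prcs, padded = _itd.get_prcs(decomp, need)
            row_flag = row_flag or padded
            for comp in components:
                v, f = signal_features(prcs[int(comp[3:]) - 1], entropy_params)
                values[pos : pos + nk] = v
                flags[pos : pos + nk] = f
                pos += nk
    return values, _column_names(channel_names, components), flags, row_flag


def _default_names(n: int) -> list[str]:
    return [f"ch{i + 1:02d}" for i in range(n)]


def build_feature_matrix(
    epochs: EpochSet,
    selection: str,
    itd_params: _itd.ITDParams | None = None,
    entropy_params: EntropyParams | None = None,
) -> FeatureMatrix:
    """Feature matrix of a whole epoch set for one component selection.

    Row order preserves trial order; labels and subject ids are carried
    through; the result is deterministic for identical inputs.
    """
    names = None
    rows = np.empty((epochs.n_trials, 0))
    flags = None
    row_flags = np.zeros(epochs.n_trials, dtype=bool)
    for t in range(epochs.n_trials):
        v, nm, f, rf = extract_trial_features(
            epochs.data[t], selection, itd_params, entropy_params, epochs.channel_names
        )
        if names is None:
            names = nm
            rows = np.empty((epochs.n_trials, len(nm)))
            flags = np.zeros((epochs.n_trials, len(nm)), dtype=bool)
        rows[t] = v
        flags[t] = f
        row_flags[t] = rf
    df = pd.DataFrame(rows, columns=names)
    return FeatureMatrix(
        values=df,
        labels=epochs.labels.copy(),
        selection=selection,
        flags=flags,
        row_flags=row_flags,
        subject_ids=epochs.subject_ids.copy(),
    )


def subset_selection(matrix: FeatureMatrix, selection: str) -> FeatureMatrix:
    """Column subset of a matrix built with a superset selection.

    Lets a single ``PRCs1-to-3`` build serve all single-PRC and pairwise
    selections without re-decomposing.
    """
    wanted = set(PRC_SELECTIONS[selection])
    have = set(PRC_SELECTIONS[matrix.selection])
    if not wanted <= have:
        raise ValueError(
            f"selection {selection!r} is not a subset of matrix selection "
            f"{matrix.selection!r}"
        )
    keep = [
        i for i, c in enumerate(matrix.columns) if c.split("|")[1] in wanted
    ]
    return FeatureMatrix(
        values=matrix.values.iloc[:, keep],
        labels=matrix.labels,
        selection=selection,
        flags=matrix.flags[:, keep],
        row_flags=matrix.row_flags.copy(),
        subject_ids=matrix.subject_ids,
    )
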