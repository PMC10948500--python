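"""Synthetic 6-class EEG epoch generator.

Emulates the study geometry — 19 channels at 1000 Hz, 1-second action
epochs, 100 trials per class, six classes, one or more subjects — with
class-dependent band-limited oscillatory content over a 1/f background:

* background: per-channel independent Gaussian 1/f^beta noise (beta = 1 by
  default), unit standard deviation before filtering;
* classes 1-5 add an amplitude-modulated sinusoid (random frequency inside
  a 4 Hz band centred at 8/12/16/20/24 Hz, random phase, raised-cosine
  envelope) on an overlapping 4-channel subset, with RMS equal to
  snr * amplitude times the background RMS. The band centres mimic mu/beta
  motor-band modulation and the overlapping subsets keep the classes
  confusable;
* class 6 is the no-mental-task (NoMT) condition: background only.

Every trial is then band-pass filtered 0.53-100 Hz and notch filtered at
50 Hz with zero-phase filters, emulating the hardware filtering of the
recording chain without phase distortion. Generation is fully reproducible
per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .epochs import EpochSet

__all__ = [
    "ClassProfile",
    "SyntheticConfig",
    "generate_epoch_set",
    "generate_null_set",
    "spectral_ground_truth",
]


@dataclass(frozen=True)
class ClassProfile:
    """Oscillatory signature of one class: a band-limited sinusoid on a
    channel subset. An empty channel tuple means background only."""

    center_hz: float
    bandwidth_hz: float
    channels: tuple[int, ...]
    amplitude: float = 1.0


def _default_profiles() -> tuple[ClassProfile, ...]:
    # classes 1-5: 4 Hz bands at 8..24 Hz on overlapping 4-channel subsets;
    # class 6 (NoMT): background only
    centers = (8.0, 12.0, 16.0, 20.0, 24.0)
    subsets = tuple(tuple(range(3 * i, 3 * i + 4)) for i in range(5))
    # modulation depth 0.3: movement-band oscillations ride on an ongoing
    # background an order of magnitude stronger in broadband power, which
    # keeps the decoding problem non-trivial like real motor imagery
    profiles = tuple(
        ClassProfile(center_hz=c, bandwidth_hz=4.0, channels=s, amplitude=0.3)
        for c, s in zip(centers, subsets)
    )
    return profiles + (ClassProfile(0.0, 0.0, ()),)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator controls; the defaults reproduce the study geometry."""

    n_subjects: int = 1
    n_channels: int = 19
    fs: float = 1000.0
    epoch_seconds: float = 1.0
    trials_per_class: int = 100
    n_classes: int = 6
    profiles: tuple[ClassProfile, ...] = field(default_factory=_default_profiles)
    beta: float = 1.0  # 1/f^beta background exponent
    band_hz: tuple[float, float] = (0.53, 100.0)
    notch_hz: float = 50.0
    snr: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.profiles) != self.n_classes:
            raise ValueError(
                f"need one profile per class; got {len(self.profiles)} "
                f"profiles for {self.n_classes} classes"
            )
        nyq = self.fs / 2.0
        for i, p in enumerate(self.profiles):
            if p.channels and p.center_hz + p.bandwidth_hz / 2.0 >= nyq:
                raise ValueError(
                    f"class {i + 1} band reaches the Nyquist frequency {nyq} Hz"
                )
            for ch in p.channels:
                if not 0 <= ch < self.n_channels:
                    raise ValueError(f"class {i + 1} channel {ch} out of range")
        if self.band_hz[1] >= nyq or self.band_hz[0] <= 0:
            raise ValueError("band-pass edges must lie inside (0, fs/2)")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.epoch_seconds))

    @property
    def n_trials_per_subject(self) -> int:
        return self.trials_per_class * self.n_classes


def _pink_noise(rng: np.random.Generator, shape, beta: float) -> np.ndarray:
    """Gaussian 1/f^beta noise via spectral shaping, unit SD, last axis time."""
    n = shape[-1]
    freqs = np.fft.rfftfreq(n)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-beta / 2.0)
    spec = rng.standard_normal(shape[:-1] + (freqs.size,)) + 1j * rng.standard_normal(
        shape[:-1] + (freqs.size,)
    )
    x = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0.0] = 1.0
    return x / sd


def _filters(config: SyntheticConfig):
    sos = sps.butter(
        4, config.band_hz, btype="bandpass", fs=config.fs, output="sos"
    )
    b, a = sps.iirnotch(config.notch_hz, Q=30.0, fs=config.fs)
    return sos, b, a


def _apply_filters(data: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    sos, b, a = _filters(config)
    out = sps.sosfiltfilt(sos, data, axis=-1)
    return sps.filtfilt(b, a, out, axis=-1)


def generate_epoch_set(config: SyntheticConfig | None = None) -> EpochSet:
    """Labelled synthetic epoch set with class-discriminative band power."""
    config = config or SyntheticConfig()
    n = config.n_samples
    t = np.arange(n) / config.fs
    envelope = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / n))  # raised cosine
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
    blocks, labels, subjects = [], [], []
    for s, seq in enumerate(seeds):
        rng = np.random.default_rng(seq)
        data = _pink_noise(
            rng,
            (config.n_trials_per_subject, config.n_channels, n),
            config.beta,
        )
        trial = 0
        for cls, profile in enumerate(config.profiles, start=1):
            for _ in range(config.trials_per_class):
                if profile.channels and config.snr > 0:
                    f0 = rng.uniform(
                        profile.center_hz - profile.bandwidth_hz / 2.0,
                        profile.center_hz + profile.bandwidth_hz / 2.0,
                    )
                    phase = rng.uniform(0.0, 2.0 * np.pi)
                    wave = envelope * np.sin(2.0 * np.pi * f0 * t + phase)
                    rms = np.sqrt(np.mean(wave**2))
                    if rms > 0:
                        target = config.snr * profile.amplitude  # background SD is 1
                        wave *= target / rms
                    data[trial, list(profile.channels)] += wave
                labels.append(cls)
                subjects.append(s + 1)
                trial += 1
        blocks.append(data)
    data = np.concatenate(blocks, axis=0)
    data = _apply_filters(data, config)
    return EpochSet(
        data=data,
        labels=np.array(labels),
        fs=config.fs,
        subject_ids=np.array(subjects),
    )


def generate_null_set(config: SyntheticConfig | None = None) -> EpochSet:
    """Background-only set: every class profile emptied, labels assigned
    round-robin, so the classes are statistically identical."""
    config = config or SyntheticConfig()
    null_profiles = tuple(
        ClassProfile(0.0, 0.0, ()) for _ in range(config.n_classes)
    )
    null_config = SyntheticConfig(
        n_subjects=config.n_subjects,
        n_channels=config.n_channels,
        fs=config.fs,
        epoch_seconds=config.epoch_seconds,
        trials_per_class=config.trials_per_class,
        n_classes=config.n_classes,
        profiles=null_profiles,
        beta=config.beta,
        band_hz=config.band_hz,
        notch_hz=config.notch_hz,
        snr=config.snr,
        seed=config.seed,
    )
    epochs = generate_epoch_set(null_config)
    per_subject = null_config.n_trials_per_subject
    labels = np.tile(
        np.arange(per_subject) % config.n_classes + 1, config.n_subjects
    )
    return EpochSet(
        data=epochs.data,
        labels=labels,
        fs=epochs.fs,
        subject_ids=epochs.subject_ids,
        channel_names=epochs.channel_names,
    )


def spectral_ground_truth(config: SyntheticConfig | None = None) -> pd.DataFrame:
    """Analytic expected band power per (class, channel, class band).

    Background power inside each class band comes from integrating the
    1/f^beta shaping over the band's share of the spectrum (unit total
    variance); channels carrying the class oscillation add its RMS^2 =
    (snr * amplitude)^2. Used by Monte-Carlo recovery tests.
    """
    config = config or SyntheticConfig()
    n = config.n_samples
    freqs = np.fft.rfftfreq(n, d=1.0 / config.fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-config.beta)
    shape /= shape.sum()  # fraction of background variance per bin
    bands = [
        (p.center_hz - p.bandwidth_hz / 2.0, p.center_hz + p.bandwidth_hz / 2.0)
        for p in config.profiles
        if p.channels
    ]
    records = []
    for cls, profile in enumerate(config.profiles, start=1):
        for ch in range(config.n_channels):
            for lo, hi in bands:
                in_band = (freqs >= lo) & (freqs <= hi)
                power = float(shape[in_band].sum())  # background share
                if (
                    profile.channels
                    and ch in profile.channels
                    and lo
                    == profile.center_hz - profile.bandwidth_hz / 2.0
                ):
                    power += (config.snr * profile.amplitude) ** 2
                records.append(
                    {
                        "class": cls,
                        "channel": ch,
                        "band_lo_hz": lo,
                        "band_hi_hz": hi,
                        "expected_power": power,
                    }
                )
    return pd.DataFrame.from_records(records)
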