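"""Epoch containers, EDF import/export, and event tables.

The native epoch container is a ``.npy`` array payload (trials x channels
x samples) next to a ``.json`` sidecar carrying the sampling rate, labels,
subject ids, channel names, a format version and free-form provenance.

EDF support: reading goes through MNE's EDF reader; export writes minimal
EDF (16-bit, one 1-second data record per block) with the epoch onsets in
a plain tab-delimited event table alongside, since epoching requires an
event table anyway.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .epochs import EpochSet

__all__ = [
    "write_epoch_container",
    "read_epoch_container",
    "write_events",
    "read_events",
    "write_edf",
    "read_edf_epochs",
    "export_edf",
]

logger = logging.getLogger("itdeeg")

CONTAINER_VERSION = "1"


def _paths(path) -> tuple[Path, Path]:
    stem = Path(path)
    if stem.suffix in (".npy", ".json"):
        stem = stem.with_suffix("")
    return stem.with_suffix(".npy"), stem.with_suffix(".json")


def write_epoch_container(epochs: EpochSet, path, provenance: dict | None = None) -> None:
    """Write the array payload and JSON sidecar for an epoch set."""
    npy, sidecar = _paths(path)
    np.save(npy, epochs.data)
    meta = {
        "version": CONTAINER_VERSION,
        "fs": epochs.fs,
        "shape": list(epochs.data.shape),
        "labels": epochs.labels.tolist(),
        "subject_ids": epochs.subject_ids.tolist(),
        "channel_names": epochs.channel_names,
        "provenance": provenance or {},
    }
    with open(sidecar, "w") as fh:
        json.dump(meta, fh)


def read_epoch_container(path) -> EpochSet:
    """Lossless read of a container written by :func:`write_epoch_container`.

    Rejects a sidecar without a version field, dimensions that disagree
    with the payload, or labels outside 1..6.
    """
    npy, sidecar = _paths(path)
    with open(sidecar) as fh:
        meta = json.load(fh)
    if "version" not in meta:
        raise ValueError(f"{sidecar}: sidecar has no 'version' field")
    data = np.load(npy)
    if list(data.shape) != list(meta["shape"]):
        raise ValueError(
            f"{npy}: payload shape {list(data.shape)} does not match "
            f"sidecar shape {meta['shape']}"
        )
    labels = np.asarray(meta["labels"], dtype=np.int64)
    if labels.size and (labels.min() < 1 or labels.max() > 6):
        raise ValueError(f"{sidecar}: labels must lie in 1..6")
    return EpochSet(
        data=data,
        labels=labels,
        fs=float(meta["fs"]),
        subject_ids=np.asarray(meta["subject_ids"], dtype=np.int64),
        channel_names=list(meta["channel_names"]),
    )


def write_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    events = pd.read_csv(path, sep="\t")
    if "onset_sample" not in events or "label" not in events:
        raise ValueError(
            f"{path}: event table needs 'onset_sample' and 'label' columns"
        )
    return events


# --- minimal EDF writer -------------------------------------------------

def _edf_number(value: float) -> str:
    """Format a float into EDF's 8-ascii-character numeric field."""
    for fmt in ("%g", "%.4G", "%.3G", "%.2G"):
        s = fmt % value
        if len(s) <= 8:
            return s
    raise ValueError(f"cannot format {value} into 8 characters")


def write_edf(data: np.ndarray, fs: float, path, channel_names=None) -> None:
    """Write a continuous multichannel recording as 16-bit EDF.

    ``data`` is (channels, samples) in microvolts; the record duration is
    one second, so the sample count is zero-padded up to a whole number of
    records. Physical ranges are symmetric per file and quantised to
    16 bits.
    """
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2:
        raise ValueError("data must be 2-D (channels, samples)")
    n_ch, n_samp = data.shape
    channel_names = channel_names or [f"ch{i + 1:02d}" for i in range(n_ch)]
    spr = int(round(fs))  # samples per 1-second record
    n_rec = int(np.ceil(n_samp / spr))
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_samp] = data

    pm = float(np.abs(padded).max())
    pm = pm * 1.0001 if pm > 0 else 1.0
    phys_max_s = _edf_number(pm)
    phys_min_s = _edf_number(-pm)
    # digitise against the *printed* physical range so the file round-trips
    pmax, pmin = float(phys_max_s), float(phys_min_s)
    dig_min, dig_max = -32768, 32767
    gain = (pmax - pmin) / (dig_max - dig_min)
    digital = np.clip(
        np.round((padded - pmin) / gain) + dig_min, dig_min, dig_max
    ).astype("<i2")

    def field(text: str, width: int) -> bytes:
        return text.ljust(width)[:width].encode("ascii")

    header = b"".join(
        [
            field("0", 8),
            field("itdeeg synthetic", 80),
            field("itdeeg export", 80),
            field("01.01.00", 8),
            field("00.00.00", 8),
            field(str(256 * (n_ch + 1)), 8),
            field("", 44),
            field(str(n_rec), 8),
            field("1", 8),
            field(str(n_ch), 4),
        ]
    )
    per_signal = b"".join(
        [
            b"".join(field(name, 16) for name in channel_names),
            b"".join(field("synthetic EEG", 80) for _ in range(n_ch)),
            b"".join(field("uV", 8) for _ in range(n_ch)),
            b"".join(field(phys_min_s, 8) for _ in range(n_ch)),
            b"".join(field(phys_max_s, 8) for _ in range(n_ch)),
            b"".join(field(str(dig_min), 8) for _ in range(n_ch)),
            b"".join(field(str(dig_max), 8) for _ in range(n_ch)),
            b"".join(field("BP 0.53-100Hz N50", 80) for _ in range(n_ch)),
            b"".join(field(str(spr), 8) for _ in range(n_ch)),
            b"".join(field("", 32) for _ in range(n_ch)),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_signal)
        for rec in range(n_rec):
            chunk = digital[:, rec * spr : (rec + 1) * spr]
            fh.write(chunk.tobytes())


def export_edf(epochs: EpochSet, directory, stem: str = "subject") -> list[Path]:
    """Write one EDF per subject (trials concatenated back to back) plus a
    tab-delimited event table with the epoch onsets and labels."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for subject in epochs.subjects:
        sub = epochs.for_subject(subject)
        continuous = sub.data.transpose(1, 0, 2).reshape(sub.n_channels, -1)
        edf_path = directory / f"{stem}{subject}.edf"
        write_edf(continuous, sub.fs, edf_path, sub.channel_names)
        events = pd.DataFrame(
            {
                "onset_sample": np.arange(sub.n_trials) * sub.n_samples,
                "label": sub.labels,
                "subject": sub.subject_ids,
                "file": edf_path.name,
            }
        )
        write_events(events, edf_path.with_suffix(".events.tsv"))
        written.append(edf_path)
    return written


def read_edf_epochs(
    paths, event_table: pd.DataFrame, epoch_seconds: float
) -> EpochSet:
    """Extract fixed-length epochs from EDF recordings at event onsets.

    Epochs are half-open sample windows [onset, onset + fs*epoch_seconds).
    Events outside a recording are skipped with a logged warning and a
    summary count. All files must share one sampling rate. The optional
    ``file`` column of the event table routes events to files; without it
    all events apply to the single path given.
    """
    import mne

    if isinstance(paths, (str, Path)):
        paths = [paths]
    paths = [Path(p) for p in paths]
    if "file" not in event_table.columns and len(paths) > 1:
        raise ValueError("event table needs a 'file' column for multiple EDFs")

    fs = None
    data_blocks: list[np.ndarray] = []
    labels: list[int] = []
    subjects: list[int] = []
    channel_names: list[str] | None = None
    skipped = 0
    for si, path in enumerate(paths):
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        if fs is None:
            fs = float(raw.info["sfreq"])
            channel_names = list(raw.ch_names)
        elif float(raw.info["sfreq"]) != fs:
            raise ValueError(
                f"{path}: sampling rate {raw.info['sfreq']} differs from {fs}"
            )
        signal = raw.get_data() * 1e6  # MNE stores EEG in volts; back to uV
        n_epoch = int(round(fs * epoch_seconds))
        if "file" in event_table.columns:
            events = event_table[event_table["file"] == path.name]
        else:
            events = event_table
        for _, ev in events.iterrows():
            onset = int(ev["onset_sample"])
            if onset < 0 or onset + n_epoch > signal.shape[1]:
                skipped += 1
                logger.warning(
                    "skipping event at sample %d in %s: epoch of %d samples "
                    "does not fit the recording",
                    onset,
                    path.name,
                    n_epoch,
                )
                continue
            data_blocks.append(signal[:, onset : onset + n_epoch])
            labels.append(int(ev["label"]))
            subjects.append(int(ev.get("subject", si + 1)))
    if skipped:
        logger.warning("skipped %d event(s) outside recordings", skipped)
    if not data_blocks:
        n_ch = len(channel_names) if channel_names else 0
        n_epoch = int(round((fs or 1.0) * epoch_seconds))
        return EpochSet(
            data=np.empty((0, n_ch, n_epoch)),
            labels=np.empty(0, dtype=np.int64),
            fs=fs or 1.0,
            subject_ids=np.empty(0, dtype=np.int64),
            channel_names=channel_names or [],
        )
    return EpochSet(
        data=np.stack(data_blocks),
        labels=np.array(labels),
        fs=fs,
        subject_ids=np.array(subjects),
        channel_names=channel_names,
    )
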