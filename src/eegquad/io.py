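"""Readers and writers: rating CSVs, truth/label CSVs, and per-subject EEG
containers (this package's ``.npz`` layout and the DEAP preprocessed-Python
pickle layout).

The per-subject container holds ``data`` (trials × channels × samples),
``labels`` (trials × 4 VADL ratings), the channel-name list and the sampling
rate. DEAP's preprocessed release stores 40 trials × 40 channels × 8064
samples at 128 Hz, where the first 32 channels are EEG and the first 3 s of
each trial is a pre-stimulus baseline; by default the peripheral channels are
dropped and the baseline removed, leaving the 60 s stimulus window.
"""

from __future__ import annotations

import pickle
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EEGEpoch, RatingsPanel, RATINGS_COLUMNS
from .montage import DEAP32_CHANNELS


class FormatError(ValueError):
    """Raised for malformed input files."""


# --------------------------------------------------------------------------
# ratings and labels
# --------------------------------------------------------------------------

def write_ratings(panel: RatingsPanel, path) -> None:
    panel.frame[list(RATINGS_COLUMNS)].to_csv(path, index=False)


def read_ratings(path) -> RatingsPanel:
    """Read a rating CSV with columns subject_id, video_id, valence..liking."""
    frame = pd.read_csv(path)
    missing = [c for c in RATINGS_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return RatingsPanel(frame)


def write_labels(labels: pd.DataFrame, path) -> None:
    labels.to_csv(path, index=False)


def read_labels(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    if "video_id" not in frame.columns:
        raise FormatError(f"{path}: label CSV needs a video_id column")
    return frame


# --------------------------------------------------------------------------
# EEG containers
# --------------------------------------------------------------------------

def write_subject_eeg(
    path,
    epochs: list[EEGEpoch],
    labels: np.ndarray | None = None,
) -> None:
    """Write one subject's epochs as an .npz container.

    All epochs must share montage and sampling rate; ``labels`` is an optional
    trials × 4 VADL array.
    """
    if not epochs:
        raise ValueError("no epochs to write")
    names = epochs[0].channel_names
    fs = epochs[0].fs
    if any(e.channel_names != names or e.fs != fs for e in epochs):
        raise ValueError("epochs differ in montage or sampling rate")
    data = np.stack([e.samples for e in epochs])
    if labels is None:
        labels = np.full((len(epochs), 4), np.nan)
    labels = np.asarray(labels, dtype=float)
    if labels.shape != (len(epochs), 4):
        raise FormatError(f"labels must be trials x 4, got {labels.shape}")
    np.savez(
        path,
        data=data,
        labels=labels,
        channel_names=np.array(names),
        fs=np.array([fs]),
        subject_id=np.array([str(epochs[0].subject_id)]),
        video_ids=np.array([str(e.video_id) for e in epochs]),
    )


def read_deap_subject(
    path,
    keep_baseline: bool = False,
    baseline_seconds: float = 3.0,
    fs: float = 128.0,
) -> tuple[list[EEGEpoch], pd.DataFrame]:
    """Read a per-subject container: our .npz layout or the DEAP .dat pickle.

    Returns the epoch list (EEG channels only, channel names attached) and a
    tidy frame of the trials × 4 VADL ratings. For DEAP-shaped arrays
    (40 channels, 8064 samples) the 8 peripheral channels are dropped and,
    unless ``keep_baseline`` is set, the 3 s pre-trial baseline is removed.
    """
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            data = z["data"]
            labels = z["labels"]
            names = [str(c) for c in z["channel_names"]]
            fs = float(z["fs"][0])
            subject = str(z["subject_id"][0]) if "subject_id" in z else path.stem
            video_ids = [str(v) for v in z["video_ids"]] if "video_ids" in z else None
    else:
        with open(path, "rb") as fh:
            obj = pickle.load(fh, encoding="latin1")
        if not isinstance(obj, dict) or "data" not in obj or "labels" not in obj:
            raise FormatError(f"{path}: expected a dict with 'data' and 'labels'")
        data = np.asarray(obj["data"], dtype=float)
        labels = np.asarray(obj["labels"], dtype=float)
        names = list(DEAP32_CHANNELS)
        subject = path.stem
        video_ids = None
    if data.ndim != 3:
        raise FormatError(f"{path}: data must be trials x channels x samples")
    if labels.ndim != 2 or labels.shape[1] != 4:
        raise FormatError(f"{path}: labels must be trials x 4, got {labels.shape}")
    if labels.shape[0] != data.shape[0]:
        raise FormatError(f"{path}: {data.shape[0]} trials but {labels.shape[0]} label rows")
    if data.shape[1] > len(names):
        data = data[:, : len(names), :]  # drop peripheral channels
    elif data.shape[1] < len(names):
        names = names[: data.shape[1]]
    if not keep_baseline:
        n_base = int(round(baseline_seconds * fs))
        if data.shape[2] > n_base and data.shape[2] in (8064, n_base + 60 * int(fs)):
            data = data[:, :, n_base:]
    epochs = []
    for t in range(data.shape[0]):
        vid = video_ids[t] if video_ids else t
        epochs.append(
            EEGEpoch(data[t], tuple(names), fs, subject_id=subject, video_id=vid)
        )
    ratings = pd.DataFrame(labels, columns=["valence", "arousal", "dominance", "liking"])
    ratings.insert(0, "video_id", [e.video_id for e in epochs])
    ratings.insert(0, "subject_id", subject)
    return epochs, ratings
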