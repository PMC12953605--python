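"""In-memory containers: subjective-rating panels and EEG epochs.

A :class:`RatingsPanel` wraps a tidy :class:`pandas.DataFrame` with one row per
(subject, video) and the four affective rating dimensions Valence, Arousal,
Dominance and Liking (VADL), each on the 1–9 self-assessment-manikin scale.
An :class:`EEGEpoch` holds one subject-video recording as a channels × samples
array in microvolts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .montage import _canon

#: Canonical rating-dimension column order.
VADL_COLUMNS = ("valence", "arousal", "dominance", "liking")

RATINGS_COLUMNS = ("subject_id", "video_id") + VADL_COLUMNS

#: Quadrant labels of the valence–arousal plane, in integer-code order 0–3.
QUADRANTS = ("HVHA", "HVLA", "LVHA", "LVLA")

#: Representative discrete emotion for each quadrant.
QUADRANT_EMOTIONS = {"HVHA": "happy", "HVLA": "relaxed", "LVHA": "fearful", "LVLA": "sad"}

QUADRANT_TO_CODE = {q: i for i, q in enumerate(QUADRANTS)}

#: Sign prototype of each quadrant in (valence, arousal) z-space.
QUADRANT_SIGNS = {"HVHA": (1, 1), "HVLA": (1, -1), "LVHA": (-1, 1), "LVLA": (-1, -1)}


def quadrant_from_sides(high_valence: bool, high_arousal: bool) -> str:
    if high_valence:
        return "HVHA" if high_arousal else "HVLA"
    return "LVHA" if high_arousal else "LVLA"


class RatingsValidationError(ValueError):
    """Raised when rating scores fall outside the 1–9 scale or columns are missing."""


@dataclass
class RatingsPanel:
    """Multi-subject VADL rating panel.

    Parameters
    ----------
    frame
        Tidy frame with columns ``subject_id, video_id, valence, arousal,
        dominance, liking``; one row per (subject, video).
    scale
        Inclusive rating bounds, default the DEAP 1–9 scale.
    """

    frame: pd.DataFrame
    scale: tuple[float, float] = (1.0, 9.0)

    def __post_init__(self) -> None:
        missing = [c for c in RATINGS_COLUMNS if c not in self.frame.columns]
        if missing:
            raise RatingsValidationError(f"ratings frame missing columns: {missing}")
        lo, hi = self.scale
        vals = self.frame[list(VADL_COLUMNS)].to_numpy(dtype=float)
        bad = np.where((vals < lo) | (vals > hi) | ~np.isfinite(vals))
        if bad[0].size:
            rows = sorted(set(bad[0].tolist()))[:10]
            raise RatingsValidationError(
                f"scores outside [{lo}, {hi}] at frame rows {rows}"
            )
        self.frame = self.frame.reset_index(drop=True)

    @property
    def subjects(self) -> list:
        return sorted(self.frame["subject_id"].unique().tolist())

    @property
    def videos(self) -> list:
        return sorted(self.frame["video_id"].unique().tolist())

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_videos(self) -> int:
        return len(self.videos)

    def __len__(self) -> int:
        return len(self.frame)

    def scores(self) -> np.ndarray:
        """(n_rows, 4) VADL score array in canonical column order."""
        return self.frame[list(VADL_COLUMNS)].to_numpy(dtype=float)


@dataclass
class EEGEpoch:
    """One subject-video EEG recording, channels × samples in microvolts."""

    samples: np.ndarray
    channel_names: tuple[str, ...]
    fs: float
    subject_id: object = None
    video_id: object = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.channel_names = tuple(self.channel_names)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels x time array")
        if self.samples.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.samples.shape[0]} rows but {len(self.channel_names)} channel names"
            )
        if not np.isfinite(self.samples).all():
            raise ValueError("EEG samples contain NaN or infinite values")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, name: str) -> int:
        canon = [_canon(c) for c in self.channel_names]
        key = _canon(name)
        if key not in canon:
            raise KeyError(f"channel {name!r} not in epoch montage {list(self.channel_names)}")
        return canon.index(key)

    def channel(self, name: str) -> np.ndarray:
        return self.samples[self.channel_index(name)]

    def select_channels(self, names) -> "EEGEpoch":
        """Sub-epoch restricted to *names* (case-insensitive), preserving sample count."""
        idx = [self.channel_index(n) for n in names]
        return replace(self, samples=self.samples[idx], channel_names=tuple(names))

    def with_samples(self, samples: np.ndarray) -> "EEGEpoch":
        return replace(self, samples=samples)
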