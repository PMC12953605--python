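"""Synthetic DEAP-like rating panels and band-structured EEG with planted truth.

The generator emulates the study conditions of a video emotion-elicitation
protocol: 32 subjects rate 40 videos on the 1–9 Valence/Arousal/Dominance/Liking
scales, and each (subject, video) pair yields a 60 s, 128 Hz multi-channel EEG
epoch. Every video carries a planted valence–arousal quadrant; ratings scatter
around the quadrant's prototype point with per-subject bias, and EEG epochs are
sums of band-limited Gaussian noise with class-dependent band gains, 1/f
background, and optional high-kurtosis blink transients on frontal channels.

None of this is physiologically realistic EEG — there is no source or forward
modeling — but it gives every downstream stage a ground truth to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .config import BAND_NAMES, DEFAULT_BANDS
from .containers import (
    QUADRANTS,
    EEGEpoch,
    RatingsPanel,
)
from .montage import KEY11_CHANNELS


class InvalidDesignError(ValueError):
    """Raised for structurally invalid synthetic designs."""


#: Prototype (valence, arousal) rating of each quadrant on the 1–9 scale;
#: the scale midpoint 5 separates the quadrants.
QUADRANT_PROTOTYPES: dict[str, tuple[float, float]] = {
    "HVHA": (7.0, 7.0),
    "HVLA": (7.0, 3.0),
    "LVHA": (3.0, 7.0),
    "LVLA": (3.0, 3.0),
}

#: Default class → band amplitude-gain profile. Each class boosts one canonical
#: band by 3x, giving the spectral pipeline a planted separable signature.
DEFAULT_GAIN_PROFILE: dict[str, dict[str, float]] = {
    "HVHA": {"delta": 1.0, "theta": 3.0, "alpha": 1.0, "beta": 1.0, "gamma": 1.0},
    "HVLA": {"delta": 1.0, "theta": 1.0, "alpha": 3.0, "beta": 1.0, "gamma": 1.0},
    "LVHA": {"delta": 1.0, "theta": 1.0, "alpha": 1.0, "beta": 3.0, "gamma": 1.0},
    "LVLA": {"delta": 3.0, "theta": 1.0, "alpha": 1.0, "beta": 1.0, "gamma": 1.0},
}

#: Blink transient channel weighting: frontal-dominant.
BLINK_WEIGHTS = {"FP1": 1.0, "FP2": 1.0, "F3": 0.5, "F4": 0.5}
BLINK_WEIGHT_OTHER = 0.1
BLINK_DURATION_S = 0.5
BLINK_AMPLITUDE_SD = 5.0  # relative to background channel SD


def default_quadrants(n_videos: int) -> tuple[str, ...]:
    """Balanced planted quadrants: cycle HVHA, HVLA, LVHA, LVLA."""
    return tuple(QUADRANTS[i % 4] for i in range(n_videos))


@dataclass
class SyntheticDesign:
    """Parameters of one synthetic study.

    ``rating_noise_sd`` and ``subject_bias_sd`` are in 1–9-scale units;
    ``artifact_rate`` is blink events per minute per epoch.
    """

    n_subjects: int = 32
    n_videos: int = 40
    true_quadrant_per_video: tuple[str, ...] | None = None
    rating_noise_sd: float = 1.0
    subject_bias_sd: float = 0.5
    dl_correlation: float = 0.6
    band_gain_profile: dict = field(
        default_factory=lambda: {c: dict(g) for c, g in DEFAULT_GAIN_PROFILE.items()}
    )
    artifact_rate: float = 2.0
    channel_names: tuple[str, ...] = KEY11_CHANNELS
    fs: float = 128.0
    duration: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0 or self.n_videos <= 0:
            raise InvalidDesignError("subject and video counts must be positive")
        if self.true_quadrant_per_video is None:
            self.true_quadrant_per_video = default_quadrants(self.n_videos)
        self.true_quadrant_per_video = tuple(self.true_quadrant_per_video)
        if len(self.true_quadrant_per_video) != self.n_videos:
            raise InvalidDesignError("one planted quadrant required per video")
        unknown = set(self.true_quadrant_per_video) - set(QUADRANTS)
        if unknown:
            raise InvalidDesignError(f"unknown quadrant labels: {sorted(unknown)}")
        if self.n_videos >= 4 and set(self.true_quadrant_per_video) != set(QUADRANTS):
            raise InvalidDesignError("every quadrant must appear at least once")
        for cls, gains in self.band_gain_profile.items():
            if cls not in QUADRANTS:
                raise InvalidDesignError(f"gain profile for unknown class {cls!r}")
            if any(g <= 0 for g in gains.values()):
                raise InvalidDesignError("band gains must be strictly positive")
        if self.rating_noise_sd < 0 or self.subject_bias_sd < 0 or self.artifact_rate < 0:
            raise InvalidDesignError("noise/bias/artifact rates must be non-negative")
        if self.duration <= 0:
            raise InvalidDesignError("epoch duration must be positive")
        if self.fs < 128:
            raise InvalidDesignError("sampling rate must be at least 128 Hz")


def gen_ratings(design: SyntheticDesign) -> tuple[RatingsPanel, pd.DataFrame]:
    """Generate a full VADL rating panel plus the planted truth table.

    Valence and arousal scatter around the planted quadrant's prototype point
    with per-subject bias and i.i.d. noise. Dominance tracks arousal and liking
    tracks valence with correlation ``design.dl_correlation``; all scores are
    clipped to the 1–9 scale.

    Returns
    -------
    panel, truth
        ``panel`` is the :class:`RatingsPanel`; ``truth`` has columns
        ``video_id, true_quadrant``.
    """
    rng = np.random.default_rng([design.seed, 101])
    rho = design.dl_correlation
    resid = float(np.sqrt(max(0.0, 1.0 - rho**2)))
    bias = rng.normal(0.0, design.subject_bias_sd, size=(design.n_subjects, 2))
    rows = []
    for s in range(design.n_subjects):
        for v in range(design.n_videos):
            quad = design.true_quadrant_per_video[v]
            pv, pa = QUADRANT_PROTOTYPES[quad]
            eps = rng.normal(0.0, design.rating_noise_sd, size=4)
            val = pv + bias[s, 0] + eps[0]
            aro = pa + bias[s, 1] + eps[1]
            dom = 5.0 + rho * (aro - 5.0) + resid * eps[2]
            lik = 5.0 + rho * (val - 5.0) + resid * eps[3]
            rows.append((s, v, val, aro, dom, lik))
    frame = pd.DataFrame(
        rows, columns=["subject_id", "video_id", "valence", "arousal", "dominance", "liking"]
    )
    for c in ("valence", "arousal", "dominance", "liking"):
        frame[c] = frame[c].clip(1.0, 9.0)
    truth = pd.DataFrame(
        {"video_id": range(design.n_videos), "true_quadrant": design.true_quadrant_per_video}
    )
    return RatingsPanel(frame), truth


def _band_noise(rng: np.random.Generator, n: int, fs: float, lo: float, hi: float) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to [lo, hi) Hz."""
    nyq = fs / 2.0
    hi = min(hi, 0.98 * nyq)
    x = rng.standard_normal(n)
    sos = signal.butter(4, [lo / nyq, hi / nyq], btype="band", output="sos")
    y = signal.sosfiltfilt(sos, x)
    rms = np.sqrt(np.mean(y**2))
    return y / rms if rms > 0 else y


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-RMS 1/f-amplitude noise via FFT spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec /= np.sqrt(f)
    y = np.fft.irfft(spec, n)
    return y / np.sqrt(np.mean(y**2))


def blink_template(fs: float) -> np.ndarray:
    """0.5 s raised-cosine (Hann) pulse used as the ocular transient shape."""
    n = int(round(BLINK_DURATION_S * fs))
    return 0.5 * (1 - np.cos(2 * np.pi * np.arange(n) / n))


def gen_epoch(
    cls: str,
    design: SyntheticDesign,
    rng: np.random.Generator,
    subject_id=None,
    video_id=None,
) -> EEGEpoch:
    """One synthetic epoch of the given class (see :func:`gen_eeg`)."""
    if cls not in QUADRANTS:
        raise InvalidDesignError(f"unknown class label {cls!r}")
    n = int(round(design.duration * design.fs))
    n_ch = len(design.channel_names)
    gains = design.band_gain_profile.get(cls, {b: 1.0 for b in BAND_NAMES})
    data = np.zeros((n_ch, n))
    for ch in range(n_ch):
        for band, (lo, hi) in DEFAULT_BANDS.items():
            g = gains.get(band, 1.0)
            data[ch] += g * _band_noise(rng, n, design.fs, lo, hi)
        data[ch] += _pink_noise(rng, n)
    if design.artifact_rate > 0:
        tmpl = blink_template(design.fs)
        n_blinks = rng.poisson(design.artifact_rate * design.duration / 60.0)
        bg_sd = float(np.std(data))
        # FP1/FP2 -> 1.0, F3/F4 -> 0.5, rest -> 0.1
        weights = np.array(
            [BLINK_WEIGHTS.get(c.upper(), BLINK_WEIGHT_OTHER) for c in design.channel_names]
        )
        for _ in range(n_blinks):
            start = rng.integers(0, max(1, n - len(tmpl)))
            amp = BLINK_AMPLITUDE_SD * bg_sd
            data[:, start:start + len(tmpl)] += amp * np.outer(weights, tmpl)
    return EEGEpoch(
        samples=data,
        channel_names=design.channel_names,
        fs=design.fs,
        subject_id=subject_id,
        video_id=video_id,
    )


def gen_eeg(labels: pd.DataFrame, design: SyntheticDesign) -> list[EEGEpoch]:
    """Generate one EEG epoch per (subject, video) row of *labels*.

    Parameters
    ----------
    labels
        Frame with columns ``subject_id, video_id, label`` where ``label`` is a
        quadrant name. Typically built by pairing :func:`gen_ratings` truth
        with the subject roster.
    design
        The study design; ``design.seed`` makes the output reproducible.
    """
    required = {"subject_id", "video_id", "label"}
    if not required.issubset(labels.columns):
        raise InvalidDesignError(f"labels frame needs columns {sorted(required)}")
    epochs = []
    for _, row in labels.iterrows():
        rng = np.random.default_rng(
            [design.seed, 202, int(row["subject_id"]), int(row["video_id"])]
        )
        epochs.append(
            gen_epoch(str(row["label"]), design, rng,
                      subject_id=row["subject_id"], video_id=row["video_id"])
        )
    return epochs


def truth_to_labels(truth: pd.DataFrame, subjects) -> pd.DataFrame:
    """Expand a per-video truth table to per-(subject, video) label rows."""
    rows = [
        (s, int(r["video_id"]), r["true_quadrant"])
        for s in subjects
        for _, r in truth.iterrows()
    ]
    return pd.DataFrame(rows, columns=["subject_id", "video_id", "label"])
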