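"""Saliency-guided multimodal feature extraction.

Four feature families are concatenated into a 149-column core vector per
(subject, video) epoch:

* wavelet relative band energies at FP1, C3, T8, O1 — 4 × 5 bands = 20
* magnitude-squared coherence of the F3–C4 pair, one value per band = 5
* time-domain statistics at FP1 and FP2 — per electrode, {median, peak |x|}
  in the α band, the β band and the 1–45 Hz broadband (12), plus the
  full-signal mean squared deviation (2) = 14
* sliding-window Welch PSD over the 11-channel montage — per electrode and
  band, the across-window mean and maximum power: 2 × 5 × 11 = 110

Every feature column is named ``family_electrode_band_statistic`` and carries
a schema entry, so a feature matrix round-trips through CSV with its layout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .config import BAND_NAMES, DEFAULT_BANDS, PipelineConfig
from .containers import EEGEpoch
from .montage import KEY11_CHANNELS
from .spectral import scalogram_band_energy

WAVELET_ELECTRODES = ("FP1", "C3", "T8", "O1")
COHERENCE_PAIR = ("F3", "C4")
TIMEDOMAIN_ELECTRODES = ("FP1", "FP2")
TIMEDOMAIN_BANDS = {"alpha": (8.0, 14.0), "beta": (14.0, 30.0), "broadband": (1.0, 45.0)}

#: Widths of the four families and the resulting core feature dimension.
FAMILY_WIDTHS = {"wavelet_energy": 20, "coherence": 5, "timedomain": 14, "psd": 110}
CORE_FEATURE_DIM = sum(FAMILY_WIDTHS.values())  # 149


class MissingElectrodeError(KeyError):
    """Raised when a required electrode is absent from the epoch montage."""


def _require(epoch: EEGEpoch, names) -> None:
    for n in names:
        try:
            epoch.channel_index(n)
        except KeyError as exc:
            raise MissingElectrodeError(str(n)) from exc


def wavelet_energy_features(epoch: EEGEpoch, config: PipelineConfig | None = None) -> dict[str, float]:
    """20 wavelet relative band energies (%): FP1, C3, T8, O1 × five bands."""
    cfg = config or PipelineConfig()
    _require(epoch, WAVELET_ELECTRODES)
    out = {}
    for el in WAVELET_ELECTRODES:
        shares = scalogram_band_energy(
            epoch.channel(el), epoch.fs,
            wavelet=cfg.cwt_wavelet, gain_calibration=cfg.cwt_gain_calibration,
        )
        for band in BAND_NAMES:
            out[f"wav_{el.lower()}_{band}"] = shares[band]
    return out


def coherence_features(epoch: EEGEpoch, config: PipelineConfig | None = None) -> dict[str, float]:
    """Five band-averaged magnitude-squared coherence values for F3–C4.

    Coherence is the squared cross-spectrum normalized by the auto-spectra,
    estimated from Hann-tapered segments (default 2 s at 50% overlap) and
    averaged over the frequency bins of each band. Estimation from a single
    segment is refused: the estimator degenerates to 1 identically.
    """
    cfg = config or PipelineConfig()
    _require(epoch, COHERENCE_PAIR)
    nperseg = int(round(cfg.coherence_segment_seconds * epoch.fs))
    if epoch.n_samples < 2 * nperseg:
        raise ValueError("epoch too short for multi-segment coherence estimation")
    x = epoch.channel(COHERENCE_PAIR[0])
    y = epoch.channel(COHERENCE_PAIR[1])
    freqs, coh = signal.coherence(
        x, y, fs=epoch.fs, nperseg=nperseg, noverlap=nperseg // 2, window="hann"
    )
    out = {}
    for band, (lo, hi) in DEFAULT_BANDS.items():
        mask = (freqs >= lo) & (freqs < hi)
        name = f"coh_f3c4_{band}"
        out[name] = float(coh[mask].mean()) if mask.any() else 0.0
    return out


def _bandpass_1d(x: np.ndarray, fs: float, lo: float, hi: float, order: int = 4) -> np.ndarray:
    nyq = fs / 2.0
    hi = min(hi, 0.99 * nyq)
    sos = signal.butter(order, [lo / nyq, hi / nyq], btype="band", output="sos")
    return signal.sosfiltfilt(sos, x)


def timedomain_features(epoch: EEGEpoch) -> dict[str, float]:
    """14 time-domain statistics from FP1 and FP2.

    Per electrode: median of the signed band-passed signal and peak absolute
    amplitude, in the α band, the β band and the 1–45 Hz broadband; plus the
    full-signal mean squared deviation from its own mean.
    """
    _require(epoch, TIMEDOMAIN_ELECTRODES)
    out = {}
    for el in TIMEDOMAIN_ELECTRODES:
        x = epoch.channel(el)
        for band, (lo, hi) in TIMEDOMAIN_BANDS.items():
            xb = _bandpass_1d(x, epoch.fs, lo, hi)
            out[f"td_{el.lower()}_{band}_median"] = float(np.median(xb))
            out[f"td_{el.lower()}_{band}_peak"] = float(np.max(np.abs(xb)))
        out[f"td_{el.lower()}_mse"] = float(np.mean((x - x.mean()) ** 2))
    return out


def psd_features(epoch: EEGEpoch, config: PipelineConfig | None = None) -> dict[str, float]:
    """110 sliding-window Welch PSD statistics over the 11-channel montage.

    The epoch is cut into sliding windows (default 4 s, 2 s step); each window
    gets a Welch PSD (2 s sub-segments, 50% overlap, Hann); per electrode and
    band the across-window mean and maximum of the in-band mean power are
    reported.
    """
    cfg = config or PipelineConfig()
    _require(epoch, KEY11_CHANNELS)
    win = int(round(cfg.psd_window_seconds * epoch.fs))
    step = int(round(cfg.psd_step_seconds * epoch.fs))
    if epoch.n_samples < win:
        raise ValueError("epoch shorter than one PSD window")
    sub = epoch.select_channels(KEY11_CHANNELS)
    starts = range(0, epoch.n_samples - win + 1, step)
    nperseg = max(8, win // 2)
    band_power = {band: [] for band in DEFAULT_BANDS}
    for s0 in starts:
        seg = sub.samples[:, s0:s0 + win]
        freqs, psd = signal.welch(
            seg, fs=epoch.fs, nperseg=nperseg, noverlap=nperseg // 2, window="hann", axis=1
        )
        for band, (lo, hi) in DEFAULT_BANDS.items():
            mask = (freqs >= lo) & (freqs < hi)
            band_power[band].append(psd[:, mask].mean(axis=1) if mask.any() else np.zeros(11))
    out = {}
    for band in DEFAULT_BANDS:
        arr = np.stack(band_power[band])  # windows x channels
        for i, el in enumerate(KEY11_CHANNELS):
            out[f"psd_{el.lower()}_{band}_mean"] = float(arr[:, i].mean())
            out[f"psd_{el.lower()}_{band}_max"] = float(arr[:, i].max())
    return out


@dataclass
class FeatureMatrix:
    """Observations × named feature columns plus label and subject-id columns."""

    frame: pd.DataFrame
    feature_columns: list[str]
    schema: dict  # column -> {family, electrode, band, statistic}

    def features(self) -> np.ndarray:
        return self.frame[self.feature_columns].to_numpy(dtype=float)

    @property
    def labels(self) -> np.ndarray:
        return self.frame["label"].to_numpy()

    @property
    def subjects(self) -> np.ndarray:
        return self.frame["subject_id"].to_numpy()

    def to_csv(self, path, schema_path=None) -> None:
        self.frame.to_csv(path, index=False)
        if schema_path is not None:
            with open(schema_path, "w") as fh:
                json.dump({"feature_columns": self.feature_columns, "schema": self.schema}, fh, indent=1)

    @classmethod
    def from_csv(cls, path, schema_path) -> "FeatureMatrix":
        frame = pd.read_csv(path)
        with open(schema_path) as fh:
            meta = json.load(fh)
        return cls(frame, meta["feature_columns"], meta["schema"])


def _schema_entry(name: str) -> dict:
    family, rest = name.split("_", 1)
    parts = rest.split("_")
    fam = {"wav": "wavelet_energy", "coh": "coherence", "td": "timedomain", "psd": "psd"}[family]
    entry = {"family": fam, "electrode": parts[0], "band": None, "statistic": None}
    if fam == "wavelet_energy":
        entry["band"] = parts[1]
        entry["statistic"] = "relative_energy"
    elif fam == "coherence":
        entry["band"] = parts[1]
        entry["statistic"] = "msc_mean"
    elif fam == "timedomain":
        if parts[-1] == "mse":
            entry["statistic"] = "mse"
        else:
            entry["band"], entry["statistic"] = parts[1], parts[2]
    else:
        entry["band"], entry["statistic"] = parts[1], parts[2]
    return entry


def extract_features(epoch: EEGEpoch, config: PipelineConfig | None = None) -> dict[str, float]:
    """One epoch's full 149-value feature row, in fixed family order."""
    row: dict[str, float] = {}
    for fam, fn in (
        ("wavelet_energy", lambda: wavelet_energy_features(epoch, config)),
        ("coherence", lambda: coherence_features(epoch, config)),
        ("timedomain", lambda: timedomain_features(epoch)),
        ("psd", lambda: psd_features(epoch, config)),
    ):
        try:
            row.update(fn())
        except Exception as exc:
            raise RuntimeError(f"feature family {fam!r} failed: {exc}") from exc
    return row


def assemble_features(
    epochs: list[EEGEpoch],
    labels: list[str],
    config: PipelineConfig | None = None,
) -> FeatureMatrix:
    """Assemble the named feature matrix for a list of labeled epochs.

    Rows follow the epoch list order; ``label`` and ``subject_id`` ride along
    as non-feature columns.
    """
    if len(epochs) != len(labels):
        raise ValueError("one label required per epoch")
    rows = []
    for epoch, lab in zip(epochs, labels):
        row = extract_features(epoch, config)
        row["label"] = lab
        row["subject_id"] = epoch.subject_id
        row["video_id"] = epoch.video_id
        rows.append(row)
    frame = pd.DataFrame(rows)
    feature_columns = [c for c in frame.columns if c not in ("label", "subject_id", "video_id")]
    if len(feature_columns) != CORE_FEATURE_DIM:
        raise RuntimeError(
            f"assembled {len(feature_columns)} features, expected {CORE_FEATURE_DIM}"
        )
    if frame[feature_columns].isna().any().any():
        raise RuntimeError("NaN in assembled feature matrix")
    schema = {c: _schema_entry(c) for c in feature_columns}
    return FeatureMatrix(frame, feature_columns, schema)
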