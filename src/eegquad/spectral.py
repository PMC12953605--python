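"""Multi-dimensional energy-ratio analysis.

Per-channel relative band energy is computed two ways — from a Welch power
spectrum ("fft" method) and from a continuous-wavelet scalogram ("wavelet"
method) — over the canonical bands δ 1–4, θ 4–8, α 8–14, β 14–30 and
γ 30–60 Hz. Shares are percentages of the total 1–60 Hz energy, so each
channel's five-band vector sums to 100.

The scalogram path sums |W(f, t)|² on a 1 Hz frequency grid. Because an
analytic Morlet wavelet has constant-Q (frequency-proportional) bandwidth, the
raw grid summation over-weights low frequencies; by default each grid
frequency's contribution is therefore divided by the scalogram's measured
response to a unit sinusoid at that frequency, flattening the response so that
equal-power narrowband components receive equal energy regardless of band.
Disable with ``gain_calibration=False`` to get the raw summation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
import pywt
from scipy import signal

from .config import BAND_NAMES, DEFAULT_BANDS
from .containers import EEGEpoch

TOTAL_RANGE = (1.0, 60.0)  # Hz — denominator range of the relative-energy ratio


def _band_items(bands=None):
    bands = bands or DEFAULT_BANDS
    return [(k, (float(v[0]), float(v[1]))) for k, v in bands.items()]


def band_energy_fft(
    epoch: EEGEpoch,
    bands=None,
    segment_seconds: float = 4.0,
    overlap: float = 0.5,
) -> pd.DataFrame:
    """Relative band energy (%) per channel from a Welch power spectrum.

    Welch averaging uses Hann-tapered segments (default 4 s at 50% overlap).
    Band energy integrates the PSD over [low, high); shares are relative to
    the total over 1–60 Hz. If the Nyquist frequency is below 60 Hz the γ band
    is truncated with a warning.
    """
    items = _band_items(bands)
    nyq = epoch.fs / 2.0
    if nyq <= items[-1][1][1]:
        warnings.warn(
            f"Nyquist {nyq} Hz truncates the {items[-1][0]} band", RuntimeWarning
        )
    nperseg = int(round(segment_seconds * epoch.fs))
    if epoch.n_samples < nperseg:
        raise ValueError("epoch shorter than one Welch segment")
    freqs, psd = signal.welch(
        epoch.samples,
        fs=epoch.fs,
        nperseg=nperseg,
        noverlap=int(nperseg * overlap),
        window="hann",
        axis=1,
    )
    total_mask = (freqs >= TOTAL_RANGE[0]) & (freqs < TOTAL_RANGE[1])
    total = psd[:, total_mask].sum(axis=1)
    total[total == 0] = np.nan
    out = {}
    for name, (lo, hi) in items:
        mask = (freqs >= lo) & (freqs < hi)
        out[name] = 100.0 * psd[:, mask].sum(axis=1) / total
    return pd.DataFrame(out, index=list(epoch.channel_names))


@lru_cache(maxsize=8)
def _cwt_calibration(fs: float, wavelet: str, f_lo: int, f_hi: int) -> np.ndarray:
    """Scalogram energy response to a unit sinusoid at each grid frequency.

    Measured on an 8 s probe; relative shape across frequency is what matters
    (stationary-signal response scales linearly with duration).
    """
    freqs = np.arange(f_lo, f_hi + 1, dtype=float)
    scales = pywt.frequency2scale(wavelet, freqs / fs)
    t = np.arange(int(8 * fs)) / fs
    gain = np.empty(len(freqs))
    for i, f0 in enumerate(freqs):
        W, _ = pywt.cwt(np.sin(2 * np.pi * f0 * t), scales, wavelet, method="fft")
        gain[i] = (np.abs(W) ** 2).sum()
    return gain / gain.mean()


def scalogram_band_energy(
    x: np.ndarray,
    fs: float,
    bands=None,
    wavelet: str = "cmor1.5-1.0",
    gain_calibration: bool = True,
) -> dict[str, float]:
    """Five-band relative energies (%) of one signal from a Morlet scalogram."""
    items = _band_items(bands)
    nyq = fs / 2.0
    # grid spans [1, 60): the 60 Hz bin belongs to neither half-open band
    f_lo = int(TOTAL_RANGE[0])
    f_hi = int(min(TOTAL_RANGE[1] - 1, np.floor(nyq - 1)))
    freqs = np.arange(f_lo, f_hi + 1, dtype=float)
    scales = pywt.frequency2scale(wavelet, freqs / fs)
    W, _ = pywt.cwt(np.asarray(x, dtype=float), scales, wavelet, method="fft")
    P = (np.abs(W) ** 2).sum(axis=1)
    if gain_calibration:
        P = P / _cwt_calibration(fs, wavelet, f_lo, f_hi)
    total = P.sum()
    if total == 0:
        return {name: np.nan for name, _ in items}
    return {
        name: float(100.0 * P[(freqs >= lo) & (freqs < hi)].sum() / total)
        for name, (lo, hi) in items
    }


def band_energy_wavelet(
    epoch: EEGEpoch,
    bands=None,
    wavelet: str = "cmor1.5-1.0",
    gain_calibration: bool = True,
) -> pd.DataFrame:
    """Relative band energy (%) per channel from a continuous wavelet transform."""
    items = _band_items(bands)
    nyq = epoch.fs / 2.0
    if nyq <= items[-1][1][1]:
        warnings.warn(
            f"Nyquist {nyq} Hz truncates the {items[-1][0]} band", RuntimeWarning
        )
    if epoch.n_samples < epoch.fs:
        raise ValueError("epoch shorter than one second; scalogram unreliable")
    rows = {
        ch: scalogram_band_energy(epoch.samples[i], epoch.fs, bands, wavelet, gain_calibration)
        for i, ch in enumerate(epoch.channel_names)
    }
    return pd.DataFrame.from_dict(rows, orient="index")[list(dict(items))]


def classwise_median(epochs: list[EEGEpoch]) -> EEGEpoch:
    """Point-wise median over equally shaped epochs (outlier-robust aggregate).

    With an even number of epochs the median is the mean of the two central
    values, element-wise.
    """
    if not epochs:
        raise ValueError("no epochs to aggregate")
    shapes = {e.samples.shape for e in epochs}
    if len(shapes) != 1:
        raise ValueError(f"epochs have mismatched shapes: {shapes}")
    stack = np.stack([e.samples for e in epochs])
    med = np.median(stack, axis=0)
    return epochs[0].with_samples(med)


def select_consistent_subjects(conformity: dict) -> list:
    """Subjects whose conformity rate strictly exceeds the mean rate.

    If all rates are equal (degenerate), warns and falls back to all subjects.
    """
    if not conformity:
        raise ValueError("empty conformity table")
    mean = float(np.mean(list(conformity.values())))
    kept = [s for s, c in conformity.items() if c > mean]
    if not kept:
        warnings.warn(
            "no subject above mean conformity; retaining all subjects", RuntimeWarning
        )
        return list(conformity)
    return kept


@dataclass
class ChannelStats:
    """Per (class, channel) median amplitude and mean squared deviation."""

    median: pd.DataFrame  # class x channel
    mse: pd.DataFrame


def channel_stats(epochs_by_class: dict[str, list[EEGEpoch]]) -> ChannelStats:
    """Median amplitude and within-window mean squared deviation per channel.

    MSE here is the mean squared deviation from the channel's own mean over
    the analysis window (i.e. the population variance of the samples) — a
    dispersion measure, invariant to constant offsets.
    """
    med_rows, mse_rows = {}, {}
    for cls, epochs in epochs_by_class.items():
        rep = classwise_median(epochs)
        med_rows[cls] = {
            ch: float(np.median(rep.samples[i]))
            for i, ch in enumerate(rep.channel_names)
        }
        mse_rows[cls] = {
            ch: float(np.mean((rep.samples[i] - rep.samples[i].mean()) ** 2))
            for i, ch in enumerate(rep.channel_names)
        }
    return ChannelStats(
        median=pd.DataFrame.from_dict(med_rows, orient="index"),
        mse=pd.DataFrame.from_dict(mse_rows, orient="index"),
    )


def build_band_table(
    epochs_by_class: dict[str, list[EEGEpoch]],
    bands=None,
    methods: tuple[str, ...] = ("fft", "wavelet"),
    aggregate: str = "median_then_spectrum",
) -> pd.DataFrame:
    """Class × band × method × channel relative-energy table (percent).

    Each class's epochs are first aggregated to one representative signal by
    the point-wise median, then band shares are estimated on that signal (the
    alternative ``aggregate='spectrum_then_median'`` computes shares per epoch
    and takes their median). The frame is indexed by (band, method, class)
    with channels as columns; every row sums to ~100.
    """
    if not epochs_by_class:
        raise ValueError("no classes supplied")
    missing = [c for c, eps in epochs_by_class.items() if not eps]
    if missing:
        raise ValueError(f"classes with no epochs: {missing}")
    rows = []
    index = []
    for method in methods:
        fn = band_energy_fft if method == "fft" else band_energy_wavelet
        for cls, epochs in epochs_by_class.items():
            if aggregate == "median_then_spectrum":
                rep = classwise_median(epochs)
                table = fn(rep, bands)  # channels x bands
            else:
                per = [fn(e, bands) for e in epochs]
                table = pd.concat(per).groupby(level=0).median()
                table = table.loc[list(epochs[0].channel_names)]
            for band in table.columns:
                rows.append(table[band].to_numpy())
                index.append((band, method, cls))
    channels = list(next(iter(epochs_by_class.values()))[0].channel_names)
    idx = pd.MultiIndex.from_tuples(index, names=["band", "method", "class"])
    frame = pd.DataFrame(rows, index=idx, columns=channels)
    frame.attrs["n_epochs"] = {c: len(e) for c, e in epochs_by_class.items()}
    return frame
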