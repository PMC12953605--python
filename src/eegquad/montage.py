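"""Electrode montages for the DEAP 32-channel layout and the reduced 11-channel set.

The reduced montage keeps four prefrontal/frontal electrodes (FP1, FP2, F3, F4),
two central (C3, C4), two temporal (T7, T8), one parietal (Pz) and two occipital
(O1, O2) — the regions most consistently implicated in valence appraisal,
arousal discrimination, auditory-emotional and visual-emotional processing.
Dropping the remaining 21 electrodes shrinks the sensor layout by roughly
two-thirds, which is the point of a portable configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: EEG channel order of the DEAP "preprocessed" release (first 32 of the 40
#: recorded channels; the remaining 8 are peripheral physiology).
DEAP32_CHANNELS: tuple[str, ...] = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "C4",
    "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2", "Cz",
)

#: The reduced 11-electrode montage used throughout the analysis.
KEY11_CHANNELS: tuple[str, ...] = (
    "FP1", "FP2", "F3", "F4", "C3", "C4", "T7", "T8", "Pz", "O1", "O2",
)

#: Scalp region of every reduced-montage electrode.
KEY11_REGIONS: dict[str, str] = {
    "FP1": "prefrontal", "FP2": "prefrontal", "F3": "prefrontal", "F4": "prefrontal",
    "C3": "central", "C4": "central",
    "T7": "temporal", "T8": "temporal",
    "Pz": "parietal",
    "O1": "occipital", "O2": "occipital",
}


def _canon(name: str) -> str:
    """Case-insensitive canonical form of a channel name ('fp1' == 'Fp1' == 'FP1')."""
    return name.strip().upper()


@dataclass(frozen=True)
class MontageSpec:
    """An ordered set of channel names with a scalp-region map.

    Channel-name matching is case-insensitive ('PZ' and 'Pz' are the same
    electrode).
    """

    channel_names: tuple[str, ...]
    region_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        canon = [_canon(c) for c in self.channel_names]
        if len(set(canon)) != len(canon):
            raise ValueError("montage channel names must be unique")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index_of(self, name: str, within: tuple[str, ...] | list[str]) -> int:
        """Index of *name* inside the channel list *within* (case-insensitive)."""
        canon = [_canon(c) for c in within]
        key = _canon(name)
        if key not in canon:
            raise KeyError(f"channel {name!r} not present in {list(within)}")
        return canon.index(key)


def deap32_montage() -> MontageSpec:
    return MontageSpec(DEAP32_CHANNELS)


def key11_montage() -> MontageSpec:
    return MontageSpec(KEY11_CHANNELS, dict(KEY11_REGIONS))


def channel_reduction_percent(full: int = 32, reduced: int = 11) -> float:
    """Percentage of channels removed when going from *full* to *reduced*."""
    if reduced > full or full <= 0:
        raise ValueError("reduced montage cannot exceed the full montage")
    return 100.0 * (full - reduced) / full
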