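"""Pipeline configuration: every tunable constant in one document.

Defaults follow the analysis protocol: 4th-order Butterworth band-pass at
1–45 Hz, common average reference, kurtosis-gated ICA (threshold 5, at most
four components removed), 4-level db4 wavelet denoising with SURE soft
thresholding, canonical band edges δ 1–4 / θ 4–8 / α 8–14 / β 14–30 /
γ 30–60 Hz, PCA at 95% cumulative variance, four clusters with 15 restarts,
consistency threshold 0.5, refinement margin 0.1, mRMR retain 80, fused
selection of 8, five-fold subject-independent cross-validation and a 70/30
stratified split.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

#: Canonical EEG band edges in Hz, half-open [low, high).
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 14.0),
    "beta": (14.0, 30.0),
    "gamma": (30.0, 60.0),
}

BAND_NAMES = tuple(DEFAULT_BANDS)


@dataclass
class PipelineConfig:
    # --- signal preprocessing ---
    bandpass_low: float = 1.0
    bandpass_high: float = 45.0
    filter_order: int = 4
    ica_kurtosis_threshold: float = 5.0
    ica_max_remove: int = 4
    ica_kurtosis_convention: str = "plain"  # "plain" (Gaussian=3) or "excess"
    dwt_level: int = 4
    dwt_wavelet: str = "db4"

    # --- spectral analysis ---
    bands: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_BANDS.items()})
    welch_segment_seconds: float = 4.0
    welch_overlap: float = 0.5
    cwt_wavelet: str = "cmor1.5-1.0"
    cwt_gain_calibration: bool = True

    # --- label calibration ---
    pca_variance_threshold: float = 0.95
    n_clusters: int = 4
    n_init: int = 15
    gmm_reg_covar: float = 1e-6
    consistency_threshold: float = 0.5
    refinement_margin: float = 0.1

    # --- feature extraction ---
    psd_window_seconds: float = 4.0
    psd_step_seconds: float = 2.0
    coherence_segment_seconds: float = 2.0

    # --- model pipeline ---
    mrmr_retain: int = 80
    fused_select: int = 8
    mrmr_bins: int = 5
    relieff_neighbors: int = 10
    cv_folds: int = 5
    train_fraction: float = 0.7
    rf_n_trees: int = 200
    rf_max_splits: int = 20
    dnn_hidden: tuple = (256, 128)
    dnn_dropout: float = 0.5
    dnn_learning_rate: float = 1e-3
    dnn_batch_size: int = 32
    dnn_epochs: int = 100

    seed: int = 0

    def __post_init__(self) -> None:
        edges = [tuple(v) for v in self.bands.values()]
        for (lo, hi) in edges:
            if not lo < hi:
                raise ValueError(f"band edges must increase: {(lo, hi)}")
        for (_, hi), (lo2, _) in zip(edges, edges[1:]):
            if lo2 < hi:
                raise ValueError("bands must be non-overlapping and ordered")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        for name in ("filter_order", "dwt_level", "n_clusters", "n_init",
                     "mrmr_retain", "fused_select", "cv_folds", "rf_n_trees"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def band_items(self) -> list[tuple[str, tuple[float, float]]]:
        return [(k, (float(v[0]), float(v[1]))) for k, v in self.bands.items()]

    def to_yaml(self) -> str:
        d = asdict(self)
        d["dnn_hidden"] = list(self.dnn_hidden)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "dnn_hidden" in data:
            data["dnn_hidden"] = tuple(data["dnn_hidden"])
        return cls(**data)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_yaml(fh.read())

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_yaml())
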