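"""End-to-end convenience pipeline: preprocess → features → engineering →
per-fold fused selection → subject-independent cross-validation.
"""

from __future__ import annotations

import numpy as np

from .config import PipelineConfig
from .containers import EEGEpoch
from .features import FeatureMatrix, assemble_features
from .models import CVReport, cv_subject_independent, diff_augment, subjectwise_zscore
from .preprocess import preprocess_epoch


def epochs_to_features(
    epochs: list[EEGEpoch],
    labels: list[str],
    config: PipelineConfig | None = None,
    preprocess: bool = True,
    seed: int = 0,
) -> FeatureMatrix:
    """Clean every epoch and assemble the 149-column feature matrix."""
    cfg = config or PipelineConfig()
    if preprocess:
        epochs = [preprocess_epoch(e, cfg, seed=seed)[0] for e in epochs]
    return assemble_features(epochs, labels, cfg)


def engineer(matrix: FeatureMatrix) -> FeatureMatrix:
    """Subject-wise z-score then first-order difference augmentation."""
    return diff_augment(subjectwise_zscore(matrix))


def evaluate_pipeline(
    matrix: FeatureMatrix,
    model: str = "rf",
    config: PipelineConfig | None = None,
    seed: int = 0,
    permute_labels: bool = False,
    engineer_features: bool = True,
) -> CVReport:
    """Engineered features → per-fold fused selection → subject-independent CV.

    With ``permute_labels`` the labels are shuffled once (seeded) before the
    whole procedure, giving the chance-level baseline.
    """
    cfg = config or PipelineConfig()
    mat = engineer(matrix) if engineer_features else matrix
    y = mat.labels
    if permute_labels:
        rng = np.random.default_rng(seed)
        y = y[rng.permutation(len(y))]
    return cv_subject_independent(
        mat.features(), y, mat.subjects,
        model=model, folds=cfg.cv_folds, seed=seed, config=cfg,
        feature_names=mat.feature_columns, select=True,
    )
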