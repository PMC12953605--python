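"""Feature engineering, fused feature selection, classifiers, and
subject-independent evaluation.

Selection methods: greedy mRMR (mutual-information difference criterion on
equal-frequency-binned features), chi-square scoring on binned non-negative
codes, and ReliefF with 10 nearest hits/misses. The fused ranking is the
ascending mean of the three per-method rank positions, ties broken by the
mRMR position.

Classifiers: RBF-kernel SVM with one-vs-one decomposition and automatic
kernel scale, a 200-tree random forest capped at 20 splits per tree, and a
256-128 batch-norm/dropout network (see :mod:`eegquad.dnn`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import chi2 as sk_chi2
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from .config import PipelineConfig
from .dnn import DenseNetClassifier
from .features import FeatureMatrix


# --------------------------------------------------------------------------
# feature engineering
# --------------------------------------------------------------------------

def subjectwise_zscore(matrix: FeatureMatrix) -> FeatureMatrix:
    """Z-score every feature column within each subject's own rows.

    Uses the population-SD convention; a column that is constant within a
    subject maps to zeros. Because each subject is normalized from its own
    statistics only, the transform is leakage-free across train/test subject
    boundaries: shifting one subject's raw features by a constant leaves that
    subject's normalized features unchanged.
    """
    frame = matrix.frame.copy()
    counts = frame.groupby("subject_id").size()
    lonely = counts[counts < 2]
    if len(lonely):
        raise ValueError(f"subjects with a single observation: {list(lonely.index)}")

    def _z(block: pd.DataFrame) -> pd.DataFrame:
        vals = block.to_numpy(dtype=float)
        mu = vals.mean(axis=0)
        sd = vals.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        return pd.DataFrame((vals - mu) / sd, index=block.index, columns=block.columns)

    cols = matrix.feature_columns
    frame[cols] = (
        frame.groupby("subject_id", group_keys=False)[cols].apply(_z)
    )
    return FeatureMatrix(frame, list(cols), dict(matrix.schema))


def diff_augment(matrix: FeatureMatrix) -> FeatureMatrix:
    """Append first-order differences along the feature (column) dimension.

    A row with feature values v1..vn gains columns (v2−v1, ..., vn−v(n−1)),
    doubling the width minus one; the label/subject columns are excluded.
    """
    cols = matrix.feature_columns
    if len(cols) < 2:
        raise ValueError("need at least 2 feature columns to difference")
    frame = matrix.frame.copy()
    vals = frame[cols].to_numpy(dtype=float)
    diffs = np.diff(vals, axis=1)
    diff_cols = [f"d_{a}__{b}" for a, b in zip(cols[:-1], cols[1:])]
    frame = pd.concat(
        [frame, pd.DataFrame(diffs, columns=diff_cols, index=frame.index)], axis=1
    )
    schema = dict(matrix.schema)
    for c in diff_cols:
        schema[c] = {"family": "diff", "electrode": None, "band": None, "statistic": "first_difference"}
    return FeatureMatrix(frame, list(cols) + diff_cols, schema)


# --------------------------------------------------------------------------
# selection
# --------------------------------------------------------------------------

def _equal_frequency_bins(X: np.ndarray, bins: int) -> np.ndarray:
    """Discretize each column into equal-frequency integer codes 0..bins-1."""
    n, p = X.shape
    codes = np.empty((n, p), dtype=np.int64)
    qs = np.linspace(0, 1, bins + 1)[1:-1]
    for j in range(p):
        edges = np.quantile(X[:, j], qs)
        codes[:, j] = np.searchsorted(edges, X[:, j], side="right")
    return codes


def _mi(a: np.ndarray, b: np.ndarray) -> float:
    """Mutual information (nats) between two integer-coded vectors.

    Plug-in estimate from the joint contingency table; agrees with
    ``sklearn.metrics.mutual_info_score`` to floating-point precision.
    """
    ka = int(a.max()) + 1
    kb = int(b.max()) + 1
    joint = np.bincount(a * kb + b, minlength=ka * kb).astype(float)
    joint /= joint.sum()
    pa = joint.reshape(ka, kb).sum(axis=1)
    pb = joint.reshape(ka, kb).sum(axis=0)
    outer = np.outer(pa, pb).ravel()
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log(joint[nz] / outer[nz])))


def mrmr_rank(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    retain: int = 80,
    bins: int = 5,
) -> list[str]:
    """Greedy minimum-redundancy maximum-relevance ranking (MID criterion).

    Features are discretized by equal-frequency binning; the first pick
    maximizes relevance I(f; y) and each subsequent pick maximizes
    I(f; y) − mean I(f; selected). Deterministic given the data (ties break
    by column order).
    """
    p = X.shape[1]
    if retain > p:
        raise ValueError(f"retain={retain} exceeds {p} features")
    classes, y_codes = np.unique(y, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    codes = _equal_frequency_bins(np.asarray(X, dtype=float), bins)
    relevance = np.array([_mi(codes[:, j], y_codes) for j in range(p)])
    selected: list[int] = []
    red_sum = np.zeros(p)
    remaining = set(range(p))
    for _ in range(retain):
        if not selected:
            obj = relevance.copy()
        else:
            obj = relevance - red_sum / len(selected)
        obj_masked = np.full(p, -np.inf)
        idx = sorted(remaining)
        obj_masked[idx] = obj[idx]
        pick = int(np.argmax(obj_masked))
        selected.append(pick)
        remaining.discard(pick)
        if remaining:
            for j in remaining:
                red_sum[j] += _mi(codes[:, j], codes[:, pick])
    return [feature_names[i] for i in selected]


def chi2_rank(X: np.ndarray, y: np.ndarray, feature_names: list[str], bins: int = 5) -> list[str]:
    """Chi-square ranking on binned, non-negative feature codes."""
    codes = _equal_frequency_bins(np.asarray(X, dtype=float), bins).astype(float)
    scores, _ = sk_chi2(codes - codes.min(axis=0), y)
    scores = np.nan_to_num(scores, nan=0.0)
    order = np.argsort(-scores, kind="stable")
    return [feature_names[i] for i in order]


def relieff_rank(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    n_neighbors: int = 10,
    seed: int = 0,
) -> list[str]:
    """ReliefF feature weighting with every observation as a probe.

    Feature differences are range-normalized; for each probe the k nearest
    hits (same class) decrease a feature's weight and the k nearest misses of
    every other class increase it, miss contributions weighted by class prior.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    classes, y_codes = np.unique(y, return_inverse=True)
    span = X.max(axis=0) - X.min(axis=0)
    span[span == 0] = 1.0
    Xn = X / span
    priors = np.bincount(y_codes) / n
    # pairwise L1 distances in range-normalized space
    d = np.abs(Xn[:, None, :] - Xn[None, :, :]).sum(axis=2)
    np.fill_diagonal(d, np.inf)
    w = np.zeros(p)
    for i in range(n):
        ci = y_codes[i]
        hits = np.where(y_codes == ci)[0]
        hits = hits[hits != i]
        k_h = min(n_neighbors, len(hits))
        if k_h:
            nearest = hits[np.argsort(d[i, hits], kind="stable")[:k_h]]
            w -= np.abs(Xn[nearest] - Xn[i]).sum(axis=0) / (k_h * n)
        for cj in range(len(classes)):
            if cj == ci:
                continue
            miss = np.where(y_codes == cj)[0]
            k_m = min(n_neighbors, len(miss))
            if not k_m:
                continue
            nearest = miss[np.argsort(d[i, miss], kind="stable")[:k_m]]
            weight = priors[cj] / (1.0 - priors[ci])
            w += weight * np.abs(Xn[nearest] - Xn[i]).sum(axis=0) / (k_m * n)
    order = np.argsort(-w, kind="stable")
    return [feature_names[i] for i in order]


@dataclass
class SelectionResult:
    """Per-method rankings, the fused ranking, and the selected subset."""

    rankings: dict  # method -> full ranked list of names
    fused: list[str]
    selected: list[str]


def fused_rank(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    top: int = 8,
    bins: int = 5,
    relieff_neighbors: int = 10,
    seed: int = 0,
) -> SelectionResult:
    """Fuse mRMR, chi-square and ReliefF rankings; keep the *top* features.

    The fused score of a feature is the mean of its three rank positions
    (lower is better); ties break by the mRMR position.
    """
    names = list(feature_names)
    if top > len(names):
        raise ValueError(f"top={top} exceeds {len(names)} features")
    rankings = {
        "mrmr": mrmr_rank(X, y, names, retain=len(names), bins=bins),
        "chi2": chi2_rank(X, y, names, bins=bins),
        "relieff": relieff_rank(X, y, names, n_neighbors=relieff_neighbors, seed=seed),
    }
    fused = fuse_rankings(rankings, names)
    return SelectionResult(rankings, fused, fused[:top])


def fuse_rankings(rankings: dict[str, list[str]], names: list[str]) -> list[str]:
    """Order *names* by ascending mean rank position; ties break by mRMR rank."""
    pos = {m: {f: i for i, f in enumerate(r)} for m, r in rankings.items()}
    return sorted(
        names,
        key=lambda f: (np.mean([pos[m][f] for m in rankings]), pos["mrmr"][f]),
    )


def select_features(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    mrmr_retain: int = 80,
    fused_top: int = 8,
    bins: int = 5,
    relieff_neighbors: int = 10,
    seed: int = 0,
) -> SelectionResult:
    """Nested selection: mRMR keeps the top 80, fusion then keeps the top 8."""
    names = list(feature_names)
    kept = mrmr_rank(X, y, names, retain=min(mrmr_retain, len(names)), bins=bins)
    idx = [names.index(f) for f in kept]
    res = fused_rank(
        X[:, idx], y, kept, top=fused_top, bins=bins,
        relieff_neighbors=relieff_neighbors, seed=seed,
    )
    return SelectionResult(res.rankings, res.fused, res.selected)


# --------------------------------------------------------------------------
# classifiers
# --------------------------------------------------------------------------

def train_model(X: np.ndarray, y: np.ndarray, model: str = "rf", config: PipelineConfig | None = None, seed: int = 0):
    """Fit one of the three classifier families and return the fitted model."""
    cfg = config or PipelineConfig()
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes to train")
    if not np.isfinite(np.asarray(X, dtype=float)).all():
        raise ValueError("feature matrix contains NaN/inf")
    if model == "svm":
        clf = SVC(kernel="rbf", gamma="auto", decision_function_shape="ovo", random_state=seed)
    elif model == "rf":
        # "at most 20 splits per tree" enforced as a 21-leaf cap
        clf = RandomForestClassifier(
            n_estimators=cfg.rf_n_trees,
            max_leaf_nodes=cfg.rf_max_splits + 1,
            random_state=seed,
        )
    elif model == "dnn":
        clf = DenseNetClassifier(
            hidden=cfg.dnn_hidden,
            dropout=cfg.dnn_dropout,
            learning_rate=cfg.dnn_learning_rate,
            batch_size=cfg.dnn_batch_size,
            epochs=cfg.dnn_epochs,
            seed=seed,
        )
    else:
        raise ValueError(f"unknown model tag {model!r}")
    return clf.fit(X, y)


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------

def metrics_report(predictions: np.ndarray, truth: np.ndarray, classes=None) -> dict:
    """Per-class recall/precision/F1 and the confusion matrix.

    A class present in the truth but never predicted gets precision 0 and is
    listed under ``undefined_precision``.
    """
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape:
        raise ValueError("predictions and truth differ in length")
    if classes is None:
        classes = sorted(set(truth.tolist()) | set(predictions.tolist()))
    cm = confusion_matrix(truth, predictions, labels=classes)
    per_class = {}
    flags = []
    for i, c in enumerate(classes):
        tp = cm[i, i]
        support = cm[i].sum()
        predicted = cm[:, i].sum()
        recall = tp / support if support else 0.0
        if predicted == 0:
            precision = 0.0
            flags.append(c)
        else:
            precision = tp / predicted
        f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
        per_class[c] = {"recall": float(recall), "precision": float(precision), "f1": float(f1)}
    return {
        "accuracy": float((predictions == truth).mean()),
        "per_class": per_class,
        "confusion_matrix": cm,
        "classes": list(classes),
        "undefined_precision": flags,
    }


@dataclass
class CVReport:
    """Five-fold subject-independent cross-validation results."""

    fold_accuracies: list[float]
    fold_subjects: list[list]
    pooled: dict
    model: str = ""
    seed: int = 0
    selected_per_fold: list = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


def subject_folds(subjects: np.ndarray, folds: int, seed: int) -> list[list]:
    """Partition the distinct subjects into *folds* balanced, seeded rosters."""
    uniq = sorted(set(np.asarray(subjects).tolist()))
    if folds > len(uniq):
        raise ValueError(f"{folds} folds but only {len(uniq)} subjects")
    rng = np.random.default_rng(seed)
    order = [uniq[i] for i in rng.permutation(len(uniq))]
    return [order[i::folds] for i in range(folds)]


def cv_subject_independent(
    X: np.ndarray,
    y: np.ndarray,
    subjects: np.ndarray,
    model: str = "rf",
    folds: int = 5,
    seed: int = 0,
    config: PipelineConfig | None = None,
    feature_names: list[str] | None = None,
    select: bool = False,
) -> CVReport:
    """Subject-independent k-fold cross-validation.

    Subjects are partitioned into disjoint fold rosters; each fold trains on
    the out-of-fold subjects and tests on the in-fold subjects, so no subject
    contributes to both sides. With ``select=True`` the nested
    mRMR-80 → fused-8 feature selection is refit inside each training fold
    (test labels never influence the selected subset).
    """
    cfg = config or PipelineConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    subjects = np.asarray(subjects)
    rosters = subject_folds(subjects, folds, seed)
    fold_acc, all_pred, all_true, selected_log = [], [], [], []
    for roster in rosters:
        test_mask = np.isin(subjects, roster)
        Xtr, ytr = X[~test_mask], y[~test_mask]
        Xte, yte = X[test_mask], y[test_mask]
        if select:
            names = feature_names or [f"f{i}" for i in range(X.shape[1])]
            sel = select_features(
                Xtr, ytr, names,
                mrmr_retain=cfg.mrmr_retain, fused_top=cfg.fused_select,
                bins=cfg.mrmr_bins, relieff_neighbors=cfg.relieff_neighbors, seed=seed,
            )
            idx = [names.index(f) for f in sel.selected]
            Xtr, Xte = Xtr[:, idx], Xte[:, idx]
            selected_log.append(sel.selected)
        clf = train_model(Xtr, ytr, model, cfg, seed)
        pred = clf.predict(Xte)
        fold_acc.append(float((pred == yte).mean()))
        all_pred.append(pred)
        all_true.append(yte)
    pooled = metrics_report(np.concatenate(all_pred), np.concatenate(all_true))
    return CVReport(fold_acc, rosters, pooled, model, seed, selected_log)


def stratified_split(
    X: np.ndarray,
    y: np.ndarray,
    train_frac: float = 0.7,
    seed: int = 0,
) -> dict:
    """70/30 stratified split with a chi-square class-distribution check.

    The homogeneity test compares train/test class counts; a p-value at or
    below 0.05 triggers a warning flag (well-matched splits have p > 0.05).
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must lie strictly between 0 and 1")
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 members to stratify")
    idx = np.arange(len(y))
    tr, te = train_test_split(
        idx, train_size=train_frac, stratify=y, random_state=seed
    )
    table = np.stack([
        [np.sum(y[tr] == c) for c in classes],
        [np.sum(y[te] == c) for c in classes],
    ])
    chi2_stat, p, _, _ = stats.chi2_contingency(table)
    return {
        "train_idx": tr,
        "test_idx": te,
        "chi2": float(chi2_stat),
        "p_value": float(p),
        "distribution_ok": bool(p > 0.05),
    }
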