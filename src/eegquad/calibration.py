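"""Dynamic hierarchical label calibration.

Turns a multi-subject VADL rating panel into per-video dominant-emotion labels.
Two routes are provided:

* **Clustering routes** (``kmeans`` / ``gmm`` / ``hier``): per-subject z-score
  normalization, per-video PCA at 95% cumulative variance, pooled unsupervised
  clustering into four groups, and an optimal bijective mapping of clusters
  onto the four valence–arousal quadrants.
* **Calibrated route** (``calibrated``): independent global z-score
  normalization, sign-based quadrant assignment in (z_V, z_A), and margin-based
  borderline refinement in which a small |z_V| defers the valence side to the
  liking score and a small |z_A| defers the arousal side to the dominance
  score.

Either way, each video's dominant label is the mode over subjects, its
consistency the modal share, and each subject's conformity the fraction of
videos where they agree with the group.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from sklearn.mixture import GaussianMixture

from .containers import (
    QUADRANT_SIGNS,
    QUADRANT_TO_CODE,
    QUADRANTS,
    RatingsPanel,
    VADL_COLUMNS,
    quadrant_from_sides,
)

Z_COLUMNS = ("z_valence", "z_arousal", "z_dominance", "z_liking")


@dataclass
class NormalizedRatings:
    """Z-scored VADL ratings with the normalization scope recorded."""

    frame: pd.DataFrame  # subject_id, video_id, z_valence..z_liking
    scope: str  # "per_subject" or "global"


def zscore_panel(panel: RatingsPanel, scope: str = "per_subject") -> NormalizedRatings:
    """Z-score the four rating dimensions (population SD, ddof 0).

    ``per_subject`` normalizes each dimension within each subject's own
    ratings, removing individual differences in how subjects use the 1–9
    scale. ``global`` normalizes each dimension over all (subject, video)
    samples — the scope used by the borderline-refinement rule. Constant
    groups map to zeros.
    """
    if len(panel) == 0:
        raise ValueError("empty panel")
    frame = panel.frame.copy()

    def _z(values: np.ndarray) -> np.ndarray:
        if values.size < 2:
            raise ValueError("z-score scope with a single observation")
        sd = values.std(ddof=0)
        if sd == 0:
            return np.zeros_like(values)
        return (values - values.mean()) / sd

    out = frame[["subject_id", "video_id"]].copy()
    for col, zcol in zip(VADL_COLUMNS, Z_COLUMNS):
        if scope == "per_subject":
            out[zcol] = (
                frame.groupby("subject_id")[col]
                .transform(lambda s: _z(s.to_numpy(dtype=float)))
            )
        elif scope == "global":
            out[zcol] = _z(frame[col].to_numpy(dtype=float))
        else:
            raise ValueError(f"unknown scope {scope!r}")
    return NormalizedRatings(out, scope)


def reduce_pca(
    norm: NormalizedRatings, variance_threshold: float = 0.95
) -> tuple[pd.DataFrame, dict]:
    """Per-video PCA of the subjects × 4 rating matrix at 95% cumulative variance.

    For each video the smallest k whose cumulative explained variance reaches
    the threshold is retained (k in 1..4); subject-wise component scores are
    returned padded with zeros to 4 columns so videos with different k pool
    into one space. Returns (scores frame, per-video retained counts).
    """
    frame = norm.frame
    videos = sorted(frame["video_id"].unique())
    retained: dict = {}
    rows = []
    for v in videos:
        sub = frame[frame["video_id"] == v].sort_values("subject_id")
        X = sub[list(Z_COLUMNS)].to_numpy(dtype=float)
        if X.shape[0] < 2:
            raise ValueError(f"video {v!r} has fewer than 2 subjects")
        Xc = X - X.mean(axis=0)
        if np.allclose(Xc, 0):
            # all subjects identical: no variance to decompose
            retained[v] = 1
            scores = np.zeros((X.shape[0], 4))
        else:
            pca = PCA(n_components=min(4, X.shape[0]))
            s = pca.fit_transform(X)
            cum = np.cumsum(pca.explained_variance_ratio_)
            k = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
            k = min(k, s.shape[1])
            retained[v] = k
            scores = np.zeros((X.shape[0], 4))
            scores[:, :k] = s[:, :k]
        block = sub[["subject_id", "video_id"]].copy()
        for j in range(4):
            block[f"pc{j + 1}"] = scores[:, j]
        rows.append(block)
    out = pd.concat(rows, ignore_index=True)
    out.attrs["avg_components"] = float(np.mean(list(retained.values())))
    return out, retained


@dataclass
class ClusterResult:
    assignments: np.ndarray  # int cluster index per row of scores frame
    silhouette: float
    responsibilities: np.ndarray | None = None  # gmm only: rows x k
    method: str = ""


def cluster_panel(
    scores: pd.DataFrame,
    method: str = "gmm",
    k: int = 4,
    n_init: int = 15,
    reg_covar: float = 1e-6,
    seed: int = 0,
) -> ClusterResult:
    """Cluster pooled per-(subject, video) PCA scores into k groups.

    GMM uses full covariances, 15 restarts and a covariance regularizer;
    k-means uses 15 restarts; hierarchical clustering uses Ward linkage.
    The silhouette score is computed in the clustered space.
    """
    X = scores[[c for c in scores.columns if c.startswith("pc")]].to_numpy(dtype=float)
    n = X.shape[0]
    if k < 2 or k > n:
        raise ValueError(f"cluster count k={k} must be in [2, {n}]")
    resp = None
    if method == "kmeans":
        model = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels = model.fit_predict(X)
    elif method == "gmm":
        model = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=n_init,
            reg_covar=reg_covar,
            random_state=seed,
        )
        labels = model.fit_predict(X)
        resp = model.predict_proba(X)
    elif method == "hier":
        model = AgglomerativeClustering(n_clusters=k, linkage="ward")
        labels = model.fit_predict(X)
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    if len(set(labels.tolist())) > 1 and not np.allclose(X.std(axis=0), 0):
        sil = float(silhouette_score(X, labels))
    else:
        sil = float("nan")
    return ClusterResult(np.asarray(labels), sil, resp, method)


def map_clusters_to_quadrants(
    assignments: np.ndarray, norm: NormalizedRatings
) -> tuple[pd.DataFrame, dict]:
    """Bijectively map cluster indices onto valence–arousal quadrants.

    Cluster centroids are computed in (z_valence, z_arousal); the bijection is
    chosen by brute force over all 4! assignments, maximizing the mean cosine
    agreement between centroids and the quadrant sign prototypes (+,+), (+,−),
    (−,+), (−,−). A degenerate clustering (< 4 non-empty clusters) is flagged
    and each observation falls back to its nearest sign prototype.
    """
    frame = norm.frame.copy()
    frame = frame.assign(cluster=np.asarray(assignments))
    za = frame[["z_valence", "z_arousal"]].to_numpy(dtype=float)
    present = sorted(set(frame["cluster"].tolist()))
    protos = {q: np.array(QUADRANT_SIGNS[q], dtype=float) for q in QUADRANTS}
    if len(present) < 4:
        warnings.warn("degenerate clustering; nearest-prototype fallback", RuntimeWarning)
        labels = []
        for row in za:
            sims = {q: float(row @ p) for q, p in protos.items()}
            labels.append(max(sims, key=sims.get))
        frame["label"] = labels
        return frame[["subject_id", "video_id", "label"]], {"degenerate": True}
    cents = {c: za[frame["cluster"] == c].mean(axis=0) for c in present}

    def cos(a, b):
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0 or nb == 0:
            return 0.0
        return float(a @ b / (na * nb))

    best, best_score = None, -np.inf
    for perm in itertools.permutations(QUADRANTS):
        score = np.mean([cos(cents[c], protos[q]) for c, q in zip(present, perm)])
        if score > best_score:
            best_score, best = score, dict(zip(present, perm))
    frame["label"] = frame["cluster"].map(best)
    return frame[["subject_id", "video_id", "label"]], {"mapping": best, "degenerate": False}


def threshold_baseline(panel: RatingsPanel) -> pd.DataFrame:
    """Conventional fixed-threshold quadrant assignment: V > 5 high, A > 5 high.

    A rating exactly at the scale midpoint 5 counts as the low side.
    """
    frame = panel.frame
    labels = [
        quadrant_from_sides(v > 5.0, a > 5.0)
        for v, a in zip(frame["valence"], frame["arousal"])
    ]
    return frame[["subject_id", "video_id"]].assign(label=labels)


def sign_quadrants(norm: NormalizedRatings) -> pd.DataFrame:
    """Quadrant per (subject, video) from the signs of (z_valence, z_arousal)."""
    frame = norm.frame
    labels = [
        quadrant_from_sides(zv > 0.0, za > 0.0)
        for zv, za in zip(frame["z_valence"], frame["z_arousal"])
    ]
    return frame[["subject_id", "video_id"]].assign(label=labels)


def dominant_label(labels: list[str]) -> tuple[str, float, bool]:
    """Modal label over subjects with its consistency (modal share).

    Ties resolve to the lowest quadrant integer code and are flagged.
    """
    if not labels:
        raise ValueError("no labels supplied")
    counts = {q: 0 for q in QUADRANTS}
    for lab in labels:
        counts[lab] += 1
    top = max(counts.values())
    winners = [q for q in QUADRANTS if counts[q] == top]
    return winners[0], top / len(labels), len(winners) > 1


def refine_borderline(
    norm: NormalizedRatings, labels: pd.DataFrame, margin: float = 0.1
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Re-decide borderline valence/arousal sides from the liking/dominance scores.

    A sample with |z_valence| < margin has its valence side set by the sign of
    z_liking; one with |z_arousal| < margin has its arousal side set by the
    sign of z_dominance. Non-borderline samples are untouched. Returns the
    refined labels plus a log of every change.
    """
    merged = labels.merge(norm.frame, on=["subject_id", "video_id"], validate="one_to_one")
    out_labels = []
    log_rows = []
    for _, row in merged.iterrows():
        old = row["label"]
        hv = old in ("HVHA", "HVLA")
        ha = old in ("HVHA", "LVHA")
        if abs(row["z_valence"]) < margin:
            hv = row["z_liking"] > 0.0
        if abs(row["z_arousal"]) < margin:
            ha = row["z_dominance"] > 0.0
        new = quadrant_from_sides(hv, ha)
        out_labels.append(new)
        if new != old:
            log_rows.append(
                {
                    "subject_id": row["subject_id"],
                    "video_id": row["video_id"],
                    "old": old,
                    "new": new,
                    "z_valence": row["z_valence"],
                    "z_arousal": row["z_arousal"],
                }
            )
    refined = merged[["subject_id", "video_id"]].assign(label=out_labels)
    log = pd.DataFrame(log_rows, columns=["subject_id", "video_id", "old", "new", "z_valence", "z_arousal"])
    return refined, log


def evaluate_labels(candidate: pd.DataFrame, reference: pd.DataFrame) -> dict:
    """Accuracy at the individual level, fit rate at the dominant-label level.

    Accuracy is the fraction of (subject, video) assignments matching the
    reference; fit rate is the fraction of videos whose dominant label matches
    the reference's dominant label.
    """
    if set(candidate["video_id"]) != set(reference["video_id"]):
        raise ValueError("candidate and reference cover different video sets")
    key = ["subject_id", "video_id"] if "subject_id" in reference.columns else ["video_id"]
    merged = candidate.merge(reference, on=key, suffixes=("_cand", "_ref"))
    acc = float((merged["label_cand"] == merged["label_ref"]).mean())

    def dom(frame):
        return {
            v: dominant_label(g["label"].tolist())[0]
            for v, g in frame.groupby("video_id")
        }

    if "subject_id" in reference.columns:
        ref_dom = dom(reference)
    else:
        ref_dom = dict(zip(reference["video_id"], reference["label"]))
    cand_dom = dom(candidate)
    fit = float(np.mean([cand_dom[v] == ref_dom[v] for v in ref_dom]))
    return {"accuracy": acc, "fit_rate": fit}


@dataclass
class DominantLabelReport:
    """Per-video dominant labels with consistency/uncertainty bookkeeping."""

    per_video: pd.DataFrame  # video_id, label, consistency, tied, p_HVHA..p_LVLA
    conformity: dict  # subject -> rate
    assignments: pd.DataFrame  # subject_id, video_id, label
    silhouette: float = float("nan")
    method: str = ""
    extras: dict = field(default_factory=dict)


def build_report(assignments: pd.DataFrame, method: str = "", silhouette: float = float("nan")) -> DominantLabelReport:
    """Aggregate per-(subject, video) labels into the dominant-label report."""
    rows = []
    for v, g in assignments.groupby("video_id"):
        labs = g["label"].tolist()
        lab, cons, tied = dominant_label(labs)
        probs = {f"p_{q}": labs.count(q) / len(labs) for q in QUADRANTS}
        rows.append({"video_id": v, "label": lab, "consistency": cons, "tied": tied, **probs})
    per_video = pd.DataFrame(rows).sort_values("video_id").reset_index(drop=True)
    dom = dict(zip(per_video["video_id"], per_video["label"]))
    conformity = {
        s: float(np.mean([row["label"] == dom[row["video_id"]] for _, row in g.iterrows()]))
        for s, g in assignments.groupby("subject_id")
    }
    return DominantLabelReport(per_video, conformity, assignments, silhouette, method)


def output_modes(report: DominantLabelReport, consistency_threshold: float = 0.5) -> dict:
    """Three views of the report: majority, confidence-filtered, probabilistic."""
    per_video = report.per_video
    majority = per_video[["video_id", "label"]].copy()
    filtered = per_video[per_video["consistency"] >= consistency_threshold][
        ["video_id", "label", "consistency"]
    ].copy()
    prob_cols = [f"p_{q}" for q in QUADRANTS]
    probabilistic = per_video[["video_id"] + prob_cols].copy()
    return {"majority": majority, "confidence_filtered": filtered, "probabilistic": probabilistic}


def calibrate_labels(
    panel: RatingsPanel,
    method: str = "calibrated",
    variance_threshold: float = 0.95,
    margin: float = 0.1,
    n_init: int = 15,
    reg_covar: float = 1e-6,
    seed: int = 0,
) -> DominantLabelReport:
    """End-to-end label calibration by any of the four strategies.

    ``kmeans`` / ``gmm`` / ``hier`` run the clustering route;
    ``calibrated`` runs the sign-based route with margin refinement (the
    hierarchical calibration strategy proper).
    """
    if method in ("kmeans", "gmm", "hier"):
        norm = zscore_panel(panel, scope="per_subject")
        scores, _ = reduce_pca(norm, variance_threshold)
        result = cluster_panel(scores, method, k=4, n_init=n_init, reg_covar=reg_covar, seed=seed)
        assignments, info = map_clusters_to_quadrants(result.assignments, norm)
        report = build_report(assignments, method, result.silhouette)
        report.extras.update(info)
        return report
    if method == "calibrated":
        norm = zscore_panel(panel, scope="global")
        base = sign_quadrants(norm)
        refined, log = refine_borderline(norm, base, margin)
        report = build_report(refined, method)
        report.extras["refinement_log"] = log
        return report
    raise ValueError(f"unknown calibration method {method!r}")
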