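"""Label calibration: normalization, PCA, clustering, quadrant mapping,
refinement, and recovery of planted video labels."""

import itertools

import numpy as np
import pandas as pd
import pytest

from eegquad.calibration import (
    NormalizedRatings,
    build_report,
    calibrate_labels,
    cluster_panel,
    dominant_label,
    evaluate_labels,
    map_clusters_to_quadrants,
    output_modes,
    reduce_pca,
    refine_borderline,
    sign_quadrants,
    threshold_baseline,
    zscore_panel,
)
from eegquad.containers import QUADRANT_SIGNS, QUADRANTS, RatingsPanel
from eegquad.simulate import SyntheticDesign, gen_ratings


class TestZScore:
    def test_three_point_hand_computation(self):
        # one subject, three videos: [1, 5, 9] -> +/- 1.2247 (population SD)
        frame = pd.DataFrame(
            {
                "subject_id": [0, 0, 0],
                "video_id": [0, 1, 2],
                "valence": [1.0, 5.0, 9.0],
                "arousal": [5.0, 5.0, 5.0],
                "dominance": [5.0, 5.0, 5.0],
                "liking": [5.0, 5.0, 5.0],
            }
        )
        norm = zscore_panel(RatingsPanel(frame), scope="per_subject")
        np.testing.assert_allclose(
            norm.frame["z_valence"], [-1.2247448, 0.0, 1.2247448], atol=1e-6
        )
        # constant column maps to zeros
        np.testing.assert_array_equal(norm.frame["z_arousal"], [0.0, 0.0, 0.0])

    def test_output_is_self_consistently_standardized(self):
        design = SyntheticDesign(n_subjects=6, n_videos=10, seed=2)
        panel, _ = gen_ratings(design)
        norm = zscore_panel(panel, scope="global")
        for col in ("z_valence", "z_arousal", "z_dominance", "z_liking"):
            vals = norm.frame[col].to_numpy()
            assert abs(vals.mean()) < 1e-9
            assert abs(vals.std(ddof=0) - 1.0) < 1e-9

    def test_single_observation_scope_errors(self):
        frame = pd.DataFrame(
            {
                "subject_id": [0],
                "video_id": [0],
                "valence": [5.0], "arousal": [5.0], "dominance": [5.0], "liking": [5.0],
            }
        )
        with pytest.raises(ValueError):
            zscore_panel(RatingsPanel(frame), scope="per_subject")


class TestPCA:
    @staticmethod
    def _norm_from_matrix(X):
        """One video rated by n subjects with the given 4-D z-rows."""
        X = np.asarray(X, dtype=float)
        frame = pd.DataFrame(X, columns=["z_valence", "z_arousal", "z_dominance", "z_liking"])
        frame.insert(0, "video_id", 0)
        frame.insert(0, "subject_id", range(len(X)))
        return NormalizedRatings(frame, "per_subject")

    def test_rank_one_matrix_keeps_one_component(self):
        base = np.array([1.0, 2.0, -1.0, 0.5])
        X = np.outer([1.0, 2.0, 3.0, 4.0], base)
        _, retained = reduce_pca(self._norm_from_matrix(X), 0.95)
        assert retained[0] == 1

    def test_threshold_one_on_full_rank_keeps_four(self, rng):
        X = rng.standard_normal((12, 4))
        _, retained = reduce_pca(self._norm_from_matrix(X), 1.0)
        assert retained[0] == 4

    def test_retained_count_matches_eigendecomposition(self, rng):
        X = np.random.default_rng(7).standard_normal((32, 4)) * [3.0, 1.5, 0.5, 0.1]
        _, retained = reduce_pca(self._norm_from_matrix(X), 0.95)
        # oracle: direct eigenvalue cumulative sum of the covariance matrix
        evals = np.linalg.eigvalsh(np.cov(X.T))[::-1]
        k = int(np.searchsorted(np.cumsum(evals) / evals.sum(), 0.95 - 1e-12) + 1)
        assert retained[0] == k

    def test_fewer_than_two_subjects_errors(self):
        with pytest.raises(ValueError):
            reduce_pca(self._norm_from_matrix(np.ones((1, 4))))


class TestClustering:
    @staticmethod
    def _blob_scores(rng, sep=10.0, n=40):
        centers = np.array([[1, 1, 0, 0], [-1, 1, 0, 0], [1, -1, 0, 0], [-1, -1, 0, 0]]) * sep
        rows, truth = [], []
        for i in range(n):
            c = i % 4
            rows.append(centers[c] + rng.standard_normal(4))
            truth.append(c)
        frame = pd.DataFrame(rows, columns=[f"pc{j+1}" for j in range(4)])
        frame.insert(0, "video_id", range(n))
        frame.insert(0, "subject_id", 0)
        return frame, np.array(truth)

    @pytest.mark.parametrize("method", ["kmeans", "gmm", "hier"])
    def test_separated_blobs_recovered_by_all_methods(self, method, rng):
        scores, truth = self._blob_scores(np.random.default_rng(3))
        result = cluster_panel(scores, method, k=4, seed=0)
        assert result.silhouette > 0.8
        # planted partition recovered up to label permutation
        best = max(
            sum(perm[t] == a for t, a in zip(truth, result.assignments))
            for perm in itertools.permutations(range(4))
        )
        assert best == len(truth)

    def test_k_of_one_rejected(self):
        scores, _ = self._blob_scores(np.random.default_rng(0))
        with pytest.raises(ValueError):
            cluster_panel(scores, "gmm", k=1)

    def test_gmm_deterministic_under_seed(self):
        scores, _ = self._blob_scores(np.random.default_rng(5), sep=2.0)
        a = cluster_panel(scores, "gmm", seed=42).assignments
        b = cluster_panel(scores, "gmm", seed=42).assignments
        np.testing.assert_array_equal(a, b)


class TestQuadrantMapping:
    @staticmethod
    def _norm_at(points):
        frame = pd.DataFrame(points, columns=["z_valence", "z_arousal"])
        frame["z_dominance"] = 0.0
        frame["z_liking"] = 0.0
        frame.insert(0, "video_id", range(len(frame)))
        frame.insert(0, "subject_id", 0)
        return NormalizedRatings(frame, "global")

    def test_exact_sign_centroids_map_by_sign(self):
        pts = [(1.0, 1.0), (1.0, -1.0), (-1.0, 1.0), (-1.0, -1.0)]
        norm = self._norm_at(pts)
        labels, info = map_clusters_to_quadrants(np.arange(4), norm)
        assert labels["label"].tolist() == ["HVHA", "HVLA", "LVHA", "LVLA"]
        assert not info["degenerate"]

    def test_jittered_centroids_match_brute_force_sign_mapping(self):
        rng = np.random.default_rng(99)
        protos = np.array([QUADRANT_SIGNS[q] for q in QUADRANTS], dtype=float)
        for _ in range(100):
            pts = protos + rng.uniform(-0.1, 0.1, size=(4, 2))
            labels, _ = map_clusters_to_quadrants(np.arange(4), self._norm_at(pts))
            # oracle: per-centroid sign rule
            expected = [
                ("H" if v > 0 else "L") + "V" + ("H" if a > 0 else "L") + "A"
                for v, a in pts
            ]
            assert labels["label"].tolist() == expected

    def test_zero_noise_panel_maps_all_to_planted(self):
        design = SyntheticDesign(
            n_subjects=6, n_videos=8, rating_noise_sd=0.0, subject_bias_sd=0.0, seed=4
        )
        panel, truth = gen_ratings(design)
        norm = zscore_panel(panel, scope="global")
        labels = sign_quadrants(norm)
        merged = labels.merge(truth, on="video_id")
        assert (merged["label"] == merged["true_quadrant"]).all()


class TestThresholdAndMode:
    @pytest.mark.parametrize("v,a,expected", [
        (7.0, 7.0, "HVHA"), (3.0, 7.0, "LVHA"), (5.0, 5.0, "LVLA"),
    ])
    def test_threshold_baseline_quadrants(self, v, a, expected):
        frame = pd.DataFrame(
            {"subject_id": [0], "video_id": [0], "valence": [v], "arousal": [a],
             "dominance": [5.0], "liking": [5.0]}
        )
        labels = threshold_baseline(RatingsPanel(frame))
        assert labels["label"].iloc[0] == expected

    def test_mode_and_consistency(self):
        lab, cons, tied = dominant_label(["HVHA", "HVHA", "HVHA", "LVLA"])
        assert (lab, cons, tied) == ("HVHA", 0.75, False)

    def test_tie_resolves_to_lowest_code_with_flag(self):
        lab, cons, tied = dominant_label(["HVHA", "HVHA", "LVLA", "LVLA"])
        assert (lab, cons, tied) == ("HVHA", 0.5, True)

    def test_consistency_arithmetic(self):
        labels = ["HVLA"] * 17 + ["HVHA"] * 8 + ["LVLA"] * 7
        lab, cons, _ = dominant_label(labels)
        assert lab == "HVLA"
        assert cons == pytest.approx(17 / 32)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            dominant_label([])


class TestRefinement:
    @staticmethod
    def _norm_row(z_v, z_a, z_d, z_l):
        frame = pd.DataFrame(
            {"subject_id": [0], "video_id": [0],
             "z_valence": [z_v], "z_arousal": [z_a],
             "z_dominance": [z_d], "z_liking": [z_l]}
        )
        return NormalizedRatings(frame, "global")

    def test_outside_margin_unchanged(self):
        norm = self._norm_row(0.5, 0.5, -2.0, -2.0)
        labels = sign_quadrants(norm)
        refined, log = refine_borderline(norm, labels, margin=0.1)
        assert refined["label"].iloc[0] == "HVHA"
        assert log.empty

    def test_borderline_valence_redecided_by_liking(self):
        norm = self._norm_row(0.05, 0.8, 0.0, -1.2)
        labels = sign_quadrants(norm)  # HVHA from raw signs
        refined, log = refine_borderline(norm, labels, margin=0.1)
        assert refined["label"].iloc[0] == "LVHA"
        assert len(log) == 1

    def test_borderline_arousal_redecided_by_dominance(self):
        norm = self._norm_row(0.8, -0.05, 1.3, 0.0)
        labels = sign_quadrants(norm)
        refined, _ = refine_borderline(norm, labels, margin=0.1)
        assert refined["label"].iloc[0] == "HVHA"

    def test_zero_margin_is_identity(self):
        design = SyntheticDesign(n_subjects=8, n_videos=8, seed=6)
        panel, _ = gen_ratings(design)
        norm = zscore_panel(panel, "global")
        labels = sign_quadrants(norm)
        refined, log = refine_borderline(norm, labels, margin=0.0)
        assert (refined["label"] == labels["label"]).all()
        assert log.empty

    def test_change_count_monotone_in_margin(self):
        design = SyntheticDesign(n_subjects=16, n_videos=12, seed=8)
        panel, _ = gen_ratings(design)
        norm = zscore_panel(panel, "global")
        labels = sign_quadrants(norm)
        counts = []
        for margin in (0.0, 0.05, 0.1, 0.3, 0.6, 1.0):
            _, log = refine_borderline(norm, labels, margin=margin)
            counts.append(len(log))
        assert counts == sorted(counts)


class TestEvaluation:
    @staticmethod
    def _labels(values):
        n_sub, n_vid = len(values), len(values[0])
        rows = [
            (s, v, values[s][v]) for s in range(n_sub) for v in range(n_vid)
        ]
        return pd.DataFrame(rows, columns=["subject_id", "video_id", "label"])

    def test_identical_labelings_score_one(self):
        cand = self._labels([["HVHA", "LVLA"], ["HVHA", "LVLA"]])
        out = evaluate_labels(cand, cand.copy())
        assert out == {"accuracy": 1.0, "fit_rate": 1.0}

    def test_complete_disagreement_scores_zero(self):
        cand = self._labels([["HVHA", "LVLA"]])
        ref = self._labels([["LVLA", "HVHA"]])
        out = evaluate_labels(cand, ref)
        assert out == {"accuracy": 0.0, "fit_rate": 0.0}

    def test_fit_rate_arithmetic_over_forty_videos(self):
        cand_vals = [["HVHA"] * 40]
        ref_vals = [["HVHA"] * 31 + ["LVLA"] * 9]
        out = evaluate_labels(self._labels(cand_vals), self._labels(ref_vals))
        assert out["fit_rate"] == pytest.approx(0.775)

    def test_mismatched_video_sets_rejected(self):
        cand = self._labels([["HVHA", "LVLA"]])
        ref = self._labels([["HVHA", "LVLA", "HVLA"]])
        with pytest.raises(ValueError):
            evaluate_labels(cand, ref)


class TestReportAndModes:
    def test_confidence_filter_counts(self):
        # 40 videos: 9 with consistency below 0.5
        rows = []
        for v in range(40):
            if v < 9:
                labs = ["HVHA", "HVLA", "LVHA", "LVLA", "LVLA"]  # consistency 0.4
            else:
                labs = ["HVHA"] * 4 + ["LVLA"]  # consistency 0.8
            rows += [(s, v, lab) for s, lab in enumerate(labs)]
        assignments = pd.DataFrame(rows, columns=["subject_id", "video_id", "label"])
        report = build_report(assignments)
        modes = output_modes(report, consistency_threshold=0.5)
        assert len(modes["confidence_filtered"]) == 31
        probs = modes["probabilistic"][[f"p_{q}" for q in QUADRANTS]].to_numpy()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_unanimous_panel_gives_one_hot_probabilities(self):
        rows = [(s, v, "HVLA") for s in range(4) for v in range(3)]
        report = build_report(pd.DataFrame(rows, columns=["subject_id", "video_id", "label"]))
        modes = output_modes(report)
        assert (report.per_video["consistency"] == 1.0).all()
        assert (modes["majority"]["label"] == "HVLA").all()
        probs = modes["probabilistic"][[f"p_{q}" for q in QUADRANTS]].to_numpy()
        assert set(probs.ravel().tolist()) == {0.0, 1.0}

    def test_consistency_invariant_under_subject_reordering(self):
        design = SyntheticDesign(n_subjects=10, n_videos=8, seed=14)
        panel, _ = gen_ratings(design)
        norm = zscore_panel(panel, "global")
        labels = sign_quadrants(norm)
        r1 = build_report(labels)
        shuffled = labels.sample(frac=1.0, random_state=0).reset_index(drop=True)
        r2 = build_report(shuffled)
        pd.testing.assert_frame_equal(
            r1.per_video.sort_values("video_id").reset_index(drop=True),
            r2.per_video.sort_values("video_id").reset_index(drop=True),
        )


class TestRecovery:
    def test_zero_noise_panel_fully_recovered(self):
        design = SyntheticDesign(
            n_subjects=32, n_videos=40, rating_noise_sd=0.0, subject_bias_sd=0.0, seed=0
        )
        panel, truth = gen_ratings(design)
        report = calibrate_labels(panel, "calibrated")
        merged = report.per_video.merge(truth, on="video_id")
        assert (merged["label"] == merged["true_quadrant"]).all()

    def test_noisy_panel_recovery_at_least_80_percent(self):
        design = SyntheticDesign(
            n_subjects=32, n_videos=40, rating_noise_sd=1.0, subject_bias_sd=0.5, seed=1
        )
        panel, truth = gen_ratings(design)
        report = calibrate_labels(panel, "calibrated")
        merged = report.per_video.merge(truth, on="video_id")
        assert (merged["label"] == merged["true_quadrant"]).mean() >= 0.8

    @pytest.mark.parametrize("method", ["kmeans", "gmm", "hier"])
    def test_clustering_routes_beat_chance_and_stay_bounded(self, method):
        """Clustering routes act on per-video PCA scores, which are centered
        across subjects and so retain only weak video-level signal; they beat
        four-class chance but fall well short of the calibrated route."""
        design = SyntheticDesign(
            n_subjects=16, n_videos=12, rating_noise_sd=0.5, subject_bias_sd=0.25, seed=3
        )
        panel, truth = gen_ratings(design)
        report = calibrate_labels(panel, method, seed=0)
        merged = report.per_video.merge(truth, on="video_id")
        assert (merged["label"] == merged["true_quadrant"]).mean() > 0.25
        assert -1.0 <= report.silhouette <= 1.0
        assert set(report.conformity) == set(range(16))
        assert all(0.0 <= c <= 1.0 for c in report.conformity.values())
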