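"""Feature assembly, k-means under both metrics, self-report concordance,
and the centroid-identity / dispersion tests."""

import numpy as np
import pandas as pd
import pytest

from neuromark import (
    FEATURE_PRESETS,
    FeatureEntry,
    FeatureSpec,
    assemble_features,
    centroid_identity_test,
    dispersion_test,
    evaluate_against_selfreport,
    kmeans_cluster,
)


def _table(rng, n_subjects=10, constant_col=False):
    rows = []
    for i in range(n_subjects):
        sid = f"sub-{i:02d}"
        for stage in ("D1", "D2"):
            for ch in ("Cz", "Fz"):
                rows.append(dict(subject_id=sid, stage=stage, band="alpha",
                                 measure="psd", location=ch,
                                 value=1.0 if constant_col and ch == "Fz"
                                 else float(np.exp(rng.normal()))))
    return pd.DataFrame(rows)


def _blobs(rng, n=30, d=6.0, dim=4, sigma=1.0, sigma2=None):
    a = rng.normal(0.0, sigma, (n // 2, dim))
    b = rng.normal(0.0, sigma2 or sigma, (n - n // 2, dim)) + d
    X = np.vstack([a, b])
    y = np.array(["A"] * (n // 2) + ["B"] * (n - n // 2))
    return X, y


class TestAssembleFeatures:
    SPEC = FeatureSpec((FeatureEntry("psd", "alpha", ("Cz", "Fz"), ("D1", "D2")),))

    def test_columns_are_zscored(self, rng):
        X, subjects, cols = assemble_features(_table(rng), self.SPEC)
        assert X.shape == (10, 4)
        np.testing.assert_allclose(X.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(X.std(axis=0), 1.0, atol=1e-10)

    def test_stage_restriction_respected(self, rng):
        spec = FEATURE_PRESETS["frontal_central_alpha_D1_D2"]
        stages = {e.stages for e in spec.entries}
        assert stages == {("D1", "D2")}
        table = _table(rng)
        _, _, cols = assemble_features(table, self.SPEC)
        assert all(c.endswith(("D1", "D2")) for c in cols)

    def test_missing_feature_names_subject(self, rng):
        table = _table(rng)
        table = table[~((table.subject_id == "sub-03") & (table.location == "Cz")
                        & (table.stage == "D2"))]
        with pytest.raises(ValueError, match="sub-03"):
            assemble_features(table, self.SPEC)

    def test_constant_column_error_or_drop(self, rng):
        table = _table(rng, constant_col=True)
        with pytest.raises(ValueError, match="constant"):
            assemble_features(table, self.SPEC)
        spec = FeatureSpec(self.SPEC.entries, on_constant="drop")
        with pytest.warns(UserWarning, match="dropping"):
            X, _, cols = assemble_features(table, spec)
        assert X.shape[1] == 2  # Fz columns dropped


class TestKmeans:
    def test_separates_well_separated_blobs(self, rng):
        X, y = _blobs(rng)
        res = kmeans_cluster(X, seed=1)
        res = evaluate_against_selfreport(res, y)
        assert res.accuracy == 100.0

    def test_deterministic_under_seed(self, rng):
        X, _ = _blobs(rng, d=1.0)
        a = kmeans_cluster(X, seed=5)
        b = kmeans_cluster(X, seed=5)
        np.testing.assert_array_equal(a.assignments, b.assignments)

    def test_agrees_with_sklearn_on_euclidean(self, rng):
        from sklearn.cluster import KMeans
        X, _ = _blobs(rng, d=4.0)
        ours = kmeans_cluster(X, seed=0)
        ref = KMeans(n_clusters=2, n_init=10, random_state=0).fit(X)
        agree = max((ours.assignments == ref.labels_).mean(),
                    (ours.assignments != ref.labels_).mean())
        assert agree == 1.0
        assert ours.objective == pytest.approx(ref.inertia_, rel=1e-6)

    def test_cityblock_centroids_are_medians(self, rng):
        X, _ = _blobs(rng, d=5.0)
        X[0] += 40.0  # coordinate outlier pulls a mean but not a median
        res = kmeans_cluster(X, distance="cityblock", seed=2)
        for c in (0, 1):
            np.testing.assert_allclose(res.centroids[c],
                                       np.median(X[res.assignments == c], axis=0))

    def test_objective_is_locally_optimal(self, rng):
        # reassigning any single point to the other centroid cannot improve
        X, _ = _blobs(rng, d=2.0)
        res = kmeans_cluster(X, seed=3)
        d0 = np.abs(X[:, None, :] - res.centroids[None]) ** 2
        d = d0.sum(axis=2)
        own = d[np.arange(len(X)), res.assignments]
        other = d[np.arange(len(X)), 1 - res.assignments]
        assert np.all(own <= other + 1e-9)

    def test_needs_more_subjects_than_clusters(self):
        with pytest.raises(ValueError):
            kmeans_cluster(np.zeros((2, 3)), k=2)


class TestSelfReportConcordance:
    def test_perfect_assignment_and_complement(self, rng):
        X, y = _blobs(rng)
        res = kmeans_cluster(X, seed=1)
        res = evaluate_against_selfreport(res, y)
        assert res.accuracy == 100.0 and res.ppv == 100.0
        flipped = kmeans_cluster(X, seed=1)
        flipped.assignments = 1 - flipped.assignments
        flipped = evaluate_against_selfreport(flipped, y)
        assert flipped.accuracy == 100.0  # cluster labels are arbitrary

    def test_accuracy_never_below_majority(self, rng):
        y = np.array(["A"] * 16 + ["B"] * 29)
        for r in range(10):
            g = np.random.default_rng(r)
            res = kmeans_cluster(g.standard_normal((45, 5)), seed=r)
            res = evaluate_against_selfreport(res, y)
            assert res.accuracy >= 100.0 * 29 / 45 - 1e-9

    def test_confusion_and_ppv_definition(self):
        from neuromark.clustering import ClusteringResult
        res = ClusteringResult(assignments=np.array([0, 0, 0, 1, 1, 1]),
                               centroids=np.zeros((2, 1)), distance="euclidean",
                               objective=0.0)
        y = np.array(["A", "A", "B", "B", "B", "B"])
        res = evaluate_against_selfreport(res, y)
        tp, fn = res.confusion[0]
        fp, tn = res.confusion[1]
        assert (tp, fn, fp, tn) == (2, 0, 1, 3)
        assert res.accuracy == pytest.approx(100 * 5 / 6)
        assert res.ppv == pytest.approx(100 * 2 / 3)


class TestCentroidIdentity:
    def test_identical_points_give_p_one(self):
        X = np.ones((12, 3))
        f, p = centroid_identity_test(X, np.array([0] * 6 + [1] * 6), seed=0)
        assert p > 0.95

    def test_separated_blobs_hit_permutation_floor(self, rng):
        X, y = _blobs(rng, d=8.0)
        groups = (y == "B").astype(int)
        f, p = centroid_identity_test(X, groups, n_permutations=999, seed=0)
        assert p == pytest.approx(1 / 1000)

    def test_matches_skbio_permanova(self, rng):
        skbio = pytest.importorskip("skbio")
        from scipy.spatial.distance import pdist, squareform
        X, y = _blobs(rng, d=1.5)
        groups = (y == "B").astype(int)
        f_ours, _ = centroid_identity_test(X, groups, n_permutations=99, seed=0)
        dm = skbio.DistanceMatrix(squareform(pdist(X)))
        res = skbio.stats.distance.permanova(dm, grouping=groups, permutations=99)
        assert f_ours == pytest.approx(res["test statistic"], rel=1e-9)

    def test_kmeans_grouping_is_biased_toward_rejection(self, rng):
        # clusters carved out of a single Gaussian still "separate": the
        # permutation p under k-means-derived grouping is anticonservative
        small_p = 0
        for r in range(10):
            g = np.random.default_rng(600 + r)
            X = g.standard_normal((30, 3))
            res = kmeans_cluster(X, seed=r)
            _, p = centroid_identity_test(X, res.assignments, n_permutations=199, seed=r)
            small_p += p < 0.05
        assert small_p >= 8

    def test_singleton_cluster_rejected(self, rng):
        X = rng.standard_normal((5, 2))
        with pytest.raises(ValueError):
            centroid_identity_test(X, np.array([0, 1, 1, 1, 1]))


class TestDispersion:
    def test_equal_spread_rarely_rejected(self):
        rejections = 0
        reps = 60
        for r in range(reps):
            g = np.random.default_rng(800 + r)
            X, _ = _blobs(g, n=40, d=5.0)
            groups = np.array([0] * 20 + [1] * 20)
            _, p = dispersion_test(X, groups)
            rejections += p < 0.05
        assert rejections / reps <= 0.15

    def test_unequal_spread_detected(self):
        hits = 0
        reps = 30
        for r in range(reps):
            g = np.random.default_rng(900 + r)
            X, _ = _blobs(g, n=40, d=5.0, sigma=1.0, sigma2=4.0)
            groups = np.array([0] * 20 + [1] * 20)
            _, p = dispersion_test(X, groups)
            hits += p < 0.05
        assert hits >= 0.9 * reps

    def test_all_points_at_centroids_give_p_one(self):
        X = np.array([[0.0, 0.0]] * 5 + [[3.0, 3.0]] * 5)
        _, p = dispersion_test(X, np.array([0] * 5 + [1] * 5))
        assert p == 1.0
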