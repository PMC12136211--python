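import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylancestry import (
    ValidationError,
    centroid_distance_matrix,
    cluster_centroids,
    evaluate_methods,
    group_multiple_correlation,
    mean_distance_to_centroid,
    mixed_model_group_lrt,
    pc_genotype_correlation,
    pc_group_association,
    silhouette,
)


def silhouette_oracle(points, labels):
    """Brute-force pairwise-distance restatement of the silhouette definition."""
    n = len(points)
    s = np.zeros(n)
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            continue
        a = np.mean([np.linalg.norm(points[i] - points[j]) for j in own])
        b = min(
            np.mean([np.linalg.norm(points[i] - points[j]) for j in range(n) if labels[j] == lab])
            for lab in set(labels) if lab != labels[i]
        )
        s[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return s


class TestSilhouette:
    def test_two_tight_far_clusters(self):
        pts = np.array([[0.0], [0.1], [10.0], [10.1]])
        labels = np.array(["A", "A", "B", "B"])
        per, mean = silhouette(pts, labels)
        # a = 0.1 within, b = 10.05 / 9.95 across → s ≈ 0.99
        assert mean == pytest.approx((1 - 0.1 / 10.05 + 1 - 0.1 / 9.95) / 2, abs=1e-3)
        assert mean > 0.98

    def test_identical_points_score_zero(self):
        pts = np.zeros((4, 3))
        per, mean = silhouette(pts, np.array(["A", "A", "B", "B"]))
        assert mean == 0.0 and (per == 0).all()

    def test_singleton_cluster_scores_zero(self):
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0], [5.0, 0, 0]])
        per, _ = silhouette(pts, np.array(["A", "A", "B"]))
        assert per[2] == 0.0

    def test_single_cluster_rejected(self):
        with pytest.raises(ValidationError):
            silhouette(np.zeros((3, 2)), np.array(["A", "A", "A"]))

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = rng.integers(4, 13)
            k = rng.integers(2, 4)
            pts = rng.normal(size=(n, 3))
            labels = rng.integers(0, k, size=n)
            if len(np.unique(labels)) < 2:
                continue
            per, _ = silhouette(pts, labels)
            np.testing.assert_allclose(per, silhouette_oracle(pts, labels), atol=1e-12)

    def test_agrees_with_sklearn_on_multi_member_clusters(self):
        from sklearn.metrics import silhouette_samples

        rng = np.random.default_rng(1)
        pts = rng.normal(size=(30, 3))
        labels = rng.integers(0, 3, size=30)
        per, _ = silhouette(pts, labels)
        np.testing.assert_allclose(per, silhouette_samples(pts, labels), atol=1e-10)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_values_bounded(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(8, 3))
        labels = np.array([0, 0, 0, 1, 1, 1, 2, 2])
        per, _ = silhouette(pts, labels)
        assert (per >= -1).all() and (per <= 1).all()


class TestCentroids:
    def test_centroid_and_density(self):
        pts = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        out = cluster_centroids(pts, np.array(["A", "A"]))
        np.testing.assert_allclose(out.loc["A", ["dim1", "dim2", "dim3"]].to_numpy(float), [1, 0, 0])
        assert out.loc["A", "mean_distance"] == pytest.approx(1.0)

    def test_singleton_distance_zero(self):
        out = cluster_centroids(np.array([[1.0, 2, 3], [0, 0, 0]]), np.array(["A", "B"]))
        assert out.loc["A", "mean_distance"] == 0.0

    def test_distance_matrix_pythagoras_and_symmetry(self):
        pts = np.array([[0.0, 0, 0], [3.0, 4, 0]])
        cents = cluster_centroids(pts, np.array(["A", "B"]))
        d = centroid_distance_matrix(cents)
        assert d.loc["A", "B"] == pytest.approx(5.0)
        np.testing.assert_allclose(d.to_numpy(), d.to_numpy().T)
        assert (np.diag(d.to_numpy()) == 0).all()

    def test_triangle_inequality_on_random_triples(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            pts = rng.normal(size=(9, 3))
            labels = np.repeat(["A", "B", "C"], 3)
            d = centroid_distance_matrix(cluster_centroids(pts, labels)).to_numpy()
            for i in range(3):
                for j in range(3):
                    for k in range(3):
                        assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestGroupAssociation:
    def test_normal_groups_use_anova(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(0, 1, 20), rng.normal(10, 1, 20)])
        labels = np.repeat(["A", "B"], 20)
        res = pc_group_association(x, labels)
        assert res.test_used == "anova"
        assert res.p_value < 1e-6
        # statistic matches the F-distribution oracle through scipy itself
        from scipy.stats import f_oneway
        assert res.statistic == pytest.approx(f_oneway(x[:20], x[20:]).statistic)

    def test_skewed_groups_fall_back_to_kruskal(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.exponential(1, 40), rng.exponential(1, 40) + 3])
        labels = np.repeat(["A", "B"], 40)
        res = pc_group_association(x, labels)
        assert res.test_used == "kruskal_wallis"
        assert res.assumption_notes["shapiro_p"] < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            pc_group_association(np.zeros(10), np.repeat(["A", "B"], 5))

    def test_small_groups_excluded(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=9)
        labels = np.array(["A"] * 4 + ["B"] * 4 + ["C"])  # C has 1 member
        res = pc_group_association(x, labels)
        assert res.p_value >= 0.0

    def test_pvalue_invariant_to_relabeling(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=30)
        labels = np.repeat(["A", "B", "C"], 10)
        renamed = np.char.add("grp_", labels)
        assert pc_group_association(x, labels).p_value == pytest.approx(
            pc_group_association(x, renamed).p_value)


class TestGenotypeCorrelation:
    def idx(self, n):
        return pd.Index([f"s{i}" for i in range(n)], name="sample_id")

    def test_identical_and_negated_give_unit_diagonal(self):
        rng = np.random.default_rng(7)
        a = pd.DataFrame(rng.normal(size=(25, 3)), index=self.idx(25))
        for other in (a, -a):
            grid, _ = pc_genotype_correlation(a, other)
            np.testing.assert_allclose(np.diag(grid.to_numpy()), 1.0, atol=1e-12)

    def test_orthogonal_columns_near_zero(self):
        rng = np.random.default_rng(8)
        n = 2000
        a = pd.DataFrame(rng.normal(size=(n, 3)), index=self.idx(n))
        g = pd.DataFrame(rng.normal(size=(n, 3)), index=self.idx(n))
        grid, mean = pc_genotype_correlation(a, g)
        assert grid.to_numpy().max() < 3 / np.sqrt(n)

    def test_constant_column_excluded_from_mean(self):
        rng = np.random.default_rng(9)
        a = pd.DataFrame(rng.normal(size=(10, 3)), index=self.idx(10))
        g = a.copy()
        g.iloc[:, 2] = 1.0
        grid, mean = pc_genotype_correlation(a, g)
        assert np.isnan(grid.to_numpy()[:, 2]).all()
        assert not np.isnan(mean)


class TestMixedModelLRT:
    def test_strong_group_shift_detected(self):
        rng = np.random.default_rng(10)
        ind = np.repeat(np.arange(40), 2)
        group = np.repeat(np.arange(40) % 2, 2)
        y = 5.0 * group + rng.normal(0, 1, 80) + rng.normal(0, 1, 40)[ind]
        res = mixed_model_group_lrt(y, group, ind)
        assert res.test_used == "lrt_mixed"
        assert res.p_value < 1e-3
        assert res.statistic >= 0

    def test_constant_group_gives_null_result(self):
        rng = np.random.default_rng(11)
        ind = np.repeat(np.arange(20), 2)
        y = rng.normal(0, 1, 40) + rng.normal(0, 1, 20)[ind]
        res = mixed_model_group_lrt(y, np.zeros(40, dtype=int), ind)
        assert res.statistic == pytest.approx(0.0, abs=1e-6)
        assert res.p_value == pytest.approx(1.0)

    def test_no_repeats_falls_back_to_anova_path(self, caplog):
        rng = np.random.default_rng(12)
        y = rng.normal(size=24)
        group = np.repeat(["A", "B"], 12)
        with caplog.at_level("WARNING"):
            res = mixed_model_group_lrt(y, group, np.arange(24))
        assert res.test_used in ("anova", "kruskal_wallis")


class TestGroupMultipleCorrelation:
    def test_two_groups_equals_abs_pearson(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=40)
        code = np.repeat([0, 1], 20)
        r = abs(np.corrcoef(x, code)[0, 1])
        assert group_multiple_correlation(x, code) == pytest.approx(r)

    def test_invariant_to_label_permutation(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=30)
        labels = np.repeat([0, 1, 2], 10)
        relabeled = (labels + 1) % 3
        assert group_multiple_correlation(x, labels) == pytest.approx(
            group_multiple_correlation(x, relabeled))


class TestEvaluateMethods:
    def test_report_structure(self, small_cohort, small_result):
        report = evaluate_methods(small_result.pcs, small_cohort.sheet,
                                  geno_pcs=small_cohort.truth["geno_pcs"])
        assert set(report.per_method) == {"raw", "residualized", "combined"}
        for entry in report.per_method.values():
            assert "group" in entry and "genotype_correlation" in entry
            assert "repeated" in entry  # default design has repeated samples
            d = entry["group"]["centroid_distances"].to_numpy()
            np.testing.assert_allclose(d, d.T)
        assert isinstance(report.to_dict()["raw"]["group"]["silhouette_mean"], float)

    def test_sections_absent_without_repeats_or_genotypes(self, small_result):
        n = len(next(iter(small_result.pcs.values())).scores)
        sheet = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n)],
            "individual_id": [f"i{i}" for i in range(n)],  # no repeats
            "sex": ["F", "M"] * (n // 2) + ["F"] * (n % 2),
            "age": np.full(n, 30.0),
            "ancestry_label": np.tile(["A", "B"], (n + 1) // 2)[:n],
        })
        report = evaluate_methods(small_result.pcs, sheet)
        for entry in report.per_method.values():
            assert "repeated" not in entry and "genotype_correlation" not in entry


def test_mean_distance_to_centroid_requires_multimember_labels():
    with pytest.raises(ValidationError):
        mean_distance_to_centroid(np.zeros((3, 3)), np.array(["a", "b", "c"]))
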