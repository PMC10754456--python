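"""Expansion-profile standardisation, k-means clustering and CH criterion."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score, calinski_harabasz_score

from clonalclock import classify
from clonalclock.cli import synthetic_archetype_profiles


class TestStandardize:
    def test_line_becomes_zero_mean_unit_sd(self):
        t = np.linspace(0.0, 1.0, 20)
        out = classify.standardize_profiles({"a": (t, 2.0 * t)})
        assert len(out) == 1
        v = out[0].values
        assert abs(v.mean()) < 1e-9 and abs(v.std() - 1.0) < 1e-9

    def test_affine_transforms_are_equivalent(self):
        t = np.linspace(0.0, 2.0, 30)
        y = np.sin(t)
        out = classify.standardize_profiles({"a": (t, y), "b": (t, 5.0 * y - 3.0)})
        np.testing.assert_allclose(out[0].values, out[1].values, atol=1e-9)

    def test_three_point_profile_interpolates_with_endpoints(self):
        out = classify.standardize_profiles(
            {"a": (np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0, 0.0]))})
        v = out[0].values
        assert v[0] == pytest.approx(v[-1])
        assert np.argmax(v) == pytest.approx(len(v) // 2, abs=2)

    def test_standardization_is_idempotent(self):
        t = np.linspace(0.0, 1.0, 50)
        y = t ** 3
        once = classify.standardize_profiles({"a": (t, y)})[0].values
        grid = np.linspace(1.0, 1000.0, 1000)
        twice = classify.standardize_profiles({"a": (grid, once)})[0].values
        np.testing.assert_allclose(once, twice, atol=1e-9)

    def test_constant_profile_excluded_with_warning(self):
        t = np.linspace(0.0, 1.0, 10)
        with pytest.warns(UserWarning, match="constant"):
            out = classify.standardize_profiles({"a": (t, np.ones(10)),
                                                 "b": (t, t)})
        assert [c.sample for c in out] == ["b"]


class TestKmeans:
    def test_two_separated_shapes_perfectly_recovered(self):
        t = np.linspace(0.0, 1.0, 40)
        prof = {}
        for i in range(5):
            prof[f"up-{i}"] = (t, t + 0.01 * np.sin(7 * t + i))
            prof[f"peak-{i}"] = (t, -(t - 0.5) ** 2 + 0.005 * i * t)
        curves = classify.standardize_profiles(prof)
        part = classify.kmeans_curves(curves, k_candidates=[2], seed=0)[2]
        truth = [s.split("-")[0] for s in part.samples]
        assert adjusted_rand_score(truth, part.labels) == 1.0

    def test_archetype_recovery_with_noise(self):
        prof = synthetic_archetype_profiles(n_per_shape=10, seed=3)
        curves = classify.standardize_profiles(prof)
        part = classify.kmeans_curves(curves, k_candidates=[4], seed=3)[4]
        truth = [s.rsplit("-", 1)[0] for s in part.samples]
        assert adjusted_rand_score(truth, part.labels) >= 0.8

    def test_duplicated_curves_do_not_change_the_partition(self):
        prof = synthetic_archetype_profiles(n_per_shape=3, seed=1)
        curves = classify.standardize_profiles(prof)
        part1 = classify.kmeans_curves(curves, k_candidates=[4], seed=2)[4]
        part2 = classify.kmeans_curves(curves + curves, k_candidates=[4], seed=2)[4]
        n = len(curves)
        assert adjusted_rand_score(part2.labels[:n], part2.labels[n:]) == 1.0
        assert adjusted_rand_score(part1.labels, part2.labels[:n]) == 1.0

    def test_oversized_k_skipped_with_warning(self):
        prof = synthetic_archetype_profiles(n_per_shape=1, seed=0)
        curves = classify.standardize_profiles(prof)
        with pytest.warns(UserWarning, match="exceeds"):
            parts = classify.kmeans_curves(curves, k_candidates=[2, 10], seed=0)
        assert set(parts) == {2}

    def test_fitted_partition_beats_random_relabelling(self):
        prof = synthetic_archetype_profiles(n_per_shape=8, seed=5)
        curves = classify.standardize_profiles(prof)
        X = np.vstack([c.values for c in curves])
        part = classify.kmeans_curves(curves, k_candidates=[4], seed=5)[4]
        rng = np.random.default_rng(6)
        worse = 0
        for _ in range(100):
            perm = rng.permutation(part.labels)
            worse += classify.calinski_harabasz(X, perm) < part.ch
        assert worse >= 99


class TestCalinskiHarabasz:
    def test_perfect_separation_hits_the_cap(self):
        X = np.array([[0.0], [0.0], [10.0], [10.0]])
        labels = np.array([0, 0, 1, 1])
        assert classify.calinski_harabasz(X, labels) == classify.CH_CAP

    def test_matches_brute_force_maximum_on_four_points(self):
        """The natural split of {0,1,10,11} maximises CH over every proper
        2-partition, and the direct formula matches exhaustive evaluation."""
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        best, best_ch = None, -np.inf
        for assignment in itertools.product([0, 1], repeat=4):
            if len(set(assignment)) < 2:
                continue
            ch = classify.calinski_harabasz(X, np.array(assignment))
            if ch > best_ch:
                best, best_ch = assignment, ch
        assert set(map(frozenset, [
            {i for i, a in enumerate(best) if a == best[0]},
            {i for i, a in enumerate(best) if a != best[0]},
        ])) == {frozenset({0, 1}), frozenset({2, 3})}
        labels = np.array([0, 0, 1, 1])
        ours = classify.calinski_harabasz(X, labels)
        # direct formula: B = 2*5.5^2*2 grand-mean distance, W = 4*0.25
        assert ours == pytest.approx(best_ch)
        assert ours == pytest.approx(calinski_harabasz_score(X, labels))

    def test_agrees_with_sklearn_on_random_data(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 5))
        labels = rng.integers(0, 3, size=40)
        assert classify.calinski_harabasz(X, labels) == pytest.approx(
            calinski_harabasz_score(X, labels))

    def test_random_labels_on_structureless_data_average_near_one(self):
        rng = np.random.default_rng(8)
        vals = []
        for _ in range(50):
            X = rng.normal(size=(30, 4))
            labels = rng.integers(0, 3, size=30)
            vals.append(classify.calinski_harabasz(X, labels))
        assert 0.5 <= np.mean(vals) <= 1.5

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            classify.calinski_harabasz(np.zeros((3, 2)), np.array([0, 0, 0]))


class TestSelection:
    def test_pure_argmax_without_reference_shapes(self):
        prof = synthetic_archetype_profiles(n_per_shape=6, seed=9)
        curves = classify.standardize_profiles(prof)
        parts = classify.kmeans_curves(curves, k_candidates=range(2, 6), seed=9)
        chosen = classify.select_partition(parts)
        assert chosen.ch == max(p.ch for p in parts.values())
        assert "argmax" in chosen.rationale

    def test_shape_coverage_rule_prefers_covering_k(self):
        prof = synthetic_archetype_profiles(n_per_shape=6, seed=10, noise_sd=0.2)
        curves = classify.standardize_profiles(prof)
        parts = classify.kmeans_curves(curves, k_candidates=range(2, 6), seed=10)
        shapes = {"Convex", "Peak", "Increase", "Paused Start"}
        chosen = classify.select_partition(parts, reference_shapes=shapes,
                                           ch_tolerance=0.9)
        assert shapes <= classify.covered_shapes(chosen)
        assert chosen.rationale is not None

    def test_names_assigned_one_to_one(self):
        prof = synthetic_archetype_profiles(n_per_shape=8, seed=11, noise_sd=0.1)
        curves = classify.standardize_profiles(prof)
        part = classify.kmeans_curves(curves, k_candidates=[4], seed=11)[4]
        classify.name_clusters(part)
        assert sorted(part.cluster_names) == sorted(
            ["Convex", "Peak", "Increase", "Paused Start"])
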