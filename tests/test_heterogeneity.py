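import itertools

import numpy as np
import pytest

from shapespace.heterogeneity import (
    TCHP,
    ShapeDistanceMatrix,
    cluster_tchps,
    compute_tchp,
    enriched_shapes,
    normalize_tchp,
    shapes_present,
    tchp_distance,
)
from shapespace.shape_clustering import ShapeAssignment
from shapespace.synthetic_data import WILDTYPE_WEIGHTS


def assignment_from(labels, tc_ids, k=7):
    labels = np.asarray(labels)
    n = len(labels)
    means = np.zeros((k, 3))
    return ShapeAssignment(
        labels=labels,
        silhouette=np.ones(n),
        corrected=np.zeros(n, dtype=bool),
        shape_means=means,
        cell_ids=np.array([f"c{i}" for i in range(n)], dtype=object),
        tc_ids=np.asarray(tc_ids, dtype=object),
        mean_silhouette_before=1.0,
        mean_silhouette_after=1.0,
    )


def normalized(fractions, tc_id="x"):
    return TCHP(tc_id=tc_id, fractions=np.asarray(fractions, float),
                normalized=True, n_cells=10)


def random_zero_sum(rng, k=7):
    d = rng.normal(size=k)
    return d - d.mean()


class TestProfiles:
    def test_counting_example(self):
        labels = [1, 1, 2, 3, 3, 3, 4, 4, 4, 4]
        profiles = compute_tchp(assignment_from(labels, ["A"] * 10))
        np.testing.assert_allclose(
            profiles[0].fractions, [0.2, 0.1, 0.3, 0.4, 0, 0, 0]
        )

    def test_single_cell_condition(self):
        labels = [5, 1]
        profiles = compute_tchp(assignment_from(labels, ["A", "B"]))
        by_id = {p.tc_id: p for p in profiles}
        assert by_id["A"].fractions[4] == 1.0
        assert by_id["B"].fractions[0] == 1.0

    def test_fractions_sum_to_one(self, rng):
        labels = rng.integers(1, 8, size=100)
        tcs = rng.choice(["A", "B", "C"], size=100)
        for p in compute_tchp(assignment_from(labels, tcs)):
            assert p.fractions.sum() == pytest.approx(1.0)

    def test_normalization(self):
        labels = [1, 2, 2, 3, 1, 2] * 2  # KD distribution identical to WT
        profiles = compute_tchp(assignment_from(labels, ["WT"] * 6 + ["KD"] * 6))
        norm = normalize_tchp(profiles, "WT")
        for p in norm:
            assert p.normalized
            assert p.fractions.sum() == pytest.approx(0.0, abs=1e-12)
            np.testing.assert_allclose(p.fractions, 0.0, atol=1e-12)

    def test_missing_wildtype_raises(self):
        profiles = compute_tchp(assignment_from([1, 2], ["A", "A"]))
        with pytest.raises(ValueError, match="not found"):
            normalize_tchp(profiles, "EGFP")


class TestWeightedDistance:
    def test_identical_profiles_distance_zero(self, rng):
        M = ShapeDistanceMatrix.from_shape_means(rng.normal(size=(7, 3)))
        x = normalized(random_zero_sum(rng))
        assert tchp_distance(x, x, M) == 0.0

    def test_closed_form_for_uniform_distance_matrix(self, rng):
        """With M = c(ones - identity), the quadratic form collapses to
        -c ||delta||^2 on zero-sum differences, so D = sqrt(c) ||delta||."""
        c = 4.0
        M = ShapeDistanceMatrix(
            M=c * (np.ones((7, 7)) - np.eye(7)),
            source_means=np.zeros((7, 3)),
            shape_ids=np.arange(1, 8),
        )
        for _ in range(20):
            d1, d2 = random_zero_sum(rng), random_zero_sum(rng)
            want = np.sqrt(c) * np.linalg.norm(d1 - d2)
            got = tchp_distance(normalized(d1), normalized(d2), M)
            assert got == pytest.approx(want, rel=1e-9)

    def test_matches_double_loop_oracle_and_nonnegative(self, rng):
        M = ShapeDistanceMatrix.from_shape_means(rng.normal(size=(7, 3)))
        for _ in range(30):
            d1, d2 = random_zero_sum(rng), random_zero_sum(rng)
            delta = d1 - d2
            q = sum(
                delta[i] * M.M[i, j] * delta[j]
                for i in range(7)
                for j in range(7)
            )
            assert q <= 1e-9  # conditionally negative definite
            got = tchp_distance(normalized(d1), normalized(d2), M)
            assert got == pytest.approx(np.sqrt(max(0.0, -q)), rel=1e-9)
            assert got >= 0

    def test_symmetry_and_triangle_inequality(self, rng):
        M = ShapeDistanceMatrix.from_shape_means(rng.normal(size=(7, 3)))
        for _ in range(200):
            x, y, z = (normalized(random_zero_sum(rng)) for _ in range(3))
            dxy = tchp_distance(x, y, M)
            assert dxy == pytest.approx(tchp_distance(y, x, M), rel=1e-12)
            assert dxy <= tchp_distance(x, z, M) + tchp_distance(z, y, M) + 1e-9

    def test_shape_permutation_invariance(self, rng):
        means = rng.normal(size=(7, 3))
        M = ShapeDistanceMatrix.from_shape_means(means)
        perm = rng.permutation(7)
        Mp = ShapeDistanceMatrix.from_shape_means(means[perm])
        d1, d2 = random_zero_sum(rng), random_zero_sum(rng)
        a = tchp_distance(normalized(d1), normalized(d2), M)
        b = tchp_distance(normalized(d1[perm]), normalized(d2[perm]), Mp)
        assert a == pytest.approx(b, rel=1e-9)

    def test_raw_profiles_rejected(self, rng):
        M = ShapeDistanceMatrix.from_shape_means(rng.normal(size=(7, 3)))
        raw = TCHP("a", np.full(7, 1 / 7), normalized=False, n_cells=7)
        with pytest.raises(ValueError, match="normalized"):
            tchp_distance(raw, raw, M)


class TestProfileClustering:
    def test_two_identical_groups_separate(self, rng):
        M = ShapeDistanceMatrix.from_shape_means(rng.normal(size=(7, 3)))
        d1, d2 = random_zero_sum(rng), random_zero_sum(rng)
        profiles = [normalized(d1, f"a{i}") for i in range(3)] + [
            normalized(d2, f"b{i}") for i in range(3)
        ]
        out = cluster_tchps(profiles, M, 2)
        groups = {out.cluster_labels[f"a{i}"] for i in range(3)}
        assert len(groups) == 1
        assert out.cluster_labels["b0"] not in groups

    def test_singleton_cut(self, rng):
        M = ShapeDistanceMatrix.from_shape_means(rng.normal(size=(7, 3)))
        profiles = [normalized(random_zero_sum(rng), f"t{i}") for i in range(5)]
        out = cluster_tchps(profiles, M, 5)
        assert out.n_clusters == 5

    def test_matches_brute_force_complete_linkage(self, rng):
        """The merge sequence on <= 8 profiles matches a naive complete-
        linkage agglomeration oracle, compared as the partition at every
        cluster count."""
        M = ShapeDistanceMatrix.from_shape_means(rng.normal(size=(7, 3)))
        profiles = [normalized(random_zero_sum(rng), f"t{i}") for i in range(7)]
        n = len(profiles)
        D = {
            (i, j): tchp_distance(profiles[i], profiles[j], M)
            for i, j in itertools.combinations(range(n), 2)
        }

        def complete(ci, cj):
            return max(D[tuple(sorted((a, b)))] for a in ci for b in cj)

        clusters = [frozenset([i]) for i in range(n)]
        oracle_partitions = {n: set(clusters)}
        while len(clusters) > 1:
            (i, j) = min(
                itertools.combinations(range(len(clusters)), 2),
                key=lambda ij: complete(clusters[ij[0]], clusters[ij[1]]),
            )
            merged = clusters[i] | clusters[j]
            clusters = [c for t, c in enumerate(clusters) if t not in (i, j)]
            clusters.append(merged)
            oracle_partitions[len(clusters)] = set(clusters)

        for k in range(1, n + 1):
            got = cluster_tchps(profiles, M, k)
            parts = {}
            for idx, p in enumerate(profiles):
                parts.setdefault(got.cluster_labels[p.tc_id], set()).add(idx)
            assert {frozenset(v) for v in parts.values()} == oracle_partitions[k]

    def test_input_order_invariance(self, rng):
        M = ShapeDistanceMatrix.from_shape_means(rng.normal(size=(7, 3)))
        profiles = [normalized(random_zero_sum(rng), f"t{i}") for i in range(6)]
        a = cluster_tchps(profiles, M, 3).cluster_labels
        b = cluster_tchps(profiles[::-1], M, 3).cluster_labels
        part_a = {}
        part_b = {}
        for tc in a:
            part_a.setdefault(a[tc], set()).add(tc)
            part_b.setdefault(b[tc], set()).add(tc)
        assert {frozenset(v) for v in part_a.values()} == {
            frozenset(v) for v in part_b.values()
        }


class TestEnrichment:
    def test_control_distribution_enrichment(self):
        """The measured control population has four shapes above the strict
        10% enrichment bar."""
        wt = TCHP("EGFP", WILDTYPE_WEIGHTS, normalized=False, n_cells=100)
        assert enriched_shapes(wt) == {4, 5, 6, 7}

    def test_uniform_profile_all_enriched(self):
        p = TCHP("u", np.full(7, 1 / 7), normalized=False, n_cells=7)
        assert enriched_shapes(p) == set(range(1, 8))

    def test_boundary_is_strict(self):
        fractions = np.array([0.10, 0.90, 0, 0, 0, 0, 0])
        p = TCHP("b", fractions, normalized=False, n_cells=10)
        assert enriched_shapes(p) == {2}

    def test_control_presence_count(self):
        wt = TCHP("EGFP", WILDTYPE_WEIGHTS, normalized=False, n_cells=100)
        present = shapes_present(wt)
        assert len(present) == 6
        assert 2 not in present

    def test_one_shape_profile(self):
        p = TCHP("one", np.eye(7)[3], normalized=False, n_cells=5)
        assert shapes_present(p) == {4}

    def test_normalized_profile_rejected(self):
        p = normalized(np.zeros(7))
        with pytest.raises(ValueError):
            enriched_shapes(p)
        with pytest.raises(ValueError):
            shapes_present(p)
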