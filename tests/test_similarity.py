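import itertools

import numpy as np
import pytest

from alemeta.similarity import (
    DistanceMatrix,
    centrality_profile,
    cut_dendrogram,
    devectorize,
    distance_matrix,
    linkage_to_tree,
    mds_embed,
    mean_distances,
    reorder_matrix,
    vectorize_maps,
    ward_dendrogram,
)
from alemeta.synthetic import default_mask


@pytest.fixture()
def small_grid():
    g = default_mask(4)
    g.mask[0, 0, :] = False  # 60 in-mask voxels
    return g


class TestVectorize:
    def test_row_length_is_mask_size(self, small_grid):
        rng = np.random.default_rng(0)
        maps = [small_grid.like(rng.random(small_grid.shape)) for _ in range(3)]
        mat = vectorize_maps(maps)
        assert mat.shape == (3, int(small_grid.mask.sum()))

    def test_identical_maps_identical_rows(self, small_grid):
        m = small_grid.like(np.random.default_rng(1).random(small_grid.shape))
        mat = vectorize_maps([m, m.copy()])
        assert np.array_equal(mat[0], mat[1])

    def test_devectorize_inverts_on_mask(self, small_grid):
        m = small_grid.like(np.random.default_rng(2).random(small_grid.shape))
        row = vectorize_maps([m])[0]
        back = devectorize(row, small_grid)
        assert np.array_equal(back.values, m.values)

    def test_constant_map_rejected(self, small_grid):
        flat = small_grid.like(np.ones(small_grid.shape))
        with pytest.raises(ValueError, match="constant"):
            vectorize_maps([flat], ["flat"])


class TestDistanceMatrix:
    def test_identical_vectors_distance_zero(self):
        v = np.array([[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]])
        dm = distance_matrix(v)
        assert dm.D[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_vectors_distance_two(self):
        v = np.array([[1.0, 2.0, 3.0], [-1.0, -2.0, -3.0]])
        dm = distance_matrix(v)
        assert dm.D[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_matches_hand_computed_pearson(self):
        v = np.array([[1.0, 2.0, 3.0, 4.0], [2.0, 1.0, 4.0, 3.0], [4.0, 3.0, 2.0, 1.0]])
        dm = distance_matrix(v, ["a", "b", "c"])

        def pearson(x, y):
            xc, yc = x - x.mean(), y - y.mean()
            return (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())

        for i, j in itertools.combinations(range(3), 2):
            assert dm.D[i, j] == pytest.approx(1 - pearson(v[i], v[j]), abs=1e-12)

    def test_zero_variance_row_names_network(self):
        v = np.array([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]])
        with pytest.raises(ValueError, match="netB"):
            distance_matrix(v, ["netA", "netB"])

    def test_invariant_under_affine_rescaling(self):
        rng = np.random.default_rng(3)
        v = rng.random((4, 30))
        a = distance_matrix(v).D
        scaled = v.copy()
        scaled[0] = 3.5 * scaled[0] - 12.0  # positive affine map
        b = distance_matrix(scaled).D
        assert np.allclose(a, b, atol=1e-12)

    def test_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [0.5, 0.0]]))


def two_block_distance(n_a, n_b, within=0.1, between=1.2):
    n = n_a + n_b
    D = np.full((n, n), between)
    D[:n_a, :n_a] = within
    D[n_a:, n_a:] = within
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix([f"x{i}" for i in range(n)], D)


class TestReorder:
    def test_block_structure_becomes_contiguous(self):
        # scramble a 2-block matrix, reorder, check blocks are contiguous
        dm = two_block_distance(3, 3)
        scramble = [0, 3, 1, 4, 2, 5]
        scrambled = dm.permuted(scramble)
        order = reorder_matrix(scrambled)
        blocks = ["A" if scrambled.labels[i] in {"x0", "x1", "x2"} else "B" for i in order]
        assert blocks in (["A"] * 3 + ["B"] * 3, ["B"] * 3 + ["A"] * 3)

    def test_matches_exhaustive_block_contiguity_oracle(self):
        # at n=6, exhaustively confirm a contiguous arrangement exists and
        # that the spectral order is one of the contiguous optima
        dm = two_block_distance(3, 3)
        scrambled = dm.permuted([5, 0, 4, 1, 3, 2])
        order = reorder_matrix(scrambled)

        def contiguous(perm):
            kinds = ["A" if scrambled.labels[i] in {"x0", "x1", "x2"} else "B" for i in perm]
            changes = sum(kinds[i] != kinds[i + 1] for i in range(5))
            return changes == 1

        assert any(contiguous(p) for p in itertools.permutations(range(6)))
        assert contiguous(order)

    def test_ordered_input_stays_ordered_or_reverses(self):
        dm = two_block_distance(2, 2)
        order = reorder_matrix(dm)
        assert order in ([0, 1, 2, 3], [3, 2, 1, 0], [1, 0, 3, 2], [2, 3, 0, 1])

    def test_permutation_is_bijection(self):
        rng = np.random.default_rng(4)
        v = rng.random((5, 20))
        order = reorder_matrix(distance_matrix(v))
        assert sorted(order) == list(range(5))


class TestWard:
    def test_two_points_single_merge(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0.0, 0.7], [0.7, 0.0]]))
        Z = ward_dendrogram(dm)
        assert Z.shape == (1, 4)
        assert Z[0, 2] == pytest.approx(0.7)

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(5)
        dm = distance_matrix(rng.random((7, 25)))
        Z = ward_dendrogram(dm)
        assert np.all(np.diff(Z[:, 2]) >= -1e-12)

    def test_two_cluster_cut_recovers_blocks(self):
        dm = two_block_distance(4, 3)
        clusters = cut_dendrogram(ward_dendrogram(dm), dm, 2)
        a = {clusters[f"x{i}"] for i in range(4)}
        b = {clusters[f"x{i}"] for i in range(4, 7)}
        assert len(a) == 1 and len(b) == 1 and a != b

    def test_tree_export_round_trip_labels(self):
        dm = two_block_distance(2, 2)
        tree = linkage_to_tree(ward_dendrogram(dm), dm.labels)

        def leaves(node):
            if "name" in node:
                return [node["name"]]
            return sum((leaves(c) for c in node["children"]), [])

        assert sorted(leaves(tree)) == dm.labels


class TestMds:
    def test_reembeds_exact_planar_configuration(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.3, 0.9], [0.8, 0.5]])
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dm = DistanceMatrix(list("abcd"), D)
        emb = mds_embed(dm, d=2)
        assert np.allclose(emb.pairwise_distances(), D, atol=1e-8)
        assert emb.stress < 1e-8

    def test_equilateral_triangle_from_equal_distances(self):
        dm = DistanceMatrix(list("abc"), np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float))
        emb = mds_embed(dm, d=2)
        d = emb.pairwise_distances()
        assert d[0, 1] == pytest.approx(d[0, 2]) == pytest.approx(d[1, 2])

    def test_full_dimension_gives_zero_stress_for_euclidean(self):
        rng = np.random.default_rng(6)
        pts = rng.random((5, 4))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dm = DistanceMatrix([f"p{i}" for i in range(5)], np.clip(D, 0, 2))
        assert mds_embed(dm, d=4).stress < 1e-10

    def test_stress_monotone_in_dimension(self):
        rng = np.random.default_rng(7)
        dm = distance_matrix(rng.random((6, 40)))
        stresses = [mds_embed(dm, d=d).stress for d in range(1, 6)]
        assert all(s1 >= s2 - 1e-12 for s1, s2 in zip(stresses, stresses[1:]))


class TestCentrality:
    def test_reference_excluded_and_percent_sums_to_100(self):
        rng = np.random.default_rng(8)
        dm = distance_matrix(rng.random((5, 30)), [f"n{i}" for i in range(5)])
        prof = centrality_profile(dm, "n2")
        assert "n2" not in set(prof["network"])
        assert prof["percent"].sum() == pytest.approx(100.0, abs=1e-9)
        assert prof["similarity"].is_monotonic_decreasing

    def test_mean_distances_matches_matrix(self):
        dm = two_block_distance(2, 2)
        md = mean_distances(dm)
        assert md["x0"] == pytest.approx(dm.D[0, 1:].sum() / 3)
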