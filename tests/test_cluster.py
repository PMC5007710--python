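"""Standardization, missing-tolerant distances, complete linkage, cutting."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from comparetx import (
    DataError,
    complete_linkage,
    cut,
    pairwise_distances,
    standardize,
)
from comparetx.cluster import linkage_from_distances


def brute_force_agglomeration(dist: pd.DataFrame):
    """Oracle: recompute every inter-cluster max leaf-pair distance each step.

    Same tie rule as the implementation (smallest sorted pair of minimum
    original leaf indices), but arrived at by exhaustive recomputation
    over the original distance matrix rather than by max-updates.
    """
    D = dist.to_numpy(dtype=float)
    n = D.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}  # node id -> leaves
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a in clusters:
            for b in clusters:
                if a >= b:
                    continue
                d = max(D[i, j] for i in clusters[a] for j in clusters[b])
                key = tuple(sorted((min(clusters[a]), min(clusters[b]))))
                cand = (d, key, a, b)
                if best is None or (d, key) < (best[0], best[1]):
                    best = cand
        d, key, a, b = best
        if min(clusters[b]) < min(clusters[a]):
            a, b = b, a
        merges.append((a, b, d))
        clusters[next_id] = clusters.pop(a) | clusters.pop(b)
        next_id += 1
    return merges


def random_distance_frame(rng, n):
    points = rng.normal(size=(n, 3))
    D = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    ids = [f"O{i}" for i in range(n)]
    return pd.DataFrame(D, index=ids, columns=ids)


class TestStandardize:
    def test_hand_case_uses_sample_sd(self):
        df = pd.DataFrame({"v": [1.0, 2.0, 3.0]})
        out = standardize(df)
        assert out["v"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_idempotent_on_standardized_input(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        once = standardize(df)
        twice = standardize(once)
        pd.testing.assert_frame_equal(once, twice, atol=1e-12, rtol=0)

    def test_zero_mean_unit_variance(self, rng):
        df = pd.DataFrame(rng.normal(5, 3, size=(15, 4)))
        out = standardize(df)
        assert np.all(np.abs(out.mean()) < 1e-10)
        assert np.all(np.abs(out.var(ddof=1) - 1) < 1e-10)

    def test_missing_entries_stay_missing(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "b"])
        df.iloc[3, 0] = np.nan
        out = standardize(df)
        assert np.isnan(out.iloc[3, 0])
        assert out.notna().sum().sum() == 19

    def test_constant_variable_named_in_error(self):
        df = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [4.0, 4.0, 4.0]})
        with pytest.raises(DataError, match="flat"):
            standardize(df)


class TestDistance:
    def test_identical_profiles_distance_zero(self):
        df = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["u", "v"])
        assert pairwise_distances(df).at["u", "v"] == pytest.approx(0.0)

    def test_three_four_five_triangle(self):
        df = pd.DataFrame([[0.0, 0.0], [3.0, 4.0]], index=["u", "v"])
        assert pairwise_distances(df).at["u", "v"] == pytest.approx(5.0)

    def test_missing_coordinate_rescaling(self):
        # shared coords give distance 5 over 2 of 3 coords: 5 * sqrt(3/2)
        df = pd.DataFrame([[0.0, 0.0, np.nan], [3.0, 4.0, 7.0]], index=["u", "v"])
        assert pairwise_distances(df).at["u", "v"] == pytest.approx(5 * np.sqrt(1.5))

    def test_no_shared_coordinates_warns_and_is_missing(self):
        df = pd.DataFrame([[1.0, np.nan], [np.nan, 2.0]], index=["u", "v"])
        with pytest.warns(UserWarning, match="no observed"):
            d = pairwise_distances(df)
        assert np.isnan(d.at["u", "v"])

    def test_reduces_to_euclidean_without_missingness(self, rng):
        df = pd.DataFrame(rng.normal(size=(6, 4)))
        ours = pairwise_distances(df).to_numpy()
        theirs = pdist(df.to_numpy())
        assert np.allclose(ours[np.triu_indices(6, 1)], theirs)


class TestCompleteLinkage:
    def test_two_objects_single_merge(self):
        df = pd.DataFrame([[0.0], [3.0]], index=["a", "b"])
        dend = complete_linkage(df)
        assert len(dend.merges) == 1
        assert dend.merges[0] == (0, 1, 3.0)

    def test_hand_agglomerated_one_dimensional_points(self):
        df = pd.DataFrame([[0.0], [1.0], [5.0], [7.0]], index=list("abcd"))
        dend = complete_linkage(df)
        heights = [h for _, _, h in dend.merges]
        assert heights == pytest.approx([1.0, 2.0, 7.0])
        assert dend.merges[0][:2] == (0, 1)
        assert dend.merges[1][:2] == (2, 3)
        assert dend.merges[2][:2] == (4, 5)

    def test_heights_non_decreasing(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 12))
            dend = linkage_from_distances(random_distance_frame(rng, n))
            h = dend.heights
            assert np.all(np.diff(h) >= -1e-12)

    def test_matches_brute_force_oracle_exactly(self, rng):
        for _ in range(40):
            n = int(rng.integers(2, 11))
            dist = random_distance_frame(rng, n)
            ours = linkage_from_distances(dist).merges
            oracle = brute_force_agglomeration(dist)
            assert [m[:2] for m in ours] == [m[:2] for m in oracle]
            assert [m[2] for m in ours] == pytest.approx(
                [m[2] for m in oracle], abs=0
            )

    def test_oracle_agreement_with_tied_distances(self):
        # unit square: all four nearest-neighbour distances tie at 1
        pts = pd.DataFrame(
            [[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]], index=list("abcd")
        )
        dist = pairwise_distances(pts)
        ours = linkage_from_distances(dist).merges
        oracle = brute_force_agglomeration(dist)
        assert [m[:2] for m in ours] == [m[:2] for m in oracle]

    def test_agrees_with_scipy_on_clean_data(self, rng):
        X = rng.normal(size=(25, 6))
        ids = [f"O{i}" for i in range(25)]
        df = pd.DataFrame(X, index=ids)
        dend = complete_linkage(df)
        Z = linkage(pdist(X), method="complete")
        assert np.allclose(np.sort(dend.heights), np.sort(Z[:, 2]))
        for k in (2, 3, 5):
            ours = cut(dend, k)
            theirs = fcluster(Z, t=k, criterion="maxclust")
            our_parts = {
                frozenset(ours.members(c)) for c in range(1, k + 1)
            }
            their_parts = {
                frozenset(np.array(ids)[theirs == c]) for c in set(theirs)
            }
            assert our_parts == their_parts

    def test_permuting_objects_preserves_partitions(self, rng):
        dist = random_distance_frame(rng, 9)
        perm = rng.permutation(9)
        shuffled = dist.iloc[perm, perm]
        for k in (1, 2, 4, 9):
            a = cut(linkage_from_distances(dist), k)
            b = cut(linkage_from_distances(shuffled), k)
            parts_a = {frozenset(a.members(c)) for c in range(1, k + 1)}
            parts_b = {frozenset(b.members(c)) for c in range(1, k + 1)}
            assert parts_a == parts_b

    def test_missing_distance_is_hard_error(self):
        df = pd.DataFrame(
            [[1.0, np.nan], [np.nan, 2.0], [0.0, 0.0]], index=list("abc")
        )
        with pytest.raises(DataError, match="impute|drop"):
            with pytest.warns(UserWarning):
                complete_linkage(df)


class TestCut:
    @pytest.fixture
    def four_point_dendrogram(self):
        df = pd.DataFrame([[0.0], [1.0], [5.0], [7.0]], index=list("abcd"))
        return complete_linkage(df)

    def test_root_cut_single_cluster(self, four_point_dendrogram):
        assignment = cut(four_point_dendrogram, 1)
        assert set(assignment.labels) == {1}

    def test_leaf_cut_singletons(self, four_point_dendrogram):
        assignment = cut(four_point_dendrogram, 4)
        assert sorted(assignment.labels) == [1, 2, 3, 4]

    def test_two_cluster_partition(self, four_point_dendrogram):
        assignment = cut(four_point_dendrogram, 2)
        assert assignment.members(1) == ["a", "b"]
        assert assignment.members(2) == ["c", "d"]

    def test_out_of_range_k(self, four_point_dendrogram):
        with pytest.raises(ValueError):
            cut(four_point_dendrogram, 0)
        with pytest.raises(ValueError):
            cut(four_point_dendrogram, 5)

    def test_cluster_numbering_by_first_leaf_appearance(self, rng):
        dist = random_distance_frame(rng, 8)
        assignment = cut(linkage_from_distances(dist), 3)
        seen = []
        for label in assignment.labels:
            if label not in seen:
                seen.append(label)
        assert seen == [1, 2, 3]


class TestNewick:
    def test_parseable_ultrametric_tree(self):
        from Bio import Phylo

        df = pd.DataFrame([[0.0], [1.0], [5.0], [7.0]], index=list("abcd"))
        dend = complete_linkage(df)
        tree = Phylo.read(io.StringIO(dend.to_newick()), "newick")
        names = sorted(t.name for t in tree.get_terminals())
        assert names == ["a", "b", "c", "d"]
        depths = tree.depths()
        leaf_depths = [d for t, d in depths.items() if t.is_terminal()]
        assert leaf_depths == pytest.approx([7.0] * 4)
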