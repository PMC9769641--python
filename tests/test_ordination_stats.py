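"""Distances, PCoA, PERMANOVA and rank-sum tests against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from simmg_eval import (
    DistanceMatrix,
    jaccard_distances,
    pcoa,
    permanova,
    wilcoxon_rank_sum,
)
from simmg_eval.ordination_stats import holm_adjust, permanova_exact


def _dm_from_points(points: np.ndarray, labels=None) -> DistanceMatrix:
    labels = labels or [f"p{i}" for i in range(len(points))]
    return DistanceMatrix(labels, squareform(pdist(points)))


class TestJaccard:
    def test_examples(self):
        df = pd.DataFrame(
            {
                "a": [1, 1, 0, 0],
                "b": [0, 1, 1, 0],
                "c": [1, 1, 0, 0],
                "d": [0, 0, 0, 1],
            },
            dtype=bool,
        )
        dm = jaccard_distances(df)
        d = pd.DataFrame(dm.d, index=dm.labels, columns=dm.labels)
        assert d.loc["a", "c"] == 0.0  # identical
        assert d.loc["a", "b"] == pytest.approx(1 - 1 / 3)  # {1,2} vs {2,3}
        assert d.loc["a", "d"] == 1.0  # disjoint non-empty

    def test_triangle_inequality_on_random_vectors(self):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(rng.random((12, 8)) < 0.4)
        dm = jaccard_distances(mat)
        n = len(dm.labels)
        for i, j, k in itertools.permutations(range(n), 3):
            assert dm.d[i, j] <= dm.d[i, k] + dm.d[k, j] + 1e-12

    def test_all_zero_pair_flagged(self):
        df = pd.DataFrame({"a": [0, 0], "b": [0, 0]}, dtype=bool)
        with pytest.warns(UserWarning):
            dm = jaccard_distances(df)
        assert dm.d[0, 1] == 0.0


class TestPcoa:
    def test_collinear_points_embed_on_one_axis(self):
        # three points on a line at 0, 1, 2
        d = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
        res = pcoa(DistanceMatrix(["a", "b", "c"], d))
        assert (res.eigenvalues > 1e-10).sum() == 1
        got = squareform(pdist(res.coordinates[:, :1]))
        np.testing.assert_allclose(got, d, atol=1e-10)

    def test_zero_distances_zero_coordinates(self):
        d = np.zeros((4, 4))
        res = pcoa(DistanceMatrix(list("abcd"), d))
        assert res.coordinates.shape[1] == 0 or np.allclose(res.coordinates, 0)

    def test_euclidean_round_trip(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(15, 4))
        dm = _dm_from_points(pts)
        res = pcoa(dm)
        got = squareform(pdist(res.coordinates))
        np.testing.assert_allclose(got, dm.d, atol=1e-8)

    def test_negative_eigenvalues_reported_for_jaccard(self):
        rng = np.random.default_rng(5)
        mat = pd.DataFrame(rng.random((30, 10)) < 0.5)
        dm = jaccard_distances(mat)
        res = pcoa(dm)
        # eigenvalues ordered descending, negatives present but not silently dropped
        assert (np.diff(res.eigenvalues) <= 1e-9).all()
        assert res.proportion_explained.sum() <= 1 + 1e-9

    def test_matches_reference_implementation(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(10, 3))
        dm = _dm_from_points(pts)
        ours = pcoa(dm)
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(dm.d, ids=dm.labels), method="eigh"
        )
        n_axes = min(3, ours.coordinates.shape[1])
        for ax in range(n_axes):
            a = ours.coordinates[:, ax]
            b = theirs.samples.to_numpy()[:, ax]
            assert abs(abs(np.dot(a, b)) / (np.linalg.norm(a) * np.linalg.norm(b)) - 1) < 1e-6


class TestPermanova:
    def test_separated_clouds_hit_enumeration_floor(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.1, size=(6, 2))
        b = rng.normal(50, 0.1, size=(6, 2))
        dm = _dm_from_points(np.vstack([a, b]))
        res = permanova(dm, ["a"] * 6 + ["b"] * 6, n_permutations=999, seed=1)
        # at most the handful of permutations that reproduce the observed
        # partition can reach the observed F
        assert res.p_value <= 6 / 1000
        assert res.r_squared > 0.99

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(6, 2))
        pts[:3] += 1.2
        dm = _dm_from_points(pts)
        groups = ["a"] * 3 + ["b"] * 3
        exact = permanova_exact(dm, groups)
        mc = permanova(dm, groups, n_permutations=999, seed=3)
        assert abs(mc.p_value - exact) <= 0.02

    def test_f_and_r2_match_reference_implementation(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(12, 3))
        pts[:6] += 0.8
        dm = _dm_from_points(pts)
        groups = ["a"] * 6 + ["b"] * 6
        ours = permanova(dm, groups, n_permutations=99, seed=0)
        theirs = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm.d, ids=dm.labels), grouping=groups, permutations=99
        )
        assert ours.pseudo_F == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_invariances(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(10, 2))
        dm = _dm_from_points(pts)
        groups = ["a"] * 5 + ["b"] * 5
        base = permanova(dm, groups, n_permutations=99, seed=4)
        relabeled = permanova(dm, ["x" if g == "a" else "y" for g in groups],
                              n_permutations=99, seed=4)
        scaled = permanova(DistanceMatrix(dm.labels, dm.d * 3.7), groups,
                           n_permutations=99, seed=4)
        assert base.pseudo_F == pytest.approx(relabeled.pseudo_F)
        assert base.pseudo_F == pytest.approx(scaled.pseudo_F)
        assert base.r_squared == pytest.approx(scaled.r_squared)

    def test_group_of_one_rejected(self):
        dm = _dm_from_points(np.random.default_rng(1).normal(size=(5, 2)))
        with pytest.raises(ValueError, match="size 1"):
            permanova(dm, ["a", "a", "a", "a", "b"])

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(12)
        dm = _dm_from_points(rng.normal(size=(9, 2)))
        groups = ["a", "b", "c"] * 3
        p1 = permanova(dm, groups, seed=5).p_value
        p2 = permanova(dm, groups, seed=5).p_value
        assert p1 == p2


class TestWilcoxon:
    def test_exact_small_sample_matches_enumeration(self):
        x, y = (1, 2, 3), (4, 5, 6)
        _, p = wilcoxon_rank_sum(x, y)
        # oracle: enumerate all C(6,3)=20 assignments of ranks to x
        pooled = sorted(x + y)
        obs = sum(pooled.index(v) + 1 for v in x)
        stats = [
            sum(c)
            for c in itertools.combinations(range(1, 7), 3)
        ]
        mean = np.mean(stats)
        extreme = sum(1 for s in stats if abs(s - mean) >= abs(obs - mean)) / len(stats)
        assert p == pytest.approx(extreme) == pytest.approx(0.1)

    def test_identical_samples(self):
        with pytest.warns(UserWarning):
            _, p = wilcoxon_rank_sum([2, 2, 2], [2, 2])
        assert p == 1.0
        _, p_same = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert p_same == pytest.approx(1.0, abs=0.05)

    def test_shifted_large_samples_significant(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 60)
        y = rng.normal(2, 1, 60)
        _, p = wilcoxon_rank_sum(x, y)
        assert p < 1e-3

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


def test_holm_adjustment_monotone():
    raw = {"a": 0.01, "b": 0.04, "c": 0.3}
    adj = holm_adjust(raw)
    assert adj["a"] == pytest.approx(0.03)
    assert adj["a"] <= adj["b"] <= adj["c"]
    assert all(adj[k] >= raw[k] for k in raw)
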