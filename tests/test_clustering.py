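"""Polarity-invariant modified k-means, K selection, template matching."""

import itertools

import numpy as np
import pytest

import microstates as m
from microstates.clustering import _prepare_maps
from microstates.exceptions import DegenerateClusteringError, InvalidInputError


def _brute_force_two_partition(X):
    """Global max of sum_k lambda_max over all 2-partitions (sign-invariant)."""
    n = X.shape[0]
    best = -np.inf
    for assign in itertools.product([0, 1], repeat=n - 1):
        labels = np.array((0,) + assign)
        total = 0.0
        ok = True
        for k in (0, 1):
            Xk = X[labels == k]
            if Xk.shape[0] == 0:
                ok = False
                break
            total += float(np.linalg.eigvalsh(Xk @ Xk.T)[-1])
        if ok:
            best = max(best, total)
    return best


def _two_orthogonal(n=16):
    a = np.zeros(n)
    a[: n // 2], a[n // 2 :] = 1.0, -1.0
    b = np.zeros(n)
    b[::2], b[1::2] = 1.0, -1.0
    b -= b.mean()
    a -= a.mean()
    return a, b


class TestModifiedKmeans:
    def test_noiseless_two_cluster_recovery(self):
        a, b = _two_orthogonal()
        maps = np.array([a, -a, a, b, -b, b])
        ms = m.modified_kmeans(maps, 2, m.ClusteringParams(seed=0, restarts=5))
        matched = m.match_templates(ms, m.MicrostateSet(np.vstack([a, b])))
        assert np.allclose(matched.pair_r, 1.0)

    def test_polarity_invariance_same_seed(self, rng):
        maps = rng.standard_normal((60, 16))
        params = m.ClusteringParams(seed=3, restarts=5)
        ms1 = m.modified_kmeans(maps, 3, params)
        ms2 = m.modified_kmeans(-maps, 3, params)
        matched = m.match_templates(ms2, ms1)
        assert np.allclose(matched.pair_r, 1.0, atol=1e-9)

    def test_scale_invariance(self, rng):
        maps = rng.standard_normal((40, 16))
        params = m.ClusteringParams(seed=4, restarts=5)
        ms1 = m.modified_kmeans(maps, 2, params)
        ms2 = m.modified_kmeans(7.3 * maps, 2, params)
        assert np.allclose(ms1.templates, ms2.templates)

    def test_four_template_recovery(self, rng):
        truth = np.array([t.values for t in m.make_templates(32, 4, seed=5)])
        idx = rng.integers(0, 4, size=200)
        signs = rng.choice([-1.0, 1.0], size=200)
        maps = signs[:, None] * truth[idx] + 0.05 * rng.standard_normal((200, 32))
        ms = m.modified_kmeans(maps, 4, m.ClusteringParams(seed=6))
        matched = m.match_templates(ms, m.MicrostateSet(truth))
        assert matched.mean_r >= 0.99

    def test_objective_monotone_within_restart(self, rng):
        maps = rng.standard_normal((80, 16))
        ms = m.modified_kmeans(maps, 3, m.ClusteringParams(seed=7, restarts=1))
        hist = ms.provenance["objective_history"]
        assert all(b >= a - 1e-12 for a, b in zip(hist, hist[1:]))

    def test_exhaustive_partition_oracle_small_instances(self, rng):
        # structured instances (maps from 2 templates, small noise): the
        # algorithm attains the global partition optimum found by brute force
        for _ in range(20):
            T = np.array([t.values for t in m.make_templates(32, 2, seed=int(rng.integers(1 << 30)))])
            n = int(rng.integers(5, 13))
            idx = rng.integers(0, 2, size=n)
            signs = rng.choice([-1.0, 1.0], size=n)
            X = _prepare_maps(signs[:, None] * T[idx] + 0.2 * rng.standard_normal((n, 32)))
            best = _brute_force_two_partition(X)
            ms = m.modified_kmeans(X, 2, m.ClusteringParams(seed=8))
            assert ms.explained * n == pytest.approx(best, abs=1e-9)

    def test_never_exceeds_brute_force_on_unstructured_maps(self, rng):
        # on arbitrary maps the local search is bounded above by the oracle
        for _ in range(10):
            n = int(rng.integers(5, 11))
            X = _prepare_maps(rng.standard_normal((n, 8)))
            best = _brute_force_two_partition(X)
            ms = m.modified_kmeans(X, 2, m.ClusteringParams(seed=8, restarts=10))
            assert best >= ms.explained * n - 1e-9

    def test_too_few_maps_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            m.modified_kmeans(rng.standard_normal((3, 8)), 4)

    def test_degenerate_identical_maps_rejected(self):
        a = np.arange(8.0) - 3.5
        maps = np.array([a, -a, 2 * a, a])
        with pytest.raises(DegenerateClusteringError):
            m.modified_kmeans(maps, 2)

    def test_templates_unit_norm_zero_mean(self, rng):
        ms = m.modified_kmeans(rng.standard_normal((50, 16)), 3, m.ClusteringParams(seed=9))
        assert np.allclose(np.linalg.norm(ms.templates, axis=1), 1.0, atol=1e-9)
        assert np.allclose(ms.templates.mean(axis=1), 0.0, atol=1e-9)


class TestSelectClusterNumber:
    def test_noiseless_four_templates_selects_four(self, rng):
        truth = np.array([t.values for t in m.make_templates(32, 4, seed=10)])
        idx = np.repeat(np.arange(4), 25)
        signs = rng.choice([-1.0, 1.0], size=100)
        maps = signs[:, None] * truth[idx]
        params = m.ClusteringParams(seed=11, k_fixed=None, restarts=5)
        ms = m.select_cluster_number(maps, params)
        assert ms.K == 4

    def test_selection_deterministic_at_zero_noise(self, rng):
        truth = np.array([t.values for t in m.make_templates(16, 3, seed=12)])
        maps = truth[np.repeat(np.arange(3), 10)]
        for seed in (1, 2):
            params = m.ClusteringParams(seed=seed, k_fixed=None, restarts=5, k_range=(2, 6))
            assert m.select_cluster_number(maps, params).K == 3

    def test_k_fixed_performs_single_fit(self, rng):
        maps = rng.standard_normal((30, 16))
        ms = m.select_cluster_number(maps, m.ClusteringParams(seed=0, k_fixed=4))
        assert ms.K == 4
        assert "k_selection" not in ms.provenance

    def test_k_range_truncated_with_warning(self, rng):
        maps = rng.standard_normal((5, 8))
        params = m.ClusteringParams(seed=0, k_fixed=None, k_range=(2, 8), restarts=2)
        with pytest.warns(UserWarning, match="truncat"):
            ms = m.select_cluster_number(maps, params)
        assert ms.K <= 5


class TestMatchTemplates:
    def test_identity_match(self, rng):
        ms = m.MicrostateSet(_prepare_maps(rng.standard_normal((4, 16))))
        matched = m.match_templates(ms, ms)
        assert matched.permutation == (0, 1, 2, 3)
        assert np.allclose(matched.pair_r, 1.0)

    def test_reversed_and_flipped_recovered(self, rng):
        T = _prepare_maps(rng.standard_normal((4, 16)))
        a = m.MicrostateSet(-T[::-1])
        matched = m.match_templates(a, m.MicrostateSet(T))
        assert matched.permutation == (3, 2, 1, 0)
        assert np.allclose(matched.pair_r, 1.0)
        # alignment flips signs so matched R is positive
        assert np.allclose(matched.aligned.templates, T)

    def test_agrees_with_brute_force(self, rng):
        for _ in range(10):
            A = _prepare_maps(rng.standard_normal((4, 12)))
            B = _prepare_maps(rng.standard_normal((4, 12)))
            matched = m.match_templates(m.MicrostateSet(A), m.MicrostateSet(B))
            R = np.abs(A @ B.T)
            best = max(
                sum(R[p[j], j] for j in range(4)) for p in itertools.permutations(range(4))
            )
            assert sum(matched.pair_r) == pytest.approx(best, abs=1e-12)

    def test_unequal_k_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            m.match_templates(
                m.MicrostateSet(rng.standard_normal((3, 8))),
                m.MicrostateSet(rng.standard_normal((4, 8))),
            )
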