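"""Fuzzy c-means: fit correctness, validity indices, preprocessing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.vq import kmeans2
from scipy.spatial.distance import cdist

from ecotransect.errors import ClusterCountError, ConfigurationError
from ecotransect.fcm import (
    FeatureMatrix,
    _centroids,
    _memberships_from_distances,
    fit_fcm,
    inverse_transform,
    max_clusters,
    preprocess,
    select_k,
    validity_indices,
)


def two_blob_data(rng, n=20, sep=10.0):
    a = rng.normal(0.0, 0.3, size=(n, 2))
    b = rng.normal(sep, 0.3, size=(n, 2))
    return np.vstack([a, b])


class TestFit:
    def test_two_cluster_recovery_1d(self):
        X = np.array([0.0, 0, 0, 10, 10, 10])[:, None]
        part = fit_fcm(X, 2, m=2.0, seed=7)
        assert np.allclose(np.sort(part.V.ravel()), [0.0, 10.0], atol=1e-3)
        assert part.U.max(axis=1).min() >= 0.99
        assert part.converged

    def test_stationarity_at_convergence(self, rng):
        X = two_blob_data(rng)
        part = fit_fcm(X, 2, seed=3)
        d2 = cdist(X, part.V, "sqeuclidean")
        U2 = _memberships_from_distances(d2, part.m)
        V2 = _centroids(X, part.U, part.m)
        assert np.max(np.abs(U2 - part.U)) < 1e-6
        assert np.max(np.abs(V2 - part.V)) < 1e-6

    def test_cluster_count_constraint_names_limit(self, rng):
        X = rng.normal(size=(8, 2))
        with pytest.raises(ClusterCountError, match=r"n/2 - 1"):
            fit_fcm(X, 4)
        with pytest.raises(ClusterCountError, match="3"):
            fit_fcm(X, 4)
        # disabling the constraint allows the fit
        assert fit_fcm(X, 4, enforce_limit=False, seed=0).k == 4

    def test_coincident_point_gets_crisp_membership(self):
        # a point sitting exactly on a centroid: singleton rule gives it 1
        d2 = np.array([[0.0, 4.0], [1.0, 1.0], [0.0, 0.0]])
        U = _memberships_from_distances(d2, 2.0)
        assert U[0].tolist() == [1.0, 0.0]
        assert U[1].tolist() == [0.5, 0.5]
        assert U[2].tolist() == [0.5, 0.5]  # coincident with both: split equally

    @pytest.mark.parametrize("seed", range(5))
    def test_rows_stochastic_and_objective_monotone(self, seed, rng):
        X = np.random.default_rng(seed).normal(size=(30, 3))
        part = fit_fcm(X, 3, seed=seed, n_starts=2)
        assert np.allclose(part.U.sum(axis=1), 1.0, atol=1e-9)
        hist = np.array(part.objective_history)
        assert np.all(np.diff(hist) <= 1e-12)

    def test_memberships_approach_kmeans_as_m_to_one(self, rng):
        X = two_blob_data(rng, n=25)
        part = fit_fcm(X, 2, m=1.05, seed=11)
        _, km_labels = kmeans2(X, 2, seed=11, minit="++")
        fcm_labels = part.hard_labels()
        agree = max(
            np.mean(fcm_labels == km_labels), np.mean(fcm_labels == 1 - km_labels)
        )
        assert agree == 1.0
        assert part.U.max(axis=1).min() > 0.999

    def test_permutation_of_clusters_only_permutes_U_and_V(self, rng):
        X = two_blob_data(rng)
        part = fit_fcm(X, 2, seed=5)
        perm = [1, 0]
        d2 = cdist(X, part.V[perm], "sqeuclidean")
        U_perm = _memberships_from_distances(d2, part.m)
        assert np.allclose(U_perm, part.U[:, perm], atol=1e-9)

    def test_m_must_exceed_one(self, rng):
        with pytest.raises(ConfigurationError):
            fit_fcm(rng.normal(size=(10, 2)), 2, m=1.0)


class TestValidity:
    def test_crisp_partition_is_maximally_valid(self):
        U = np.eye(3)[[0, 1, 2, 0, 1]]
        v = validity_indices(U)
        assert v.PC_norm == pytest.approx(1.0)
        assert v.PE_norm == pytest.approx(0.0)

    def test_uniform_partition_is_minimally_valid(self):
        U = np.full((6, 3), 1 / 3)
        v = validity_indices(U)
        assert v.PC_norm == pytest.approx(0.0, abs=1e-12)
        assert v.PE_norm == pytest.approx(1.0)

    def test_hand_computed_two_by_two(self):
        v = validity_indices(np.array([[0.8, 0.2], [0.3, 0.7]]))
        assert v.PC == pytest.approx(0.63)
        assert v.PC_norm == pytest.approx(0.26)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(2, 6), st.integers(2, 12), st.integers(0, 10_000))
    def test_index_bounds(self, k, n, seed):
        U = np.random.default_rng(seed).dirichlet(np.ones(k) * 0.5, size=n)
        v = validity_indices(U)
        assert 1 / k - 1e-12 <= v.PC <= 1 + 1e-12
        assert -1e-12 <= v.PC_norm <= 1 + 1e-12
        assert -1e-12 <= v.PE <= np.log(k) + 1e-12
        assert -1e-12 <= v.PE_norm <= 1 + 1e-12


class TestSelectK:
    def test_two_blobs_choose_two(self, rng):
        X = two_blob_data(rng, n=8)
        k, table, _ = select_k(X, (2, 3), seed=0, n_starts=5)
        assert k == 2
        pc = {v.k: v.PC_norm for v in table}
        assert pc[2] > pc[3]

    def test_range_truncated_at_limit(self, rng):
        X = rng.normal(size=(8, 2))
        k, table, _ = select_k(X, (2, 3, 4, 5), seed=0, n_starts=3)
        assert max_clusters(8) == 3
        assert {v.k for v in table} == {2, 3}

    def test_empty_feasible_range_raises(self, rng):
        with pytest.raises(ClusterCountError, match=r"n/2 - 1"):
            select_k(rng.normal(size=(8, 2)), (4, 5), seed=0)

    def test_tie_breaks_toward_smaller_k(self):
        # one tight blob: no k is better, the smaller must win
        X = np.random.default_rng(0).normal(size=(24, 2)) * 1e-6
        k, _, _ = select_k(X, (2, 3), seed=0, n_starts=3)
        assert k == 2


class TestPreprocess:
    def make_fm(self, X, pos=None):
        pos = np.arange(X.shape[0], dtype=float) if pos is None else pos
        return FeatureMatrix(X, pos, [f"v{i}" for i in range(X.shape[1])])

    def test_zscore_constant_column_raises(self):
        X = np.column_stack([np.arange(5.0), np.ones(5)])
        with pytest.raises(ConfigurationError, match="zero-variance"):
            preprocess(self.make_fm(X), "env_zscore")

    def test_hellinger_unit_row_norm(self, rng):
        X = rng.uniform(0, 5, size=(6, 10))
        X = 100 * X / X.sum(axis=1, keepdims=True)
        ft = preprocess(self.make_fm(X), "hellinger")
        assert np.allclose((ft.values**2).sum(axis=1), 1.0, atol=1e-12)

    @pytest.mark.parametrize("mode", ["env_zscore", "hellinger"])
    def test_round_trip_recovers_natural_units(self, mode, rng):
        X = rng.uniform(0.1, 5, size=(6, 8))
        if mode == "hellinger":
            X = 100 * X / X.sum(axis=1, keepdims=True)
        ft = preprocess(self.make_fm(X), mode)
        back = inverse_transform(ft.values, ft.transform)
        assert np.allclose(back, X, atol=1e-9)

    def test_unknown_mode_raises(self, rng):
        with pytest.raises(ConfigurationError):
            preprocess(self.make_fm(rng.normal(size=(5, 2))), "rank")
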