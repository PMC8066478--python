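"""Centroid interpretation: natural-unit summaries, labels, representative OTUs."""

import numpy as np
import pandas as pd
import pytest

from ecotransect.centroids import (
    env_centroid_summary,
    label_community_clusters,
    label_env_clusters_by_position,
    otu_memberships,
    representative_otus,
    top_fraction_otus,
    aggregate_by_taxon,
)
from ecotransect.errors import ConfigurationError
from ecotransect.fcm import FeatureMatrix, fit_fcm, preprocess


def fitted_env(rng, n=24):
    x = np.sort(rng.uniform(0, 60, n))
    X = np.column_stack([np.where(x < 30, 13.0, 11.0) + rng.normal(0, 0.1, n),
                         np.where(x < 30, 34.3, 34.6) + rng.normal(0, 0.02, n)])
    fm = FeatureMatrix(X, x, ["sst_c", "sss_psu"])
    fz = preprocess(fm, "env_zscore")
    return fit_fcm(fz, 2, seed=0), fz, X


class TestEnvSummary:
    def test_zscore_inverse_equals_weighted_mean_of_raw(self, rng):
        part, fz, X = fitted_env(rng)
        out = env_centroid_summary(part, fz)
        W = part.U**part.m
        for k in range(2):
            w = W[:, k] / W[:, k].sum()
            assert out.loc[k, "sst_c"] == pytest.approx(float(w @ X[:, 0]), abs=1e-6)
            assert out.loc[k, "sss_psu"] == pytest.approx(float(w @ X[:, 1]), abs=1e-6)

    def test_constant_data_centroid_is_the_constant(self):
        X = np.full((8, 2), 5.0)
        fm = FeatureMatrix(X, np.arange(8.0), ["a", "b"])
        part = fit_fcm(fm, 1, seed=0, enforce_limit=False)
        out = env_centroid_summary(part, fm)
        assert out.loc[0, "a"] == pytest.approx(5.0)
        assert out.loc[0, "a_sd"] == pytest.approx(0.0, abs=1e-9)

    def test_positional_labels_follow_spatial_order(self, rng):
        part, fz, _ = fitted_env(rng)
        labels = label_env_clusters_by_position(part, fz.positions, ["inshore", "offshore"])
        centers = (part.U.T @ fz.positions) / part.U.sum(axis=0)
        assert labels[int(np.argmin(centers))] == "inshore"


class TestCommunityLabels:
    def test_identical_profile_gets_that_label(self):
        u = np.array([0.9, 0.8, 0.2, 0.1])
        U_env = np.column_stack([u, 1 - u])
        labels = label_community_clusters(u[:, None], U_env, ["STW", "SAW"])
        assert labels == [["STW"]]

    def test_anticorrelated_profile_unassigned(self):
        u = np.array([0.9, 0.8, 0.2, 0.1])
        labels = label_community_clusters((1 - u)[:, None], u[:, None], ["STW"])
        assert labels == [["unassigned"]]

    def test_near_tied_masses_share_the_label(self):
        u = np.array([0.9, 0.7, 0.3, 0.1])
        noise = np.array([0.01, -0.01, 0.01, -0.01])
        U_env = np.column_stack([u, u + noise])
        labels = label_community_clusters(u[:, None], U_env, ["STW", "FRONT"])
        assert set(labels[0]) == {"STW", "FRONT"}


class TestOTUMemberships:
    def test_shares_are_row_stochastic_and_zero_otus_dropped(self, rng):
        C = pd.DataFrame(rng.uniform(0, 3, (3, 20)),
                         index=["C0", "C1", "C2"],
                         columns=[f"o{i}" for i in range(20)])
        C["o0"] = 0.0
        shares = otu_memberships(C)
        assert "o0" not in shares.index
        assert np.allclose(shares.sum(axis=1), 1.0, atol=1e-9)

    def test_exclusive_otu_is_always_representative(self):
        C = pd.DataFrame([[4.0, 0.0], [0.0, 0.0]], index=["C0", "C1"], columns=["x", "y"])
        shares = otu_memberships(C)
        assert shares.loc["x", "C0"] == 1.0
        assert "x" in representative_otus(shares, 0.99)["C0"]

    def test_six_one_one_threshold_arithmetic(self):
        C = pd.DataFrame([[6.0], [1.0], [1.0]], index=["C0", "C1", "C2"], columns=["o"])
        shares = otu_memberships(C)
        assert shares.loc["o", "C0"] == pytest.approx(0.75)
        assert "o" in representative_otus(shares, 0.75)["C0"]
        assert "o" not in representative_otus(shares, 0.85)["C0"]

    def test_even_otu_never_representative(self):
        C = pd.DataFrame([[2.0], [2.0], [2.0]], index=list("abc"), columns=["o"])
        pools = representative_otus(otu_memberships(C), 0.75)
        assert all(len(p) == 0 for p in pools.values())

    @pytest.mark.parametrize("seed", range(3))
    def test_raising_tau_shrinks_pools_monotonically(self, seed):
        rng = np.random.default_rng(seed)
        C = pd.DataFrame(rng.gamma(0.5, 1.0, (3, 60)), index=["C0", "C1", "C2"])
        shares = otu_memberships(C)
        prev = None
        for tau in (0.75, 0.85, 0.95, 0.99):
            pools = representative_otus(shares, tau)
            if prev is not None:
                for c in pools:
                    assert pools[c] <= prev[c]
            prev = pools


class TestTopFraction:
    def test_full_fraction_returns_everything(self):
        c = pd.Series([5.0, 3.0, 1.0], index=list("abc"))
        assert top_fraction_otus(c, 1.0) == {"a", "b", "c"}

    def test_ceiling_guarantees_at_least_one(self):
        c = pd.Series(np.linspace(1, 2, 100), index=[f"o{i}" for i in range(100)])
        assert len(top_fraction_otus(c, 0.01)) == 1

    def test_quarter_of_eight_is_top_two(self):
        c = pd.Series([8.0, 7, 6, 5, 4, 3, 2, 1], index=list("abcdefgh"))
        assert top_fraction_otus(c, 0.25) == {"a", "b"}

    def test_ties_at_cut_are_kept(self):
        c = pd.Series([5.0, 3.0, 3.0, 1.0], index=list("abcd"))
        assert top_fraction_otus(c, 0.5) == {"a", "b", "c"}

    def test_empty_centroid_empty_set(self):
        assert top_fraction_otus(pd.Series(dtype=float), 0.5) == set()


def test_taxon_aggregation_sums_member_otus():
    C = pd.DataFrame([[1.0, 2.0, 3.0]], index=["C0"], columns=["o1", "o2", "o3"])
    agg = aggregate_by_taxon(C, {"o1": "PhA", "o2": "PhA"})
    assert agg.loc["C0", "PhA"] == pytest.approx(3.0)
    assert agg.loc["C0", "unclassified"] == pytest.approx(3.0)


class TestPlantedStructure:
    def test_specialists_representative_ubiquitous_not(self, small_scenario):
        """Planted STW/SAW specialists concentrate in the matching cluster
        centroid; ubiquitous OTUs never reach the representativeness cut."""
        from ecotransect.evaluate import analyse_month
        from ecotransect.synthetic import generate_dataset

        hits = total = ubiq_hits = ubiq_total = runs_ok = 0
        n_runs = 6
        for seed in range(n_runs):
            env, comms, truth = generate_dataset(small_scenario, seed=seed)
            rng = np.random.default_rng(seed)
            month = small_scenario.months[0]
            res = analyse_month(env[env["month"] == month], comms[month],
                                small_scenario, rng, n_starts=6)
            pools = representative_otus(otu_memberships(res.community_centroids), 0.85)
            lab = {f"C{i}": labs[0] for i, labs in enumerate(res.community_labels)}
            pool_by_mass = {}
            for c, pool in pools.items():
                pool_by_mass.setdefault(lab.get(c, ""), set()).update(pool)
            run_hits = run_total = 0
            for otu, mass in truth.specialists.items():
                if mass in ("STW", "SAW") and mass in pool_by_mass:
                    run_total += 1
                    run_hits += int(otu in pool_by_mass[mass])
            hits += run_hits
            total += run_total
            all_pools = set().union(*pools.values()) if pools else set()
            ubiq_total += len(truth.ubiquitous)
            ubiq_hits += sum(o in all_pools for o in truth.ubiquitous)
            if run_total and run_hits / run_total >= 0.9:
                runs_ok += 1
        assert runs_ok / n_runs >= 0.9
        assert ubiq_hits / ubiq_total < 0.05
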