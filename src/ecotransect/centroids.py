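"""Interpret fuzzy-cluster centroids: water-mass summaries, community labels,
and representative-OTU selection.

Environmental centroids are mapped back to degC / PSU so each cluster reads
as a water-mass signature.  Community clusters are tied to water masses by
correlating their membership profiles with the environmental ones at the
sampled stations.  An OTU's "membership grade" in a community cluster is
operationalized as its share of centroid abundance across clusters — the
centroid abundance in that cluster divided by its summed centroid abundance —
which lives in (0, 1) and sums to 1 over clusters; OTUs whose maximum share
reaches a threshold tau (default 0.85) are the cluster's representative pool.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .fcm import FeatureMatrix, FuzzyPartition, inverse_transform

__all__ = [
    "env_centroid_summary",
    "label_env_clusters_by_position",
    "label_community_clusters",
    "otu_memberships",
    "representative_otus",
    "top_fraction_otus",
    "aggregate_by_taxon",
]


def env_centroid_summary(partition: FuzzyPartition, fm: FeatureMatrix) -> pd.DataFrame:
    """Centroids in natural units with membership-weighted dispersions.

    ``fm`` is the preprocessed matrix the partition was fitted on; its
    recorded transform is inverted for both centroids and data, and the
    attached SDs are sqrt(sum_i u_ik^m (x_i - v_k)^2 / sum_i u_ik^m).
    """
    V_nat = inverse_transform(partition.V, fm.transform)
    X_nat = inverse_transform(fm.values, fm.transform)
    W = partition.U**partition.m
    rows = []
    for k in range(partition.k):
        w = W[:, k] / W[:, k].sum()
        sd = np.sqrt(w @ (X_nat - V_nat[k]) ** 2)
        row = {"cluster": k}
        for j, name in enumerate(fm.var_names):
            row[name] = V_nat[k, j]
            row[f"{name}_sd"] = sd[j]
        rows.append(row)
    return pd.DataFrame(rows)


def label_env_clusters_by_position(
    partition: FuzzyPartition, positions, labels_in_order: list[str]
) -> list[str]:
    """Name environmental clusters by their spatial order along the transect.

    Clusters are ranked by their membership-weighted mean position and given
    ``labels_in_order`` (coast to offshore).  Requires k == len(labels).
    """
    if partition.k != len(labels_in_order):
        raise ConfigurationError("one label per cluster required")
    x = np.asarray(positions, dtype=float)
    centers = (partition.U.T @ x) / partition.U.sum(axis=0)
    order = np.argsort(centers)
    labels = [""] * partition.k
    for rank, idx in enumerate(order):
        labels[idx] = labels_in_order[rank]
    return labels


def label_community_clusters(
    U_comm: np.ndarray,
    U_env_at_stations: np.ndarray,
    env_labels: list[str],
    share_margin: float = 0.05,
    min_corr: float = 0.3,
) -> list[list[str]]:
    """Associate each community cluster with the water mass(es) it tracks.

    For every community cluster the Pearson correlation between its station
    memberships and each environmental cluster's memberships (evaluated at
    the same stations) is computed; the best-correlated mass gives the label.
    A second mass within ``share_margin`` of the best correlation is reported
    too (a shared cluster).  If no correlation reaches ``min_corr`` the
    cluster is ["unassigned"].
    """
    U_comm = np.asarray(U_comm, float)
    U_env = np.asarray(U_env_at_stations, float)
    if U_comm.shape[0] != U_env.shape[0]:
        raise ConfigurationError("community and env memberships must share stations")
    out: list[list[str]] = []
    for c in range(U_comm.shape[1]):
        y = U_comm[:, c]
        corrs = []
        for e in range(U_env.shape[1]):
            x = U_env[:, e]
            if np.std(x) == 0 or np.std(y) == 0:
                corrs.append(-np.inf)
            else:
                corrs.append(float(np.corrcoef(x, y)[0, 1]))
        corrs = np.asarray(corrs)
        best = int(np.argmax(corrs))
        if corrs[best] < min_corr:
            out.append(["unassigned"])
            continue
        labels = [env_labels[best]]
        for e in np.argsort(corrs)[::-1][1:]:
            if corrs[best] - corrs[e] <= share_margin and corrs[e] >= min_corr:
                labels.append(env_labels[e])
        out.append(labels)
    return out


def otu_memberships(centroids: pd.DataFrame, drop_tol: float = 0.0) -> pd.DataFrame:
    """Per-OTU share of centroid abundance in each cluster (rows sum to 1).

    ``centroids``: clusters x OTUs in natural (%) units.  OTUs absent from
    every centroid (total abundance <= ``drop_tol``) are dropped.
    """
    C = centroids.to_numpy(dtype=float)
    if C.shape[0] < 2:
        raise ConfigurationError("need at least 2 cluster centroids")
    if np.any(C < -1e-12):
        raise ConfigurationError("centroid abundances must be non-negative")
    totals = C.sum(axis=0)
    keep = totals > drop_tol
    shares = C[:, keep] / totals[keep]
    return pd.DataFrame(shares.T, index=centroids.columns[keep], columns=centroids.index)


def representative_otus(shares: pd.DataFrame, tau: float = 0.85) -> dict:
    """Representative pool per cluster: OTUs whose max share >= tau there."""
    if not (0 < tau <= 1):
        raise ConfigurationError("tau must be in (0, 1]")
    S = shares.to_numpy(dtype=float)
    best = np.argmax(S, axis=1)
    qualifies = S[np.arange(S.shape[0]), best] >= tau
    pools: dict = {c: set() for c in shares.columns}
    for otu, b, q in zip(shares.index, best, qualifies):
        if q:
            pools[shares.columns[b]].add(otu)
    return pools


def top_fraction_otus(centroid: pd.Series, fraction: float) -> set:
    """The ``fraction`` most abundant OTUs of one centroid (ties at cut kept)."""
    if not (0 < fraction <= 1):
        raise ConfigurationError("fraction must be in (0, 1]")
    nz = centroid[centroid > 0]
    if nz.empty:
        return set()
    n_keep = math.ceil(fraction * nz.size)
    ranked = nz.sort_values(ascending=False)
    cut = ranked.iloc[n_keep - 1]
    return set(ranked[ranked >= cut].index)


def aggregate_by_taxon(centroids: pd.DataFrame, otu_to_taxon: dict) -> pd.DataFrame:
    """Sum centroid abundances by a user-supplied OTU -> taxon map."""
    taxa = [otu_to_taxon.get(o, "unclassified") for o in centroids.columns]
    return centroids.T.groupby(taxa).sum().T
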