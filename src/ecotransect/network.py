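"""Shared-OTU networks between community clusters and spinglass consensus.

Nodes are (month, water-mass-labelled community cluster) pairs carrying their
representative-OTU pools; an edge's weight is the number of OTUs the two
pools share.  Network modules are found with the Reichardt-Bornholdt
spinglass model, H = -sum_{i<j} (A_ij - gamma * k_i k_j / 2m) delta(s_i, s_j)
with the configuration-model null p_ij = k_i k_j / 2m, minimized by simulated
annealing (geometric cooling, start temperature calibrated so most early
moves accept, and a final zero-temperature quench so every run ends in a
local optimum).  The optimization is stochastic, so it is repeated (default
1000 runs) and the modal partition is reported along with every partition
seen in more than 1% of runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np

from .errors import ConfigurationError

__all__ = [
    "build_network",
    "rb_hamiltonian",
    "exhaustive_min_hamiltonian",
    "spinglass_communities",
    "ConsensusPartition",
    "network_summary",
]


def build_network(pools, tau: float | None = None) -> nx.Graph:
    """Weighted shared-OTU graph from per-cluster representative pools.

    ``pools`` maps a hashable node id (e.g. ``("Jan", "STW")``) to a set of
    OTU ids; an iterable of (id, set) pairs is also accepted, in which case
    duplicate ids raise.  Edge weight = |intersection|; zero-weight pairs
    carry no edge; pool sizes are stored on the nodes.
    """
    if not isinstance(pools, dict):
        items = list(pools)
        ids = [i for i, _ in items]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate node ids in pools")
        pools = dict(items)
    if len(pools) < 2:
        raise ConfigurationError("need at least 2 pools to build a network")
    G = nx.Graph(tau=tau)
    for node, pool in pools.items():
        G.add_node(node, pool=frozenset(pool), size=len(pool))
    for a, b in combinations(pools, 2):
        w = len(pools[a] & pools[b])
        if w > 0:
            G.add_edge(a, b, weight=w)
    return G


def _adjacency(G: nx.Graph) -> tuple[np.ndarray, list]:
    nodes = list(G.nodes)
    A = nx.to_numpy_array(G, nodelist=nodes, weight="weight")
    return A, nodes


def rb_hamiltonian(A: np.ndarray, labels, gamma: float = 1.0) -> float:
    """Reichardt-Bornholdt energy of a partition under the configuration null."""
    A = np.asarray(A, dtype=float)
    labels = np.asarray(labels)
    k = A.sum(axis=1)
    two_m = A.sum()
    if two_m == 0:
        raise ConfigurationError("empty network")
    same = labels[:, None] == labels[None, :]
    B = A - gamma * np.outer(k, k) / two_m
    return float(-np.sum(np.triu(B * same, 1)))


def _partitions(n: int):
    """All set partitions of range(n) as canonical label arrays."""
    labels = np.zeros(n, dtype=int)

    def rec(i: int, n_used: int):
        if i == n:
            yield labels.copy()
            return
        for lab in range(n_used + 1):
            labels[i] = lab
            yield from rec(i + 1, max(n_used, lab + 1))

    yield from rec(1, 1)


def exhaustive_min_hamiltonian(A: np.ndarray, gamma: float = 1.0) -> tuple[float, np.ndarray]:
    """Global minimum of the spinglass energy by enumerating all partitions.

    Only feasible for small graphs (n <= 12); used as the ground-truth
    reference for the annealed optimizer.
    """
    n = A.shape[0]
    if n > 12:
        raise ConfigurationError("exhaustive search limited to n <= 12")
    best_h, best_p = np.inf, None
    for labels in _partitions(n):
        h = rb_hamiltonian(A, labels, gamma)
        if h < best_h:
            best_h, best_p = h, labels
    return best_h, best_p


def _canonical(labels) -> tuple:
    """Relabel communities by order of first appearance (permutation-invariant)."""
    seen: dict = {}
    out = []
    for lab in labels:
        if lab not in seen:
            seen[lab] = len(seen)
        out.append(seen[lab])
    return tuple(out)


@dataclass
class ConsensusPartition:
    """Consensus over repeated spinglass runs on the largest component."""

    nodes: list
    modal_labels: tuple
    modal_count: int
    frequencies: dict  # canonical labels -> fraction of runs
    n_runs: int
    isolates: list
    gamma: float

    @property
    def modal_frequency(self) -> float:
        return self.frequencies[self.modal_labels]

    def recurrent_partitions(self, min_freq: float = 0.01) -> dict:
        """Partitions seen in more than ``min_freq`` of the runs."""
        return {p: f for p, f in self.frequencies.items() if f > min_freq}

    def communities(self) -> list[set]:
        out: dict[int, set] = {}
        for node, lab in zip(self.nodes, self.modal_labels):
            out.setdefault(lab, set()).add(node)
        return [out[k] for k in sorted(out)]


def _anneal_once(
    B: np.ndarray,
    q: int,
    rng: np.random.Generator,
    cool_fact: float,
    max_sweeps: int,
    accept_target: float,
) -> tuple[np.ndarray, float]:
    """One simulated-annealing attempt on the modularity matrix ``B`` (zero diag).

    Metropolis single-spin moves in random order; the start temperature is
    calibrated from the typical move cost so that about ``accept_target`` of
    early proposals accept, then cooled geometrically per sweep.  A greedy
    quench finishes the attempt, alternating single-spin descent with
    community merges (a community split in two is a single-move trap that
    merges repair), so the result is always a local optimum of H.
    Returns (labels, H).
    """
    n = B.shape[0]
    labels = rng.integers(0, q, size=n)
    # S[i, c] = sum_j B_ij [sigma_j = c]; move gains read off in O(1)
    S = np.zeros((n, q))
    for c in range(q):
        S[:, c] = B[:, labels == c].sum(axis=1)

    def move(i: int, c_new: int) -> None:
        c_old = labels[i]
        S[:, c_old] -= B[:, i]
        S[:, c_new] += B[:, i]
        labels[i] = c_new

    typical = max(float(np.abs(S).mean()), 1e-12)
    T = typical / -np.log(accept_target)

    for _ in range(max_sweeps):
        accepted = 0
        order = rng.permutation(n)
        proposals = rng.integers(0, q, size=n)
        accept_u = rng.random(n)
        for t in range(n):
            i = order[t]
            c_new = proposals[t]
            c_old = labels[i]
            if c_new == c_old:
                continue
            dH = S[i, c_old] - S[i, c_new]
            if dH <= 0 or accept_u[t] < np.exp(-dH / T):
                move(i, c_new)
                accepted += 1
        T *= cool_fact
        if accepted == 0 and T < 1e-3 * typical:
            break

    while True:
        improved = True
        while improved:
            improved = False
            for i in range(n):
                c_best = int(np.argmax(S[i]))
                if S[i, c_best] > S[i, labels[i]] + 1e-12:
                    move(i, c_best)
                    improved = True
        present = np.unique(labels)
        merge_gain, merge_pair = 0.0, None
        for a_i, a in enumerate(present):
            in_a = labels == a
            for b in present[a_i + 1 :]:
                gain = float(S[in_a, b].sum())
                if gain > merge_gain + 1e-12:
                    merge_gain, merge_pair = gain, (a, b)
        if merge_pair is None:
            break
        a, b = merge_pair
        for i in np.where(labels == b)[0]:
            move(int(i), a)
    H = -0.5 * float(sum(S[i, labels[i]] for i in range(n)))
    return labels, H


def spinglass_communities(
    G: nx.Graph,
    gamma: float = 1.0,
    n_runs: int = 1000,
    seed: int | None = None,
    spins: int | None = None,
    cool_fact: float = 0.99,
    max_sweeps: int = 1000,
    accept_target: float = 0.8,
    restarts: int = 8,
) -> ConsensusPartition:
    """Repeat the annealed spinglass optimization and keep the modal partition.

    Runs on the largest connected component (isolated/minor-component nodes
    are reported separately, not clustered).  Each of the ``n_runs``
    independent runs takes the lowest-energy result of ``restarts`` annealing
    attempts (single-attempt anneals occasionally settle in a local optimum a
    two-node barrier away from the minimum); spins are initialized uniformly
    over ``spins`` states (default min(n, 25)).  Partitions are canonicalized
    up to relabeling and their frequencies over all runs recorded.
    """
    if G.number_of_nodes() == 0 or G.number_of_edges() == 0:
        raise ConfigurationError("empty network")
    components = sorted(nx.connected_components(G), key=len, reverse=True)
    main = list(components[0])
    isolates = [n for comp in components[1:] for n in comp]
    sub = G.subgraph(main)
    nodes = list(sub.nodes)
    A = nx.to_numpy_array(sub, nodelist=nodes, weight="weight")
    k = A.sum(axis=1)
    two_m = A.sum()
    B = A - gamma * np.outer(k, k) / two_m
    np.fill_diagonal(B, 0.0)
    q = spins if spins is not None else min(len(nodes), 25)

    rng = np.random.default_rng(seed)
    counts: dict[tuple, int] = {}
    for _ in range(n_runs):
        best_labels, best_h = None, np.inf
        for _ in range(max(restarts, 1)):
            labels, h = _anneal_once(B, q, rng, cool_fact, max_sweeps, accept_target)
            if h < best_h:
                best_labels, best_h = labels, h
        can = _canonical(best_labels)
        counts[can] = counts.get(can, 0) + 1
    freqs = {p: c / n_runs for p, c in counts.items()}
    modal = max(counts, key=lambda p: counts[p])
    return ConsensusPartition(
        nodes=nodes,
        modal_labels=modal,
        modal_count=counts[modal],
        frequencies=freqs,
        n_runs=n_runs,
        isolates=isolates,
        gamma=gamma,
    )


def network_summary(
    pools: dict,
    month_otus: dict,
    global_pool: set,
) -> dict:
    """Bookkeeping fractions describing how exclusive the pools are.

    ``pools``: (month, label) -> representative OTU set;
    ``month_otus``: month -> set of OTUs detected that month;
    ``global_pool``: all OTUs over the study.
    Returns percentages: per-cluster representative fraction (pool size over
    the month's detected OTUs), per-cluster shared fraction (pool members
    found in at least one other pool), per-month detected fraction of the
    global pool, and per-month fraction of detected OTUs shared with other
    months.
    """
    rep_frac, shared_frac = {}, {}
    for key, pool in pools.items():
        month = key[0] if isinstance(key, tuple) else key
        denom = len(month_otus.get(month, [])) or 1
        rep_frac[key] = 100.0 * len(pool) / denom
        others = set().union(*(p for k2, p in pools.items() if k2 != key)) if len(pools) > 1 else set()
        shared_frac[key] = 100.0 * len(pool & others) / len(pool) if pool else 0.0
    month_present, month_shared = {}, {}
    for month, present in month_otus.items():
        month_present[month] = 100.0 * len(present) / len(global_pool) if global_pool else 0.0
        others = set().union(*(p for m2, p in month_otus.items() if m2 != month)) if len(month_otus) > 1 else set()
        month_shared[month] = 100.0 * len(present & others) / len(present) if present else 0.0
    return {
        "representative_pct_per_cluster": rep_frac,
        "shared_pct_per_cluster": shared_frac,
        "present_pct_per_month": month_present,
        "shared_pct_per_month": month_shared,
    }
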