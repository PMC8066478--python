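"""Prototype-based fuzzy c-means clustering with validity indices.

The same machinery classifies both the environmental track (SST/SSS,
z-scored) and the community matrices (OTU relative abundances, Hellinger
transformed).  Memberships ``u_ik`` live in (0, 1) and sum to one over
clusters for every observation; centroids ``v_k`` are explicit prototype
vectors so that cluster composition can be read off directly.

The number of fuzzy clusters is capped at ``floor(n/2) - 1`` — with 8
stations at most 3 community clusters can be fitted.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ClusterCountError, ConfigurationError

__all__ = [
    "FeatureMatrix",
    "FuzzyPartition",
    "PartitionValidity",
    "max_clusters",
    "preprocess",
    "inverse_transform",
    "fit_fcm",
    "validity_indices",
    "select_k",
]


@dataclass
class FeatureMatrix:
    """Observations x variables plus along-transect positions (km).

    ``transform`` records how ``values`` were derived from raw data so that
    centroids can be mapped back to natural units (degC, PSU, abundance %).
    """

    values: np.ndarray
    positions: np.ndarray
    var_names: list[str]
    transform: dict | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.values.ndim != 2:
            raise ConfigurationError("feature matrix must be 2-D")
        n = self.values.shape[0]
        if n < 4:
            raise ConfigurationError("need at least 4 observations")
        if self.positions.shape != (n,):
            raise ConfigurationError("positions must have one entry per observation")
        if np.any(np.diff(self.positions) <= 0):
            raise ConfigurationError("positions must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("feature matrix contains missing/non-finite values")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass
class FuzzyPartition:
    """Result of a fuzzy c-means fit.

    U : (n, k) membership matrix, rows sum to 1.
    V : (k, p) centroids in the (possibly transformed) feature space.
    """

    U: np.ndarray
    V: np.ndarray
    m: float
    objective: float
    converged: bool
    n_iter: int
    positions: np.ndarray | None = None
    transform: dict | None = None
    objective_history: list[float] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.U.shape[0]

    @property
    def k(self) -> int:
        return self.U.shape[1]

    def hard_labels(self) -> np.ndarray:
        return np.argmax(self.U, axis=1)


@dataclass
class PartitionValidity:
    """Bezdek partition coefficient / entropy, raw and normalized."""

    k: int
    PC: float
    PC_norm: float
    PE: float
    PE_norm: float

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def max_clusters(n: int) -> int:
    """Largest permitted cluster count: floor(n/2) - 1."""
    return n // 2 - 1


# ---------------------------------------------------------------------------
# preprocessing


def preprocess(fm: FeatureMatrix, mode: str = "none") -> FeatureMatrix:
    """Transform features for Euclidean FCM; parameters kept for inversion.

    ``env_zscore``  : per-variable standardization (temperature/salinity).
    ``hellinger``   : sqrt of row proportions, the standard transform that
                      makes Euclidean distance ecologically defensible for
                      community data.
    ``none``        : identity.
    """
    X = fm.values
    if mode == "none":
        transform = {"mode": "none"}
        Xt = X.copy()
    elif mode == "env_zscore":
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        if np.any(sd == 0):
            bad = [fm.var_names[i] for i in np.where(sd == 0)[0]]
            raise ConfigurationError(f"zero-variance variable(s) under env_zscore: {bad}")
        Xt = (X - mean) / sd
        transform = {"mode": "env_zscore", "mean": mean, "sd": sd}
    elif mode == "hellinger":
        if np.any(X < 0):
            raise ConfigurationError("hellinger requires non-negative abundances")
        row_sums = X.sum(axis=1)
        if np.any(row_sums <= 0):
            raise ConfigurationError("hellinger requires positive row sums")
        Xt = np.sqrt(X / row_sums[:, None])
        transform = {"mode": "hellinger", "row_total": 100.0}
    else:
        raise ConfigurationError(f"unknown preprocessing mode: {mode!r}")
    return FeatureMatrix(Xt, fm.positions.copy(), list(fm.var_names), transform)


def inverse_transform(V: np.ndarray, transform: dict | None) -> np.ndarray:
    """Map centroids from transformed space back to natural units.

    Hellinger inversion squares the centroid and renormalizes each row to the
    recorded total (100 for relative-abundance %): FCM centroids in
    sqrt-proportion space do not lie exactly on the unit sphere.
    """
    V = np.asarray(V, dtype=float)
    if transform is None or transform["mode"] == "none":
        return V.copy()
    if transform["mode"] == "env_zscore":
        return V * transform["sd"] + transform["mean"]
    if transform["mode"] == "hellinger":
        sq = V**2
        totals = sq.sum(axis=-1, keepdims=True)
        return transform["row_total"] * sq / totals
    raise ConfigurationError(f"unknown transform: {transform['mode']!r}")


# ---------------------------------------------------------------------------
# core fit


def _memberships_from_distances(d2: np.ndarray, m: float) -> np.ndarray:
    """u_ik = 1 / sum_j (d_ik/d_ij)^(2/(m-1)), with the singleton rule at d=0.

    When an observation coincides with one or more centroids, its membership
    mass (1) is split equally among the coincident centroids.
    """
    n, k = d2.shape
    U = np.zeros((n, k))
    zero = d2 <= 0.0
    any_zero = zero.any(axis=1)
    if any_zero.any():
        rows = np.where(any_zero)[0]
        U[rows] = zero[rows] / zero[rows].sum(axis=1, keepdims=True)
    ok = ~any_zero
    if ok.any():
        w = d2[ok] ** (-1.0 / (m - 1.0))
        U[ok] = w / w.sum(axis=1, keepdims=True)
    return U


def _centroids(X: np.ndarray, U: np.ndarray, m: float) -> np.ndarray:
    W = U**m
    return (W.T @ X) / W.sum(axis=0)[:, None]


def _objective(d2: np.ndarray, U: np.ndarray, m: float) -> float:
    return float(np.sum((U**m) * d2))


def fit_fcm(
    fm: FeatureMatrix | np.ndarray,
    k: int,
    m: float = 2.0,
    tol: float = 1e-8,
    max_iter: int = 500,
    n_starts: int = 20,
    seed: int | np.random.Generator | None = None,
    enforce_limit: bool = True,
) -> FuzzyPartition:
    """Fit fuzzy c-means by alternating optimization, best of ``n_starts``.

    Each start draws the initial membership matrix from a flat Dirichlet and
    alternates the centroid update v_k = sum_i u_ik^m x_i / sum_i u_ik^m with
    the membership update until the memberships move by less than ``tol``
    (max-abs).  The objective J = sum_ik u_ik^m d_ik^2 is non-increasing along
    the iterations; the start with the lowest final J is returned.
    """
    if isinstance(fm, FeatureMatrix):
        X, positions, transform = fm.values, fm.positions, fm.transform
    else:
        X = np.asarray(fm, dtype=float)
        positions, transform = None, None
    n = X.shape[0]
    if m <= 1:
        raise ConfigurationError("fuzziness exponent m must be > 1")
    kmax = max_clusters(n)
    if enforce_limit and not (2 <= k <= kmax):
        raise ClusterCountError(
            f"k={k} not allowed for n={n}: the number of fuzzy clusters cannot "
            f"exceed n/2 - 1 = {kmax} (and must be >= 2)"
        )
    if k < 1 or k > n:
        raise ConfigurationError(f"k={k} out of range for n={n}")

    rng = np.random.default_rng(seed)
    best: FuzzyPartition | None = None
    for _ in range(n_starts):
        U = rng.dirichlet(np.ones(k), size=n)
        converged = False
        it = 0
        history: list[float] = []
        for it in range(1, max_iter + 1):
            V = _centroids(X, U, m)
            d2 = cdist(X, V, "sqeuclidean")
            U_new = _memberships_from_distances(d2, m)
            history.append(_objective(d2, U_new, m))
            delta = np.max(np.abs(U_new - U))
            U = U_new
            if delta < tol:
                converged = True
                break
        V = _centroids(X, U, m)
        d2 = cdist(X, V, "sqeuclidean")
        J = _objective(d2, U, m)
        if best is None or J < best.objective:
            best = FuzzyPartition(U, V, m, J, converged, it, positions, transform, history)
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# validity indices and k selection


def validity_indices(U: np.ndarray, k: int | None = None) -> PartitionValidity:
    """Partition coefficient / entropy of a row-stochastic membership matrix.

    PC = (1/n) sum u^2, normalized to [0,1] as (PC - 1/k)/(1 - 1/k);
    PE = -(1/n) sum u ln u (with 0 ln 0 := 0), normalized by ln k.
    """
    U = np.asarray(U, dtype=float)
    n, kk = U.shape
    k = kk if k is None else k
    if not np.allclose(U.sum(axis=1), 1.0, atol=1e-6):
        raise ConfigurationError("membership matrix rows must sum to 1")
    PC = float(np.sum(U**2) / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        logU = np.where(U > 0, np.log(np.where(U > 0, U, 1.0)), 0.0)
    PE = float(-np.sum(U * logU) / n)
    if k <= 1:
        return PartitionValidity(k, PC, 1.0, PE, 0.0)
    PC_norm = (PC - 1.0 / k) / (1.0 - 1.0 / k)
    PE_norm = PE / math.log(k)
    return PartitionValidity(k, PC, PC_norm, PE, PE_norm)


def select_k(
    fm: FeatureMatrix | np.ndarray,
    k_range,
    m: float = 2.0,
    seed: int | np.random.Generator | None = None,
    n_starts: int = 20,
    **fit_kwargs,
) -> tuple[int, list[PartitionValidity], dict[int, FuzzyPartition]]:
    """Pick the cluster count maximizing the normalized partition coefficient.

    Candidate k beyond the floor(n/2)-1 limit are silently dropped; ties are
    broken toward the smaller k.  The full validity table and the fitted
    partitions are returned so the choice is auditable.
    """
    X = fm.values if isinstance(fm, FeatureMatrix) else np.asarray(fm)
    n = X.shape[0]
    kmax = max_clusters(n)
    feasible = sorted({int(k) for k in k_range if 2 <= k <= kmax})
    if not feasible:
        raise ClusterCountError(
            f"no feasible k in {sorted(set(int(k) for k in k_range))}: "
            f"the number of fuzzy clusters cannot exceed n/2 - 1 = {kmax}"
        )
    rng = np.random.default_rng(seed)
    table: list[PartitionValidity] = []
    partitions: dict[int, FuzzyPartition] = {}
    for k in feasible:
        part = fit_fcm(fm, k, m=m, seed=rng, n_starts=n_starts, **fit_kwargs)
        partitions[k] = part
        table.append(validity_indices(part.U))
    # ties toward smaller k: strict improvement required to switch
    best_k = table[0].k
    best_pc = table[0].PC_norm
    for v in table[1:]:
        if v.PC_norm > best_pc + 1e-12:
            best_k, best_pc = v.k, v.PC_norm
    return best_k, table, partitions
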