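"""Synthetic coastal-to-offshore transects with known ground truth.

The generator emulates a ~65 km surface transect crossing four water masses
(neritic NW, subtropical STW, the subtropical front FRONT, and sub-Antarctic
SAW).  Each water mass has a characteristic sea-surface temperature and
salinity; between masses the environment blends through logistic edges of
configurable midpoint and scale, so the true boundary locations, maximum
slopes (1/(4s) per unit mixing weight) and transition widths are known in
closed form.  Microbial communities follow the environment: each mass has a
set of specialist OTUs whose expected abundance tracks that mass's mixing
weight, a shared pool of ubiquitous OTUs is present everywhere, and a large
pool of rare OTUs appears sporadically (mostly within a single "home" month).
Sequencing is simulated per station as a multinomial draw, then rarefied a
configurable number of times to a fixed depth; replicate rarefactions are
averaged, rounded (half-to-even) and converted to relative abundance (%).

Default parameter values mirror the study conditions the pipeline is meant
to exercise: 8 stations x 6 months, boundaries near 14 / 29.5 / 46.5 km with
+-5 km monthly jitter, the mid-transect transition (STW|FRONT) about twice as
steep and narrow as the offshore one (FRONT|SAW), 10 rarefactions at depth
10,000, and an OTU pool sized so each month detects roughly 41% of it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigurationError

__all__ = [
    "WaterMassSpec",
    "TransectScenario",
    "SyntheticTruth",
    "default_masses",
    "default_scenario",
    "mixing_weights",
    "generate_env_track",
    "generate_community",
    "generate_dataset",
]

MONTHS = ("Jan", "Mar", "Apr", "Jun", "Jul", "Dec")


@dataclass
class WaterMassSpec:
    """One water mass: T/S signature, spatial extent and edge sharpness.

    ``bounds`` are the (left, right) edge midpoints in km; the outermost
    edges of the first/last mass are open (use -inf / +inf).
    ``scales`` are the logistic scales s (km) of the left and right edges.
    """

    label: str
    center_sst: float
    center_sss: float
    bounds: tuple[float, float]
    scales: tuple[float, float]
    specialist_otu_count: int = 30

    def __post_init__(self):
        if self.bounds[0] >= self.bounds[1]:
            raise ConfigurationError(f"{self.label}: bounds must be increasing")
        for s in self.scales:
            if np.isfinite(s) and s <= 0:
                raise ConfigurationError(f"{self.label}: transition scale must be > 0")


def default_masses(
    boundaries: tuple[float, float, float] = (14.0, 29.5, 46.5),
    scales: tuple[float, float, float] = (1.4, 1.2, 2.4),
    length_km: float = 65.0,
) -> list[WaterMassSpec]:
    """Four-mass scenario anchored on observed surface T/S signatures.

    NW 13.15 degC / 34.32 PSU, STW 12.32 / 34.67, FRONT 11.30 / 34.42,
    SAW 10.78 / 34.31.  The STW|FRONT edge (scale 1.2 km) is twice as sharp
    as the FRONT|SAW edge (2.4 km); NW|STW sits in between (1.4 km).
    """
    b1, b2, b3 = boundaries
    s1, s2, s3 = scales
    inf = float("inf")
    return [
        WaterMassSpec("NW", 13.15, 34.32, (-inf, b1), (inf, s1)),
        WaterMassSpec("STW", 12.32, 34.67, (b1, b2), (s1, s2)),
        WaterMassSpec("FRONT", 11.30, 34.42, (b2, b3), (s2, s3)),
        WaterMassSpec("SAW", 10.78, 34.31, (b3, length_km + 1e3), (s3, inf)),
    ]


def _validate_masses(masses: list[WaterMassSpec]) -> None:
    labels = [m.label for m in masses]
    if len(set(labels)) != len(labels):
        raise ConfigurationError("water mass labels must be unique")
    for a, b in zip(masses, masses[1:]):
        if not np.isclose(a.bounds[1], b.bounds[0]):
            raise ConfigurationError(
                f"masses {a.label}/{b.label} must share their common boundary"
            )
        if a.bounds[1] <= a.bounds[0] or b.bounds[0] >= b.bounds[1]:
            raise ConfigurationError("boundaries must be strictly increasing")
    mids = [a.bounds[1] for a in masses[:-1]]
    if any(x >= y for x, y in zip(mids, mids[1:])):
        raise ConfigurationError("boundaries must be strictly increasing")


def mixing_weights(x, masses: list[WaterMassSpec]) -> np.ndarray:
    """Water-mass mixing weights at positions ``x``; rows sum to 1.

    Each mass contributes the product of a rising logistic at its left edge
    and a falling logistic at its right edge; weights are renormalized so
    that exactly at an isolated boundary midpoint the two adjacent masses
    each weigh 0.5.
    """
    _validate_masses(masses)
    x = np.atleast_1d(np.asarray(x, dtype=float))
    W = np.empty((x.size, len(masses)))
    for j, mass in enumerate(masses):
        (left, right), (sl, sr) = mass.bounds, mass.scales
        wl = np.ones_like(x) if not np.isfinite(sl) else expit((x - left) / sl)
        wr = np.ones_like(x) if not np.isfinite(sr) else expit((right - x) / sr)
        W[:, j] = wl * wr
    return W / W.sum(axis=1, keepdims=True)


def generate_env_track(
    masses: list[WaterMassSpec],
    grid_step: float = 0.25,
    length_km: float = 65.0,
    noise_sst: float = 0.15,
    noise_sss: float = 0.02,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Dense SST/SSS track for one month: mixing-weighted mass signatures plus noise."""
    if noise_sst < 0 or noise_sss < 0:
        raise ConfigurationError("noise SDs must be >= 0")
    rng = np.random.default_rng(seed)
    x = np.arange(0.0, length_km + grid_step / 2, grid_step)
    W = mixing_weights(x, masses)
    sst = W @ np.array([m.center_sst for m in masses])
    sss = W @ np.array([m.center_sss for m in masses])
    sst = sst + rng.normal(0.0, noise_sst, x.size)
    sss = sss + rng.normal(0.0, noise_sss, x.size)
    return pd.DataFrame({"distance_km": x, "sst_c": sst, "sss_psu": sss})


# ---------------------------------------------------------------------------
# community generation


@dataclass
class SyntheticTruth:
    """Ground truth of one generated dataset, for recovery checks."""

    boundaries: dict  # month -> list of {pair, midpoint_km, scale_km}
    specialists: dict  # otu_id -> water-mass label
    ubiquitous: list
    rare: dict  # otu_id -> home month
    mass_order: list

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class TransectScenario:
    """Full multi-month study design; defaults are the reference conditions."""

    boundaries: tuple = (14.0, 29.5, 46.5)
    scales: tuple = (1.4, 1.2, 2.4)
    length_km: float = 65.0
    grid_step: float = 0.25
    noise_sst: float = 0.15
    noise_sss: float = 0.02
    months: tuple = MONTHS
    boundary_jitter_km: float = 5.0
    stations: tuple = tuple(float(x) for x in np.linspace(1.0, 64.0, 8))
    total_otus: int = 600
    # NW, STW, FRONT, SAW; the front is a mixing zone and carries fewer
    # unique taxa, so its community can merge with a bordering one
    specialist_counts: tuple = (30, 30, 12, 30)
    ubiquitous_otus: int = 60
    depth: int = 10_000
    n_rarefactions: int = 10
    library_size_range: tuple = (15_000, 30_000)
    # abundance model (log-normal parameters, arbitrary intensity units)
    specialist_lognorm: tuple = (0.0, 1.0)
    ubiquitous_lognorm: tuple = (-0.2, 1.0)
    rare_intensity: float = 0.35
    rare_stations_per_occurrence: tuple = (1, 3)
    rare_leak_prob: float = 0.02  # chance a rare OTU also shows outside its home month

    def __post_init__(self):
        n_assigned = sum(self.specialist_counts) + self.ubiquitous_otus
        if n_assigned > self.total_otus:
            raise ConfigurationError("specialist + ubiquitous counts exceed total_otus")
        if self.depth <= 0:
            raise ConfigurationError("rarefaction depth must be > 0")
        if len(self.stations) == 0:
            raise ConfigurationError("stations must be non-empty")
        st = np.asarray(self.stations, float)
        if st.min() < 0 or st.max() > self.length_km:
            raise ConfigurationError("stations must lie within the transect")

    def masses(self, boundaries=None) -> list[WaterMassSpec]:
        return default_masses(
            tuple(boundaries) if boundaries is not None else self.boundaries,
            self.scales,
            self.length_km,
        )

    def jittered_boundaries(self, rng: np.random.Generator) -> np.ndarray:
        """Monthly boundary midpoints: base positions + seeded uniform +-jitter."""
        for _ in range(100):
            b = np.asarray(self.boundaries) + rng.uniform(
                -self.boundary_jitter_km, self.boundary_jitter_km, 3
            )
            if np.all(np.diff(b) > 2.0) and b[0] > 2.0 and b[-1] < self.length_km - 2.0:
                return b
        raise ConfigurationError("could not draw valid jittered boundaries")


def _otu_pool(scenario: TransectScenario, rng: np.random.Generator):
    """Assign every OTU to exactly one category and draw its base intensity."""
    labels = ["NW", "STW", "FRONT", "SAW"]
    otu_ids, specialists, ubiquitous, rare = [], {}, [], {}
    mu_s, sd_s = scenario.specialist_lognorm
    mu_u, sd_u = scenario.ubiquitous_lognorm
    intensity = {}
    i = 0
    for lab, count in zip(labels, scenario.specialist_counts):
        for _ in range(count):
            oid = f"OTU_{i:04d}"
            specialists[oid] = lab
            intensity[oid] = float(rng.lognormal(mu_s, sd_s))
            otu_ids.append(oid)
            i += 1
    for _ in range(scenario.ubiquitous_otus):
        oid = f"OTU_{i:04d}"
        ubiquitous.append(oid)
        intensity[oid] = float(rng.lognormal(mu_u, sd_u))
        otu_ids.append(oid)
        i += 1
    n_rare = scenario.total_otus - i
    months = list(scenario.months)
    for j in range(n_rare):
        oid = f"OTU_{i:04d}"
        rare[oid] = months[j % len(months)]
        intensity[oid] = scenario.rare_intensity
        otu_ids.append(oid)
        i += 1
    return otu_ids, specialists, ubiquitous, rare, intensity


def _expected_intensities(
    scenario: TransectScenario,
    masses: list[WaterMassSpec],
    month: str,
    otu_ids,
    specialists,
    ubiquitous,
    rare,
    intensity,
    rng: np.random.Generator,
) -> np.ndarray:
    """Expected (unnormalized) abundance of every OTU at every station."""
    stations = np.asarray(scenario.stations, float)
    W = mixing_weights(stations, masses)  # (n_st, 4)
    col = {m.label: j for j, m in enumerate(masses)}
    A = np.zeros((stations.size, len(otu_ids)))
    for o, oid in enumerate(otu_ids):
        if oid in specialists:
            A[:, o] = W[:, col[specialists[oid]]] * intensity[oid]
        elif oid in rare:
            home = rare[oid]
            present = home == month or rng.random() < scenario.rare_leak_prob
            if present:
                lo, hi = scenario.rare_stations_per_occurrence
                n_at = int(rng.integers(lo, hi + 1))
                at = rng.choice(stations.size, size=min(n_at, stations.size), replace=False)
                A[at, o] = intensity[oid]
        else:
            A[:, o] = intensity[oid]
    return A


def _rarefy_mean(counts: np.ndarray, depth: int, n_rar: int, rng: np.random.Generator) -> np.ndarray:
    """Average of ``n_rar`` subsamples of ``counts`` without replacement at ``depth``."""
    total = int(counts.sum())
    if total <= depth:
        return counts.astype(float)
    acc = np.zeros_like(counts, dtype=float)
    for _ in range(n_rar):
        acc += rng.multivariate_hypergeometric(counts, depth, method="marginals")
    return acc / n_rar


def generate_community(
    scenario: TransectScenario,
    masses: list[WaterMassSpec],
    month: str,
    pool,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Stations x OTUs relative-abundance matrix (%) for one month.

    Sequencing is a multinomial draw per station at a library size drawn
    uniformly from ``library_size_range``; reads are rarefied
    ``n_rarefactions`` times to ``depth``, averaged, rounded half-to-even
    and converted to percentages (rows sum to 100 up to rounding slack).
    """
    rng = np.random.default_rng(seed)
    otu_ids, specialists, ubiquitous, rare, intensity = pool
    A = _expected_intensities(
        scenario, masses, month, otu_ids, specialists, ubiquitous, rare, intensity, rng
    )
    stations = np.asarray(scenario.stations, float)
    rel = np.zeros_like(A)
    lo, hi = scenario.library_size_range
    for s in range(stations.size):
        probs = A[s] / A[s].sum()
        libsize = int(rng.integers(lo, hi + 1))
        counts = rng.multinomial(libsize, probs)
        avg = _rarefy_mean(counts, scenario.depth, scenario.n_rarefactions, rng)
        rounded = np.round(avg)  # numpy rounds half-to-even
        rel[s] = 100.0 * rounded / rounded.sum()
    df = pd.DataFrame(rel, columns=otu_ids)
    df.insert(0, "distance_km", stations)
    df.insert(0, "month", month)
    return df


def generate_dataset(
    scenario: TransectScenario | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], SyntheticTruth]:
    """Generate the full multi-month dataset.

    Returns the environmental track (all months stacked), a month -> community
    matrix mapping, and the ground truth (per-month boundaries + OTU map).
    Deterministic given the seed.
    """
    scenario = scenario or TransectScenario()
    rng = np.random.default_rng(seed)
    pool = _otu_pool(scenario, rng)
    otu_ids, specialists, ubiquitous, rare, _ = pool
    env_frames = []
    communities: dict[str, pd.DataFrame] = {}
    boundaries: dict[str, list] = {}
    pair_names = ["NW|STW", "STW|FRONT", "FRONT|SAW"]
    for month in scenario.months:
        b = scenario.jittered_boundaries(rng)
        masses = scenario.masses(b)
        boundaries[month] = [
            {"pair": pair_names[i], "midpoint_km": float(b[i]), "scale_km": float(scenario.scales[i])}
            for i in range(3)
        ]
        env = generate_env_track(
            masses,
            grid_step=scenario.grid_step,
            length_km=scenario.length_km,
            noise_sst=scenario.noise_sst,
            noise_sss=scenario.noise_sss,
            seed=rng,
        )
        env.insert(0, "month", month)
        env_frames.append(env)
        communities[month] = generate_community(scenario, masses, month, pool, seed=rng)
    truth = SyntheticTruth(
        boundaries=boundaries,
        specialists=specialists,
        ubiquitous=ubiquitous,
        rare=rare,
        mass_order=["NW", "STW", "FRONT", "SAW"],
    )
    return pd.concat(env_frames, ignore_index=True), communities, truth
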