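"""Recovery evaluation of the full method against synthetic ground truth.

Runs the in-memory analysis chain (environmental FCM -> membership smoothing
-> transition detection -> boundary estimation; community FCM -> water-mass
labelling) on repeatedly re-generated transects and scores the results
against the generator's truth.  Used by the validation tests and by the
reporting script; kept in the package because "does the pipeline recover a
known transect?" is itself an analysis users will want to run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import centroids as ca
from . import ecotone as ec
from . import fcm
from .synthetic import TransectScenario, generate_dataset, mixing_weights

__all__ = ["MonthResult", "RecoveryResult", "analyse_month", "evaluate_recovery"]

MASS_ORDER = ["NW", "STW", "FRONT", "SAW"]
PAIRS = ["NW|STW", "STW|FRONT", "FRONT|SAW"]


@dataclass
class MonthResult:
    """Analysis of one month: boundaries, slopes/widths, community labels."""

    month: str
    boundaries: list[dict]
    community_labels: list[list[str]]
    env_labels: list[str]
    chosen_k: int
    community_centroids: object = None  # DataFrame clusters x OTUs, natural %


@dataclass
class RecoveryResult:
    """Scores of ``n_seeds`` independent transects against their truths."""

    location_errors: dict = field(default_factory=lambda: {p: [] for p in PAIRS})
    per_run_mean_abs_err: dict = field(default_factory=lambda: {p: [] for p in PAIRS})
    slope_rank_ok: list = field(default_factory=list)
    label_hits: dict = field(default_factory=lambda: {"STW": [0, 0], "SAW": [0, 0]})
    slopes: dict = field(default_factory=lambda: {p: [] for p in PAIRS})
    widths: dict = field(default_factory=lambda: {p: [] for p in PAIRS})

    def label_rate(self, mass: str) -> float:
        hit, n = self.label_hits[mass]
        return hit / n if n else float("nan")

    def mean_abs_location_error(self) -> float:
        errs = np.concatenate([np.asarray(v) for v in self.location_errors.values()])
        return float(np.nanmean(np.abs(errs)))


def analyse_month(env_month, comm_month, scenario: TransectScenario, rng,
                  n_starts: int = 8, comm_k_range=(2, 3)) -> MonthResult:
    """One month of the core chain, in memory (no file I/O)."""
    fm = fcm.FeatureMatrix(
        env_month[["sst_c", "sss_psu"]].to_numpy(),
        env_month["distance_km"].to_numpy(),
        ["sst_c", "sss_psu"],
    )
    fz = fcm.preprocess(fm, "env_zscore")
    part = fcm.fit_fcm(fz, 4, seed=rng, n_starts=n_starts)
    env_labels = ca.label_env_clusters_by_position(part, fz.positions, MASS_ORDER)
    recs = {}
    for i, lab in enumerate(env_labels):
        prof = ec.smooth_profile(fz.positions, np.clip(part.U[:, i], 0, 1))
        recs[lab] = ec.detect_transitions(prof)
    bounds = ec.boundaries_from_records(recs, MASS_ORDER)

    otus = [c for c in comm_month.columns if c not in ("month", "distance_km")]
    stations = comm_month["distance_km"].to_numpy()
    fh = fcm.preprocess(fcm.FeatureMatrix(comm_month[otus].to_numpy(), stations, otus), "hellinger")
    k, _, parts = fcm.select_k(fh, comm_k_range, seed=rng, n_starts=n_starts)
    U_env_st = np.column_stack(
        [np.interp(stations, fz.positions, part.U[:, i]) for i in range(part.k)]
    )
    labels = ca.label_community_clusters(parts[k].U, U_env_st, env_labels)
    cent = pd.DataFrame(
        fcm.inverse_transform(parts[k].V, fh.transform),
        index=[f"C{i}" for i in range(k)],
        columns=otus,
    )
    return MonthResult(
        str(env_month["month"].iloc[0]), bounds, labels, env_labels, k, cent
    )


def evaluate_recovery(
    scenario: TransectScenario | None = None,
    n_seeds: int = 50,
    seed: int = 0,
    n_starts: int = 8,
) -> RecoveryResult:
    """Score boundary recovery, slope ranking and labelling over many transects.

    Water-mass labelling is scored only for months where the mass actually
    dominates at least two stations: with +-5 km boundary jitter a mass can
    shrink to a single station, in which case no distinct community cluster
    for it exists and the correct output genuinely omits the label.
    """
    scenario = scenario or TransectScenario()
    out = RecoveryResult()
    base = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_seeds)
    for run, run_seed in enumerate(base):
        env, comms, truth = generate_dataset(scenario, seed=int(run_seed))
        rng = np.random.default_rng([int(run_seed), 1])
        run_errs: dict[str, list] = {p: [] for p in PAIRS}
        run_slopes: dict[str, list] = {p: [] for p in PAIRS}
        for month, sub in env.groupby("month", sort=False):
            res = analyse_month(sub, comms[month], scenario, rng, n_starts=n_starts)
            tb = {d["pair"]: d["midpoint_km"] for d in truth.boundaries[month]}
            for b in res.boundaries:
                err = b["location_km"] - tb[b["pair"]]
                out.location_errors[b["pair"]].append(err)
                run_errs[b["pair"]].append(err)
                run_slopes[b["pair"]].append(b["slope_per_km"])
                out.slopes[b["pair"]].append(b["slope_per_km"])
                out.widths[b["pair"]].append(b["transition_width_km"])
            flat = {l for ls in res.community_labels for l in ls}
            b_mid = [d["midpoint_km"] for d in truth.boundaries[month]]
            stations = comms[month]["distance_km"].to_numpy()
            W = mixing_weights(stations, scenario.masses(b_mid))
            dom = np.array(MASS_ORDER)[W.argmax(axis=1)]
            for m in ("STW", "SAW"):
                if (dom == m).sum() >= 2:
                    out.label_hits[m][1] += 1
                    out.label_hits[m][0] += int(m in flat)
        for p in PAIRS:
            out.per_run_mean_abs_err[p].append(abs(float(np.nanmean(run_errs[p]))))
        med = {p: np.nanmedian(run_slopes[p]) for p in PAIRS}
        out.slope_rank_ok.append(
            med["STW|FRONT"] > med["FRONT|SAW"] and med["NW|STW"] > med["FRONT|SAW"]
        )
    return out
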