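"""End-to-end orchestration: simulate -> cluster -> ecotones -> centroids ->
network -> stats, with file I/O, a serialized config and a run manifest.

Every stage reads its inputs from the run directory and writes its outputs
there, so stages can be re-run individually from the CLI; a manifest records
outputs, checksums and the seed so identical config + seed reproduce
byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx
import yaml

from . import centroids as ca
from . import ecotone as ec
from . import fcm
from . import groupstats as gs
from . import network as net
from .errors import ConfigurationError, StageError
from .synthetic import SyntheticTruth, TransectScenario, generate_dataset

__all__ = ["RunConfig", "Pipeline", "run_pipeline", "read_community_table"]

log = logging.getLogger("ecotransect")

MASS_ORDER = ["NW", "STW", "FRONT", "SAW"]
STAGES = [
    "simulate",
    "cluster_env",
    "cluster_otu",
    "ecotones",
    "centroids",
    "network",
    "stats",
]


@dataclass
class RunConfig:
    """Validated, serializable description of one pipeline run."""

    outdir: str = "ecotransect_run"
    seed: int = 0
    scenario: TransectScenario = field(default_factory=TransectScenario)
    env_track_path: str | None = None  # use real inputs instead of simulating
    community_paths: dict | None = None  # month -> TSV path
    env_k: int = 4
    comm_k_range: tuple = (2, 3)
    m: float = 2.0
    n_starts: int = 20
    grid_step: float = 0.05
    min_prominence: float = 0.05
    tau: float = 0.85
    tau_sweep: tuple = (0.75, 0.85, 0.95, 0.99)
    top_fractions: tuple = (0.25, 0.10, 0.05, 0.01)
    gamma: float = 1.0
    spinglass_runs: int = 1000
    alpha: float = 0.05

    def validate(self) -> "RunConfig":
        if self.seed < 0:
            raise ConfigurationError("seed must be >= 0")
        if not (0 < self.tau <= 1):
            raise ConfigurationError("tau must be in (0, 1]")
        if self.m <= 1:
            raise ConfigurationError("fuzziness m must be > 1")
        if self.env_k < 2:
            raise ConfigurationError("env_k must be >= 2")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        scen = TransectScenario(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in (raw.pop("scenario", {}) or {}).items()
        })
        raw = {k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()}
        return cls(scenario=scen, **raw).validate()

    def to_yaml(self, path) -> None:
        def plain(v):
            if isinstance(v, (tuple, list)):
                return [plain(x) for x in v]
            if isinstance(v, dict):
                return {k: plain(x) for k, x in v.items()}
            if isinstance(v, np.floating):
                return float(v)
            if isinstance(v, np.integer):
                return int(v)
            return v

        d = plain(dataclasses.asdict(self))
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def read_community_table(path, fmt: str = "tsv", positions=None) -> pd.DataFrame:
    """Read and validate a stations x OTUs relative-abundance table.

    Station positions (km from the coastline) must come as a
    ``distance_km`` column or through ``positions``.  Rows off 100% by more
    than 1% are renormalized with a warning; negative abundances, duplicate
    OTU ids and missing positions are typed errors.
    """
    if fmt != "tsv":
        raise ConfigurationError(f"unsupported community format: {fmt!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    dupes = {h for h in header if header.count(h) > 1}
    if dupes:
        raise ConfigurationError(f"duplicate OTU ids in {path}: {sorted(dupes)}")
    df = pd.read_csv(path, sep="\t")
    if "distance_km" in df.columns:
        pos = df.pop("distance_km").to_numpy(dtype=float)
    elif positions is not None:
        pos = np.asarray(positions, dtype=float)
    else:
        raise ConfigurationError("station positions missing (distance_km column or sidecar)")
    if "month" in df.columns:
        df = df.drop(columns="month")
    vals = df.to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ConfigurationError("negative abundance in community table")
    if len(pos) != vals.shape[0]:
        raise ConfigurationError("positions do not match number of stations")
    sums = vals.sum(axis=1)
    if np.any(np.abs(sums - 100.0) > 1.0):
        warnings.warn("community rows off 100% by >1%; renormalizing")
    vals = 100.0 * vals / sums[:, None]
    out = pd.DataFrame(vals, columns=df.columns)
    out.insert(0, "distance_km", pos)
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class Pipeline:
    """Stage runner over a run directory; see :data:`STAGES` for the order."""

    def __init__(self, config: RunConfig):
        self.config = config.validate()
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.outdir / "manifest.json"

    # -- plumbing -----------------------------------------------------------

    def _stage_seed(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([self.config.seed, STAGES.index(stage)])

    def _record(self, stage: str, outputs: list[Path], t0: float) -> None:
        manifest = {}
        if self.manifest_path.exists():
            manifest = json.loads(self.manifest_path.read_text())
        manifest.setdefault("seed", self.config.seed)
        manifest.setdefault("stages", {})
        manifest["stages"][stage] = {
            "outputs": {p.name: _sha256(p) for p in outputs},
            "wall_time_s": round(time.time() - t0, 3),
        }
        self.manifest_path.write_text(json.dumps(manifest, indent=1))
        log.info("stage %s: %d outputs in %.2fs", stage, len(outputs), time.time() - t0)

    def _months(self) -> list[str]:
        env = pd.read_csv(self.outdir / "env_track.csv")
        return list(dict.fromkeys(env["month"]))

    # -- stages -------------------------------------------------------------

    def stage_simulate(self) -> list[Path]:
        t0 = time.time()
        cfg = self.config
        if cfg.env_track_path is not None:
            env = pd.read_csv(cfg.env_track_path)
            months = list(dict.fromkeys(env["month"]))
            comms = {
                m: read_community_table(cfg.community_paths[m]) for m in months
            }
            truth = None
        else:
            rng = self._stage_seed("simulate")
            env, comms, truth = generate_dataset(cfg.scenario, seed=int(rng.integers(2**31)))
        outputs = []
        p = self.outdir / "env_track.csv"
        env.to_csv(p, index=False)
        outputs.append(p)
        for month, df in comms.items():
            p = self.outdir / f"community_{month}.tsv"
            df.to_csv(p, sep="\t", index=False)
            outputs.append(p)
        if truth is not None:
            p = self.outdir / "truth.json"
            truth.to_json(p)
            outputs.append(p)
        cfgp = self.outdir / "config.yaml"
        self.config.to_yaml(cfgp)
        outputs.append(cfgp)
        self._record("simulate", outputs, t0)
        return outputs

    def stage_cluster_env(self) -> list[Path]:
        t0 = time.time()
        cfg = self.config
        rng = self._stage_seed("cluster_env")
        env = pd.read_csv(self.outdir / "env_track.csv")
        outputs = []
        cent_rows = []
        validity = {}
        for month, sub in env.groupby("month", sort=False):
            fmat = fcm.FeatureMatrix(
                sub[["sst_c", "sss_psu"]].to_numpy(),
                sub["distance_km"].to_numpy(),
                ["sst_c", "sss_psu"],
            )
            fz = fcm.preprocess(fmat, "env_zscore")
            part = fcm.fit_fcm(
                fz, cfg.env_k, m=cfg.m, n_starts=cfg.n_starts, seed=rng
            )
            labels = ca.label_env_clusters_by_position(part, fz.positions, MASS_ORDER)
            validity[month] = fcm.validity_indices(part.U).as_dict()
            memb = pd.DataFrame(part.U, columns=labels)
            memb.insert(0, "distance_km", fz.positions)
            p = self.outdir / f"memberships_env_{month}.csv"
            memb.to_csv(p, index=False)
            outputs.append(p)
            summary = ca.env_centroid_summary(part, fz)
            summary["label"] = [labels[k] for k in summary["cluster"]]
            summary.insert(0, "month", month)
            cent_rows.append(summary)
        p = self.outdir / "centroids_env.csv"
        pd.concat(cent_rows, ignore_index=True).to_csv(p, index=False)
        outputs.append(p)
        p = self.outdir / "validity_env.json"
        p.write_text(json.dumps(validity, indent=1))
        outputs.append(p)
        self._record("cluster_env", outputs, t0)
        return outputs

    def stage_cluster_otu(self) -> list[Path]:
        t0 = time.time()
        cfg = self.config
        rng = self._stage_seed("cluster_otu")
        outputs = []
        validity = {}
        for month in self._months():
            df = read_community_table(self.outdir / f"community_{month}.tsv")
            pos = df["distance_km"].to_numpy()
            otus = [c for c in df.columns if c != "distance_km"]
            fmat = fcm.FeatureMatrix(df[otus].to_numpy(), pos, otus)
            fh = fcm.preprocess(fmat, "hellinger")
            k, table, parts = fcm.select_k(
                fh, cfg.comm_k_range, m=cfg.m, seed=rng, n_starts=cfg.n_starts
            )
            part = parts[k]
            validity[month] = {"chosen_k": k, "table": [v.as_dict() for v in table]}
            memb = pd.DataFrame(part.U, columns=[f"C{i}" for i in range(k)])
            memb.insert(0, "distance_km", pos)
            p = self.outdir / f"memberships_otu_{month}.csv"
            memb.to_csv(p, index=False)
            outputs.append(p)
            cent = pd.DataFrame(
                fcm.inverse_transform(part.V, fh.transform),
                index=[f"C{i}" for i in range(k)],
                columns=otus,
            )
            p = self.outdir / f"centroids_otu_{month}.tsv"
            cent.to_csv(p, sep="\t")
            outputs.append(p)
        p = self.outdir / "validity_otu.json"
        p.write_text(json.dumps(validity, indent=1))
        outputs.append(p)
        self._record("cluster_otu", outputs, t0)
        return outputs

    def _transitions_for(self, memb: pd.DataFrame, scope: str, month: str):
        """Smooth every cluster column and detect its transitions."""
        cfg = self.config
        pos = memb["distance_km"].to_numpy()
        records = {}
        for col in [c for c in memb.columns if c != "distance_km"]:
            prof = ec.smooth_profile(
                pos, np.clip(memb[col].to_numpy(), 0, 1), cluster_id=col,
                grid_step=cfg.grid_step,
            )
            records[col] = ec.detect_transitions(prof, cfg.min_prominence)
        rows = []
        for col, recs in records.items():
            for r in recs:
                rows.append({
                    "scope": scope, "month": month, "cluster": col,
                    "location_km": r.location, "slope_per_km": r.slope,
                    "direction": r.direction,
                    "transition_width_km": r.transition_width,
                    "patch_width_left_km": r.patch_width_left,
                    "patch_width_right_km": r.patch_width_right,
                    "prominence": r.prominence,
                })
        return records, rows

    def stage_ecotones(self) -> list[Path]:
        t0 = time.time()
        outputs = []
        all_rows, env_bounds, otu_bounds, pair_rows = [], [], [], []
        for month in self._months():
            memb_env = pd.read_csv(self.outdir / f"memberships_env_{month}.csv")
            rec_env, rows = self._transitions_for(memb_env, "env", month)
            all_rows += rows
            for b in ec.boundaries_from_records(rec_env, MASS_ORDER):
                env_bounds.append({"month": month, **b})
            memb_otu = pd.read_csv(self.outdir / f"memberships_otu_{month}.csv")
            rec_otu, rows = self._transitions_for(memb_otu, "otu", month)
            all_rows += rows
            pos = memb_otu["distance_km"].to_numpy()
            ccols = [c for c in memb_otu.columns if c != "distance_km"]
            order = sorted(
                ccols,
                key=lambda c: float(memb_otu[c] @ pos / memb_otu[c].sum()),
            )
            for b in ec.boundaries_from_records(rec_otu, order):
                otu_bounds.append({"month": month, **b})
            flat_env = [r for rs in rec_env.values() for r in rs]
            flat_otu = [r for rs in rec_otu.values() for r in rs]
            pairs, un_e, un_c = ec.pair_transitions(flat_env, flat_otu)
            for e, c, off in pairs:
                pair_rows.append({
                    "month": month, "env_cluster": e.cluster_id,
                    "otu_cluster": c.cluster_id, "env_location_km": e.location,
                    "otu_location_km": c.location, "offset_km": off,
                    "matched": True,
                })
            for r in un_e + un_c:
                pair_rows.append({
                    "month": month,
                    "env_cluster": r.cluster_id if r in un_e else "",
                    "otu_cluster": r.cluster_id if r in un_c else "",
                    "env_location_km": np.nan, "otu_location_km": np.nan,
                    "offset_km": np.nan, "matched": False,
                })
        for name, rows in [
            ("transitions.csv", all_rows),
            ("boundaries_env.csv", env_bounds),
            ("boundaries_otu.csv", otu_bounds),
            ("transition_pairs.csv", pair_rows),
        ]:
            p = self.outdir / name
            pd.DataFrame(rows).to_csv(p, index=False)
            outputs.append(p)
        self._record("ecotones", outputs, t0)
        return outputs

    def stage_centroids(self) -> list[Path]:
        t0 = time.time()
        cfg = self.config
        outputs = []
        label_rows, pool_rows, top_rows = [], [], []
        for month in self._months():
            memb_env = pd.read_csv(self.outdir / f"memberships_env_{month}.csv")
            memb_otu = pd.read_csv(self.outdir / f"memberships_otu_{month}.csv")
            pos_env = memb_env["distance_km"].to_numpy()
            stations = memb_otu["distance_km"].to_numpy()
            env_cols = [c for c in memb_env.columns if c != "distance_km"]
            U_env_st = np.column_stack(
                [np.interp(stations, pos_env, memb_env[c]) for c in env_cols]
            )
            ccols = [c for c in memb_otu.columns if c != "distance_km"]
            labels = ca.label_community_clusters(
                memb_otu[ccols].to_numpy(), U_env_st, env_cols
            )
            for c, labs in zip(ccols, labels):
                label_rows.append({
                    "month": month, "cluster": c, "label": labs[0],
                    "all_labels": "+".join(labs),
                })
            cent = pd.read_csv(
                self.outdir / f"centroids_otu_{month}.tsv", sep="\t", index_col=0
            )
            shares = ca.otu_memberships(cent)
            for tau in sorted(set(cfg.tau_sweep) | {cfg.tau}):
                pools = ca.representative_otus(shares, tau)
                for c, pool in pools.items():
                    for otu in sorted(pool):
                        pool_rows.append({
                            "month": month, "cluster": c, "tau": tau, "otu": otu,
                            "share": float(shares.loc[otu, c]),
                        })
            for frac in cfg.top_fractions:
                for c in cent.index:
                    for otu in sorted(ca.top_fraction_otus(cent.loc[c], frac)):
                        top_rows.append(
                            {"month": month, "cluster": c, "fraction": frac, "otu": otu}
                        )
        for name, rows in [
            ("community_labels.csv", label_rows),
            ("representative_otus.tsv", pool_rows),
            ("top_fraction_otus.tsv", top_rows),
        ]:
            p = self.outdir / name
            sep = "\t" if name.endswith(".tsv") else ","
            pd.DataFrame(rows).to_csv(p, index=False, sep=sep)
            outputs.append(p)
        self._record("centroids", outputs, t0)
        return outputs

    def _pools(self, tau: float) -> dict:
        """(month, water-mass label) -> representative OTU set at one tau."""
        pools_df = pd.read_csv(self.outdir / "representative_otus.tsv", sep="\t")
        labels = pd.read_csv(self.outdir / "community_labels.csv")
        lab = {(r.month, r.cluster): r.label for r in labels.itertuples()}
        sub = pools_df[np.isclose(pools_df["tau"], tau)]
        pools: dict = {}
        for (month, cluster), grp in sub.groupby(["month", "cluster"]):
            key = (month, lab.get((month, cluster), cluster), cluster)
            pools[(key[0], f"{key[1]}:{cluster}")] = set(grp["otu"])
        return pools

    def stage_network(self) -> list[Path]:
        t0 = time.time()
        cfg = self.config
        rng = self._stage_seed("network")
        pools = self._pools(cfg.tau)
        if len(pools) < 2:
            raise StageError("network", "pools", "fewer than 2 representative pools")
        G = net.build_network(pools, tau=cfg.tau)
        outputs = []
        p = self.outdir / "network.graphml"
        Gx = nx.relabel_nodes(G, {n: f"{n[0]}|{n[1]}" for n in G})
        for _, data in Gx.nodes(data=True):
            data.pop("pool", None)  # sets are not GraphML-serializable
        nx.write_graphml(Gx, p)
        outputs.append(p)
        edges = nx.to_pandas_edgelist(G)
        edges["source"] = edges["source"].map(lambda n: f"{n[0]}|{n[1]}")
        edges["target"] = edges["target"].map(lambda n: f"{n[0]}|{n[1]}")
        p = self.outdir / "network_edges.tsv"
        edges[["source", "target", "weight"]].to_csv(p, sep="\t", index=False)
        outputs.append(p)
        A, nodes = nx.to_numpy_array(G, weight="weight"), list(G.nodes)
        adj = pd.DataFrame(A, index=[f"{n[0]}|{n[1]}" for n in nodes],
                           columns=[f"{n[0]}|{n[1]}" for n in nodes])
        p = self.outdir / "network_adjacency.csv"
        adj.to_csv(p)
        outputs.append(p)
        cons = net.spinglass_communities(
            G, gamma=cfg.gamma, n_runs=cfg.spinglass_runs,
            seed=int(rng.integers(2**31)),
        )
        result = {
            "n_communities": len(set(cons.modal_labels)),
            "modal_frequency": cons.modal_frequency,
            "communities": [sorted(f"{n[0]}|{n[1]}" for n in c) for c in cons.communities()],
            "isolates": [f"{n[0]}|{n[1]}" for n in cons.isolates],
            "recurrent_partition_freqs": sorted(
                cons.recurrent_partitions().values(), reverse=True
            ),
            "n_runs": cons.n_runs,
        }
        p = self.outdir / "spinglass_consensus.json"
        p.write_text(json.dumps(result, indent=1))
        outputs.append(p)
        # summary fractions against the detected month pools
        month_otus = {}
        for month in self._months():
            df = read_community_table(self.outdir / f"community_{month}.tsv")
            vals = df.drop(columns="distance_km")
            month_otus[month] = set(vals.columns[(vals > 0).any(axis=0)])
        global_pool = set().union(*month_otus.values())
        summ = net.network_summary(pools, month_otus, global_pool)
        p = self.outdir / "network_summary.json"
        p.write_text(json.dumps(
            {k: {str(kk): vv for kk, vv in v.items()} for k, v in summ.items()},
            indent=1,
        ))
        outputs.append(p)
        self._record("network", outputs, t0)
        return outputs

    def stage_stats(self) -> list[Path]:
        t0 = time.time()
        cfg = self.config
        outputs = []
        rows = []
        for scope, fname in [("env", "boundaries_env.csv"), ("otu", "boundaries_otu.csv")]:
            bounds = pd.read_csv(self.outdir / fname)
            if scope == "otu":
                # community boundaries are between consecutive clusters; reuse
                # the env boundary names via location matching with env truth
                env_b = pd.read_csv(self.outdir / "boundaries_env.csv")
                bounds = _relabel_otu_boundaries(bounds, env_b)
            for metric in ("slope_per_km", "transition_width_km"):
                for grouping in ("boundary_type", "month", "season"):
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        res = gs.compare_boundaries(bounds, metric, grouping, cfg.alpha)
                    if res["dunn"].empty:
                        continue
                    for _, r in res["dunn"].iterrows():
                        rows.append({
                            "scope": scope, "metric": metric, "grouping": grouping,
                            "H": res["H"], "p_kw": res["p"],
                            "comparison": f"{r['group_a']} vs {r['group_b']}",
                            "z": r["z"], "p_raw": r["p_raw"], "p_adj": r["p_adj"],
                            "letters_a": res["letters"][r["group_a"]],
                            "letters_b": res["letters"][r["group_b"]],
                        })
        p = self.outdir / "stats_report.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        outputs.append(p)
        self._record("stats", outputs, t0)
        return outputs

    def run_all(self) -> dict:
        results = {}
        for stage in STAGES:
            try:
                results[stage] = [p.name for p in getattr(self, f"stage_{stage}")()]
            except Exception as exc:  # noqa: BLE001 - abort with stage context
                if isinstance(exc, StageError):
                    raise
                code = getattr(exc, "code", type(exc).__name__.lower())
                raise StageError(stage, code, str(exc)) from exc
        return results


def _relabel_otu_boundaries(bounds: pd.DataFrame, env_bounds: pd.DataFrame) -> pd.DataFrame:
    """Rename community boundaries after the nearest env boundary that month."""
    out = bounds.copy()
    for i, row in bounds.iterrows():
        sub = env_bounds[env_bounds["month"] == row["month"]].dropna(subset=["location_km"])
        if sub.empty or not np.isfinite(row["location_km"]):
            continue
        j = (sub["location_km"] - row["location_km"]).abs().idxmin()
        out.at[i, "pair"] = sub.at[j, "pair"]
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in order; returns stage -> list of output file names."""
    return Pipeline(config).run_all()
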