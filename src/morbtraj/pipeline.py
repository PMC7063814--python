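"""Configuration-driven orchestration of the full analysis pipeline.

Stages: data (generate or ingest a stay table) -> cohort -> clustering
-> transition network -> trajectory statistics -> risks -> simulation
benchmark comparison.  Every artifact is written under the configured
output directory and listed, with SHA-256 checksums, in a manifest so
reruns with an identical configuration can be verified byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd

from . import blocks as blocks_mod
from . import clustering, risk, simulation, trajectories, transitions
from .cohort import CohortSpec, build_health_states, select_washout_cohort
from .errors import ConfigurationError
from .registry import GeneratorConfig, generate_registry

log = logging.getLogger("morbtraj.pipeline")

DEFAULT_CONFIG: dict = {
    "output_dir": "morbtraj_output",
    "seed": 1,
    "generate": True,
    "stays_path": None,
    "block_table_path": None,
    "generator": {"n_patients": 5000},
    "cohort": {"washout": [1997, 2002], "observation": [2003, 2014]},
    "k": 132,
    "min_rate": 0.005,
    "min_count": 100,
    "mortality_bands": None,  # transitions.DEFAULT_MORTALITY_BANDS
    "min_mean_age": 55.0,
    "risk_horizon": 1,
    "compare_models": True,
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    import yaml

    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for k, v in user.items():
            if isinstance(v, dict) and isinstance(cfg.get(k), dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    for k, v in (overrides or {}).items():
        if v is not None:
            cfg[k] = v
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict) -> dict:
    """Execute every stage; returns the manifest (also written to disk).

    Raises :class:`ConfigurationError` before any compute when referenced
    input paths are missing; any stage failure aborts with the stage name.
    """
    cfg = {**DEFAULT_CONFIG, **config}
    out = Path(cfg["output_dir"])
    seed = int(cfg["seed"])
    if not cfg["generate"]:
        if not cfg.get("stays_path") or not Path(cfg["stays_path"]).exists():
            raise ConfigurationError("stays_path", "stay table not found and generate=false")
    if cfg.get("block_table_path") and not Path(cfg["block_table_path"]).exists():
        raise ConfigurationError("block_table_path", "block table path does not exist")
    out.mkdir(parents=True, exist_ok=True)

    artifacts: list[str] = []
    timings: dict[str, float] = {}

    def stage(name):
        class _T:
            def __enter__(self):
                self.t = time.perf_counter()
                log.info("stage %s: start", name)
                return self

            def __exit__(self, et, ev, tb):
                timings[name] = round(time.perf_counter() - self.t, 3)
                if et is None:
                    log.info("stage %s: done in %.2fs", name, timings[name])
                else:
                    log.error("stage %s: FAILED (%s)", name, ev)
                return False

        return _T()

    def save_df(df: pd.DataFrame, name: str):
        p = out / name
        df.to_csv(p, index=False)
        artifacts.append(name)

    def save_json(obj, name: str):
        p = out / name
        with open(p, "w") as fh:
            json.dump(obj, fh, indent=1, default=str)
        artifacts.append(name)

    with stage("data"):
        if cfg["generate"]:
            gen = GeneratorConfig(seed=seed, **cfg["generator"])
            stays, truth = generate_registry(gen)
            save_df(stays, "registry.csv")
            truth.to_json(out / "ground_truth.json")
            artifacts.append("ground_truth.json")
            n_blocks = gen.n_blocks
        else:
            stays = pd.read_csv(cfg["stays_path"], dtype=str)
            truth = None
            n_blocks = 131
        if cfg.get("block_table_path"):
            blocks = blocks_mod.BlockTable.from_csv(cfg["block_table_path"])
        else:
            blocks = blocks_mod.default_block_table(n_blocks)
        log.info("stays: %d rows, %d patients", len(stays), stays["patient_id"].nunique())

    with stage("cohort"):
        spec = CohortSpec(
            washout=tuple(cfg["cohort"]["washout"]), observation=tuple(cfg["cohort"]["observation"])
        )
        cohort_ids = select_washout_cohort(stays, spec)
        states = build_health_states(stays, cohort_ids, spec, blocks)
        save_df(pd.DataFrame({"patient_id": sorted(cohort_ids)}), "cohort_patients.csv")
        states.to_sparse_csv(out / "health_states_sparse.csv")
        artifacts.append("health_states_sparse.csv")
        log.info("cohort M=%d, %d patient-years", len(cohort_ids), states.n_rows)

    with stage("cluster"):
        model = clustering.fit_divclus(states, int(cfg["k"]))
        labels = clustering.assign_many(states, model)
        profiles = clustering.characterise_clusters(model, states, labels)
        save_df(model.criteria_frame(blocks), "cluster_criteria.csv")
        save_json(model.to_json_dict(), "cluster_tree.json")
        save_df(profiles.frame, "cluster_profiles.csv")
        assignments = states.assignment_frame(labels)
        log.info("fitted %d clusters (truncated=%s)", model.K, model.truncated)

    with stage("network"):
        net = transitions.estimate_transition_rates(assignments)
        save_df(transitions.edge_list_frame(net), "network_edges.csv")
        transitions.export_graphml(
            net, out / "network.graphml", profiles.frame,
            min_rate=float(cfg["min_rate"]), min_count=int(cfg["min_count"]),
        )
        artifacts.append("network.graphml")
        ok, cycle = transitions.acyclicity_check(net)
        sinks = transitions.find_sink_states(net)
        regions = transitions.label_mortality_regions(
            profiles.frame, cfg["mortality_bands"], float(cfg["min_mean_age"])
        )
        save_json(
            {
                "acyclic": ok,
                "cycle": cycle,
                "sink_clusters": sinks,
                "regions": {r.name: r.members for r in regions},
            },
            "network_summary.json",
        )
        log.info("network: acyclic=%s, %d sink states", ok, len(sinks))

    with stage("trajectories"):
        trajs = trajectories.trajectories_from_assignments(assignments)
        dist = trajectories.length_distribution(trajs)
        modal3 = trajectories.most_frequent_reduced(trajs, 3, mode="exact")
        modal3p = trajectories.most_frequent_reduced(trajs, 3, mode="prefix")
        start_age = assignments.sort_values("year").groupby("patient_id")["age"].first()
        by_age = trajectories.mean_length_by_age(trajs, start_age)
        save_df(dist.rename("freq").reset_index(), "reduced_length_distribution.csv")
        save_df(by_age, "mean_length_by_age.csv")
        save_df(trajectories.reduced_summary(trajs).head(1000), "reduced_trajectories_top.csv")
        save_json(
            {
                "modal_length3_exact": None if modal3 is None else {"seq": list(modal3[0]), "count": modal3[1]},
                "modal_length3_prefix": None if modal3p is None else {"seq": list(modal3p[0]), "count": modal3p[1]},
            },
            "trajectory_summary.json",
        )

    with stage("risk"):
        region_members = next((r.members for r in regions if r.name == "high" and r.members), None)
        if region_members is None:
            pf = profiles.frame.dropna(subset=["annual_mortality"])
            region_members = [int(pf.sort_values("annual_mortality").iloc[-1]["cluster_id"])] if len(pf) else []
        risk_rows = []
        gender_rows = pd.DataFrame()
        if region_members:
            ranking = transitions.rank_entry_clusters(assignments, region_members)
            save_df(ranking, "region_entry_ranking.csv")
            strata = (
                assignments.groupby(["sex", "age_group"], as_index=False).size()
                .sort_values("size", ascending=False)
            )
            top_sources = [int(c) for c in ranking["cluster"].head(3) if int(c) not in region_members]
            for src in top_sources:
                for _, st in strata.head(4).iterrows():
                    for baseline in ("all", "cluster0"):
                        est = risk.region_entry_risk(
                            assignments, src, region_members, st["sex"], st["age_group"],
                            horizon=int(cfg["risk_horizon"]), baseline=baseline,
                        )
                        risk_rows.append(
                            {
                                "cluster": src,
                                "sex": est.sex,
                                "age_group": est.age_group,
                                "baseline": est.baseline_kind,
                                "absolute_risk": est.absolute_risk,
                                "relative_risk": est.relative_risk,
                                "ci_low": est.ci_low,
                                "ci_high": est.ci_high,
                                "ci_half_width": est.ci_half_width if est.defined else np.nan,
                            }
                        )
            gender_rows = risk.gender_biased_transitions(net, min_count=int(cfg["min_count"]))
        save_df(pd.DataFrame(risk_rows), "risk_report.csv")
        save_df(gender_rows, "gender_bias.csv")

    if cfg.get("compare_models", True):
        with stage("compare"):
            years = (int(assignments["year"].min()), int(assignments["year"].max()))
            models = {"divclus": (assignments, net)}
            for mode in ("most_recent", "least_frequent"):
                bench = simulation.benchmark_assign(states, mode)
                models[mode] = (bench, transitions.estimate_transition_rates(bench))
            comparison = simulation.compare_models(models, years, seed=seed, states=states)
            save_df(comparison, "model_comparison.csv")

    manifest = {
        "package_version": _pkg_version("morbtraj"),
        "seed": seed,
        "parameters": {k: v for k, v in cfg.items() if k != "output_dir"},
        "timings_s": timings,
        "artifacts": {name: _sha256(out / name) for name in sorted(set(artifacts))},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
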