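"""End-to-end pipeline: simulate/load -> prep -> dFC -> states -> metrics
-> group stats, from a single validated configuration.

Every stage writes tab-separated tables with a provenance header
(config hash, seed) into the run directory, plus a manifest with
checksums. Reruns with the same config and seed are table-identical.
All randomness flows from one top-level seed, expanded deterministically
per stage.
"""
from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .preprocess import TimeCoursePreprocessor, component_qc
from .simulate import default_cohort_spec, generate_cohort
from .states import cluster_states, occupancy_scan, state_metrics
from .stats import (dominant_state, dominant_state_test, group_mean_compare,
                    testretest_report)
from .graph import centroid_to_state_graph, fdr_threshold_adjacency, \
    graph_metrics
from .windows import WindowParams, dfc_stack, window_correlation

__all__ = ["PipelineConfig", "validate_config", "run_pipeline",
           "STAGES", "DEFAULT_CONFIG"]

STAGES = ("simulate", "prep", "dfc", "states", "metrics", "stats")

DEFAULT_CONFIG = {
    "input": {"manifest": None},          # path, or None -> synthesize
    "simulate": {"n_subjects_per_group": 20, "n_runs": 2, "n_volumes": 244,
                 "n_nodes": 20, "n_states": 4, "noise_sd": 0.5,
                 "coupling_strength": 0.8, "control_self_prob": 0.94,
                 "sticky_self_prob": 0.97, "subject_concentration": 7.0,
                 "tr_seconds": 2.0},
    "prep": {"n_discard": 4, "cutoff_hz": 0.15, "qc_split_hz": 0.10},
    "windows": {"window_length": 15, "step": 1, "taper": "rectangular",
                "estimator": "correlation", "l1_penalty": 0.1},
    "states": {"k": 6, "k_range": None, "n_replicates": 5,
               "low_band": [0.02, 0.04]},
    "metrics": {"alpha": 0.05, "sd_multiplier": 1.5,
                "edge_threshold_rule": "top_percent:10",
                "hub_metric": "node_strength"},
    "log_level": "info",
}


@dataclass
class PipelineConfig:
    """Validated configuration; every defaulted value is echoed."""
    raw: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.raw[key]

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True).encode()).hexdigest()[:12]


def _merge_defaults(raw: dict, defaults: dict, path: str, errors: list
                    ) -> dict:
    out = {}
    for key, dval in defaults.items():
        if isinstance(dval, dict) and not path.endswith("input"):
            out[key] = _merge_defaults(raw.get(key, {}) or {}, dval,
                                       f"{path}.{key}", errors)
        else:
            out[key] = raw.get(key, dval)
    for key in raw:
        if key not in defaults:
            errors.append(f"{path}.{key}: unknown key")
    return out


def validate_config(raw: dict | str | Path):
    """Validate a config dict (or YAML path/text) against the schema.

    Returns ``(PipelineConfig, [])`` on success or ``(None, errors)``
    where ``errors`` lists every violation with its path.
    """
    import yaml
    if isinstance(raw, (str, Path)):
        p = Path(raw)
        text = p.read_text() if p.exists() else str(raw)
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        return None, ["config root must be a mapping"]
    errors: list = []
    cfg = _merge_defaults(raw, DEFAULT_CONFIG, "config", errors)

    w = cfg["windows"]
    if w["window_length"] < 3:
        errors.append("config.windows.window_length: must be >= 3 volumes")
    if w["step"] < 1:
        errors.append("config.windows.step: must be >= 1")
    if w["estimator"] not in ("correlation", "sparse_precision"):
        errors.append("config.windows.estimator: unknown estimator")
    if w["l1_penalty"] < 0:
        errors.append("config.windows.l1_penalty: must be >= 0")
    m = cfg["metrics"]
    if not 0 < m["alpha"] < 1:
        errors.append("config.metrics.alpha: must be in (0, 1)")
    if m["sd_multiplier"] <= 0:
        errors.append("config.metrics.sd_multiplier: must be positive")
    s = cfg["states"]
    if s["k_range"] is not None:
        kr = s["k_range"]
        if (not isinstance(kr, (list, tuple)) or len(kr) != 2
                or kr[0] < 2 or kr[1] < kr[0]):
            errors.append("config.states.k_range: must be [kmin, kmax] "
                          "with 2 <= kmin <= kmax")
    elif s["k"] < 2:
        errors.append("config.states.k: must be >= 2")
    p = cfg["prep"]
    if p["n_discard"] < 0:
        errors.append("config.prep.n_discard: must be >= 0")
    sim = cfg["simulate"]
    n_after = sim["n_volumes"] - p["n_discard"]
    if cfg["input"]["manifest"] is None and n_after < w["window_length"]:
        errors.append("config.simulate.n_volumes: too short for the window "
                      "length after discarding initial volumes")
    if sim["noise_sd"] < 0:
        errors.append("config.simulate.noise_sd: must be >= 0")
    nyq = 0.5 / sim["tr_seconds"]
    if not 0 < p["cutoff_hz"] < nyq:
        errors.append(f"config.prep.cutoff_hz: must be in (0, {nyq}) Hz")
    if cfg["log_level"] not in ("debug", "info", "warn"):
        errors.append("config.log_level: must be debug|info|warn")
    if errors:
        return None, errors
    return PipelineConfig(raw=cfg), []


def run_pipeline(config, seed: int = 0, out_dir="dfcstates_run",
                 stop_after: str | None = None) -> dict:
    """Run the full analysis; returns a dict of in-memory results.

    ``stop_after`` names a stage from :data:`STAGES` to halt at (the
    stage itself is executed). All tables land in ``out_dir`` with a
    provenance header; a ``manifest.json`` with sha256 checksums is
    written last.
    """
    if not isinstance(config, PipelineConfig):
        config, errors = validate_config(config)
        if errors:
            raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    if stop_after is not None and stop_after not in STAGES:
        raise ValueError(f"unknown stage {stop_after!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = {"config_hash": config.hash(), "seed": seed,
            "package": "dfcstates 0.1.0"}
    results: dict = {"config": config, "out_dir": out}
    written: list = []

    def emit(df: pd.DataFrame, name: str):
        path = out / name
        dio.write_table(df, path, provenance=prov)
        written.append(path)

    seeds = {stage: np.random.SeedSequence(seed).spawn(len(STAGES))[i]
             for i, stage in enumerate(STAGES)}

    # --- simulate / load -------------------------------------------------
    sim = config["simulate"]
    if config["input"]["manifest"]:
        cohort, info = dio.read_cohort(config["input"]["manifest"])
        tr = info["tr_seconds"]
    else:
        sim_seed = int(seeds["simulate"].generate_state(1)[0] % (2 ** 31))
        spec = default_cohort_spec(
            seed=sim_seed, n_states=sim["n_states"], n_nodes=sim["n_nodes"],
            n_subjects_per_group=sim["n_subjects_per_group"],
            n_runs=sim["n_runs"], n_volumes=sim["n_volumes"],
            coupling_strength=sim["coupling_strength"],
            noise_sd=sim["noise_sd"],
            control_self_prob=sim["control_self_prob"],
            sticky_self_prob=sim["sticky_self_prob"],
            subject_concentration=sim["subject_concentration"])
        spec.tr_seconds = sim["tr_seconds"]
        cohort = generate_cohort(spec)
        dio.write_cohort(cohort, spec, out / "cohort")
        tr = spec.tr_seconds
    group_map = {rec.subject_id: rec.group for rec in cohort}
    results["cohort"] = cohort
    results["group_map"] = group_map
    if stop_after == "simulate":
        return _finish(results, out, written, prov)

    # --- prep -------------------------------------------------------------
    pcfg = config["prep"]
    prep = TimeCoursePreprocessor(n_discard=pcfg["n_discard"],
                                  cutoff_hz=pcfg["cutoff_hz"],
                                  tr_seconds=tr)
    prepared = {}   # (subject, run) -> ComponentTimeSeries
    qc_rows = []
    for rec in cohort:
        for ts in rec.runs:
            pts = prep.prepare_timeseries(ts)
            prepared[(rec.subject_id, ts.run_id)] = pts
            qc = component_qc(pts, split_hz=pcfg["qc_split_hz"])
            qc.insert(0, "run_id", ts.run_id)
            qc.insert(0, "subject_id", rec.subject_id)
            qc_rows.append(qc)
    qc_table = pd.concat(qc_rows, ignore_index=True)
    emit(qc_table, "qc_report.tsv")
    results["prepared"] = prepared
    results["qc"] = qc_table
    if stop_after == "prep":
        return _finish(results, out, written, prov)

    # --- dynamic connectivity ----------------------------------------------
    wcfg = config["windows"]
    params = WindowParams(window_length=wcfg["window_length"],
                          step=wcfg["step"], taper=wcfg["taper"],
                          estimator=wcfg["estimator"],
                          l1_penalty=wcfg["l1_penalty"])
    run_keys, run_lengths, feats = [], [], []
    for key, pts in prepared.items():
        stack = dfc_stack(pts, params)
        F = stack.to_features()
        run_keys.append(key)
        run_lengths.append(F.shape[0])
        feats.append(F)
    features = np.vstack(feats)
    results["features"] = features
    results["run_keys"] = run_keys
    results["run_lengths"] = run_lengths
    long_rows = pd.DataFrame({
        "subject_id": np.repeat([k[0] for k in run_keys], run_lengths),
        "run_id": np.repeat([k[1] for k in run_keys], run_lengths),
    })
    emit(long_rows.groupby(["subject_id", "run_id"]).size()
         .rename("n_windows").reset_index(), "window_counts.tsv")
    if stop_after == "dfc":
        return _finish(results, out, written, prov)

    # --- states -------------------------------------------------------------
    scfg = config["states"]
    cluster_seed = int(seeds["states"].generate_state(1)[0] % (2 ** 31))
    if scfg["k_range"] is not None:
        lo, hi = scfg["k_range"]
        scan = occupancy_scan(features, k_range=range(lo, hi + 1),
                              low_band=tuple(scfg["low_band"]),
                              seed=cluster_seed,
                              n_replicates=scfg["n_replicates"],
                              run_keys=run_keys, run_lengths=run_lengths)
        emit(scan.assign(mean_frequencies=scan["mean_frequencies"].map(
            lambda v: ",".join(f"{x:.4f}" for x in v))), "occupancy_scan.tsv")
        k = int(scan.loc[scan["recommended"], "k"].iloc[0])
        results["occupancy_scan"] = scan
    else:
        k = scfg["k"]
    part = cluster_states(features, k, seed=cluster_seed,
                          n_replicates=scfg["n_replicates"],
                          run_keys=run_keys, run_lengths=run_lengths)
    results["partition"] = part
    dio.write_matrix(part.centroids, out / "state_centroids.tsv",
                     node_ids=[f"e{i}" for i in range(part.centroids.shape[1])])
    written.append(out / "state_centroids.tsv")
    step_seconds = wcfg["step"] * tr
    sm_rows = []
    for (subj, run), labels in part.labels.items():
        np.savetxt(out / f"labels_{subj}_{run}.txt", labels, fmt="%d")
        sm = state_metrics(labels, k=k, window_step_seconds=step_seconds)
        row = {"subject_id": subj, "run_id": run, "group": group_map[subj],
               "k": k, "n_transitions": sm.n_transitions,
               "n_windows": sm.n_windows}
        for s in range(1, k + 1):
            row[f"freq_state{s}"] = sm.frequency[s - 1]
            row[f"dwell_state{s}"] = sm.mean_dwell[s - 1]
        sm_rows.append(row)
    state_table = pd.DataFrame(sm_rows)
    emit(state_table, "state_metrics.tsv")
    results["state_metrics"] = state_table
    if stop_after == "states":
        return _finish(results, out, written, prov)

    # --- graph metrics -------------------------------------------------------
    mcfg = config["metrics"]
    node_meta = cohort[0].runs[0].node_meta
    static_rows = []
    for (subj, run), pts in prepared.items():
        R, _ = window_correlation(pts.data)
        adj = fdr_threshold_adjacency(R, n_samples=pts.n_volumes,
                                      alpha=mcfg["alpha"],
                                      node_meta=node_meta)
        gm = graph_metrics(adj, sd_multiplier=mcfg["sd_multiplier"],
                           hub_metric=mcfg["hub_metric"])
        static_rows.append({
            "subject_id": subj, "run_id": run, "group": group_map[subj],
            "total_connections": gm.total_connections,
            "network_strength": gm.network_strength,
            "network_cost": gm.network_cost, "mean_cc": gm.mean_cc,
            "path_length": gm.path_length,
            "global_efficiency": gm.global_efficiency,
            "reachability": gm.reachability_fraction,
            "hubs": ",".join(node_meta["node_id"].iloc[gm.hub_set])})
    static_table = pd.DataFrame(static_rows)
    emit(static_table, "static_graph_metrics.tsv")
    results["static_graph_metrics"] = static_table

    state_rows = []
    for s in range(k):
        adj = centroid_to_state_graph(
            part.centroids[s], node_meta=node_meta,
            edge_threshold_rule=mcfg["edge_threshold_rule"])
        gm = graph_metrics(adj, sd_multiplier=mcfg["sd_multiplier"],
                           hub_metric=mcfg["hub_metric"])
        state_rows.append({
            "state": s + 1, "total_connections": gm.total_connections,
            "network_strength": gm.network_strength,
            "network_cost": gm.network_cost, "mean_cc": gm.mean_cc,
            "path_length": gm.path_length,
            "global_efficiency": gm.global_efficiency,
            "hubs": ",".join(node_meta["node_id"].iloc[gm.hub_set])})
    state_graph_table = pd.DataFrame(state_rows)
    emit(state_graph_table, "state_graph_metrics.tsv")
    results["state_graph_metrics"] = state_graph_table
    if stop_after == "metrics":
        return _finish(results, out, written, prov)

    # --- group statistics -----------------------------------------------------
    runs_present = sorted({r for (_, r) in part.labels})
    if len(runs_present) >= 2:
        r1, r2 = runs_present[:2]
        cols = ([f"freq_state{s}" for s in range(1, k + 1)]
                + ["n_transitions"])
        m1 = state_table[state_table.run_id == r1].set_index("subject_id")[cols]
        m2 = state_table[state_table.run_id == r2].set_index("subject_id")[cols]
        g1 = static_table[static_table.run_id == r1].set_index("subject_id")
        g2 = static_table[static_table.run_id == r2].set_index("subject_id")
        gcols = ["path_length", "mean_cc", "network_strength"]
        rel = pd.concat([
            testretest_report(m1, m2, group_map),
            testretest_report(g1[gcols], g2[gcols], group_map),
        ], ignore_index=True)
        emit(rel, "reliability.tsv")
        results["reliability"] = rel

    freq_cols = [f"freq_state{s}" for s in range(1, k + 1)]
    subj_freq = (state_table.groupby("subject_id")[freq_cols].mean())
    subj_freq.columns = list(range(1, k + 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        dom = dominant_state(subj_freq)
        try:
            chi2, dof, pval, table, _, small = dominant_state_test(
                dom, group_map)
            emit(pd.DataFrame([{"chi2": chi2, "df": dof, "p": pval,
                                "small_cells": small}]),
                 "dominant_state_test.tsv")
            results["dominant_state_test"] = (chi2, dof, pval, table)
        except ValueError:
            pass
    trans = state_table.groupby("subject_id")["n_transitions"].mean()
    cmp_res = group_mean_compare(trans, group_map)
    emit(pd.DataFrame([{
        "metric": "n_transitions",
        **{f"mean_{g}": cmp_res["mean"][g] for g in cmp_res["groups"]},
        **{f"sd_{g}": cmp_res["sd"][g] for g in cmp_res["groups"]},
        "t": cmp_res["t"], "p": cmp_res["p"]}]), "group_transitions.tsv")
    results["transitions_compare"] = cmp_res
    return _finish(results, out, written, prov)


def _finish(results: dict, out: Path, written: list, prov: dict) -> dict:
    manifest = {"provenance": prov,
                "outputs": {p.name: dio.file_checksum(p) for p in written}}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    results["manifest"] = manifest
    return results
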