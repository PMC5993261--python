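"""Plain-text persistence for cohorts, matrices and report tables.

Formats
-------
- time courses: one TSV per subject-run, volumes as rows, header row of
  node IDs
- ground-truth state labels: one label per line
- node metadata: TSV (node_id, network, x, y, z)
- transition models / cohort manifest: YAML
- square matrices: TSV with node-ID header
- report tables: TSV with a ``#``-prefixed provenance header block
"""
from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import ComponentTimeSeries
from .simulate import CohortSpec, SubjectRecord, TransitionModel

__all__ = [
    "write_cohort", "read_cohort", "write_timeseries", "read_timeseries",
    "write_matrix", "read_matrix", "write_table", "read_table",
    "transition_model_to_dict", "transition_model_from_dict",
]


# ---------------------------------------------------------------------------
# time series

def write_timeseries(ts: ComponentTimeSeries, path) -> None:
    df = pd.DataFrame(ts.data, columns=ts.node_meta["node_id"].tolist())
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_timeseries(path, tr_seconds: float, node_meta=None,
                    subject_id: str = "", run_id: str = ""
                    ) -> ComponentTimeSeries:
    df = pd.read_csv(path, sep="\t")
    return ComponentTimeSeries(data=df.to_numpy(dtype=float),
                               tr_seconds=tr_seconds, node_meta=node_meta,
                               subject_id=subject_id, run_id=run_id)


# ---------------------------------------------------------------------------
# matrices and tables

def write_matrix(M: np.ndarray, path, node_ids=None) -> None:
    n = M.shape[0]
    if node_ids is None:
        node_ids = [f"IC{i + 1:02d}" for i in range(n)]
    pd.DataFrame(M, columns=list(node_ids)).to_csv(
        path, sep="\t", index=False, float_format="%.12g")


def read_matrix(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t").to_numpy(dtype=float)


def write_table(df: pd.DataFrame, path, provenance: dict | None = None
                ) -> None:
    """TSV with a leading ``#`` provenance header block."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, val in (provenance or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# transition models (YAML round-trip preserving row-stochasticity)

def transition_model_to_dict(tm: TransitionModel) -> dict:
    return {"matrix": [[float(x) for x in row] for row in tm.matrix],
            "initial": [float(x) for x in tm.initial]}


def transition_model_from_dict(d: dict) -> TransitionModel:
    return TransitionModel(matrix=np.array(d["matrix"], dtype=float),
                           initial=np.array(d["initial"], dtype=float))


# ---------------------------------------------------------------------------
# cohorts

def write_cohort(cohort, spec: CohortSpec, out_dir) -> Path:
    """Write a generated cohort to ``out_dir``; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    node_meta = cohort[0].runs[0].node_meta
    node_meta.to_csv(out / "node_meta.tsv", sep="\t", index=False,
                     float_format="%.6g")
    manifest = {
        "tr_seconds": float(spec.tr_seconds),
        "n_volumes": int(spec.n_volumes),
        "n_runs": int(spec.n_runs),
        "noise_sd": float(spec.noise_sd),
        "seed": int(spec.seed),
        "subject_concentration": float(spec.subject_concentration),
        "groups": {name: transition_model_to_dict(tm)
                   for name, tm in spec.groups.items()},
        "state_ids": [int(s) for s in spec.library.state_ids],
        "subjects": [],
    }
    for s in range(spec.library.n_states):
        write_matrix(spec.library.covariances[s],
                     out / f"state_{spec.library.state_ids[s]}_cov.tsv",
                     node_ids=node_meta["node_id"])
    for rec in cohort:
        entry = {"subject_id": rec.subject_id, "group": rec.group, "runs": []}
        for ts, seq in zip(rec.runs, rec.state_sequences):
            stem = f"{rec.subject_id}_{ts.run_id}"
            write_timeseries(ts, out / f"{stem}_timecourses.tsv")
            np.savetxt(out / f"{stem}_labels.txt", seq, fmt="%d")
            entry["runs"].append({
                "run_id": ts.run_id,
                "timecourses": f"{stem}_timecourses.tsv",
                "labels": f"{stem}_labels.txt",
            })
        manifest["subjects"].append(entry)
    manifest_path = out / "cohort.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest_path


def read_cohort(manifest_path):
    """Read a cohort written by :func:`write_cohort`.

    Returns ``(records, info)`` where ``info`` carries tr/groups/seed.
    """
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    node_meta = pd.read_csv(root / "node_meta.tsv", sep="\t")
    tr = float(manifest["tr_seconds"])
    records = []
    for entry in manifest["subjects"]:
        rec = SubjectRecord(subject_id=entry["subject_id"],
                            group=entry["group"])
        for run in entry["runs"]:
            rec.runs.append(read_timeseries(
                root / run["timecourses"], tr_seconds=tr, node_meta=node_meta,
                subject_id=entry["subject_id"], run_id=run["run_id"]))
            labels_file = root / run["labels"]
            if labels_file.exists():
                rec.state_sequences.append(
                    np.loadtxt(labels_file, dtype=int, ndmin=1))
        records.append(rec)
    info = {
        "tr_seconds": tr,
        "seed": manifest.get("seed"),
        "groups": {name: transition_model_from_dict(d)
                   for name, d in manifest.get("groups", {}).items()},
        "node_meta": node_meta,
    }
    return records, info
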