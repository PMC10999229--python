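"""Readers and writers binding the pipeline stages to plain-text files.

Everything is CSV/TSV so runs are human-auditable: cohort covariates and
behavior as CSV, per-participant time series or matrices as per-file CSV
plus a manifest (participant, timepoint, domain, kind, path), the partition
as a two-column CSV and the simulation ground truth as a key-value text
file next to a truth CSV.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from .connectivity import (
    read_matrix_csv,
    read_timeseries_csv,
    write_matrix_csv,
    write_timeseries_csv,
)
from .errors import ValidationError
from .partition import read_partition
from .synthetic import SyntheticCohort

MANIFEST_COLUMNS = ("participant", "timepoint", "domain", "kind", "path")


def write_cohort(cohort: SyntheticCohort, outdir) -> Path:
    """Serialize a synthetic cohort under ``outdir``; returns the directory."""
    out = Path(outdir)
    (out / "data").mkdir(parents=True, exist_ok=True)
    cohort.covariates.to_csv(out / "covariates.csv", index=False)
    cohort.behavior.to_csv(out / "behavior.csv", index=False)
    cohort.partition.write_csv(out / "partition.csv")
    if cohort.truth is not None:
        cohort.truth.to_csv(out / "truth.csv", index=False)
    with open(out / "ground_truth.txt", "w") as fh:
        for key, value in asdict(cohort.config).items():
            fh.write(f"{key} = {value!r}\n")
    rows = []
    for (pid, tp, domain), obj in cohort.data.items():
        kind = "matrix" if hasattr(obj, "weights") else "timeseries"
        rel = f"data/{pid}_{tp}_{domain}.csv"
        if kind == "matrix":
            write_matrix_csv(obj, out / rel)
        else:
            write_timeseries_csv(obj, out / rel)
        rows.append(
            {"participant": pid, "timepoint": tp, "domain": domain,
             "kind": kind, "path": rel}
        )
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(
        out / "manifest.csv", index=False
    )
    return out


def read_manifest_data(cohort_dir) -> dict:
    """Load the manifest-driven data container back into memory."""
    root = Path(cohort_dir)
    manifest = pd.read_csv(root / "manifest.csv")
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValidationError(
            f"manifest {root / 'manifest.csv'}: missing columns {sorted(missing)}"
        )
    data = {}
    for _, row in manifest.iterrows():
        path = root / row["path"]
        if not path.exists():
            raise ValidationError(f"manifest references missing file {path}")
        reader = read_matrix_csv if row["kind"] == "matrix" else read_timeseries_csv
        data[(row["participant"], row["timepoint"], row["domain"])] = reader(path)
    return data


def read_cohort_dir(cohort_dir):
    """Read (covariates, behavior, partition, data) from a cohort directory."""
    root = Path(cohort_dir)
    for name in ("covariates.csv", "behavior.csv", "partition.csv"):
        if not (root / name).exists():
            raise ValidationError(f"cohort directory {root}: missing {name}")
    covariates = pd.read_csv(root / "covariates.csv")
    behavior = pd.read_csv(root / "behavior.csv")
    partition = read_partition(root / "partition.csv")
    data = read_manifest_data(root) if (root / "manifest.csv").exists() else {}
    return covariates, behavior, partition, data


def config_hash(config) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_run_manifest(outdir, config, seeds: dict) -> None:
    """Record resolved configuration, seeds and a config hash for replay."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    record = {
        "config": asdict(config),
        "config_hash": config_hash(config),
        "seeds": seeds,
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(record, fh, indent=2, default=str)
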