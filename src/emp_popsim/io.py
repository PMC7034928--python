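"""Tabular output writers and readers (CSV for tables, JSON for scalars)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .population import PHENOTYPES, DivisionRecord, Trajectory, tally_divisions

__all__ = [
    "write_tables",
    "read_trajectory",
    "read_divisions",
    "trajectory_frame",
    "records_frame",
    "write_summary_json",
]


def trajectory_frame(traj: Trajectory) -> pd.DataFrame:
    return traj.to_frame()


def records_frame(records: list[DivisionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        records, columns=["time_h", "parent_phenotype", "daughter1", "daughter2"]
    )


def write_tables(traj: Trajectory, records: list[DivisionRecord], outdir) -> dict:
    """Write trajectory and division-record CSVs; returns the paths.

    The CSVs round-trip losslessly through :func:`read_trajectory` /
    :func:`read_divisions`; an empty record list yields a header-only CSV.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tpath = outdir / "trajectory.csv"
    rpath = outdir / "divisions.csv"
    trajectory_frame(traj).to_csv(tpath, index=False)
    records_frame(records).to_csv(rpath, index=False)
    return {"trajectory": tpath, "divisions": rpath}


def read_trajectory(path) -> Trajectory:
    df = pd.read_csv(path)
    counts = {k: df[f"n_{k}"].to_numpy() for k in PHENOTYPES}
    n = len(df)
    return Trajectory(
        df["time_h"].to_numpy(),
        counts,
        np.zeros(n, dtype=int),
        np.zeros(n, dtype=int),
    )


def read_divisions(path) -> list[DivisionRecord]:
    df = pd.read_csv(path)
    return [
        DivisionRecord(r.time_h, r.parent_phenotype, r.daughter1, r.daughter2)
        for r in df.itertuples()
    ]


def write_summary_json(path, summary, config=None, records=None,
                       extra: dict | None = None) -> dict:
    """Day-wise mean±SD fractions plus tallies and provenance, as JSON."""
    days = summary.times / 24.0
    payload = {
        "days": [round(float(d), 6) for d in days],
        "fractions_mean": {
            k: [float(v) for v in summary.mean_fractions[k]] for k in PHENOTYPES
        },
        "fractions_sd": {
            k: [float(v) for v in summary.sd_fractions[k]] for k in PHENOTYPES
        },
        "total_mean": [float(v) for v in summary.mean_total],
        "total_sd": [float(v) for v in summary.sd_total],
    }
    if records:
        tal = tally_divisions(records)
        payload["division_tally"] = json.loads(tal.to_json(orient="index"))
    if config is not None:
        payload["config"] = config.to_dict()
        payload["config_hash"] = config.config_hash()
        payload["base_seed"] = config.base_seed
    if extra:
        payload.update(extra)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    return payload
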