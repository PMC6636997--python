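"""Cohort container I/O: HDF5 traces plus CSV metadata and ground truth.

A cohort directory holds:

* ``traces.h5`` — one dataset per segment: the (n_cycles, n_bins)
  photon-count array, with decay-bin edges and cycle period as
  attributes;
* ``metadata.csv`` — one row per segment (animal, vessel class, depth,
  branch order);
* ``ground_truth.csv`` — generating parameters per segment (synthetic
  cohorts only).

All CSVs are comma-separated UTF-8 with a header row and '.' decimals.
"""

from __future__ import annotations

import json
from dataclasses import asdict, fields
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .simulate import CohortData, GroundTruthProfile, SimulationConfig
from .trace import PhotonTrace

__all__ = [
    "write_cohort",
    "read_cohort",
    "load_config",
    "dump_config",
]


def write_cohort(outdir, cohort: CohortData, header: dict | None = None) -> Path:
    """Write traces, metadata and ground truth to a cohort directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with h5py.File(outdir / "traces.h5", "w") as f:
        for key, val in (header or {}).items():
            f.attrs[key] = val
        for trace in cohort.traces:
            ds = f.create_dataset(
                trace.segment_id, data=trace.counts, compression="gzip", compression_opts=4
            )
            ds.attrs["bin_edges_us"] = trace.bin_edges_us
            ds.attrs["cycle_period_us"] = trace.cycle_period_us
    cohort.records.to_csv(outdir / "metadata.csv", index=False)
    cohort.truth.to_csv(outdir / "ground_truth.csv", index=False)
    if header:
        (outdir / "manifest.json").write_text(json.dumps(header, indent=2, default=str))
    return outdir


def read_cohort(indir) -> CohortData:
    """Read a cohort directory written by :func:`write_cohort`."""
    indir = Path(indir)
    records = pd.read_csv(indir / "metadata.csv")
    truth_path = indir / "ground_truth.csv"
    truth = pd.read_csv(truth_path) if truth_path.exists() else pd.DataFrame()
    traces = []
    with h5py.File(indir / "traces.h5", "r") as f:
        for seg_id in records["segment_id"]:
            if seg_id not in f:
                raise KeyError(f"trace for segment {seg_id!r} missing from traces.h5")
            ds = f[seg_id]
            traces.append(
                PhotonTrace(
                    ds[()],
                    np.asarray(ds.attrs["bin_edges_us"]),
                    float(ds.attrs["cycle_period_us"]),
                    str(seg_id),
                )
            )
    return CohortData(traces, records, truth)


_CONFIG_KEYS = {f.name for f in fields(SimulationConfig)}
_PROFILE_KEYS = {f.name for f in fields(GroundTruthProfile)}


def load_config(path) -> tuple[SimulationConfig, GroundTruthProfile]:
    """Read a flat YAML/JSON key-value file into config + profile.

    Keys matching SimulationConfig fields configure the acquisition and
    cohort design; keys matching GroundTruthProfile fields override the
    generating layer profiles (scalars broadcast over layers).  Unknown
    keys raise, naming the offender.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must be a key-value mapping")
    cfg_kwargs, prof_kwargs = {}, {}
    for key, value in raw.items():
        if key in _CONFIG_KEYS:
            cfg_kwargs[key] = value
        elif key in _PROFILE_KEYS:
            prof_kwargs[key] = value
        else:
            raise ValueError(f"unknown configuration key {key!r}")
    return SimulationConfig(**cfg_kwargs), GroundTruthProfile(**prof_kwargs)


def dump_config(path, config: SimulationConfig, profile: GroundTruthProfile) -> None:
    data = {**asdict(config), **asdict(profile)}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
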