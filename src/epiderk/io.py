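"""Readers and writers for the pipeline's tabular text formats.

All artifacts are plain text: ROI and conditioned-sample tables as
tab-delimited files with a one-line header, partition profiles as long-form
TSV, smoothed curves and association tables as CSV, configuration as
YAML or JSON, fit results and run manifests as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .association import AssociationResult
from .cascade import CascadeParameters, NormalizedHillParams, SpatialSteadyState
from .conditioning import ROI_COLUMNS, PartitionProfile, SmoothedProfile
from .exceptions import ConfigError
from .fitting import FitResult

__all__ = [
    "read_roi_table", "write_roi_table",
    "read_table", "write_table",
    "read_profiles", "write_profiles",
    "write_smoothed", "write_spatial_profile", "read_spatial_profile",
    "write_associations", "read_associations",
    "read_config", "params_from_dict", "params_to_dict",
    "write_fit_result", "write_json",
]


def read_roi_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ROI_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"ROI table {path} lacks columns {missing}")
    return df


def write_roi_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_profiles(profiles: list[PartitionProfile], path) -> None:
    rows = []
    for p in profiles:
        for k in range(p.n_partitions):
            rows.append(
                {
                    "target": p.target,
                    "compartment": p.compartment,
                    "patient": p.patient,
                    "scheme": p.scheme,
                    "partition": k + 1,
                    "value": p.values[k],
                    "count": int(p.counts[k]),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_profiles(path) -> list[PartitionProfile]:
    df = pd.read_csv(path, sep="\t")
    profiles = []
    for (target, compartment, patient, scheme), grp in df.groupby(
        ["target", "compartment", "patient", "scheme"], sort=True
    ):
        grp = grp.sort_values("partition")
        profiles.append(
            PartitionProfile(
                scheme=scheme,
                values=grp["value"].to_numpy(dtype=float),
                counts=grp["count"].to_numpy(dtype=int),
                target=str(target),
                compartment=str(compartment),
                patient=str(patient),
            )
        )
    return profiles


def write_smoothed(curves: dict[str, SmoothedProfile], path) -> None:
    """Write loess curves as CSV with columns series, u, fitted_z."""
    frames = [
        pd.DataFrame({"series": name, "u": sp.u, "fitted_z": sp.fitted})
        for name, sp in curves.items()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_spatial_profile(profile: SpatialSteadyState, path) -> None:
    pd.DataFrame(
        {
            "d": profile.depths,
            "ca": profile.ca,
            "cam": profile.cam,
            "rafc": profile.states[0],
            "mekc": profile.states[1],
            "mekn": profile.states[2],
            "erkc": profile.states[3],
            "erkn": profile.states[4],
            "residual": profile.residuals,
            "converged": profile.converged,
        }
    ).to_csv(path, index=False)


def read_spatial_profile(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_associations(results: list[AssociationResult], path) -> None:
    rows = []
    for r in results:
        row = dataclasses.asdict(r)
        row["pair_a"], row["pair_b"] = row.pop("pair")
        rows.append(row)
    cols = [
        "pair_a", "pair_b", "pearson_r", "mutual_info", "null_lo", "null_hi",
        "null_mi_hi", "p_pearson", "p_mi", "significant_pearson",
        "significant_mi", "n_used",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_associations(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        cfg = yaml.safe_load(text)
    elif path.suffix == ".json":
        cfg = json.loads(text)
    else:
        raise ConfigError(f"config must be .yaml/.yml/.json, got {path.suffix}")
    if not isinstance(cfg, dict):
        raise ConfigError(f"config {path} must contain a mapping")
    return cfg


def params_from_dict(cfg: dict) -> CascadeParameters:
    """Build CascadeParameters from a flat mapping (hill.n / hill.ec50 nested)."""
    cfg = dict(cfg)
    hill_cfg = cfg.pop("hill", {})
    hill = NormalizedHillParams(**hill_cfg) if hill_cfg else NormalizedHillParams()
    valid = {f.name for f in dataclasses.fields(CascadeParameters)} - {"hill"}
    unknown = set(cfg) - valid
    if unknown:
        raise ConfigError(f"unknown cascade parameters: {sorted(unknown)}")
    return CascadeParameters(hill=hill, **cfg)


def params_to_dict(params: CascadeParameters) -> dict:
    d = dataclasses.asdict(params)
    return d


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, np.bool_):
            return bool(o)
        return super().default(o)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder) + "\n")


def write_fit_result(result: FitResult, path) -> None:
    d = dataclasses.asdict(result)
    d.pop("start_results")
    write_json(d, path)
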