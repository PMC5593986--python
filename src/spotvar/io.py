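"""File formats: trajectories (HDF5/CSV), traces and correlation curves
(CSV), diffusion-law tables (CSV) and experiment configs (YAML/JSON).

Conventions: lag times are stored in seconds in files and reported in
milliseconds in fit reports; spot diameters in diffusion-law tables are
in nm under a ``d_nm`` column (a ``d_um`` column is auto-converted).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .difflaw import DiffusionLawPoint
from .membrane import TrajectorySet
from .signal import CorrelationCurve, IntensityTrace

__all__ = [
    "save_trajectories_h5",
    "load_trajectories_h5",
    "trajectories_to_frame",
    "write_trace_csv",
    "read_trace_csv",
    "write_trace_h5",
    "read_trace_h5",
    "write_curve_csv",
    "read_curve_csv",
    "read_diffusion_law_csv",
    "write_diffusion_law_csv",
    "load_config",
    "TableFormatError",
]


class TableFormatError(ValueError):
    """A CSV table does not conform to the documented dialect."""


def save_trajectories_h5(path, traj: TrajectorySet) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("positions", data=traj.positions)
        meta = f.create_group("meta")
        meta.attrs["dt"] = traj.dt
        meta.attrs["box_edge"] = traj.box_edge
        meta.attrs["model_tag"] = traj.model_tag


def load_trajectories_h5(path) -> TrajectorySet:
    import h5py

    with h5py.File(path, "r") as f:
        return TrajectorySet(
            positions=f["positions"][...],
            dt=float(f["meta"].attrs["dt"]),
            box_edge=float(f["meta"].attrs["box_edge"]),
            model_tag=str(f["meta"].attrs["model_tag"]),
        )


def trajectories_to_frame(traj: TrajectorySet) -> pd.DataFrame:
    """Long-format view: columns particle, step, x, y (um)."""
    n_steps, n_part, _ = traj.positions.shape
    step, particle = np.meshgrid(
        np.arange(n_steps), np.arange(n_part), indexing="ij"
    )
    return pd.DataFrame(
        {
            "particle": particle.ravel(),
            "step": step.ravel(),
            "x": traj.positions[..., 0].ravel(),
            "y": traj.positions[..., 1].ravel(),
        }
    )


def write_trace_h5(path, trace: IntensityTrace) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("intensity", data=trace.values)
        f.attrs["dt_sample"] = trace.dt_sample


def read_trace_h5(path) -> IntensityTrace:
    import h5py

    with h5py.File(path, "r") as f:
        return IntensityTrace(f["intensity"][...], float(f.attrs["dt_sample"]))


def write_trace_csv(path, trace: IntensityTrace) -> None:
    t = np.arange(trace.n_samples) * trace.dt_sample
    pd.DataFrame({"time": t, "intensity": trace.values}).to_csv(
        path, index=False
    )


def read_trace_csv(path) -> IntensityTrace:
    df = pd.read_csv(path)
    for col in ("time", "intensity"):
        if col not in df.columns:
            raise TableFormatError(f"trace CSV missing column '{col}'")
    t = df["time"].to_numpy(float)
    if len(t) < 2:
        raise TableFormatError("trace CSV needs at least two samples")
    dts = np.diff(t)
    if not np.allclose(dts, dts[0], rtol=1e-6):
        raise TableFormatError("trace CSV must be uniformly sampled")
    return IntensityTrace(df["intensity"].to_numpy(float), float(dts[0]))


def write_curve_csv(path, curve: CorrelationCurve) -> None:
    data = {"lag_s": curve.lags, "G": curve.G}
    if curve.sem is not None:
        data["sem"] = curve.sem
    pd.DataFrame(data).to_csv(path, index=False)


def read_curve_csv(path) -> CorrelationCurve:
    df = pd.read_csv(path)
    for col in ("lag_s", "G"):
        if col not in df.columns:
            raise TableFormatError(f"curve CSV missing column '{col}'")
    sem = df["sem"].to_numpy(float) if "sem" in df.columns else None
    return CorrelationCurve(
        df["lag_s"].to_numpy(float), df["G"].to_numpy(float), sem
    )


def write_diffusion_law_csv(path, points) -> None:
    pd.DataFrame(
        {
            "d_nm": [p.d for p in points],
            "tau_ms": [p.tau_D for p in points],
            "tau_se_ms": [p.tau_se for p in points],
        }
    ).to_csv(path, index=False)


def read_diffusion_law_csv(path) -> "list[DiffusionLawPoint]":
    """Parse a diffusion-law table.

    Dialect: columns ``d_nm`` (or ``d_um``, auto-converted), ``tau_ms``
    and optionally ``tau_se_ms``.  Malformed rows are rejected with their
    line numbers (1-based, header = line 1).
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # header-only / empty / unreadable
        raise TableFormatError(f"cannot parse {path}: {exc}") from exc
    if "d_nm" in df.columns:
        d = df["d_nm"].to_numpy(float)
    elif "d_um" in df.columns:
        d = df["d_um"].to_numpy(float) * 1e3
    else:
        raise TableFormatError("diffusion-law CSV needs a d_nm or d_um column")
    if "tau_ms" not in df.columns:
        raise TableFormatError("diffusion-law CSV needs a tau_ms column")
    if len(df) == 0:
        raise TableFormatError("diffusion-law CSV has no data rows")
    tau = df["tau_ms"].to_numpy(float)
    se = (
        df["tau_se_ms"].to_numpy(float)
        if "tau_se_ms" in df.columns
        else np.full(len(df), np.nan)
    )
    points = []
    bad: list[int] = []
    for i in range(len(df)):
        line_no = i + 2
        if not (np.isfinite(d[i]) and np.isfinite(tau[i])
                and d[i] > 0 and tau[i] > 0):
            bad.append(line_no)
            continue
        tau_se = float(se[i]) if np.isfinite(se[i]) and se[i] > 0 else None
        points.append(DiffusionLawPoint(float(d[i]), float(tau[i]), tau_se))
    if bad:
        raise TableFormatError(
            f"malformed diffusion-law rows at lines {bad}"
        )
    return points


def load_config(path) -> dict:
    """Load a YAML or JSON experiment config as a dict."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    import yaml

    return yaml.safe_load(text)
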