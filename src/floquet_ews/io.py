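"""Readers and writers for the package's on-disk formats.

Time series travel as CSV (columns ``time,value``, 17-significant-digit
floats, so write/read round-trips are exact); fields and spatial modes as
NetCDF (dims ``time, y, x``, written through xarray's scipy backend);
eigenvalue tracks as CSV plus a JSON summary; configuration as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .series import SpatioTemporalField, UniformSeries
from .tracking import EigenTrack

__all__ = [
    "write_series_csv",
    "read_series_csv",
    "write_field_netcdf",
    "read_field_netcdf",
    "write_eigentrack_csv",
    "write_summary_json",
    "write_mode_netcdf",
    "write_config_yaml",
    "read_config_yaml",
]

_FLOAT_FMT = "%.17g"


def write_series_csv(series: UniformSeries, path: str | Path) -> None:
    df = pd.DataFrame({"time": series.times, "value": series.values})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_series_csv(path: str | Path) -> UniformSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("time", "value"):
        if col not in df.columns:
            raise ValueError(f"malformed series CSV: missing column {col!r}")
    return UniformSeries(df["time"].to_numpy(float), df["value"].to_numpy(float))


def write_field_netcdf(
    field: SpatioTemporalField,
    path: str | Path,
    var_name: str = "value",
) -> None:
    ny, nx = field.grid_shape
    ds = xr.Dataset(
        {
            var_name: (("time", "y", "x"), field.to_cube()),
            "valid": (("y", "x"), field.valid_cells.astype(np.int8)),
        },
        coords={"time": field.times, "y": np.arange(ny), "x": np.arange(nx)},
    )
    ds.to_netcdf(path, engine="scipy")


def read_field_netcdf(path: str | Path, var_name: str = "value") -> SpatioTemporalField:
    with xr.open_dataset(path, engine="scipy") as ds:
        if var_name not in ds:
            raise ValueError(f"malformed field NetCDF: missing variable {var_name!r}")
        for dim in ("time", "y", "x"):
            if dim not in ds[var_name].dims:
                raise ValueError(f"malformed field NetCDF: missing dimension {dim!r}")
        cube = ds[var_name].values
        times = ds["time"].values.astype(float)
        valid = ds["valid"].values.astype(bool) if "valid" in ds else None
    return SpatioTemporalField.from_cube(times, cube, valid)


def write_eigentrack_csv(track: EigenTrack, path: str | Path) -> None:
    """Long-format dump: one row per (window, eigenvalue) with track id/label."""
    member: dict[tuple[int, int], tuple[int, str]] = {}
    for tid, chain in enumerate(track.tracks):
        lab = track.labels[tid] if track.labels else ""
        for we in chain:
            member[we] = (tid, lab)
    rows = []
    for w, fit in enumerate(track.fits):
        for e, rho in enumerate(fit.eigenvalues):
            tid, lab = member.get((w, e), (-1, ""))
            rows.append(
                {
                    "window_time": track.window_times[w],
                    "eig_real": rho.real,
                    "eig_imag": rho.imag,
                    "magnitude": abs(rho),
                    "track_id": tid,
                    "label": lab,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_summary_json(track: EigenTrack, path: str | Path) -> None:
    terminal: dict[str, float] = {}
    for tid, chain in enumerate(track.tracks):
        lab = track.labels[tid] if track.labels else str(tid)
        w, e = chain[-1]
        mag = float(abs(track.fits[w].eigenvalues[e]))
        if lab not in terminal or mag > terminal[lab]:
            terminal[lab] = mag
    payload = {
        "crossing_time": track.crossing_time,
        "n_windows": track.n_windows,
        "n_skipped": len(track.skipped),
        "terminal_magnitudes": terminal,
        "filtered_max_last": float(track.filtered_max[-1])
        if track.filtered_max is not None
        else None,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_mode_netcdf(grid_map: np.ndarray, path: str | Path,
                      var_name: str = "mode_magnitude") -> None:
    ny, nx = grid_map.shape
    ds = xr.Dataset(
        {var_name: (("y", "x"), np.asarray(grid_map, float))},
        coords={"y": np.arange(ny), "x": np.arange(nx)},
    )
    ds.to_netcdf(path, engine="scipy")


def write_config_yaml(config: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=False))


def read_config_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
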