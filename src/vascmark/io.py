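"""Readers and writers for the delimited-text interchange formats.

All files are comma-separated UTF-8 with a header row and '.' decimal:
curves as (time_ms, velocity_cms), centerlines as (x_mm, y_mm[, z_mm]),
contour stacks as (slice, ring, vertex_index, x_mm, y_mm), stenosis grades
as (patient_id, segment_id, reading_type, value), and the cohort table with
blank cells marking invalid/unavailable values.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .carotid import CarotidSlice, ContourStack
from .errors import ConfigurationError, DataError
from .pwv import VelocityTimeCurve


def _read_table(path, required_columns) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise DataError(f"{path}: file not found")
    except Exception as exc:  # malformed CSV
        raise DataError(f"{path}: cannot parse ({exc})")
    missing = set(required_columns) - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def _require_numeric(df: pd.DataFrame, columns, path) -> None:
    for col in columns:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() & df[col].notna()
        if bad.any():
            line = int(df.index[bad][0]) + 2  # header is line 1
            raise DataError(f"{path}: line {line}, field {col!r}: not a number")
        df[col] = values


def read_curve(path, rr_interval: float | None = None, site_label: str = "") -> VelocityTimeCurve:
    df = _read_table(path, ("time_ms", "velocity_cms"))
    _require_numeric(df, ("time_ms", "velocity_cms"), path)
    t = df["time_ms"].to_numpy(dtype=float)
    if rr_interval is None:
        rr_interval = float(t[-1] + (t[1] - t[0]))
    return VelocityTimeCurve(t, df["velocity_cms"].to_numpy(dtype=float),
                             rr_interval, site_label)


def write_curve(curve: VelocityTimeCurve, path) -> None:
    pd.DataFrame({"time_ms": curve.time, "velocity_cms": curve.velocity}).to_csv(
        path, index=False
    )


def read_centerline(path) -> np.ndarray:
    df = _read_table(path, ("x_mm", "y_mm"))
    cols = ["x_mm", "y_mm"] + (["z_mm"] if "z_mm" in df.columns else [])
    _require_numeric(df, cols, path)
    return df[cols].to_numpy(dtype=float)


def write_centerline(points: np.ndarray, path) -> None:
    points = np.asarray(points, dtype=float)
    cols = ["x_mm", "y_mm", "z_mm"][: points.shape[1]]
    pd.DataFrame(points, columns=cols).to_csv(path, index=False)


def read_contour_stack(path) -> ContourStack:
    df = _read_table(path, ("slice", "ring", "vertex_index", "x_mm", "y_mm"))
    _require_numeric(df, ("slice", "vertex_index", "x_mm", "y_mm"), path)
    bad_ring = ~df["ring"].isin(("inner", "outer"))
    if bad_ring.any():
        line = int(df.index[bad_ring][0]) + 2
        raise DataError(f"{path}: line {line}, field 'ring': must be inner|outer")
    slices = []
    for idx in range(1, 9):
        sub = df[df["slice"] == idx]
        if sub.empty:
            raise DataError(f"{path}: slice {idx} missing from contour stack")
        rings = {}
        for ring in ("inner", "outer"):
            pts = sub[sub["ring"] == ring].sort_values("vertex_index")
            if len(pts) < 3:
                raise DataError(f"{path}: slice {idx} {ring} ring has <3 vertices")
            rings[ring] = pts[["x_mm", "y_mm"]].to_numpy(dtype=float)
        slices.append(CarotidSlice(idx, rings["inner"], rings["outer"]))
    return ContourStack(tuple(slices))


def write_contour_stack(stack: ContourStack, path) -> None:
    rows = []
    for s in stack.slices:
        for ring, pts in (("inner", s.inner), ("outer", s.outer)):
            for k, (x, y) in enumerate(pts):
                rows.append((s.slice_index, ring, k, x, y))
    pd.DataFrame(rows, columns=["slice", "ring", "vertex_index", "x_mm", "y_mm"]).to_csv(
        path, index=False
    )


def read_grades(path) -> pd.DataFrame:
    df = _read_table(path, ("patient_id", "segment_id", "reading_type", "value"))
    _require_numeric(df, ("segment_id",), path)
    return df


def load_config_file(path) -> dict:
    path = Path(path)
    try:
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    except FileNotFoundError:
        raise ConfigurationError(f"{path}: config file not found")
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"{path}: invalid YAML ({exc})")
    if raw is None:
        return {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    return raw
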