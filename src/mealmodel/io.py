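"""Readers and writers for the package's exchange formats.

Timecourses travel as two-column CSV (``time_min,value``); parameter
sets as flat key-value YAML (one key per model symbol); results as JSON
or CSV.  Units are fixed package-wide and never auto-detected.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gastric_fit import AcFitResult, Timecourse
from .model_core import PARAMETER_FIELDS, ModelParameters
from .sensitivity import SensitivityResult
from .simulator import Trajectory

__all__ = [
    "read_timecourse",
    "write_timecourse",
    "read_params",
    "write_params",
    "write_results",
    "write_trajectory",
    "read_s1_workbook",
]


def read_timecourse(
    path,
    time_col: str = "time_min",
    value_col: str = "value",
    analyte: str = "",
) -> Timecourse:
    """Load an observed timecourse from CSV.

    A single pre-meal sample at a negative time (the -30-min baseline
    draw) is remapped to t=0, matching the modelling convention that the
    baseline defines the initial state.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    for col in (time_col, value_col):
        if col not in df.columns:
            raise ValueError(
                f"{path}: missing column {col!r}; found {list(df.columns)}"
            )
    times = df[time_col].to_numpy(dtype=float)
    values = df[value_col].to_numpy(dtype=float)

    neg = times < 0
    if neg.sum() == 1 and not np.any(times == 0):
        times = times.copy()
        times[neg] = 0.0
        order = np.argsort(times, kind="stable")
        times, values = times[order], values[order]
    elif neg.any():
        raise ValueError(
            f"{path}: negative sample times beyond a single pre-meal "
            "baseline are not supported"
        )

    dup = np.flatnonzero(np.diff(times) == 0)
    if len(dup):
        raise ValueError(
            f"{path}: duplicated time {times[dup[0]]} at row {dup[0] + 1}"
        )
    return Timecourse(times, values, analyte=analyte)


def write_timecourse(tc: Timecourse, path) -> None:
    pd.DataFrame({"time_min": tc.times, "value": tc.values}).to_csv(
        path, index=False
    )


def read_params(path) -> ModelParameters:
    """Flat key-value YAML → parameter set (unknown keys rejected)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a flat key: value mapping")
    return ModelParameters.from_dict(data)


def write_params(params: ModelParameters, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        if hasattr(obj, "to_dict"):
            return _to_jsonable(obj.to_dict())
        return _to_jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_to_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_results(result, path, format: str = "json") -> None:
    """Serialize a result object (fit outcome, sensitivity table, ...).

    JSON is lossless for round-tripping; CSV is supported for tabular
    results (a list of sensitivity rows, or any list of flat records).
    """
    path = Path(path)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(_to_jsonable(result), fh, indent=2)
            fh.write("\n")
    elif format == "csv":
        rows = result if isinstance(result, (list, tuple)) else [result]
        records = []
        for row in rows:
            rec = _to_jsonable(row)
            if not isinstance(rec, dict):
                raise TypeError(f"cannot tabulate {type(row).__name__} as CSV")
            records.append(rec)
        pd.DataFrame.from_records(records).to_csv(path, index=False, float_format="%.12g")
    else:
        raise ValueError(f"unknown format {format!r}; use 'json' or 'csv'")


def write_trajectory(traj: Trajectory, path) -> None:
    traj.to_frame().to_csv(path, index=False, float_format="%.10g")


def read_s1_workbook(path, sheet_map=None) -> dict:
    """Read a supplementary-style XLSX of per-animal timecourses.

    ``sheet_map`` maps analyte name -> (sheet, time column, one value
    column per animal).  Returns {animal: {analyte: Timecourse}}.  The
    layout must be given explicitly; no guessing.
    """
    import openpyxl  # local import: only needed for workbook input

    if sheet_map is None:
        raise ValueError("sheet_map (analyte -> sheet/column layout) is required")
    wb = openpyxl.load_workbook(path, data_only=True)
    out: dict = {}
    for analyte, spec in sheet_map.items():
        ws = wb[spec["sheet"]]
        header = [c.value for c in next(ws.iter_rows(max_row=1))]
        cols = {name: header.index(name) for name in
                [spec["time"], *spec["animals"].values()]}
        rows = [[c.value for c in row] for row in ws.iter_rows(min_row=2)]
        times = [r[cols[spec["time"]]] for r in rows if r[cols[spec["time"]]] is not None]
        for animal, col in spec["animals"].items():
            values = [r[cols[col]] for r in rows[: len(times)]]
            times_arr = np.asarray(times, dtype=float)
            values_arr = np.asarray(values, dtype=float)
            neg = times_arr < 0
            if neg.sum() == 1 and not np.any(times_arr == 0):
                times_arr[neg] = 0.0
                order = np.argsort(times_arr, kind="stable")
                times_arr, values_arr = times_arr[order], values_arr[order]
            out.setdefault(animal, {})[analyte] = Timecourse(
                times_arr, values_arr, analyte=analyte
            )
    return out
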