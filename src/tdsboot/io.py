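"""Reading and writing TDS tasks, curves, bands and Markov model specs.

Formats are deliberately plain text:

* task event CSV (long form): columns ``task_id, start_time, stop_time,
  event_time, descriptor``, one row per selection event;
* task JSON: a list of ``{task_id, start, stop, events: [{t, descriptor}]}``;
* curve CSV (wide form): a ``# n_tasks=N`` metadata line, then ``t_prime``
  plus one column per descriptor;
* band CSV: ``# key=value`` metadata lines (method, band, m, q, seed), then
  ``t_prime`` plus ``<descriptor>_lower`` / ``<descriptor>_upper`` columns;
* model spec JSON/YAML: ``descriptors, initial, phases: [{first_step,
  matrix}], n_steps``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .bootstrap import UncertaintyBands
from .core import TaskRecord, TDSCurveSet, TDSValidationError, TimeGrid
from .markov import MarkovTDSModel, Phase

_TASK_COLUMNS = ["task_id", "start_time", "stop_time", "event_time", "descriptor"]


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("csv", "json", "yaml", "yml"):
        return "yaml" if suffix == "yml" else suffix
    raise TDSValidationError(f"cannot infer format from {path.name!r}; pass format explicitly")


# --- tasks ---------------------------------------------------------------------


def read_tasks(path: str | Path, fmt: str | None = None) -> list[TaskRecord]:
    """Load task records from long-form CSV or JSON; validates every record."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        return _read_tasks_csv(path)
    if fmt == "json":
        return _read_tasks_json(path)
    raise TDSValidationError(f"unsupported task format {fmt!r}")


def _read_tasks_csv(path: Path) -> list[TaskRecord]:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise TDSValidationError(f"{path}: file is empty") from None
    missing = [c for c in _TASK_COLUMNS if c not in df.columns]
    if missing:
        raise TDSValidationError(f"{path}: missing required columns {missing}")
    if df.empty:
        raise TDSValidationError(f"{path}: no event rows")
    tasks = []
    # groupby(sort=False) preserves file order of tasks; event order within a
    # task is taken as-is and validated, never silently re-sorted.
    for task_id, rows in df.groupby("task_id", sort=False):
        starts = rows["start_time"].unique()
        stops = rows["stop_time"].unique()
        if len(starts) != 1 or len(stops) != 1:
            raise TDSValidationError(
                f"task {task_id!r}: inconsistent start_time/stop_time across rows"
            )
        events = tuple(zip(rows["descriptor"].astype(str), rows["event_time"].astype(float)))
        tasks.append(TaskRecord(str(task_id), float(starts[0]), float(stops[0]), events))
    return tasks


def _read_tasks_json(path: Path) -> list[TaskRecord]:
    text = path.read_text()
    if not text.strip():
        raise TDSValidationError(f"{path}: file is empty")
    raw = json.loads(text)
    if not isinstance(raw, list) or not raw:
        raise TDSValidationError(f"{path}: expected a non-empty list of task objects")
    tasks = []
    for obj in raw:
        try:
            events = tuple((e["descriptor"], float(e["t"])) for e in obj["events"])
            tasks.append(
                TaskRecord(str(obj["task_id"]), float(obj["start"]), float(obj["stop"]), events)
            )
        except (KeyError, TypeError) as exc:
            raise TDSValidationError(
                f"{path}: malformed task object {obj.get('task_id', '?')!r}: {exc}"
            ) from None
    return tasks


def write_tasks(tasks: Sequence[TaskRecord], path: str | Path, fmt: str | None = None) -> None:
    """Write task records; round-trips with :func:`read_tasks`."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if len(tasks) == 0:
        raise TDSValidationError("refusing to write an empty task list")
    if fmt == "csv":
        rows = [
            {
                "task_id": t.task_id,
                "start_time": t.start_time,
                "stop_time": t.stop_time,
                "event_time": time,
                "descriptor": d,
            }
            for t in tasks
            for d, time in t.events
        ]
        # %.17g keeps event times round-trip exact through text
        pd.DataFrame(rows, columns=_TASK_COLUMNS).to_csv(
            path, index=False, float_format="%.17g"
        )
    elif fmt == "json":
        payload = [
            {
                "task_id": t.task_id,
                "start": t.start_time,
                "stop": t.stop_time,
                "events": [{"t": time, "descriptor": d} for d, time in t.events],
            }
            for t in tasks
        ]
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise TDSValidationError(f"unsupported task format {fmt!r}")


# --- curves --------------------------------------------------------------------


def write_curves(curves: TDSCurveSet, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# n_tasks={curves.n_tasks}\n")
        curves.to_frame().to_csv(fh, index=False)


def read_curves(path: str | Path) -> TDSCurveSet:
    path = Path(path)
    n_tasks = 0
    with path.open() as fh:
        first = fh.readline()
        if first.startswith("# n_tasks="):
            n_tasks = int(first.split("=", 1)[1])
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    if "t_prime" not in df.columns:
        raise TDSValidationError(f"{path}: missing t_prime column")
    descriptors = tuple(c for c in df.columns if c != "t_prime")
    grid = TimeGrid(df["t_prime"].to_numpy())
    values = df[list(descriptors)].to_numpy().T
    return TDSCurveSet(descriptors, grid, values, n_tasks=n_tasks)


# --- bands ---------------------------------------------------------------------


def write_bands(
    bands: UncertaintyBands,
    path: str | Path,
    m: int | None = None,
    q: int | None = None,
    seed: int | None = None,
) -> None:
    path = Path(path)
    meta = {"method": bands.method, "band": bands.band, "m": m, "q": q, "seed": seed}
    data = {"t_prime": bands.grid.points}
    for j, d in enumerate(bands.descriptors):
        data[f"{d}_lower"] = bands.lower[j]
        data[f"{d}_upper"] = bands.upper[j]
    with path.open("w") as fh:
        for key, val in meta.items():
            if val is not None:
                fh.write(f"# {key}={val}\n")
        pd.DataFrame(data).to_csv(fh, index=False)


def read_bands(path: str | Path) -> UncertaintyBands:
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open() as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("# "):
            key, _, val = line[2:].strip().partition("=")
            meta[key] = val
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    grid = TimeGrid(df["t_prime"].to_numpy())
    descriptors = tuple(
        c[: -len("_lower")] for c in df.columns if c.endswith("_lower")
    )
    lower = np.vstack([df[f"{d}_lower"].to_numpy() for d in descriptors])
    upper = np.vstack([df[f"{d}_upper"].to_numpy() for d in descriptors])
    return UncertaintyBands(
        descriptors,
        grid,
        lower,
        upper,
        band=meta.get("band", "ci95"),
        method=meta.get("method", "bootstrap"),
    )


# --- model specs ---------------------------------------------------------------


def model_to_dict(model: MarkovTDSModel) -> dict:
    return {
        "descriptors": list(model.descriptors),
        "initial": [float(x) for x in model.initial_distribution],
        "phases": [
            {"first_step": ph.first_step, "matrix": ph.matrix.tolist()} for ph in model.phases
        ],
        "n_steps": model.n_steps,
    }


def model_from_dict(spec: dict) -> MarkovTDSModel:
    try:
        phases = tuple(
            Phase(int(ph["first_step"]), np.asarray(ph["matrix"], dtype=float))
            for ph in spec["phases"]
        )
        return MarkovTDSModel(
            tuple(spec["descriptors"]),
            np.asarray(spec["initial"], dtype=float),
            phases,
            n_steps=int(spec["n_steps"]),
        )
    except (KeyError, TypeError) as exc:
        raise TDSValidationError(f"malformed model spec: {exc}") from None


def write_model(model: MarkovTDSModel, path: str | Path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, fmt)
    spec = model_to_dict(model)
    if fmt == "json":
        path.write_text(json.dumps(spec, indent=1))
    elif fmt == "yaml":
        path.write_text(yaml.safe_dump(spec, sort_keys=False))
    else:
        raise TDSValidationError(f"unsupported model format {fmt!r}")


def read_model(path: str | Path, fmt: str | None = None) -> MarkovTDSModel:
    """Load and validate a model spec; row-sum violations name the bad rows."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    text = path.read_text()
    if not text.strip():
        raise TDSValidationError(f"{path}: file is empty")
    if fmt == "json":
        spec = json.loads(text)
    elif fmt == "yaml":
        spec = yaml.safe_load(text)
    else:
        raise TDSValidationError(f"unsupported model format {fmt!r}")
    return model_from_dict(spec)
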