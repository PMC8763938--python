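"""Readers/writers for the package's on-disk formats.

Recordings round-trip through an HDF5 container (datasets ``/raw``, ``/fs``,
``/carriers``) or a plain CSV with a TOML sidecar; cell maps and event
tables are TSV; sweep sets are wide CSV plus TOML sidecar; morphologies are
standard SWC; maze tracks are CSV with a TOML geometry file.  Every reader
validates its schema and raises :class:`IOValidationError` naming the
offending row or field — nothing loads partially and silently.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .photometry import Carrier, ConditionedTrace, ModulatedRecording

__all__ = [
    "IOValidationError",
    "write_recording_h5", "read_recording_h5",
    "write_recording_csv", "read_recording_csv",
    "write_cellmap_tsv", "read_cellmap_tsv",
    "write_events_tsv", "read_events_tsv",
    "write_trace_csv", "read_trace_csv",
    "write_sweeps_csv", "read_sweeps_csv",
    "write_track_csv", "read_track_csv",
    "write_swc", "read_swc",
    "toml_dumps",
    "validate_io",
]


class IOValidationError(ValueError):
    """Schema violation in an input file; ``details`` names row/field."""

    def __init__(self, message: str, **details):
        super().__init__(message)
        self.details = details


# ---------------------------------------------------------------------------
# minimal TOML emitter (flat sections of scalars/lists; read with tomllib)
# ---------------------------------------------------------------------------

def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float, np.integer, np.floating)):
        return repr(float(v)) if isinstance(v, (float, np.floating)) else str(int(v))
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple, np.ndarray)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot TOML-encode {type(v)}")


def toml_dumps(data: dict) -> str:
    """Serialize a {key: scalar/list} or {section: {key: ...}} dict to TOML."""
    top, sections = [], []
    for k, v in data.items():
        if isinstance(v, dict):
            sections.append(f"[{k}]")
            sections.extend(f"{kk} = {_toml_value(vv)}" for kk, vv in v.items())
            sections.append("")
        else:
            top.append(f"{k} = {_toml_value(v)}")
    return "\n".join(top + [""] + sections) + "\n"


# ---------------------------------------------------------------------------
# modulated recordings
# ---------------------------------------------------------------------------

def write_recording_h5(path, rec: ModulatedRecording) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("raw", data=rec.samples)
        f.create_dataset("fs", data=rec.fs_raw)
        f.create_dataset("carriers", data=np.asarray([c.frequency for c in rec.carriers]))
        f.attrs["carrier_roles"] = [c.role for c in rec.carriers]
        f.attrs["sensors"] = list(rec.sensors)
        f.attrs["start_time"] = rec.start_time


def read_recording_h5(path) -> ModulatedRecording:
    with h5py.File(path, "r") as f:
        for ds in ("raw", "fs", "carriers"):
            if ds not in f:
                raise IOValidationError(f"recording container missing /{ds}", field=ds)
        freqs = np.asarray(f["carriers"])
        roles = [r if isinstance(r, str) else r.decode() for r in f.attrs["carrier_roles"]]
        sensors = tuple(s if isinstance(s, str) else s.decode() for s in f.attrs["sensors"])
        return ModulatedRecording(
            fs_raw=float(np.asarray(f["fs"])),
            samples=np.asarray(f["raw"]),
            carriers=tuple(Carrier(float(fq), r) for fq, r in zip(freqs, roles)),
            sensors=sensors,
            start_time=float(f.attrs.get("start_time", 0.0)),
        )


def write_recording_csv(path, rec: ModulatedRecording) -> None:
    """CSV of (time, one column per sensor) plus a ``<path>.toml`` sidecar."""
    path = Path(path)
    t = rec.start_time + np.arange(rec.n_samples) / rec.fs_raw
    df = pd.DataFrame({"time": t})
    for role, row in zip(rec.sensors, rec.samples):
        df[role] = row
    df.to_csv(path, index=False)
    sidecar = {
        "fs_raw": rec.fs_raw,
        "start_time": rec.start_time,
        "sensors": list(rec.sensors),
        "carriers": {c.role: c.frequency for c in rec.carriers},
    }
    path.with_suffix(path.suffix + ".toml").write_text(toml_dumps(sidecar))


def read_recording_csv(path) -> ModulatedRecording:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".toml")
    if not sidecar_path.exists():
        raise IOValidationError("recording CSV needs a .toml sidecar", field="sidecar")
    meta = tomllib.loads(sidecar_path.read_text())
    df = pd.read_csv(path)
    sensors = tuple(meta["sensors"])
    for col in ("time",) + sensors:
        if col not in df.columns:
            raise IOValidationError(f"recording CSV missing column {col!r}", field=col)
    return ModulatedRecording(
        fs_raw=float(meta["fs_raw"]),
        samples=np.vstack([df[s].to_numpy(dtype=float) for s in sensors]),
        carriers=tuple(Carrier(float(f), r) for r, f in meta["carriers"].items()),
        sensors=sensors,
        start_time=float(meta.get("start_time", 0.0)),
    )


# ---------------------------------------------------------------------------
# conditioned traces
# ---------------------------------------------------------------------------

def write_trace_csv(path, trace: ConditionedTrace) -> None:
    pd.DataFrame({"time": trace.times, "value": trace.values}).to_csv(path, index=False)
    Path(str(path) + ".toml").write_text(
        toml_dumps({"fs": trace.fs, "channel": trace.channel, "stage": trace.stage,
                    "units": trace.units, "t0": trace.t0})
    )


def read_trace_csv(path) -> ConditionedTrace:
    meta_path = Path(str(path) + ".toml")
    meta = tomllib.loads(meta_path.read_text()) if meta_path.exists() else {}
    df = pd.read_csv(path)
    if "value" not in df.columns:
        raise IOValidationError("trace CSV missing 'value' column", field="value")
    fs = float(meta.get("fs", 0.0))
    if fs <= 0:
        t = df["time"].to_numpy(dtype=float)
        if t.size < 2:
            raise IOValidationError("cannot infer sampling rate", field="fs")
        fs = 1.0 / float(np.median(np.diff(t)))
    return ConditionedTrace(
        fs=fs,
        values=df["value"].to_numpy(dtype=float),
        channel=meta.get("channel", "green"),
        stage=meta.get("stage", "downsampled"),
        units=meta.get("units", "au"),
        t0=float(meta.get("t0", df["time"].iloc[0] if "time" in df.columns else 0.0)),
    )


# ---------------------------------------------------------------------------
# cell maps and event tables
# ---------------------------------------------------------------------------

def write_cellmap_tsv(path, cellmap) -> None:
    cellmap.cells.to_csv(path, sep="\t", index=False)


def read_cellmap_tsv(path):
    from .layers import CellMap

    df = pd.read_csv(path, sep="\t")
    for col in ("radial", "longitudinal"):
        if col not in df.columns:
            raise IOValidationError(f"cell map missing column {col!r}", field=col)
        bad = df.index[(df[col] < 0) | (df[col] > 1)]
        if len(bad):
            raise IOValidationError(
                f"{col} out of [0, 1] at row {int(bad[0])} (value {df[col].iloc[bad[0]]})",
                field=col, row=int(bad[0]),
            )
    flags = tuple(c for c in df.columns if df[c].dtype == bool or set(df[c].unique()) <= {0, 1, True, False})
    flags = tuple(f for f in flags if f not in ("radial", "longitudinal", "slice"))
    for f in flags:
        df[f] = df[f].astype(bool)
    return CellMap(cells=df, tracer_flags=flags)


def write_events_tsv(path, events: pd.DataFrame) -> None:
    events.to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> pd.DataFrame:
    from .perievent import validate_events

    df = pd.read_csv(path, sep="\t")
    try:
        return validate_events(df)
    except ValueError as e:
        raise IOValidationError(str(e)) from e


# ---------------------------------------------------------------------------
# sweep sets
# ---------------------------------------------------------------------------

def write_sweeps_csv(path, sweeps) -> None:
    """Wide CSV (time + sweep_<i> columns) with a TOML sidecar."""
    path = Path(path)
    t = np.arange(sweeps.sweeps.shape[1]) / sweeps.fs
    df = pd.DataFrame({"time": t})
    for i, row in enumerate(sweeps.sweeps):
        df[f"sweep_{i}"] = row
    df.to_csv(path, index=False)
    meta = {
        "fs": sweeps.fs,
        "stim_onset": sweeps.stim_onset,
        "holding_mv": sweeps.holding_mv if sweeps.holding_mv is not None else float("nan"),
    }
    if sweeps.pulse_ms is not None:
        meta["pulse_ms"] = np.atleast_1d(sweeps.pulse_ms).tolist()
    path.with_suffix(path.suffix + ".toml").write_text(toml_dumps(meta))


def read_sweeps_csv(path):
    from .cracm import SweepSet

    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".toml")
    if not sidecar.exists():
        raise IOValidationError("sweep CSV needs a .toml sidecar", field="sidecar")
    meta = tomllib.loads(sidecar.read_text())
    df = pd.read_csv(path)
    cols = [c for c in df.columns if c.startswith("sweep_")]
    if not cols:
        raise IOValidationError("sweep CSV has no sweep_<i> columns", field="sweeps")
    pulse = meta.get("pulse_ms")
    return SweepSet(
        sweeps=np.vstack([df[c].to_numpy(dtype=float) for c in cols]),
        fs=float(meta["fs"]),
        stim_onset=float(meta["stim_onset"]),
        pulse_ms=np.asarray(pulse, dtype=float) if isinstance(pulse, list) else pulse,
        holding_mv=meta.get("holding_mv"),
    )


# ---------------------------------------------------------------------------
# maze tracks
# ---------------------------------------------------------------------------

def write_track_csv(path, track) -> None:
    path = Path(path)
    pd.DataFrame({"t": track.t, "x": track.x, "y": track.y}).to_csv(path, index=False)
    geom = {name: {"xy": list(np.asarray(poly.exterior.coords).ravel())}
            for name, poly in track.geometry.items()}
    meta = {"epochs": [list(e) for e in track.epochs]} if track.epochs else {}
    meta.update(geom)
    path.with_suffix(path.suffix + ".toml").write_text(toml_dumps(meta))


def read_track_csv(path):
    from shapely.geometry import Polygon

    from .epm import EPMTrack

    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".toml")
    if not sidecar.exists():
        raise IOValidationError("track CSV needs a .toml geometry sidecar", field="sidecar")
    meta = tomllib.loads(sidecar.read_text())
    df = pd.read_csv(path)
    for col in ("t", "x", "y"):
        if col not in df.columns:
            raise IOValidationError(f"track CSV missing column {col!r}", field=col)
    geometry = {}
    for name, val in meta.items():
        if isinstance(val, dict) and "xy" in val:
            xy = np.asarray(val["xy"], dtype=float).reshape(-1, 2)
            geometry[name] = Polygon(xy)
    epochs = [tuple(e) for e in meta.get("epochs", [])] or None
    return EPMTrack(
        t=df["t"].to_numpy(dtype=float),
        x=df["x"].to_numpy(dtype=float),
        y=df["y"].to_numpy(dtype=float),
        geometry=geometry,
        epochs=epochs,
    )


# ---------------------------------------------------------------------------
# SWC morphologies
# ---------------------------------------------------------------------------

def write_swc(path, morph) -> None:
    lines = []
    if morph.reference_line is not None:
        (x1, y1), (x2, y2) = morph.reference_line
        lines.append(f"# reference_line {x1} {y1} {x2} {y2}")
    for _, n in morph.nodes.iterrows():
        lines.append(
            f"{int(n['id'])} {int(n['type'])} {n['x']:.4f} {n['y']:.4f} {n['z']:.4f} "
            f"{n['radius']:.4f} {int(n['parent'])}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_swc(path):
    from .layers import Morphology

    rows = []
    reference = None
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split()
            if parts and parts[0] == "reference_line" and len(parts) == 5:
                x1, y1, x2, y2 = map(float, parts[1:])
                reference = ((x1, y1), (x2, y2))
            continue
        parts = line.split()
        if len(parts) != 7:
            raise IOValidationError(f"SWC line {lineno}: expected 7 fields, got {len(parts)}", row=lineno)
        try:
            rows.append(
                (int(parts[0]), int(parts[1]), float(parts[2]), float(parts[3]),
                 float(parts[4]), float(parts[5]), int(parts[6]))
            )
        except ValueError as e:
            raise IOValidationError(f"SWC line {lineno}: {e}", row=lineno) from e
    df = pd.DataFrame(rows, columns=["id", "type", "x", "y", "z", "radius", "parent"])
    try:
        return Morphology(nodes=df, reference_line=reference)
    except ValueError as e:
        raise IOValidationError(str(e)) from e


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

_READERS = {
    "recording_h5": read_recording_h5,
    "recording_csv": read_recording_csv,
    "trace_csv": read_trace_csv,
    "cellmap": read_cellmap_tsv,
    "events": read_events_tsv,
    "sweeps": read_sweeps_csv,
    "track": read_track_csv,
    "swc": read_swc,
}


def validate_io(path, fmt: str):
    """Parse ``path`` as ``fmt``, returning the object or raising
    :class:`IOValidationError` with row/field context."""
    path = Path(path)
    if not path.exists():
        raise IOValidationError(f"no such file: {path}", field="path")
    if fmt not in _READERS:
        raise IOValidationError(f"unknown format {fmt!r}; known: {sorted(_READERS)}", field="format")
    try:
        return _READERS[fmt](path)
    except IOValidationError:
        raise
    except (ValueError, KeyError, OSError) as e:
        raise IOValidationError(f"failed to parse {path} as {fmt}: {e}") from e
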