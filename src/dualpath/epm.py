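"""Elevated-plus-maze zone classification, arm entries and closed-loop gating.

Head positions are classified frame-by-frame against five labelled maze
polygons (two open arms, two closed arms, centre); arm entries are debounced
runs in an arm class; per-epoch metrics cover open-arm dwell time and entry
probability.  The closed-loop gate reproduces the position-triggered latched
stimulation protocol: within the designated epoch light switches on in the
centre/open zones and latches until the first closed-arm frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely import contains_xy
from shapely.geometry import box

__all__ = [
    "EPMTrack",
    "GateTrace",
    "standard_epm_geometry",
    "zone_class",
    "default_epochs",
    "classify_zone",
    "detect_arm_entries",
    "open_arm_time_per_epoch",
    "entry_probability",
    "closed_loop_gate",
]

ZONE_NAMES = ("open1", "open2", "closed1", "closed2", "centre")


def zone_class(zone: str) -> str:
    """Collapse a detailed zone name to {open, closed, centre, off_maze}."""
    if zone.startswith("open"):
        return "open"
    if zone.startswith("closed"):
        return "closed"
    return zone


def standard_epm_geometry(arm_length: float = 30.0, arm_width: float = 6.0) -> dict:
    """Plus-maze polygons: open arms along x, closed arms along y, centre at origin."""
    h = arm_width / 2.0
    return {
        "centre": box(-h, -h, h, h),
        "open1": box(h, -h, h + arm_length, h),
        "open2": box(-h - arm_length, -h, -h, h),
        "closed1": box(-h, h, h, h + arm_length),
        "closed2": box(-h, -h - arm_length, h, -h),
    }


def default_epochs(session_length: float = 540.0, n_epochs: int = 3) -> list[tuple[float, float]]:
    """Equal epochs tiling the session (default three 3-min epochs)."""
    edge = session_length / n_epochs
    return [(i * edge, (i + 1) * edge) for i in range(n_epochs)]


@dataclass
class EPMTrack:
    """Head-position track plus maze geometry and session epochs."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    geometry: dict
    epochs: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.size == self.x.size == self.y.size):
            raise ValueError("t, x, y must have equal length")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        for a, pa in enumerate(ZONE_NAMES):
            for pb in ZONE_NAMES[a + 1 :]:
                inter = self.geometry[pa].intersection(self.geometry[pb])
                if inter.area > 0:
                    raise ValueError(f"zones {pa!r} and {pb!r} overlap")
        if self.epochs is None:
            self.epochs = default_epochs(float(self.t[-1] - self.t[0] + self.frame_dt)) if self.t.size else []

    @property
    def frame_dt(self) -> float:
        return float(np.median(np.diff(self.t))) if self.t.size > 1 else 0.0

    @property
    def fs(self) -> float:
        return 1.0 / self.frame_dt


@dataclass
class GateTrace:
    """Boolean light-on series aligned to track frames."""

    on: np.ndarray
    t: np.ndarray
    stim_hz: float = 20.0
    log: list[dict] = field(default_factory=list)


def _interpolate_gaps(t: np.ndarray, v: np.ndarray, gap_limit: float) -> np.ndarray:
    """Linear interpolation of NaN runs no longer than ``gap_limit`` seconds."""
    out = v.copy()
    nan = ~np.isfinite(out)
    if not nan.any():
        return out
    idx = np.arange(out.size)
    runs = np.flatnonzero(np.diff(np.concatenate(([0], nan.view(np.int8), [0]))))
    for start, stop in zip(runs[::2], runs[1::2]):
        if start == 0 or stop == out.size:
            continue  # cannot interpolate at the edges
        if t[stop] - t[start - 1] <= gap_limit:
            out[start:stop] = np.interp(idx[start:stop], [start - 1, stop], [out[start - 1], out[stop]])
    return out


def classify_zone(track: EPMTrack, gap_limit: float = 0.5) -> pd.DataFrame:
    """Per-frame zone via point-in-polygon on the head position.

    Missing (NaN) positions are linearly interpolated across gaps up to
    ``gap_limit`` seconds; longer gaps (and points outside every polygon)
    are labelled ``off_maze``.  Returns columns ``zone`` (detailed) and
    ``zone_class``.
    """
    x = _interpolate_gaps(track.t, track.x, gap_limit)
    y = _interpolate_gaps(track.t, track.y, gap_limit)
    n = track.t.size
    zone = np.full(n, "off_maze", dtype=object)
    valid = np.isfinite(x) & np.isfinite(y)
    for name in ZONE_NAMES:
        hit = np.zeros(n, dtype=bool)
        hit[valid] = contains_xy(track.geometry[name], x[valid], y[valid])
        zone[hit] = name
    cls = np.asarray([zone_class(z) for z in zone], dtype=object)
    return pd.DataFrame({"time": track.t, "zone": zone, "zone_class": cls})


def _runs(labels: np.ndarray):
    """Yield (start, stop, label) for maximal constant runs."""
    if labels.size == 0:
        return
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    bounds = np.concatenate(([0], change, [labels.size]))
    for a, b in zip(bounds[:-1], bounds[1:]):
        yield int(a), int(b), labels[a]


def detect_arm_entries(
    track: EPMTrack,
    zones: pd.DataFrame | None = None,
    debounce: float = 0.5,
) -> pd.DataFrame:
    """Arm-entry and arm-end events from the zone-class series.

    An entry is the first frame of a maximal run in an arm class lasting at
    least ``debounce`` seconds, excluding a run that begins the session
    (occupancy, not entry).  Within each qualifying visit the frame farthest
    from the maze centre yields an ``arm_end_reached`` event.
    """
    if zones is None:
        zones = classify_zone(track)
    cls = zones["zone_class"].to_numpy()
    t = zones["time"].to_numpy()
    dt = track.frame_dt
    min_frames = max(1, int(np.ceil(debounce / dt))) if dt > 0 else 1
    rows = []
    for a, b, label in _runs(cls):
        if label not in ("open", "closed") or (b - a) < min_frames:
            continue
        if a > 0:
            rows.append((t[a], f"{label}_entry"))
        dist = np.hypot(track.x[a:b], track.y[a:b])
        far = a + int(np.nanargmax(dist)) if np.any(np.isfinite(dist)) else a
        rows.append((t[far], "arm_end_reached"))
    ev = pd.DataFrame(rows, columns=["time", "event_type"]).sort_values(
        "time", kind="stable", ignore_index=True
    )
    if not ev.empty:
        ev["ordinal"] = ev.groupby("event_type").cumcount() + 1
    else:
        ev["ordinal"] = pd.Series(dtype=int)
    return ev


def open_arm_time_per_epoch(
    zones: pd.DataFrame,
    epochs: list[tuple[float, float]],
    frame_dt: float | None = None,
) -> list[float]:
    """Seconds of open-zone dwell per session epoch."""
    t = zones["time"].to_numpy()
    if frame_dt is None:
        frame_dt = float(np.median(np.diff(t))) if t.size > 1 else 0.0
    is_open = (zones["zone_class"] == "open").to_numpy()
    out = []
    for start, end in epochs:
        in_epoch = (t >= start) & (t < end)
        out.append(float(np.sum(is_open & in_epoch) * frame_dt))
    return out


def entry_probability(events: pd.DataFrame, epochs: list[tuple[float, float]]) -> list[float]:
    """Per-epoch probability that an arm entry is into an open arm.

    Defined as open entries / (open + closed entries); NaN when the epoch has
    no arm entries.
    """
    out = []
    for start, end in epochs:
        ev = events[(events["time"] >= start) & (events["time"] < end)]
        n_open = int((ev["event_type"] == "open_entry").sum())
        n_closed = int((ev["event_type"] == "closed_entry").sum())
        out.append(n_open / (n_open + n_closed) if (n_open + n_closed) else float("nan"))
    return out


def closed_loop_gate(
    zones: pd.DataFrame,
    epochs: list[tuple[float, float]],
    stim_epoch: int = 1,
    mode: str = "latched",
    stim_hz: float = 20.0,
) -> GateTrace:
    """Position-triggered stimulation gate.

    In ``latched`` mode (the experiment's protocol), within the stimulation
    epoch the light turns on when the animal is in the centre or an open
    arm and stays on until the first closed-arm frame (off-maze frames do
    not release the latch); outside the epoch the light is always off.  In
    ``constant`` mode the light is on for the whole stimulation epoch
    irrespective of position.
    """
    if mode not in ("latched", "constant"):
        raise ValueError("mode must be 'latched' or 'constant'")
    t = zones["time"].to_numpy()
    cls = zones["zone_class"].to_numpy()
    on = np.zeros(t.size, dtype=bool)
    log: list[dict] = []
    if stim_epoch is None or not epochs:
        return GateTrace(on=on, t=t, stim_hz=stim_hz, log=log)
    start, end = epochs[stim_epoch]
    in_epoch = (t >= start) & (t < end)
    if mode == "constant":
        on[in_epoch] = True
        if in_epoch.any():
            log.append({"time": float(t[in_epoch][0]), "action": "on", "reason": "epoch start (constant)"})
            log.append({"time": float(end), "action": "off", "reason": "epoch end"})
        return GateTrace(on=on, t=t, stim_hz=stim_hz, log=log)

    state = False
    for i in np.flatnonzero(in_epoch):
        if not state and cls[i] in ("centre", "open"):
            state = True
            log.append({"time": float(t[i]), "action": "on", "reason": f"{cls[i]} trigger"})
        elif state and cls[i] == "closed":
            state = False
            log.append({"time": float(t[i]), "action": "off", "reason": "closed-arm entry"})
        on[i] = state
    if state:
        log.append({"time": float(end), "action": "off", "reason": "epoch end"})
    return GateTrace(on=on, t=t, stim_hz=stim_hz, log=log)
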