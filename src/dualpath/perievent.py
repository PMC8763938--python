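"""Event-aligned epoching and window statistics for conditioned traces.

Traces are cut into fixed windows around behavioural events (12 s epochs by
default), baselined to an early window, and summarized as bl / pre / post
window means with event-type-specific post windows.  Also provides the
superficial-minus-deep layer difference score, ordinal (first/middle/last)
entry splits, 20 s long epochs, and a step-down Sidak (Holm-Sidak)
multiple-comparison helper.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .photometry import ConditionedTrace

__all__ = [
    "EVENT_TYPES",
    "WindowSpec",
    "PeriEventTensor",
    "extract_epochs",
    "baseline_subtract",
    "window_stats",
    "layer_difference",
    "ordinal_split",
    "long_epochs",
    "holm_sidak",
    "validate_events",
]

EVENT_TYPES = (
    "open_entry",
    "closed_entry",
    "rear",
    "stretch_attend",
    "head_dip",
    "arm_end_reached",
)


def validate_events(events: pd.DataFrame, session_bounds: tuple[float, float] | None = None) -> pd.DataFrame:
    """Check an event table: required columns, known types, increasing times per type."""
    if "time" not in events.columns or "event_type" not in events.columns:
        raise ValueError("event table needs 'time' and 'event_type' columns")
    unknown = set(events["event_type"]) - set(EVENT_TYPES)
    if unknown:
        raise ValueError(f"unknown event types: {sorted(unknown)}")
    for et, grp in events.groupby("event_type"):
        times = grp["time"].to_numpy()
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError(f"event times for {et!r} are not strictly increasing")
    if session_bounds is not None:
        lo, hi = session_bounds
        if ((events["time"] < lo) | (events["time"] > hi)).any():
            raise ValueError("event times outside session bounds")
    return events


@dataclass(frozen=True)
class WindowSpec:
    """Baseline / pre / post analysis windows (seconds relative to the event).

    The post window depends on event type: (2, 4) s for open-arm entries and
    most events, (0, 4) s for closed-arm entries.  An alternative baseline of
    (-6, -5) s can be supplied for the legend-style variant.
    """

    bl: tuple[float, float] = (-6.0, -4.0)
    pre: tuple[float, float] = (-2.0, 0.0)
    post: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"open_entry": (2.0, 4.0), "closed_entry": (0.0, 4.0)}
    )
    default_post: tuple[float, float] = (2.0, 4.0)

    def __post_init__(self) -> None:
        for name, w in (("bl", self.bl), ("pre", self.pre)):
            if w[0] >= w[1]:
                raise ValueError(f"{name} window must be increasing")
        if not (self.bl[1] <= self.pre[0] < self.pre[1]):
            raise ValueError("bl must precede pre")

    def post_for(self, event_type: str) -> tuple[float, float]:
        if event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {event_type!r}")
        return tuple(self.post.get(event_type, self.default_post))


@dataclass
class PeriEventTensor:
    """Event x time matrix of epochs cut around events of one trace."""

    epochs: np.ndarray
    window: tuple[float, float]
    fs: float
    events: pd.DataFrame
    dropped: list[dict] = field(default_factory=list)
    baseline_subtracted: bool = False
    bl_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.epochs = np.atleast_2d(np.asarray(self.epochs, dtype=float))
        n_expect = int(round((self.window[1] - self.window[0]) * self.fs))
        if self.epochs.size and self.epochs.shape[1] != n_expect:
            raise ValueError(
                f"epochs have {self.epochs.shape[1]} samples; window implies {n_expect}"
            )

    @property
    def n_events(self) -> int:
        return 0 if self.epochs.size == 0 else self.epochs.shape[0]

    @property
    def rel_times(self) -> np.ndarray:
        n = int(round((self.window[1] - self.window[0]) * self.fs))
        return self.window[0] + np.arange(n) / self.fs

    def window_slice(self, w: tuple[float, float]) -> slice:
        """Half-open sample slice [w0, w1) on the relative time base."""
        if w[0] < self.window[0] - 1e-9 or w[1] > self.window[1] + 1e-9:
            raise ValueError(f"window {w} outside epoch window {self.window}")
        i0 = int(round((w[0] - self.window[0]) * self.fs))
        i1 = i0 + int(round((w[1] - w[0]) * self.fs))
        return slice(i0, i1)


def extract_epochs(
    trace: ConditionedTrace,
    events: pd.DataFrame,
    window: tuple[float, float] = (-6.0, 6.0),
    event_type: str | None = None,
) -> PeriEventTensor:
    """Cut half-open ``[t+start, t+end)`` sample windows around each event.

    Events whose window would read outside the trace are dropped and logged
    in ``tensor.dropped`` with a reason.
    """
    if not (window[0] < 0 < window[1]):
        raise ValueError("window must straddle the event (start < 0 < end)")
    ev = events if event_type is None else events[events["event_type"] == event_type]
    n_samp = int(round((window[1] - window[0]) * trace.fs))
    rows, kept, dropped = [], [], []
    for _, row in ev.iterrows():
        i0 = int(round((row["time"] + window[0] - trace.t0) * trace.fs))
        if i0 < 0 or i0 + n_samp > trace.values.size:
            dropped.append({"time": float(row["time"]), "reason": "window outside recording"})
            continue
        rows.append(trace.values[i0 : i0 + n_samp])
        kept.append(row)
    epochs = np.asarray(rows) if rows else np.empty((0, n_samp))
    kept_df = pd.DataFrame(kept).reset_index(drop=True) if kept else ev.iloc[0:0].copy()
    return PeriEventTensor(epochs=epochs, window=window, fs=trace.fs, events=kept_df, dropped=dropped)


def baseline_subtract(tensor: PeriEventTensor, bl_window: tuple[float, float] = (-6.0, -4.0)) -> PeriEventTensor:
    """Subtract each epoch's mean over ``bl_window`` row-wise."""
    sl = tensor.window_slice(bl_window)
    if sl.stop <= sl.start:
        raise ValueError("empty baseline window")
    epochs = tensor.epochs.copy()
    if epochs.size:
        epochs -= epochs[:, sl].mean(axis=1, keepdims=True)
    return PeriEventTensor(
        epochs=epochs,
        window=tensor.window,
        fs=tensor.fs,
        events=tensor.events.copy(),
        dropped=list(tensor.dropped),
        baseline_subtracted=True,
        bl_window=bl_window,
    )


def window_stats(
    tensor: PeriEventTensor,
    spec: WindowSpec,
    event_type: str,
) -> pd.DataFrame:
    """Per-event bl/pre/post window means as a tidy frame.

    Requires a baseline-subtracted tensor.  If the kept-events frame carries
    an ``animal`` column the result keeps it, so animal-level values
    (mean of event means) can be aggregated downstream.
    """
    if not tensor.baseline_subtracted:
        raise ValueError("window_stats requires a baseline-subtracted tensor")
    post = spec.post_for(event_type)
    rows = []
    for name, w in (("bl", spec.bl), ("pre", spec.pre), ("post", post)):
        sl = tensor.window_slice(w)
        vals = tensor.epochs[:, sl].mean(axis=1) if tensor.n_events else np.empty(0)
        for i, v in enumerate(vals):
            row = {"event_index": i, "event_type": event_type, "window": name, "value": float(v)}
            if "animal" in tensor.events.columns:
                row["animal"] = tensor.events["animal"].iloc[i]
            rows.append(row)
    return pd.DataFrame(rows, columns=["event_index", "event_type", "window", "value"]
                        + (["animal"] if "animal" in tensor.events.columns else []))


def animal_means(stats: pd.DataFrame) -> pd.DataFrame:
    """Mean-of-event-means per animal, event type and window."""
    if "animal" not in stats.columns:
        raise ValueError("stats frame has no 'animal' column")
    return (
        stats.groupby(["animal", "event_type", "window"], as_index=False)["value"].mean()
    )


def layer_difference(
    sup_tensor: PeriEventTensor,
    deep_tensor: PeriEventTensor,
    spec: WindowSpec,
    event_type: str,
) -> tuple[PeriEventTensor, pd.DataFrame]:
    """Superficial-minus-deep difference score; positive = superficial bias."""
    if sup_tensor.n_events != deep_tensor.n_events or not np.allclose(
        sup_tensor.events["time"].to_numpy(), deep_tensor.events["time"].to_numpy()
    ):
        raise ValueError("tensors must be aligned to identical events")
    if sup_tensor.window != deep_tensor.window or sup_tensor.fs != deep_tensor.fs:
        raise ValueError("tensor windows/rates differ")
    diff = PeriEventTensor(
        epochs=sup_tensor.epochs - deep_tensor.epochs,
        window=sup_tensor.window,
        fs=sup_tensor.fs,
        events=sup_tensor.events.copy(),
        baseline_subtracted=sup_tensor.baseline_subtracted and deep_tensor.baseline_subtracted,
        bl_window=sup_tensor.bl_window,
    )
    post = spec.post_for(event_type)
    rows = []
    for name, w in (("pre", spec.pre), ("post", post)):
        sl = diff.window_slice(w)
        vals = diff.epochs[:, sl].mean(axis=1) if diff.n_events else np.empty(0)
        rows.extend(
            {"event_index": i, "event_type": event_type, "window": name, "value": float(v)}
            for i, v in enumerate(vals)
        )
    return diff, pd.DataFrame(rows, columns=["event_index", "event_type", "window", "value"])


def ordinal_split(events: pd.DataFrame, event_type: str) -> dict:
    """Split events of one type into first / middle / last within the session.

    A session with a single event has first == last, an empty middle, and is
    flagged ``excluded`` (one-entry sessions cannot support the comparison).
    """
    ev = events[events["event_type"] == event_type].sort_values("time")
    idx = list(ev.index)
    if not idx:
        return {"first": [], "middle": [], "last": [], "excluded": False}
    if len(idx) == 1:
        return {"first": idx, "middle": [], "last": idx, "excluded": True}
    return {"first": [idx[0]], "middle": idx[1:-1], "last": [idx[-1]], "excluded": False}


def long_epochs(
    trace: ConditionedTrace,
    events: pd.DataFrame,
    window: tuple[float, float] = (-10.0, 10.0),
    bl: tuple[float, float] = (-10.0, -8.0),
    event_type: str | None = None,
) -> PeriEventTensor:
    """20 s epochs baselined to (-10, -8) s: full-arm-visit activity profiles."""
    tensor = extract_epochs(trace, events, window=window, event_type=event_type)
    return baseline_subtract(tensor, bl)


def holm_sidak(pvalues) -> np.ndarray:
    """Step-down Sidak adjusted p-values, returned in the input order.

    Sorted ascending, ``adj_(i) = max_{j<=i} 1 - (1 - p_(j))^(m-j)`` (0-based
    j), clipped to 1; monotone non-decreasing in rank by construction.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-D")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out
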