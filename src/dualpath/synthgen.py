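"""Seeded synthetic-data generators with attached ground truth.

Every downstream module can be exercised against these generators: a
two-carrier amplitude-modulated photometry session with calcium-like
transients, slow bleaching and a shared autofluorescence artifact; a
two-layer cell map along the straightened hippocampal axis; light-evoked
synaptic sweep sets; and a semi-Markov elevated-plus-maze walk rendered to
head positions.  All randomness flows from the config seed and a fixed seed
gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .photometry import Carrier, ConditionedTrace, ModulatedRecording

__all__ = [
    "SynthPhotometryConfig",
    "SynthCellMapConfig",
    "SynthCracmConfig",
    "SynthEPMConfig",
    "SynthGroundTruth",
    "gen_photometry_session",
    "gen_cellmap",
    "gen_cracm_sweeps",
    "gen_epm_track",
    "gen_pattern_session",
    "PatternSessionConfig",
    "DEFAULT_CELLMAP_CONFIG",
]


@dataclass
class SynthGroundTruth:
    """Noise-free generating quantities recorded alongside each synthetic output."""

    transient_times: dict[str, np.ndarray] | None = None
    transient_amplitudes: dict[str, np.ndarray] | None = None
    true_envelopes: dict[str, np.ndarray] | None = None
    transient_trains: dict[str, np.ndarray] | None = None
    bleach_trend: dict[str, np.ndarray] | None = None
    autofluor_trace: np.ndarray | None = None
    connectivity_truth: dict[str, Any] | None = None
    zone_truth: pd.DataFrame | None = None
    layer_labels: np.ndarray | None = None
    extras: dict[str, Any] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# photometry session
# ---------------------------------------------------------------------------

@dataclass
class SynthPhotometryConfig:
    """Parameters of the modulated photometry generator.

    ``transient_rate`` / ``transient_amplitude`` / ``autofluor_gain`` may be a
    scalar (shared by both channels) or a ``{role: value}`` mapping.
    ``bleach_poly_coeffs`` are polynomial coefficients in normalized session
    time ``u = t / duration`` (constant term first).
    """

    duration: float = 600.0
    fs_raw: float = 100_000.0
    carriers: tuple[tuple[float, str], ...] = ((210.0, "green"), (500.0, "red"))
    transient_rate: float | Mapping[str, float] = 0.2
    transient_amplitude: float | Mapping[str, float] = 1.0
    transient_kinetics: tuple[float, float] = (0.05, 0.5)
    bleach_poly_coeffs: tuple[float, ...] = (5.0, -1.0, 0.3, 0.0)
    autofluor_gain: float | Mapping[str, float] = 0.1
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        fmax = max(f for f, _ in self.carriers)
        if self.fs_raw < 10 * fmax:
            raise ValueError(
                f"fs_raw={self.fs_raw} must be at least 10x the {fmax} Hz carrier"
            )
        rise, decay = self.transient_kinetics
        if rise <= 0 or decay <= 0 or rise >= decay:
            raise ValueError("transient kinetics require 0 < rise < decay")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name in ("transient_rate", "transient_amplitude", "autofluor_gain"):
            v = getattr(self, name)
            vals = v.values() if isinstance(v, Mapping) else [v]
            if any(x < 0 for x in vals):
                raise ValueError(f"{name} must be >= 0")

    def per_channel(self, name: str, role: str) -> float:
        v = getattr(self, name)
        return float(v[role]) if isinstance(v, Mapping) else float(v)


def _doe_kernel(rise: float, decay: float, fs: float) -> np.ndarray:
    """Difference-of-exponentials kernel, peak-normalized to 1."""
    length = int(round((rise + 8 * decay) * fs))
    tk = np.arange(max(length, 2)) / fs
    k = np.exp(-tk / decay) - np.exp(-tk / rise)
    peak = k.max()
    if peak <= 0:
        raise ValueError("degenerate transient kernel")
    return k / peak


def _slow_artifact(rng: np.random.Generator, t: np.ndarray) -> np.ndarray:
    """Shared slow positive artifact, ~[0.5, 1.5], built from random slow sinusoids."""
    freqs = rng.uniform(0.005, 0.05, size=6)
    phases = rng.uniform(0, 2 * np.pi, size=6)
    amps = rng.uniform(0.5, 1.0, size=6)
    s = np.zeros_like(t)
    for f, p, a in zip(freqs, phases, amps):
        s += a * np.sin(2 * np.pi * f * t + p)
    m = np.max(np.abs(s))
    if m > 0:
        s /= m
    return 1.0 + 0.5 * s


def gen_photometry_session(
    cfg: SynthPhotometryConfig,
) -> tuple[ModulatedRecording, SynthGroundTruth]:
    """Simulate a two-carrier modulated photometry recording.

    Each sensor row is
    ``env_own * (1 + sin(2 pi f_own t))/2 + gain*artifact * (1 + sin(2 pi f_other t))/2 + noise``
    where ``env_own = bleach + transient train + gain*artifact``.  Transient
    event times are a homogeneous Poisson process per channel.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration * cfg.fs_raw))
    t = np.arange(n) / cfg.fs_raw
    u = t / cfg.duration
    carriers = tuple(Carrier(f, r) for f, r in cfg.carriers)
    rise, decay = cfg.transient_kinetics
    kernel = _doe_kernel(rise, decay, cfg.fs_raw)

    artifact = _slow_artifact(rng, t)
    bleach = np.polynomial.polynomial.polyval(u, cfg.bleach_poly_coeffs)

    times: dict[str, np.ndarray] = {}
    amps: dict[str, np.ndarray] = {}
    trains: dict[str, np.ndarray] = {}
    envs: dict[str, np.ndarray] = {}
    bleaches: dict[str, np.ndarray] = {}
    rows = []
    for c in carriers:
        rate = cfg.per_channel("transient_rate", c.role)
        amp = cfg.per_channel("transient_amplitude", c.role)
        gain = cfg.per_channel("autofluor_gain", c.role)
        n_ev = rng.poisson(rate * cfg.duration)
        ev = np.sort(rng.uniform(0.0, cfg.duration, size=n_ev))
        a = np.full(n_ev, amp)
        train = np.zeros(n)
        for ti, ai in zip(ev, a):
            i0 = int(round(ti * cfg.fs_raw))
            if i0 >= n:
                continue
            seg = min(kernel.size, n - i0)
            train[i0 : i0 + seg] += ai * kernel[:seg]
        env = bleach + train + gain * artifact
        if env.min() < 0:  # envelopes must stay physical
            env = np.clip(env, 0.0, None)
        cross = gain * artifact
        other = next(cc for cc in carriers if cc.role != c.role)
        row = (
            env * (1.0 + np.sin(2 * np.pi * c.frequency * t)) / 2.0
            + cross * (1.0 + np.sin(2 * np.pi * other.frequency * t)) / 2.0
        )
        if cfg.noise_sd > 0:
            row = row + cfg.noise_sd * rng.standard_normal(n)
        times[c.role] = ev
        amps[c.role] = a
        trains[c.role] = train
        envs[c.role] = env
        bleaches[c.role] = bleach.copy()
        rows.append(row)

    rec = ModulatedRecording(
        fs_raw=cfg.fs_raw,
        samples=np.vstack(rows),
        carriers=carriers,
        sensors=tuple(c.role for c in carriers),
    )
    truth = SynthGroundTruth(
        transient_times=times,
        transient_amplitudes=amps,
        true_envelopes=envs,
        transient_trains=trains,
        bleach_trend=bleaches,
        autofluor_trace=artifact,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# cell maps
# ---------------------------------------------------------------------------

@dataclass
class SynthCellMapConfig:
    """Mixture-of-Gaussians cell-map generator over normalized [0,1]^2 coordinates.

    ``subset_rules`` maps each tracer flag to per-component labelling
    probabilities (aligned with ``component_means`` order).
    """

    n_cells: int = 500
    component_means: tuple[tuple[float, float], ...] = ((0.15, 0.7), (0.85, 0.7))
    component_sds: tuple[tuple[float, float], ...] = ((0.06, 0.12), (0.06, 0.12))
    component_weights: tuple[float, ...] = (0.5, 0.5)
    subset_rules: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: {"ctxb": (1.0, 1.0), "rabies": (0.8, 0.2)}
    )
    slice_id: str = "s0"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if abs(sum(self.component_weights) - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")
        for m in self.component_means:
            if not (0 <= m[0] <= 1 and 0 <= m[1] <= 1):
                raise ValueError("component means must lie in [0,1]^2")
        for s in self.component_sds:
            if s[0] <= 0 or s[1] <= 0:
                raise ValueError("component sds must be positive")
        k = len(self.component_means)
        if len(self.component_sds) != k or len(self.component_weights) != k:
            raise ValueError("component parameter lengths disagree")
        for flag, probs in self.subset_rules.items():
            if len(probs) != k:
                raise ValueError(f"subset rule {flag!r} needs {k} probabilities")
            if any(not 0 <= p <= 1 for p in probs):
                raise ValueError(f"subset rule {flag!r} probabilities must be in [0,1]")


#: documented package default used by the demo pipeline and acceptance run
DEFAULT_CELLMAP_CONFIG = SynthCellMapConfig()


def gen_cellmap(cfg: SynthCellMapConfig):
    """Sample a cell map; returns ``(CellMap, SynthGroundTruth)``.

    The true mixture component of each cell is kept in the ground truth, and
    tracer flags are Bernoulli draws with per-component probabilities.
    """
    from .layers import CellMap  # local import to avoid a cycle

    rng = np.random.default_rng(cfg.seed)
    k = len(cfg.component_means)
    comp = rng.choice(k, size=cfg.n_cells, p=np.asarray(cfg.component_weights))
    means = np.asarray(cfg.component_means)
    sds = np.asarray(cfg.component_sds)
    coords = means[comp] + sds[comp] * rng.standard_normal((cfg.n_cells, 2))
    coords = np.clip(coords, 0.0, 1.0)
    data = {
        "slice": np.full(cfg.n_cells, cfg.slice_id, dtype=object),
        "radial": coords[:, 0],
        "longitudinal": coords[:, 1],
    }
    for flag, probs in cfg.subset_rules.items():
        p = np.asarray(probs)[comp] if cfg.n_cells else np.zeros(0)
        data[flag] = rng.random(cfg.n_cells) < p
    cells = pd.DataFrame(data)
    cellmap = CellMap(cells=cells, tracer_flags=tuple(cfg.subset_rules))
    truth = SynthGroundTruth(layer_labels=comp, extras={"config": cfg})
    return cellmap, truth


# ---------------------------------------------------------------------------
# CRACM sweeps
# ---------------------------------------------------------------------------

@dataclass
class SynthCracmConfig:
    """Light-evoked sweep generator: Gaussian baseline noise plus, when
    connected, a difference-of-exponentials response at fixed latency."""

    n_sweeps: int = 5
    fs: float = 10_000.0
    sweep_duration: float = 0.3
    stim_onset: float = 0.1
    pulse_durations_ms: tuple[float, ...] = (0.2, 0.5, 1.0, 2.0, 5.0)
    amplitude: float = 100.0
    latency: float = 0.005
    kinetics: tuple[float, float] = (0.001, 0.010)
    noise_sd: float = 5.0
    holding_mv: float = -70.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        rise, decay = self.kinetics
        if rise <= 0 or decay <= 0 or rise >= decay:
            raise ValueError("kinetics require 0 < rise < decay")
        if not (0 <= self.stim_onset < self.sweep_duration):
            raise ValueError("pulse onset outside sweep window")
        if self.amplitude < 0:
            raise ValueError("amplitude is a magnitude; must be >= 0")


def _duration_scaling(pulse_ms: float) -> float:
    """Saturating response scaling with pulse duration (1.0 at 5 ms)."""
    return (1.0 - np.exp(-pulse_ms / 1.0)) / (1.0 - np.exp(-5.0))


def gen_cracm_sweeps(cfg: SynthCracmConfig):
    """Generate sweeps for every pulse duration; returns ``(SweepSet, truth)``.

    Response polarity follows clamp convention: inward (negative) at -70 mV,
    outward (positive) at 0 mV.  ``amplitude == 0`` means unconnected.
    """
    from .cracm import SweepSet  # local import to avoid a cycle

    rng = np.random.default_rng(cfg.seed)
    nt = int(round(cfg.sweep_duration * cfg.fs))
    onset_idx = int(round(cfg.stim_onset * cfg.fs))
    if onset_idx + int(round(cfg.latency * cfg.fs)) >= nt:
        raise ValueError("response onset outside sweep window")
    rise, decay = cfg.kinetics
    kernel = _doe_kernel(rise, decay, cfg.fs)
    sign = -1.0 if cfg.holding_mv < -30 else 1.0
    connected = cfg.amplitude > 0

    sweeps = []
    pulse_ms = []
    true_amp = {}
    for d in cfg.pulse_durations_ms:
        peak = cfg.amplitude * _duration_scaling(d) if connected else 0.0
        true_amp[d] = sign * peak
        resp = np.zeros(nt)
        i0 = onset_idx + int(round(cfg.latency * cfg.fs))
        seg = min(kernel.size, nt - i0)
        resp[i0 : i0 + seg] = sign * peak * kernel[:seg]
        for _ in range(cfg.n_sweeps):
            noise = cfg.noise_sd * rng.standard_normal(nt) if cfg.noise_sd > 0 else 0.0
            sweeps.append(resp + noise)
            pulse_ms.append(d)
    sweep_set = SweepSet(
        sweeps=np.asarray(sweeps),
        fs=cfg.fs,
        stim_onset=cfg.stim_onset,
        pulse_ms=np.asarray(pulse_ms),
        holding_mv=cfg.holding_mv,
    )
    truth = SynthGroundTruth(
        connectivity_truth={
            "connected": connected,
            "true_peak_by_pulse": true_amp,
            "latency": cfg.latency,
            "kinetics": cfg.kinetics,
            "noise_sd": cfg.noise_sd,
        }
    )
    return sweep_set, truth


# ---------------------------------------------------------------------------
# EPM tracks
# ---------------------------------------------------------------------------

_EPM_STATES = ("centre", "open1", "open2", "closed1", "closed2")


def _default_transitions() -> dict[str, dict[str, float]]:
    return {
        "centre": {"open1": 0.15, "open2": 0.15, "closed1": 0.35, "closed2": 0.35},
        "open1": {"centre": 1.0},
        "open2": {"centre": 1.0},
        "closed1": {"centre": 1.0},
        "closed2": {"centre": 1.0},
    }


@dataclass
class SynthEPMConfig:
    """Semi-Markov walk over the five maze zones rendered to head positions.

    Dwells are exponential with per-zone means; inside an arm the head moves
    out to (90% of) the arm end and back, with Gaussian jitter everywhere so
    zone classification is non-trivial.
    """

    duration: float = 540.0
    frame_rate: float = 50.0
    arm_length: float = 30.0
    arm_width: float = 6.0
    transitions: dict[str, dict[str, float]] = field(default_factory=_default_transitions)
    mean_dwell: dict[str, float] = field(
        default_factory=lambda: {
            "centre": 2.0, "open1": 5.0, "open2": 5.0, "closed1": 10.0, "closed2": 10.0,
        }
    )
    jitter_sd: float = 1.0
    start_state: str = "closed1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.frame_rate <= 0:
            raise ValueError("duration and frame_rate must be positive")
        for s in _EPM_STATES:
            if s not in self.transitions:
                raise ValueError(f"transition row missing for state {s!r}")
            row = self.transitions[s]
            tot = sum(row.values())
            if row and abs(tot - 1.0) > 1e-9:
                raise ValueError(f"transition row for {s!r} sums to {tot}, not 1")
            if any(p < 0 for p in row.values()):
                raise ValueError("transition probabilities must be >= 0")

    def transition_matrix(self) -> np.ndarray:
        m = np.zeros((len(_EPM_STATES), len(_EPM_STATES)))
        for i, s in enumerate(_EPM_STATES):
            for j, sj in enumerate(_EPM_STATES):
                m[i, j] = self.transitions[s].get(sj, 0.0)
        return m


def gen_epm_track(cfg: SynthEPMConfig):
    """Simulate an EPM session; returns ``(EPMTrack, EventTable, truth)``.

    Ground truth holds the frame-level zone series; the event table lists
    open/closed arm entries (excluding the initial state) at dwell starts.
    """
    from .epm import EPMTrack, standard_epm_geometry, zone_class

    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration * cfg.frame_rate))
    dt = 1.0 / cfg.frame_rate

    # semi-Markov walk in whole frames
    states: list[str] = []
    dwell_frames: list[int] = []
    state = cfg.start_state
    total = 0
    while total < n:
        m = max(1, int(round(rng.exponential(cfg.mean_dwell[state]) * cfg.frame_rate)))
        m = min(m, n - total)
        states.append(state)
        dwell_frames.append(m)
        total += m
        row = cfg.transitions[state]
        nxt = list(row)
        state = nxt[rng.choice(len(nxt), p=np.asarray([row[s] for s in nxt]))] if nxt else state

    geom = standard_epm_geometry(cfg.arm_length, cfg.arm_width)
    half = cfg.arm_width / 2.0
    arm_dirs = {
        "open1": np.array([1.0, 0.0]),
        "open2": np.array([-1.0, 0.0]),
        "closed1": np.array([0.0, 1.0]),
        "closed2": np.array([0.0, -1.0]),
    }

    x = np.empty(n)
    y = np.empty(n)
    zone = np.empty(n, dtype=object)
    events = []
    idx = 0
    for seg_i, (s, m) in enumerate(zip(states, dwell_frames)):
        sl = slice(idx, idx + m)
        zone[sl] = s
        if s == "centre":
            base = np.zeros((m, 2))
        else:
            if seg_i > 0:  # the initial state is occupancy, not an entry
                events.append((idx * dt, f"{zone_class(s)}_entry"))
            k = np.arange(m)
            prog = 1.0 - np.abs(1.0 - 2.0 * k / max(m - 1, 1))  # out and back
            reach = half + prog[:, None] * (0.9 * cfg.arm_length) * np.ones((m, 1))
            base = reach * arm_dirs[s][None, :]
            far = int(np.argmax(prog))
            events.append(((idx + far) * dt, "arm_end_reached"))
        jit = cfg.jitter_sd * rng.standard_normal((m, 2))
        # jitter stays inside the current zone polygon so the rendered track
        # matches the ground-truth zone series frame for frame
        minx, miny, maxx, maxy = geom[s].bounds
        eps = 1e-3
        x[sl] = np.clip(base[:, 0] + jit[:, 0], minx + eps, maxx - eps)
        y[sl] = np.clip(base[:, 1] + jit[:, 1], miny + eps, maxy - eps)
        idx += m

    t = np.arange(n) * dt
    track = EPMTrack(t=t, x=x, y=y, geometry=geom)
    ev = pd.DataFrame(events, columns=["time", "event_type"]).sort_values(
        "time", kind="stable", ignore_index=True
    )
    ev["ordinal"] = ev.groupby("event_type").cumcount() + 1
    truth = SynthGroundTruth(
        zone_truth=pd.DataFrame({"time": t, "zone": zone}),
        extras={"states": states, "dwell_frames": dwell_frames, "config": cfg},
    )
    return track, ev, truth


# ---------------------------------------------------------------------------
# programmed peri-event pattern sessions (50 Hz, post-processing scale)
# ---------------------------------------------------------------------------

@dataclass
class PatternSessionConfig:
    """Programmed superficial/deep peri-event response pattern at 50 Hz.

    Encodes the qualitative in-vivo pattern: on open-arm entry the
    superficial channel is flat before and rises after entry while the deep
    channel rises before and falls after; on closed-arm entry the deep
    channel rises before and stays up after while the superficial channel is
    flat throughout.
    """

    duration: float = 540.0
    fs: float = 50.0
    n_open: int = 8
    n_closed: int = 8
    amplitude: float = 1.0
    noise_sd: float = 0.1
    min_separation: float = 20.0
    seed: int = 0


def _bump(t_rel: np.ndarray, start: float, end: float, amp: float) -> np.ndarray:
    """Smooth raised-cosine bump spanning [start, end] (relative seconds)."""
    out = np.zeros_like(t_rel)
    inside = (t_rel >= start) & (t_rel <= end)
    phase = (t_rel[inside] - start) / (end - start)
    out[inside] = amp * 0.5 * (1 - np.cos(2 * np.pi * phase))
    return out


def gen_pattern_session(cfg: PatternSessionConfig):
    """Build (superficial trace, deep trace, EventTable, truth) at 50 Hz."""
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration * cfg.fs))
    t = np.arange(n) / cfg.fs

    n_ev = cfg.n_open + cfg.n_closed
    lo, hi = 15.0, cfg.duration - 15.0
    slack = (hi - lo) - max(n_ev - 1, 0) * cfg.min_separation
    if slack <= 0:
        raise ValueError("cannot place events: min_separation too large for the session")
    # uniform order statistics in the slack interval plus enforced gaps
    times = np.sort(rng.uniform(0.0, slack, size=n_ev)) + lo
    times += np.arange(n_ev) * cfg.min_separation
    kinds = np.array(["open_entry"] * cfg.n_open + ["closed_entry"] * cfg.n_closed)
    rng.shuffle(kinds)

    sup = np.zeros(n)
    deep = np.zeros(n)
    a = cfg.amplitude
    for ti, kind in zip(times, kinds):
        rel = t - ti
        if kind == "open_entry":
            sup += _bump(rel, 1.0, 5.0, a)       # post-entry rise
            deep += _bump(rel, -3.0, 0.0, a)     # pre-entry rise
            deep -= _bump(rel, 0.5, 5.0, a)      # post-entry suppression
        else:
            deep += _bump(rel, -3.0, 0.0, a)     # pre-entry rise
            deep += _bump(rel, 0.0, 5.0, a)      # sustained post-entry
    if cfg.noise_sd > 0:
        sup = sup + cfg.noise_sd * rng.standard_normal(n)
        deep = deep + cfg.noise_sd * rng.standard_normal(n)

    sup_tr = ConditionedTrace(fs=cfg.fs, values=sup, channel="red", stage="detrended")
    deep_tr = ConditionedTrace(fs=cfg.fs, values=deep, channel="green", stage="detrended")
    ev = pd.DataFrame({"time": times, "event_type": kinds})
    ev["ordinal"] = ev.groupby("event_type").cumcount() + 1
    truth = SynthGroundTruth(extras={"amplitude": a, "config": cfg})
    return sup_tr, deep_tr, ev, truth
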