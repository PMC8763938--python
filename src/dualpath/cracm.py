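"""Light-evoked synaptic response quantification and intrinsic features.

Amplitudes are measured on the sweep-averaged, baseline-subtracted trace as
the mean over a 1 ms window centred on the peak found in the response
window; a cell counts as connected when |amplitude| strictly exceeds
6 x the baseline SD of the same averaged trace.  Paired comparisons are
reported as ratios (with log10) of response magnitudes.  Current-step data
yield spike counts, burst flags, sag amplitude, membrane time constant and
AP half-width; fast-spiking classification is a 2-means partition on
standardized (tau_m, half-width).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.cluster import KMeans

__all__ = [
    "SweepSet",
    "ConnectivityResult",
    "IntrinsicFeatures",
    "response_amplitude",
    "baseline_sd",
    "detect_connection",
    "analyze_connectivity",
    "pair_ratio",
    "spike_times",
    "spike_count",
    "burst_flag",
    "sag_amplitude",
    "membrane_tau",
    "ap_half_width",
    "intrinsic_features",
    "classify_fs",
]

#: default analysis windows (seconds relative to stimulus onset)
BASELINE_WINDOW = 0.05       # 50 ms immediately pre-stimulus
RESPONSE_WINDOW = (0.002, 0.05)
PEAK_AVG_WINDOW = 0.001      # 1 ms window around the peak


@dataclass
class SweepSet:
    """Trial x time matrix of voltage- or current-clamp sweeps."""

    sweeps: np.ndarray
    fs: float
    stim_onset: float
    pulse_ms: np.ndarray | float | None = None
    holding_mv: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sweeps = np.atleast_2d(np.asarray(self.sweeps, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not (0 <= self.stim_onset < self.sweeps.shape[1] / self.fs):
            raise ValueError("stimulus onset outside sweep")
        if self.pulse_ms is not None and np.ndim(self.pulse_ms) == 1:
            self.pulse_ms = np.asarray(self.pulse_ms, dtype=float)
            if self.pulse_ms.size != self.sweeps.shape[0]:
                raise ValueError("pulse_ms length must match sweep count")

    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[0]

    @property
    def duration(self) -> float:
        return self.sweeps.shape[1] / self.fs

    def subset(self, pulse_ms: float) -> "SweepSet":
        if self.pulse_ms is None or np.ndim(self.pulse_ms) == 0:
            raise ValueError("sweep set has no per-sweep pulse durations")
        mask = np.isclose(self.pulse_ms, pulse_ms)
        if not mask.any():
            raise ValueError(f"no sweeps with pulse duration {pulse_ms} ms")
        return SweepSet(
            sweeps=self.sweeps[mask],
            fs=self.fs,
            stim_onset=self.stim_onset,
            pulse_ms=float(pulse_ms),
            holding_mv=self.holding_mv,
            metadata=dict(self.metadata),
        )


@dataclass
class ConnectivityResult:
    amplitude: float
    baseline_sd: float
    connected: bool
    threshold_factor: float
    response_window: tuple[float, float]
    pulse_ms: float | None = None


def _mean_trace(sweeps: SweepSet) -> np.ndarray:
    return sweeps.sweeps.mean(axis=0)


def _baseline_slice(sweeps: SweepSet, baseline_window: float) -> slice:
    i1 = int(round(sweeps.stim_onset * sweeps.fs))
    i0 = max(0, i1 - int(round(baseline_window * sweeps.fs)))
    return slice(i0, i1)


def response_amplitude(
    sweeps: SweepSet,
    response_window: tuple[float, float] = RESPONSE_WINDOW,
    baseline_window: float = BASELINE_WINDOW,
) -> float:
    """Signed amplitude of the averaged, baseline-subtracted response.

    The peak is the largest |value| within the response window (relative to
    stimulus onset) on the mean trace; the amplitude is the mean over the
    1 ms window centred on that peak.
    """
    if sweeps.n_sweeps < 1:
        raise ValueError("need at least one sweep")
    if response_window[0] < 0 or response_window[0] >= response_window[1]:
        raise ValueError("response window must follow stimulus onset")
    mean = _mean_trace(sweeps)
    bsl = _baseline_slice(sweeps, baseline_window)
    mean = mean - mean[bsl].mean()
    i0 = int(round((sweeps.stim_onset + response_window[0]) * sweeps.fs))
    i1 = int(round((sweeps.stim_onset + response_window[1]) * sweeps.fs))
    if i1 > mean.size or i0 >= i1:
        raise ValueError("response window outside sweep")
    seg = mean[i0:i1]
    peak = i0 + int(np.argmax(np.abs(seg)))
    half = int(round(PEAK_AVG_WINDOW * sweeps.fs / 2))
    w0, w1 = max(0, peak - half), min(mean.size, peak + half + 1)
    return float(mean[w0:w1].mean())


def baseline_sd(sweeps: SweepSet, baseline_window: float = BASELINE_WINDOW) -> float:
    """SD of the averaged trace over the pre-stimulus baseline window."""
    mean = _mean_trace(sweeps)
    return float(np.std(mean[_baseline_slice(sweeps, baseline_window)]))


def detect_connection(amplitude: float, baseline_sd_: float, factor: float = 6.0) -> bool:
    """Connected iff |amplitude| strictly exceeds ``factor`` x baseline SD."""
    if baseline_sd_ < 0:
        raise ValueError("baseline SD must be >= 0")
    if baseline_sd_ == 0.0:
        if amplitude == 0.0:
            warnings.warn("zero amplitude with zero baseline SD: detection undefined", stacklevel=2)
            return False
        return True
    return bool(abs(amplitude) > factor * baseline_sd_)


def analyze_connectivity(
    sweeps: SweepSet,
    factor: float = 6.0,
    response_window: tuple[float, float] = RESPONSE_WINDOW,
    baseline_window: float = BASELINE_WINDOW,
) -> list[ConnectivityResult]:
    """Amplitude + detection per pulse duration (or once if undistinguished)."""
    if sweeps.pulse_ms is not None and np.ndim(sweeps.pulse_ms) == 1:
        groups = [sweeps.subset(d) for d in np.unique(sweeps.pulse_ms)]
    else:
        groups = [sweeps]
    out = []
    for grp in groups:
        amp = response_amplitude(grp, response_window, baseline_window)
        sd = baseline_sd(grp, baseline_window)
        out.append(
            ConnectivityResult(
                amplitude=amp,
                baseline_sd=sd,
                connected=detect_connection(amp, sd, factor),
                threshold_factor=factor,
                response_window=response_window,
                pulse_ms=None if grp.pulse_ms is None else float(np.atleast_1d(grp.pulse_ms)[0]),
            )
        )
    return out


def pair_ratio(amp_first: float, amp_second: float, eps: float | None = None) -> dict:
    """Magnitude ratio first/second with log10; optional epsilon floor."""
    a, b = abs(amp_first), abs(amp_second)
    if eps is not None:
        a, b = max(a, eps), max(b, eps)
    if a == 0 or b == 0:
        raise ValueError("pair_ratio needs non-zero magnitudes (or an eps floor)")
    r = a / b
    return {"ratio": float(r), "log10_ratio": float(np.log10(r))}


# ---------------------------------------------------------------------------
# intrinsic features
# ---------------------------------------------------------------------------

def spike_times(
    trace: np.ndarray,
    fs: float,
    window: tuple[float, float] | None = None,
    threshold: float = 0.0,
    refractory: float = 0.002,
) -> np.ndarray:
    """Times of upward threshold crossings with a refractory rule."""
    v = np.asarray(trace, dtype=float)
    up = np.flatnonzero((v[:-1] < threshold) & (v[1:] >= threshold)) + 1
    times = up / fs
    if window is not None:
        times = times[(times >= window[0]) & (times < window[1])]
    kept = []
    last = -np.inf
    for ti in times:
        if ti - last >= refractory:
            kept.append(ti)
            last = ti
    return np.asarray(kept)


def spike_count(
    trace: np.ndarray,
    fs: float,
    step_window: tuple[float, float],
    threshold: float = 0.0,
    refractory: float = 0.002,
    rail_mv: float = 80.0,
) -> int:
    """Number of action potentials during the current step."""
    v = np.asarray(trace, dtype=float)
    if np.any(np.abs(v) >= rail_mv * 2):
        warnings.warn("trace appears clipped/railed", stacklevel=2)
    return int(spike_times(v, fs, step_window, threshold, refractory).size)


def burst_flag(trace: np.ndarray, fs: float, step_window: tuple[float, float],
               isi_criterion: float = 0.010) -> bool:
    """Burst iff the first inter-spike interval is below the ISI criterion."""
    st = spike_times(trace, fs, step_window)
    if st.size < 2:
        return False
    return bool(st[1] - st[0] < isi_criterion)


def sag_amplitude(
    trace: np.ndarray,
    fs: float,
    step_window: tuple[float, float],
    step_current_pa: float = -160.0,
    min_search: float = 0.300,
    steady_window: float = 0.100,
) -> float:
    """Sag (mV) for a hyperpolarizing step: steady-state minus early minimum.

    Steady state is the mean over the last ``steady_window`` of the step; the
    minimum is searched within the first ``min_search`` of the step.
    Positive values indicate sag (Ih rebound).
    """
    if step_current_pa >= 0:
        raise ValueError("sag is defined for hyperpolarizing (negative) steps")
    v = np.asarray(trace, dtype=float)
    s0, s1 = (int(round(w * fs)) for w in step_window)
    if s1 <= s0 or s1 > v.size:
        raise ValueError("step window outside trace")
    early = v[s0 : min(s1, s0 + int(round(min_search * fs)))]
    steady = v[max(s0, s1 - int(round(steady_window * fs))) : s1]
    return float(steady.mean() - early.min())


def membrane_tau(
    trace: np.ndarray,
    fs: float,
    step_window: tuple[float, float],
    fit_duration: float = 0.1,
) -> float:
    """Membrane time constant (ms) from an exponential fit of the step onset.

    Fits ``v(t) = v_inf + (v0 - v_inf) * exp(-t/tau)`` on the first
    ``fit_duration`` seconds after step onset of a (subthreshold,
    hyperpolarizing) response.
    """
    v = np.asarray(trace, dtype=float)
    s0 = int(round(step_window[0] * fs))
    s1 = min(v.size, s0 + int(round(fit_duration * fs)))
    seg = v[s0:s1]
    if seg.size < 10:
        raise ValueError("too few samples for tau fit")
    if np.ptp(seg) < 1e-9:
        raise ValueError("flat trace: tau undefined")
    t = np.arange(seg.size) / fs

    def model(tt, v_inf, dv, tau):
        return v_inf + dv * np.exp(-tt / tau)

    v0, v_inf0 = seg[0], seg[-1]
    p0 = (v_inf0, v0 - v_inf0, 0.02)
    popt, _ = curve_fit(model, t, seg, p0=p0, maxfev=10_000)
    tau = float(abs(popt[2]))
    return tau * 1000.0


def ap_half_width(
    trace: np.ndarray,
    fs: float,
    window: tuple[float, float] | None = None,
    dvdt_threshold: float = 20.0,
) -> float:
    """Width (ms) at half the peak-to-threshold height of the first spike.

    Spike threshold is the voltage where dV/dt first exceeds
    ``dvdt_threshold`` (mV/ms) before the peak; crossings of the half level
    are located by linear interpolation.
    """
    v = np.asarray(trace, dtype=float)
    st = spike_times(v, fs, window)
    if st.size == 0:
        raise ValueError("no spikes in trace")
    i_cross = int(round(st[0] * fs))
    # peak: first local max at/after the upward crossing
    i_peak = i_cross
    while i_peak + 1 < v.size and v[i_peak + 1] >= v[i_peak]:
        i_peak += 1
    dvdt = np.diff(v) * fs / 1000.0  # mV per ms
    # anchor at the steepest point of the upstroke, then walk back until the
    # slope drops below threshold (robust to flat samples at the peak)
    lo = max(i_peak - int(0.005 * fs), 0)
    i_rise = lo + int(np.argmax(dvdt[lo:i_peak])) if i_peak > lo else i_cross
    i_thr = i_rise
    while i_thr > lo and dvdt[i_thr - 1] >= dvdt_threshold:
        i_thr -= 1
    v_thr = v[i_thr]
    half = (v[i_peak] + v_thr) / 2.0

    def interp_cross(i_lo: int, i_hi: int, rising: bool) -> float:
        rng = range(i_lo, i_hi) if rising else range(i_hi - 1, i_lo - 1, -1)
        for i in rng:
            a, b = v[i], v[i + 1]
            if (rising and a < half <= b) or (not rising and a >= half > b):
                return i + (half - a) / (b - a)
        raise ValueError("half level not crossed")

    t_up = interp_cross(i_thr, i_peak + 1, rising=True)
    i_end = min(v.size - 1, i_peak + int(0.01 * fs))
    t_down = interp_cross(i_peak, i_end, rising=False)
    return float((t_down - t_up) / fs * 1000.0)


@dataclass
class IntrinsicFeatures:
    spike_counts: dict[float, int] = field(default_factory=dict)
    burst: bool | None = None
    sag_mv: float = float("nan")
    tau_m_ms: float = float("nan")
    ap_half_width_ms: float = float("nan")
    resting_mv: float = float("nan")
    flags: list[str] = field(default_factory=list)


def intrinsic_features(
    steps: dict[float, np.ndarray],
    fs: float,
    step_window: tuple[float, float],
    tau_step_pa: float = -40.0,
    sag_step_pa: float = -160.0,
) -> IntrinsicFeatures:
    """Summarize a current-step protocol given ``{current_pA: trace}``.

    tau_m comes from the smallest-magnitude hyperpolarizing step (or
    ``tau_step_pa`` if present), sag from the ``sag_step_pa`` step, spike
    statistics from depolarizing steps, and half-width from the first spike
    of the lowest suprathreshold step.
    """
    feats = IntrinsicFeatures()
    if not steps:
        raise ValueError("no current steps supplied")
    any_trace = next(iter(steps.values()))
    pre = np.asarray(any_trace)[: int(round(step_window[0] * fs))]
    feats.resting_mv = float(pre.mean()) if pre.size else float("nan")

    hyper = sorted((c for c in steps if c < 0), key=abs)
    tau_key = tau_step_pa if tau_step_pa in steps else (hyper[0] if hyper else None)
    if tau_key is not None:
        try:
            feats.tau_m_ms = membrane_tau(steps[tau_key], fs, step_window)
        except (ValueError, RuntimeError):
            feats.flags.append("tau_fit_failed")
    else:
        feats.flags.append("no_subthreshold_step")

    if sag_step_pa in steps:
        feats.sag_mv = sag_amplitude(steps[sag_step_pa], fs, step_window, sag_step_pa)

    first_spiking = None
    for c in sorted(c for c in steps if c > 0):
        n = spike_count(steps[c], fs, step_window)
        feats.spike_counts[c] = n
        if n > 0 and first_spiking is None:
            first_spiking = c
    if first_spiking is not None:
        if feats.spike_counts[first_spiking] >= 2:
            feats.burst = burst_flag(steps[first_spiking], fs, step_window)
        else:
            feats.burst = False
        try:
            feats.ap_half_width_ms = ap_half_width(steps[first_spiking], fs, step_window)
        except ValueError:
            feats.flags.append("half_width_failed")
    else:
        feats.burst = None
        if not feats.spike_counts:
            feats.flags.append("no_depolarizing_step")
        feats.flags.append("no_spikes")
    return feats


def classify_fs(features: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """2-means partition on standardized (tau_m_ms, ap_half_width_ms).

    FS+ is the cluster with the smaller mean half-width.  Requires >= 4 cells
    with finite features; identical features yield a degenerate flag.
    """
    req = {"tau_m_ms", "ap_half_width_ms"}
    if not req <= set(features.columns):
        raise ValueError(f"features need columns {sorted(req)}")
    x = features[["tau_m_ms", "ap_half_width_ms"]].to_numpy(dtype=float)
    finite = np.all(np.isfinite(x), axis=1)
    if finite.sum() < 4:
        raise ValueError("need at least 4 cells with finite features")
    xf = x[finite]
    sd = xf.std(axis=0)
    out = features.copy()
    out["fs_label"] = pd.NA
    if np.any(sd == 0) and np.allclose(xf, xf[0]):
        out["degenerate"] = True
        return out
    sd = np.where(sd == 0, 1.0, sd)
    z = (xf - xf.mean(axis=0)) / sd
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    labels = km.fit_predict(z)
    hw_means = [xf[labels == k, 1].mean() for k in (0, 1)]
    fs_cluster = int(np.argmin(hw_means))
    names = np.where(labels == fs_cluster, "FS+", "FS-")
    out.loc[finite, "fs_label"] = names
    out["degenerate"] = False
    return out
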