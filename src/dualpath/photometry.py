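"""Frequency-multiplexed fiber-photometry signal conditioning.

Two LED carriers (blue -> 210 Hz -> green sensor, green -> 500 Hz -> red
sensor by default) amplitude-modulate the fluorescence collected by the
photoreceiver(s).  The envelope of each carrier is recovered offline by
quadrature lock-in (synchronous) demodulation, downsampled to 50 Hz,
detrended with a low-order polynomial, regressed against the
cross-frequency autofluorescence estimate, and z-scored over the session.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

__all__ = [
    "Carrier",
    "ModulatedRecording",
    "ConditionedTrace",
    "PhotometryConfig",
    "ProcessedSession",
    "demodulate",
    "extract_autofluorescence",
    "downsample",
    "detrend_poly",
    "fit_autofluorescence",
    "zscore_corrected",
    "process_session",
]

#: channel roles understood by the pipeline
ROLES = ("green", "red")


@dataclass(frozen=True)
class Carrier:
    """One LED modulation carrier: sinusoid frequency plus the sensor it feeds."""

    frequency: float
    role: str

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError(f"carrier frequency must be positive, got {self.frequency}")
        if self.role not in ROLES:
            raise ValueError(f"carrier role must be one of {ROLES}, got {self.role!r}")


@dataclass
class ModulatedRecording:
    """Raw photoreceiver samples with carrier metadata.

    ``samples`` is a ``(n_sensors, n_samples)`` array; ``sensors`` names the
    role of each row.  A sensor row contains its own channel's envelope on the
    matching carrier plus the autofluorescence envelope on the non-matching
    carrier, so demodulating a row at the *other* carrier frequency yields
    that sensor's autofluorescence estimate.
    """

    fs_raw: float
    samples: np.ndarray
    carriers: tuple[Carrier, ...]
    sensors: tuple[str, ...] = ("green", "red")
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.carriers = tuple(
            c if isinstance(c, Carrier) else Carrier(*c) for c in self.carriers
        )
        self.sensors = tuple(self.sensors)
        if self.samples.shape[0] != len(self.sensors):
            raise ValueError(
                f"samples has {self.samples.shape[0]} rows but {len(self.sensors)} sensors named"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        fmax = max(c.frequency for c in self.carriers)
        if self.fs_raw <= 2 * fmax:
            raise ValueError(
                f"fs_raw={self.fs_raw} Hz violates Nyquist for carrier {fmax} Hz"
            )
        if self.fs_raw < 10 * fmax:
            warnings.warn(
                f"fs_raw={self.fs_raw} Hz is below 10x the {fmax} Hz carrier; "
                "demodulation accuracy may degrade",
                stacklevel=2,
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs_raw

    def sensor_row(self, role: str) -> np.ndarray:
        try:
            return self.samples[self.sensors.index(role)]
        except ValueError:
            raise KeyError(f"no sensor with role {role!r}") from None

    def carrier_for(self, role: str) -> Carrier:
        for c in self.carriers:
            if c.role == role:
                return c
        raise KeyError(f"no carrier with role {role!r}")


@dataclass
class ConditionedTrace:
    """A regularly sampled single-channel trace at some processing stage."""

    fs: float
    values: np.ndarray
    channel: str = "green"  # green | red | autofluorescence
    stage: str = "demodulated"  # demodulated | downsampled | detrended | zscored
    units: str = "au"  # au | z
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("ConditionedTrace values must be 1-D")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.stage == "zscored":
            if abs(float(np.mean(self.values))) > 1e-6 or abs(float(np.std(self.values)) - 1) > 1e-6:
                raise ValueError("zscored trace must have mean 0 and SD 1")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fs

    @property
    def duration(self) -> float:
        return self.values.size / self.fs


@dataclass(frozen=True)
class PhotometryConfig:
    """Knobs for the conditioning pipeline.

    ``detrend_after_downsample`` and ``zscore_window`` exist because the
    original acquisition script's order of operations is not fully specified;
    defaults detrend the 50 Hz trace and z-score over the whole session.
    """

    lowpass_cutoff: float = 20.0
    filter_order: int = 4
    poly_order: int = 3
    downsample_fs: float = 50.0
    settle_discard: float = 0.5
    detrend_after_downsample: bool = True
    zscore_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.lowpass_cutoff <= 0 or self.filter_order < 1:
            raise ValueError("invalid low-pass settings")
        if self.poly_order < 0:
            raise ValueError("poly_order must be >= 0")
        if self.downsample_fs <= 2 * self.lowpass_cutoff:
            raise ValueError(
                "downsample_fs must exceed twice the low-pass cutoff "
                f"({self.downsample_fs} <= 2*{self.lowpass_cutoff})"
            )


def _check_crosstalk(cfg: PhotometryConfig, carriers: tuple[Carrier, ...]) -> None:
    freqs = sorted(c.frequency for c in carriers)
    if len(freqs) >= 2:
        gap = min(b - a for a, b in zip(freqs, freqs[1:]))
        if cfg.lowpass_cutoff >= gap / 2:
            raise ValueError(
                f"low-pass cutoff {cfg.lowpass_cutoff} Hz >= half the carrier gap "
                f"({gap} Hz); channels would cross-talk"
            )


def demodulate(
    rec: ModulatedRecording,
    carrier: Carrier | tuple[float, str],
    cfg: PhotometryConfig | None = None,
    sensor: str | None = None,
) -> ConditionedTrace:
    """Quadrature lock-in recovery of one carrier's envelope.

    The sensor row is mixed with sine and cosine references at the carrier
    frequency, each product is zero-phase low-pass filtered, and the envelope
    is ``4*sqrt(I^2 + Q^2)`` so a unit-amplitude offset sinusoid
    ``(1 + sin)/2`` demodulates to exactly 1.  The quadrature magnitude makes
    the result invariant to the (unrecoverable) carrier phase.
    """
    cfg = cfg or PhotometryConfig()
    if not isinstance(carrier, Carrier):
        carrier = Carrier(*carrier)
    if rec.fs_raw <= 2 * carrier.frequency:
        raise ValueError("fs_raw must exceed twice the carrier frequency")
    _check_crosstalk(cfg, rec.carriers)
    role = sensor if sensor is not None else carrier.role
    x = rec.sensor_row(role)

    t = np.arange(x.size) / rec.fs_raw
    w = 2 * np.pi * carrier.frequency * t
    sos = sps.butter(cfg.filter_order, cfg.lowpass_cutoff, fs=rec.fs_raw, output="sos")
    i = sps.sosfiltfilt(sos, x * np.sin(w))
    q = sps.sosfiltfilt(sos, x * np.cos(w))
    env = 4.0 * np.hypot(i, q)
    channel = carrier.role if role == carrier.role else "autofluorescence"
    return ConditionedTrace(
        fs=rec.fs_raw, values=env, channel=channel, stage="demodulated", t0=rec.start_time
    )


def extract_autofluorescence(
    rec: ModulatedRecording,
    own_carrier: Carrier | tuple[float, str],
    other_carrier: Carrier | tuple[float, str],
    cfg: PhotometryConfig | None = None,
) -> ConditionedTrace:
    """Autofluorescence estimate for one sensor.

    Demodulates the sensor at the *non-matching* carrier frequency: at that
    frequency the sensor sees only broadband autofluorescence excited by the
    other LED, not its own indicator.
    """
    if not isinstance(own_carrier, Carrier):
        own_carrier = Carrier(*own_carrier)
    if not isinstance(other_carrier, Carrier):
        other_carrier = Carrier(*other_carrier)
    if own_carrier.frequency == other_carrier.frequency:
        raise ValueError("autofluorescence extraction needs two distinct carriers")
    trace = demodulate(rec, other_carrier, cfg, sensor=own_carrier.role)
    trace.channel = "autofluorescence"
    return trace


def downsample(
    trace: ConditionedTrace,
    target_fs: float,
    lowpass_cutoff: float | None = None,
) -> ConditionedTrace:
    """Anti-alias filter and decimate to ``target_fs``.

    Output length is ``floor(duration * target_fs)``.
    """
    if target_fs > trace.fs:
        raise ValueError("target_fs must not exceed the trace rate")
    if lowpass_cutoff is not None and target_fs <= 2 * lowpass_cutoff:
        raise ValueError("target_fs must exceed twice the low-pass cutoff")
    q = trace.fs / target_fs
    if abs(q - round(q)) > 1e-9:
        raise ValueError(
            f"decimation factor {q} is not integral (fs={trace.fs}, target={target_fs})"
        )
    q = int(round(q))
    if q == 1:
        out = trace.values.copy()
    else:
        out = sps.resample_poly(trace.values, up=1, down=q, padtype="line")
    n_out = trace.values.size // q
    out = out[:n_out]
    return ConditionedTrace(
        fs=target_fs, values=out, channel=trace.channel, stage="downsampled", t0=trace.t0
    )


def detrend_poly(trace: ConditionedTrace, order: int = 3) -> ConditionedTrace:
    """Subtract a least-squares polynomial of ``order`` fitted over the full trace."""
    n = trace.values.size
    if n <= order + 1:
        raise ValueError(f"trace of length {n} too short for order-{order} detrend")
    t = trace.times
    if np.ptp(t) == 0:
        raise ValueError("degenerate (constant) time base")
    fit = np.polynomial.Polynomial.fit(t, trace.values, deg=order)
    resid = trace.values - fit(t)
    return ConditionedTrace(
        fs=trace.fs, values=resid, channel=trace.channel, stage="detrended", t0=trace.t0
    )


def fit_autofluorescence(
    sig: ConditionedTrace, autofluor: ConditionedTrace
) -> tuple[float, float, ConditionedTrace]:
    """OLS fit of the channel signal on its autofluorescence estimate.

    Returns ``(slope, intercept, fitted)`` where
    ``fitted = slope * autofluor + intercept``.  A zero-variance
    autofluorescence regressor yields ``slope = nan`` (flagged by warning)
    with ``fitted`` equal to the signal mean.
    """
    if sig.values.size != autofluor.values.size or sig.fs != autofluor.fs:
        raise ValueError("signal and autofluorescence traces must be aligned")
    a = autofluor.values
    s = sig.values
    var = float(np.var(a))
    if var == 0.0:
        warnings.warn("autofluorescence regressor has zero variance; slope undefined", stacklevel=2)
        slope, intercept = float("nan"), float(np.mean(s))
        fitted_vals = np.full_like(s, np.mean(s))
    else:
        slope = float(np.cov(a, s, bias=True)[0, 1] / var)
        intercept = float(np.mean(s) - slope * np.mean(a))
        fitted_vals = slope * a + intercept
    fitted = ConditionedTrace(
        fs=sig.fs, values=fitted_vals, channel=sig.channel, stage=sig.stage, t0=sig.t0
    )
    return slope, intercept, fitted


def zscore_corrected(sig: ConditionedTrace, fitted_autofluor: ConditionedTrace) -> ConditionedTrace:
    """z-score of (signal - fitted autofluorescence) over the whole trace."""
    if sig.values.size != fitted_autofluor.values.size:
        raise ValueError("signal and fitted autofluorescence must be aligned")
    d = sig.values - fitted_autofluor.values
    sd = float(np.std(d))
    if sd == 0.0:
        raise ValueError("zero-variance residual; z-score undefined")
    z = (d - np.mean(d)) / sd
    return ConditionedTrace(
        fs=sig.fs, values=z, channel=sig.channel, stage="zscored", units="z", t0=sig.t0
    )


@dataclass
class ProcessedSession:
    """Outputs of :func:`process_session`: one z-trace per channel plus a stage log."""

    green: ConditionedTrace
    red: ConditionedTrace
    autofluorescence: dict[str, ConditionedTrace] = field(default_factory=dict)
    log: list[dict] = field(default_factory=list)

    def channel(self, role: str) -> ConditionedTrace:
        if role == "green":
            return self.green
        if role == "red":
            return self.red
        raise KeyError(role)


def _trim(trace: ConditionedTrace, seconds: float) -> ConditionedTrace:
    k = int(round(seconds * trace.fs))
    if k == 0:
        return trace
    if 2 * k >= trace.values.size:
        raise ValueError("settle_discard longer than the trace")
    return ConditionedTrace(
        fs=trace.fs,
        values=trace.values[k:-k].copy(),
        channel=trace.channel,
        stage=trace.stage,
        units=trace.units,
        t0=trace.t0 + k / trace.fs,
    )


def process_session(rec: ModulatedRecording, cfg: PhotometryConfig | None = None) -> ProcessedSession:
    """Full conditioning pipeline for a two-carrier recording.

    Per channel: demodulate own carrier -> demodulate the cross carrier on the
    same sensor (autofluorescence) -> downsample both to 50 Hz -> trim the
    filter settling margin -> polynomial detrend -> regress out the fitted
    autofluorescence -> z-score.  Channel-role convention: red carries the
    superficial (creON RGeCO1a) population, green the deep (creOFF GCaMP6f)
    population.
    """
    cfg = cfg or PhotometryConfig()
    if len(rec.carriers) != 2:
        raise ValueError("process_session expects exactly two carriers")
    log: list[dict] = []
    out: dict[str, ConditionedTrace] = {}
    afs: dict[str, ConditionedTrace] = {}
    by_role = {c.role: c for c in rec.carriers}
    for role, own in by_role.items():
        other = next(c for c in rec.carriers if c.role != role)
        sig = demodulate(rec, own, cfg)
        af = extract_autofluorescence(rec, own, other, cfg)
        log.append({"channel": role, "stage": "demodulated", "fs": rec.fs_raw})
        sig = downsample(sig, cfg.downsample_fs, cfg.lowpass_cutoff)
        af = downsample(af, cfg.downsample_fs, cfg.lowpass_cutoff)
        sig = _trim(sig, cfg.settle_discard)
        af = _trim(af, cfg.settle_discard)
        log.append({"channel": role, "stage": "downsampled", "fs": cfg.downsample_fs,
                    "n": int(sig.values.size), "settle_discard_s": cfg.settle_discard})
        sig = detrend_poly(sig, cfg.poly_order)
        af = detrend_poly(af, cfg.poly_order)
        log.append({"channel": role, "stage": "detrended", "poly_order": cfg.poly_order})
        slope, intercept, fitted = fit_autofluorescence(sig, af)
        z = zscore_corrected(sig, fitted)
        log.append({"channel": role, "stage": "zscored",
                    "autofluor_slope": slope, "autofluor_intercept": intercept})
        out[role] = z
        afs[role] = af
    return ProcessedSession(green=out["green"], red=out["red"], autofluorescence=afs, log=log)
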