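"""Patch-clamp trace containers and event analysis.

This module implements the trace-level analysis pipeline: the online GDP
detector (a causal floating average compared against a preset threshold,
emulating a microcontroller running next to the amplifier), action-potential
counting, charge integration, the voltage-ramp subtraction method for
E_GABA, template-free PSC detection with rise/decay/charge features, and
first-derivative event detection for recordings where outward GABAergic
and inward glutamatergic currents overlap.

Traces are uniformly sampled, stored in mV (current clamp) or pA (voltage
clamp) with the sampling interval ``dt`` in ms.  Trace files are plain
text: a ``# key = value`` header block followed by two whitespace-separated
columns (time_ms, value).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "RecordingMode",
    "Trace",
    "DetectorConfig",
    "GdpEvent",
    "PscEvent",
    "RampSpec",
    "NoReversalError",
    "TraceConfigError",
    "read_trace",
    "write_trace",
    "floating_average",
    "detect_gdps",
    "count_action_potentials",
    "integrate_charge",
    "extract_egaba_from_ramp",
    "detect_pscs",
    "detect_events_by_derivative",
    "cumulative_onset_distribution",
]


class RecordingMode(str, Enum):
    CURRENT_CLAMP = "current_clamp"
    VOLTAGE_CLAMP = "voltage_clamp"


class TraceConfigError(ValueError):
    """Detector/analysis configuration incompatible with the trace."""


class NoReversalError(ValueError):
    """The ramp difference current never changes sign."""


@dataclass
class Trace:
    """A uniformly sampled recording.

    ``samples`` are mV in current clamp and pA in voltage clamp; ``dt`` is
    the sampling interval in ms.  ``meta`` carries free-form provenance
    (holding potential, pipette Cl-, applied junction offset, seed, ...).
    """

    samples: np.ndarray
    dt: float
    mode: RecordingMode = RecordingMode.CURRENT_CLAMP
    units: str = "mV"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace samples must be finite")
        expected = {"current_clamp": "mV", "voltage_clamp": "pA"}
        if self.units != expected[RecordingMode(self.mode).value]:
            raise ValueError(
                f"units {self.units!r} inconsistent with mode {self.mode!r}"
            )
        self.mode = RecordingMode(self.mode)

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Total duration in ms."""
        return self.n * self.dt

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms (first sample at t = 0)."""
        return np.arange(self.n) * self.dt

    def index(self, t_ms: float) -> int:
        return int(round(t_ms / self.dt))


@dataclass(frozen=True)
class DetectorConfig:
    """Configuration of the online GDP detector.

    ``window_n`` is the length (in samples) of the causal floating average
    that suppresses triggering by single action potentials; ``latency`` is
    the interval (s) between the detected event end and the trigger signal
    that would switch the amplifier to the ramp protocol.
    """

    threshold: float
    window_n: int = 50
    latency: float = 2.0
    min_event_duration: float = 0.0  # ms

    def __post_init__(self) -> None:
        if self.window_n < 1:
            raise TraceConfigError("window_n must be >= 1")
        if not 0.1 <= self.latency <= 20.0:
            raise TraceConfigError("latency must be within 0.1-20 s")


@dataclass(frozen=True)
class GdpEvent:
    onset: float          # ms
    end: float            # ms
    peak_amplitude: float  # mV above pre-event baseline
    duration: float       # s
    ap_count: int = 0
    trigger_time: float = float("nan")  # ms; end + latency

    def __post_init__(self) -> None:
        if self.end <= self.onset:
            raise ValueError("event end must be after onset")


@dataclass(frozen=True)
class PscEvent:
    onset: float       # ms
    amplitude: float   # pA, positive
    rise_time: float   # ms, 10-90%
    decay_tau: float   # ms, single-exponential
    charge: float      # fC
    polarity: str      # "inward" | "outward"


@dataclass(frozen=True)
class RampSpec:
    """Voltage-ramp command: a depolarized pre-step, then a linear ramp."""

    v_start: float = -3.0
    v_end: float = -63.0
    pre_step_duration: float = 100.0  # ms
    ramp_duration: float = 200.0      # ms

    def __post_init__(self) -> None:
        if self.v_start <= self.v_end:
            raise ValueError("v_start must be above v_end")
        if self.ramp_duration <= 0:
            raise ValueError("ramp_duration must be > 0")

    def command(self, times: np.ndarray, t0: float = 0.0) -> np.ndarray:
        """Command voltage (mV) at ``times`` (ms); pre-step begins at t0."""
        t = np.asarray(times, dtype=float) - t0
        frac = np.clip((t - self.pre_step_duration) / self.ramp_duration, 0.0, 1.0)
        return self.v_start + frac * (self.v_end - self.v_start)


# ---------------------------------------------------------------------------
# Trace file I/O

def write_trace(path: str | Path, trace: Trace) -> None:
    path = Path(path)
    lines = [f"# mode = {trace.mode.value}", f"# units = {trace.units}",
             f"# dt = {float(trace.dt)!r}"]
    for key, value in sorted(trace.meta.items()):
        lines.append(f"# {key} = {value}")
    header = "\n".join(lines) + "\n"
    with path.open("w") as fh:
        fh.write(header)
        for t, v in zip(trace.times, trace.samples):
            fh.write(f"{float(t)!r}\t{float(v)!r}\n")


def read_trace(path: str | Path) -> Trace:
    path = Path(path)
    meta: dict = {}
    with path.open() as fh:
        body_start = 0
        for line in fh:
            if not line.startswith("#"):
                break
            body_start += 1
            key, _, value = line[1:].partition("=")
            meta[key.strip()] = value.strip()
    data = np.loadtxt(path, comments="#", ndmin=2)
    mode = meta.pop("mode", "current_clamp")
    units = meta.pop("units", "mV")
    dt = float(meta.pop("dt"))
    return Trace(samples=data[:, 1], dt=dt, mode=RecordingMode(mode),
                 units=units, meta=meta)


# ---------------------------------------------------------------------------
# GDP detection

def floating_average(x: np.ndarray, window_n: int) -> np.ndarray:
    """Strictly causal moving average of the last ``window_n`` samples.

    Before ``window_n`` samples have accumulated the average runs over the
    samples seen so far, as a streaming implementation would.
    """
    x = np.asarray(x, dtype=float)
    c = np.cumsum(x)
    out = np.empty_like(x)
    n = min(window_n, x.size)
    out[:n] = c[:n] / np.arange(1, n + 1)
    if x.size > window_n:
        out[window_n:] = (c[window_n:] - c[:-window_n]) / window_n
    return out


def detect_gdps(trace: Trace, cfg: DetectorConfig) -> list[GdpEvent]:
    """Online GDP detection by threshold crossing of a floating average.

    An event opens when the causal ``window_n``-sample average of the
    membrane potential crosses ``cfg.threshold`` upward and closes when the
    average falls below the threshold again.  The causal average delays the
    detected onset by up to ``window_n * dt`` ms relative to the true
    depolarization onset.  Events shorter than ``min_event_duration`` are
    discarded.  ``trigger_time`` is the event end plus the configured
    latency (the moment the ramp protocol would be launched).
    """
    if trace.mode is not RecordingMode.CURRENT_CLAMP:
        raise TraceConfigError("GDP detection requires a current-clamp trace")
    if cfg.window_n > trace.n:
        raise TraceConfigError("floating-average window longer than trace")
    avg = floating_average(trace.samples, cfg.window_n)
    above = avg >= cfg.threshold
    edges = np.diff(above.astype(np.int8))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(trace.n - 1)

    baseline_win = trace.index(200.0)  # 200 ms pre-event baseline
    events = []
    for i0, i1 in zip(starts, ends):
        onset, end = i0 * trace.dt, i1 * trace.dt
        if end - onset < cfg.min_event_duration:
            continue
        b0 = max(0, i0 - baseline_win)
        baseline = float(np.median(trace.samples[b0:i0])) if i0 > b0 \
            else float(trace.samples[0])
        peak = float(np.max(trace.samples[i0:i1 + 1]) - baseline)
        events.append(GdpEvent(onset=onset, end=end, peak_amplitude=peak,
                               duration=(end - onset) / 1e3,
                               trigger_time=end + cfg.latency * 1e3))
    return events


def count_action_potentials(trace: Trace, event: GdpEvent,
                            dvdt_threshold: float = 10.0,
                            lockout: float = 2.0) -> int:
    """Count APs inside an event window by upward dV/dt crossings.

    ``dvdt_threshold`` is in mV/ms; crossings within ``lockout`` ms of the
    previous one are ignored (a spike is counted once).
    """
    if trace.mode is not RecordingMode.CURRENT_CLAMP:
        raise TraceConfigError("AP counting requires a current-clamp trace")
    i0, i1 = trace.index(event.onset), min(trace.index(event.end), trace.n - 1)
    seg = trace.samples[i0:i1 + 1]
    dvdt = np.diff(seg) / trace.dt
    above = dvdt >= dvdt_threshold
    crossings = np.nonzero(~above[:-1] & above[1:])[0]
    count, last = 0, -np.inf
    for idx in crossings:
        t = idx * trace.dt
        if t - last >= lockout:
            count += 1
            last = t
    return count


def integrate_charge(trace: Trace, t0: float, t1: float,
                     baseline: float) -> float:
    """Charge (pC) as the trapezoidal integral of |I - baseline| over [t0, t1]."""
    if trace.mode is not RecordingMode.VOLTAGE_CLAMP:
        raise TraceConfigError("charge integration requires a voltage-clamp trace")
    if not 0 <= t0 < t1 <= trace.duration:
        raise IndexError("integration window outside trace")
    i0, i1 = trace.index(t0), min(trace.index(t1), trace.n - 1)
    seg = np.abs(trace.samples[i0:i1 + 1] - baseline)
    return float(np.trapezoid(seg, dx=trace.dt)) / 1e3  # pA*ms -> pC


# ---------------------------------------------------------------------------
# Ramp-subtraction E_GABA

def extract_egaba_from_ramp(control: Trace, gaba: Trace, spec: RampSpec,
                            ramp_start: float | None = None,
                            method: str = "interp",
                            voltage: np.ndarray | None = None) -> float:
    """E_GABA (mV) from a control/GABA voltage-ramp pair.

    The control current is subtracted sample-wise from the current recorded
    in the presence of GABA; the membrane potential at which the difference
    current reverses sign is E_GABA.  By default the potential axis is the
    nominal command ramp; a recorded voltage trace (e.g. the sampled soma
    potential of a discontinuous single-electrode clamp, which is free of
    the I*Rs electrode drop) can be passed as ``voltage``.  ``method=
    "interp"`` locates the zero crossing by linear interpolation between
    the bracketing samples; ``method="linefit"`` fits a least-squares line
    to the difference current against voltage over the ramp (robust to
    noise).  If several crossings occur inside the ramp the one closest to
    mid-ramp is used and a warning is emitted.
    """
    if control.n != gaba.n or control.dt != gaba.dt:
        raise ValueError("control and GABA traces must share timing")
    if ramp_start is None:
        ramp_start = float(control.meta.get("ramp_start_ms", spec.pre_step_duration))
    i0 = control.index(ramp_start)
    i1 = control.index(ramp_start + spec.ramp_duration)
    i1 = min(i1, control.n - 1)
    if i1 <= i0 + 1:
        raise ValueError("traces do not cover the ramp segment")
    diff = gaba.samples[i0:i1 + 1] - control.samples[i0:i1 + 1]
    if voltage is not None:
        voltage = np.asarray(voltage, dtype=float)
        if voltage.size != control.n:
            raise ValueError("voltage trace must share the current timing")
        v = voltage[i0:i1 + 1]
    else:
        v = spec.command(control.times[i0:i1 + 1],
                         t0=ramp_start - spec.pre_step_duration)

    if method == "linefit":
        slope, intercept = np.polyfit(v, diff, 1)
        if slope == 0:
            raise NoReversalError("difference current does not depend on voltage")
        e_rev = -intercept / slope
        if not (min(v) <= e_rev <= max(v)):
            raise NoReversalError(
                f"fitted reversal {e_rev:.1f} mV lies outside the ramp span"
            )
        return float(e_rev)

    sign = np.sign(diff)
    sign[sign == 0] = 1
    crossings = np.nonzero(np.diff(sign))[0]
    if crossings.size == 0:
        raise NoReversalError("difference current never changes sign over the ramp")
    v_mid = 0.5 * (spec.v_start + spec.v_end)
    cand = []
    for k in crossings:
        # linear interpolation of the crossing against command voltage
        d0, d1 = diff[k], diff[k + 1]
        frac = d0 / (d0 - d1)
        cand.append(v[k] + frac * (v[k + 1] - v[k]))
    if len(cand) > 1:
        warnings.warn(
            f"{len(cand)} zero crossings in ramp difference; "
            "using the one closest to mid-ramp", stacklevel=2)
    return float(min(cand, key=lambda e: abs(e - v_mid)))


# ---------------------------------------------------------------------------
# PSC detection

def _single_exp(t, a, tau):
    return a * np.exp(-t / tau)


def detect_pscs(trace: Trace, polarity: str = "outward",
                amp_threshold: float = 10.0,
                min_separation: float = 5.0) -> list[PscEvent]:
    """Template-free PSC detection with shape features.

    The trace is baseline-subtracted (median), rectified according to
    ``polarity`` and searched for peaks above ``amp_threshold`` (pA).  For
    each event the 10-90% rise time, a single-exponential decay constant
    (fit from 90% of peak), and the charge (integral to return-to-baseline)
    are measured.  Events overlapping within one decay constant are split
    at the local minimum between peaks.
    """
    if trace.mode is not RecordingMode.VOLTAGE_CLAMP:
        raise TraceConfigError("PSC detection requires a voltage-clamp trace")
    if polarity not in ("inward", "outward"):
        raise ValueError("polarity must be 'inward' or 'outward'")
    # baseline from the event-free side of the distribution: at high event
    # rates the median itself is dragged toward the event polarity
    pct = 25.0 if polarity == "outward" else 75.0
    baseline = float(np.percentile(trace.samples, pct))
    y = trace.samples - baseline
    if polarity == "inward":
        y = -y
    # one event per contiguous supra-threshold region
    above = y >= amp_threshold
    edges = np.diff(above.astype(np.int8))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    stops = list(np.nonzero(edges == -1)[0] + 1)
    if above.size and above[0]:
        starts.insert(0, 0)
    if above.size and above[-1]:
        stops.append(y.size)
    regions: list[list[int]] = []
    gap = max(1, trace.index(min_separation))
    for s, e in zip(starts, stops):
        if e <= s:
            continue
        if regions and s - regions[-1][1] < gap:
            regions[-1][1] = e  # brief dips below threshold do not split
        else:
            regions.append([s, e])
    peaks = np.array([s + int(np.argmax(y[s:e])) for s, e in regions],
                     dtype=int)

    events: list[PscEvent] = []
    noise_floor = 0.1 * amp_threshold
    for j, p in enumerate(peaks):
        amp = float(y[p])
        # onset: walk back to 10% of peak
        i = p
        lo = peaks[j - 1] if j > 0 else 0
        while i > lo and y[i] > 0.1 * amp:
            i -= 1
        onset_idx = i
        # 10-90% rise
        seg = y[onset_idx:p + 1]
        t10 = np.searchsorted(seg, 0.1 * amp)
        t90 = np.searchsorted(seg, 0.9 * amp)
        rise = max(t90 - t10, 1) * trace.dt
        # decay fit from 90% of peak down to return-to-baseline or next event
        hi = peaks[j + 1] if j + 1 < len(peaks) else y.size
        k = p
        while k < hi - 1 and y[k] > noise_floor:
            k += 1
        if j + 1 < len(peaks) and k == hi - 1:
            # overlapping events: split at the minimum between the peaks
            k = p + int(np.argmin(y[p:hi]))
        tail = y[p:k + 1]
        tt = np.arange(tail.size) * trace.dt
        if tail.size >= 4:
            try:
                popt, _ = curve_fit(_single_exp, tt, tail, p0=(amp, 10.0),
                                    maxfev=2000)
                tau = float(abs(popt[1]))
            except RuntimeError:
                tau = float(np.trapezoid(tail, dx=trace.dt) / max(amp, 1e-12))
        else:
            tau = trace.dt
        charge = float(np.trapezoid(y[onset_idx:k + 1], dx=trace.dt))  # pA*ms = fC
        events.append(PscEvent(onset=onset_idx * trace.dt, amplitude=amp,
                               rise_time=float(rise), decay_tau=tau,
                               charge=max(charge, 0.0), polarity=polarity))
    return events


def detect_events_by_derivative(trace: Trace, k: float = 6.0,
                                smooth_ms: float = 1.0,
                                lockout_ms: float = 5.0
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Onset detection from the first derivative of a current trace.

    Designed for recordings at intermediate holding potentials where
    outward (GABAergic) and inward (glutamatergic) currents overlap and
    cannot be separated by amplitude.  The trace is smoothed over
    ``smooth_ms``, differentiated, and onsets are flagged where the
    derivative exceeds +/- ``k`` times the MAD-estimated derivative noise.
    Returns (outward_onsets, inward_onsets) in ms.  Onset times are
    invariant under amplitude rescaling of the trace.
    """
    if trace.n < 3:
        return np.empty(0), np.empty(0)
    w = max(1, trace.index(smooth_ms))
    kernel = np.ones(w) / w
    sm = np.convolve(trace.samples, kernel, mode="same")
    deriv = np.diff(sm) / trace.dt
    mad = float(np.median(np.abs(deriv - np.median(deriv))))
    # relative floor keeps noiseless traces usable and preserves
    # amplitude-rescaling invariance of the onset times
    scale = max(1.4826 * mad, 0.05 * float(np.max(np.abs(deriv))))
    if scale == 0:
        return np.empty(0), np.empty(0)
    thr = k * scale
    lock = max(1, trace.index(lockout_ms))

    def _onsets(mask: np.ndarray) -> np.ndarray:
        idx = np.nonzero(mask)[0]
        keep, last = [], -lock - 1
        for i in idx:
            if i - last > lock:
                keep.append(i)
            last = i
        return np.asarray(keep, dtype=float) * trace.dt

    return _onsets(deriv > thr), _onsets(deriv < -thr)


def cumulative_onset_distribution(onsets: Sequence[float],
                                  gdp_windows: Sequence[tuple[float, float]]
                                  ) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF of event onsets over normalized GDP time.

    Each onset is mapped to (onset - w0)/(w1 - w0) within the window that
    contains it; onsets outside every window are excluded with a warning.
    Returns (sorted normalized onsets, cumulative probabilities).
    """
    normed, dropped = [], 0
    for t in onsets:
        for w0, w1 in gdp_windows:
            if w0 <= t <= w1:
                normed.append((t - w0) / (w1 - w0))
                break
        else:
            dropped += 1
    if dropped:
        warnings.warn(f"{dropped} onsets outside all GDP windows were excluded",
                      stacklevel=2)
    x = np.sort(np.asarray(normed))
    cdf = np.arange(1, x.size + 1) / max(x.size, 1)
    return x, cdf
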