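"""Seeded generators for surrogate morphologies and synthetic recordings.

No recordings or reconstructions were deposited with the measurements this
package models, so every pipeline stage is exercised on synthetic data
whose statistics match the reported values: GDPs at ~1.3 min^-1 with
~24.9 mV amplitude and ~1.24 s duration riding action potentials in
current clamp; GABAergic/glutamatergic sPSC trains (7.8 / 5.8 Hz, with the
reported amplitudes and kinetics) in voltage clamp; ramp-protocol current
pairs; and surrogate immature CA3 pyramidal morphologies consistent with
the measured membrane capacitance.

Every generator is a pure function of (spec, seed): identical inputs give
identical outputs, and each recording generator returns the exact injected
ground-truth event table for recovery testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .morphology import Morphology, Section
from .traces import RampSpec, RecordingMode, Trace

__all__ = [
    "SurrogateMorphologySpec",
    "SyntheticRecordingSpec",
    "GenerationError",
    "make_surrogate_morphology",
    "generate_recording",
    "generate_ramp_pair",
]


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SurrogateMorphologySpec:
    """Surrogate immature CA3 pyramidal cell.

    The tree is scaled so the total membrane area matches
    ``target_capacitance`` at 1 uF/cm^2.  Defaults emulate a small
    perforated-patch-sized cell (65 pF) with a few long, thin, tapering
    dendrites; see the methods note for the geometric reasoning.
    """

    soma_diameter: float = 15.0       # um
    n_primary_dendrites: int = 7
    mean_path_length: float = 700.0   # um
    taper: float = 0.4                # distal/proximal diameter ratio
    branch_prob: float = 0.5          # per 100 um
    trunk_fraction: float = 0.5       # unbranched trunk, fraction of path
    primary_diameter: float = 0.5     # um at the soma
    target_capacitance: float = 65.0  # pF
    seed: int = 0

    def __post_init__(self) -> None:
        if self.soma_diameter <= 0 or self.mean_path_length <= 0 \
                or self.primary_diameter <= 0:
            raise GenerationError("geometry must be positive")
        if not 30.0 <= self.target_capacitance <= 200.0:
            raise GenerationError("target_capacitance must be in 30-200 pF")
        if self.n_primary_dendrites < 1:
            raise GenerationError("need at least one primary dendrite")


@dataclass(frozen=True)
class SyntheticRecordingSpec:
    """Statistics of a synthetic current- or voltage-clamp recording.

    Defaults are the reported population values: GDP rate 1.3 min^-1,
    current-clamp amplitude 24.9 mV and duration 1.24 s (0.91 s for the
    voltage-clamp envelope at 0 mV); sPSC frequencies 7.8 Hz (GABAergic)
    and 5.8 Hz (glutamatergic).
    """

    duration: float = 300.0           # s
    mode: RecordingMode = RecordingMode.CURRENT_CLAMP
    dt: float = 0.1                   # ms (10 kHz)
    baseline: float = -55.0           # mV (CC) or holding current pA (VC)
    holding: float = 0.0              # mV, VC only
    gdp_rate: float = 1.3             # min^-1
    gdp_amplitude: float = 24.9       # mV (CC); VC amplitude set by holding
    gdp_duration: float = 1.24        # s (CC)
    spsc_freq_gaba: float = 7.8       # Hz
    spsc_freq_glu: float = 5.8        # Hz
    suprathreshold: bool = True
    ap_mean_count: float = 6.4
    noise_sd: float = 0.5             # mV or pA
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", RecordingMode(self.mode))
        if self.duration <= 0 or self.dt <= 0:
            raise GenerationError("duration and dt must be positive")
        for r in (self.gdp_rate, self.spsc_freq_gaba, self.spsc_freq_glu):
            if r < 0:
                raise GenerationError("rates must be >= 0")


# ---------------------------------------------------------------------------
# Morphology

def make_surrogate_morphology(spec: SurrogateMorphologySpec) -> Morphology:
    """Random branched tree scaled to the target capacitance (within 5%).

    Primary dendrites grow from the soma in sections of ~40 um; each
    section may bifurcate with probability ``branch_prob`` per 100 um,
    children tapering toward ``taper`` times the primary diameter at the
    tips.  Dendritic diameters are rescaled (lengths fixed) until total
    membrane area times 1 uF/cm^2 matches the target capacitance.
    """
    rng = np.random.default_rng(spec.seed)
    sections = [Section(id=1, parent_id=-1, length=spec.soma_diameter,
                        diam_prox=spec.soma_diameter,
                        diam_dist=spec.soma_diameter, region="soma")]
    next_id = 2
    seg_len = 40.0

    def grow(parent_id: int, diam: float, grown: float, path_target: float,
             depth: int) -> None:
        nonlocal next_id
        if grown >= path_target or diam < 0.15 or depth > 12:
            return
        length = float(np.clip(rng.normal(seg_len, 8.0), 15.0, 80.0))
        frac_left = max(path_target - grown, 1.0)
        d_tip = spec.taper * spec.primary_diameter
        d_end = max(d_tip, diam - (diam - d_tip) * min(length / frac_left, 1.0))
        sec = Section(id=next_id, parent_id=parent_id, length=length,
                      diam_prox=diam, diam_dist=d_end, region="dendrite")
        sections.append(sec)
        sid = next_id
        next_id += 1
        may_branch = grown + length > spec.trunk_fraction * path_target
        if may_branch and rng.random() < spec.branch_prob * length / 100.0 \
                and depth < 8:
            for _ in range(2):
                child_target = path_target * float(rng.uniform(0.7, 1.0))
                grow(sid, d_end, grown + length, child_target, depth + 1)
        else:
            grow(sid, d_end, grown + length, path_target, depth + 1)

    for _ in range(spec.n_primary_dendrites):
        target = float(rng.normal(spec.mean_path_length,
                                  0.2 * spec.mean_path_length))
        target = max(target, 60.0)
        grow(1, spec.primary_diameter, 0.0, target, 0)

    morph = Morphology(sections=sections)
    soma_area = morph.root.lateral_area
    target_area = spec.target_capacitance / 0.01  # cm=1 uF/cm^2 -> um^2
    for _ in range(30):
        cap = morph.capacitance()
        if abs(cap - spec.target_capacitance) / spec.target_capacitance < 0.05:
            return morph
        dend_area = morph.total_area - soma_area
        want = target_area - soma_area
        if want <= 0 or dend_area <= 0:
            break
        f = want / dend_area
        for s in morph.sections:
            if s.region == "dendrite":
                s.diam_prox *= f
                s.diam_dist *= f
    raise GenerationError(
        f"could not reach {spec.target_capacitance} pF "
        f"(got {morph.capacitance():.1f} pF)")


# ---------------------------------------------------------------------------
# Waveform primitives

def _biexp(t: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Unit-peak difference of exponentials for t >= 0."""
    tp = tau_rise * tau_decay / (tau_decay - tau_rise) * math.log(tau_decay / tau_rise)
    norm = math.exp(-tp / tau_decay) - math.exp(-tp / tau_rise)
    y = np.where(t >= 0, np.exp(-np.maximum(t, 0) / tau_decay)
                 - np.exp(-np.maximum(t, 0) / tau_rise), 0.0)
    return y / norm


def _poisson_times(rng: np.random.Generator, rate_hz: float, duration_ms: float,
                   min_interval_ms: float = 0.0, t0: float = 0.0) -> np.ndarray:
    times, t = [], t0
    if rate_hz <= 0:
        return np.empty(0)
    while True:
        t += rng.exponential(1e3 / rate_hz)
        if min_interval_ms and times and t - times[-1] < min_interval_ms:
            t = times[-1] + min_interval_ms
        if t >= duration_ms:
            return np.asarray(times)
        times.append(t)


# VC GDP envelope per holding potential: (amplitude pA, charge pC); the
# decay constant is solved so the biexponential integral matches the
# charge (reported 309.5 pA / 88 pC at 0 mV, 79.3 pA / 14.6 pC at -60 mV).
_VC_GDP = {0.0: (309.5, 88.0), -60.0: (79.3, 14.6), -30.0: (120.0, 30.0)}
_VC_RISE = 20.0  # ms


def _decay_for_charge(amp: float, charge_pc: float,
                      tau_rise: float = _VC_RISE) -> float:
    """Decay constant (ms) so a unit-peak biexponential of amplitude
    ``amp`` integrates to ``charge_pc``."""
    from scipy.optimize import brentq

    def integral(td: float) -> float:
        tp = tau_rise * td / (td - tau_rise) * math.log(td / tau_rise)
        norm = math.exp(-tp / td) - math.exp(-tp / tau_rise)
        return amp * (td - tau_rise) / norm / 1e3  # pC

    return float(brentq(lambda td: integral(td) - charge_pc,
                        tau_rise * 1.01 + 1e-6, 5e3))
# sPSC shape per class: amplitude pA, rise ms, decay ms (10-90%/exp fit values)
_SPSC_GABA = (46.9, 4.9, 37.3)
_SPSC_GLU = (18.3, 3.5, 10.8)


def generate_recording(spec: SyntheticRecordingSpec
                       ) -> tuple[Trace, pd.DataFrame]:
    """Synthesize a recording plus its ground-truth event table.

    Current clamp: GDPs are placed by a Poisson process (rate
    ``gdp_rate``, minimum inter-event interval 5 s), each a
    difference-of-exponentials depolarizing envelope (rise 150 ms, decay
    400 ms) scaled to ``gdp_amplitude``, with stereotyped 2.7 ms / 55 mV
    action potentials riding the crest when ``suprathreshold``.  sPSP/sPSC
    trains of both classes and Gaussian noise are superimposed.

    Voltage clamp: GDP-associated currents are single-exponential-decay
    envelopes whose amplitude and charge match the reported values at the
    holding potential; sPSCs use the reported class-specific shapes.

    The returned table lists every injected event (kind, onset ms,
    amplitude, duration ms, ap_count).
    """
    rng = np.random.default_rng(spec.seed)
    dur_ms = spec.duration * 1e3
    n = int(round(dur_ms / spec.dt))
    tt = np.arange(n) * spec.dt
    y = np.full(n, spec.baseline)
    rows = []

    gdp_times = _poisson_times(rng, spec.gdp_rate / 60.0, dur_ms,
                               min_interval_ms=5e3)
    cc = spec.mode is RecordingMode.CURRENT_CLAMP
    if cc:
        rise, decay = 150.0, 400.0
        for t0 in gdp_times:
            i0 = int(t0 / spec.dt)
            span = int(min(5 * decay, dur_ms - t0) / spec.dt)
            seg_t = (np.arange(span) * spec.dt)
            env = spec.gdp_amplitude * _biexp(seg_t, rise, decay)
            y[i0:i0 + span] += env
            ap_count = 0
            if spec.suprathreshold:
                ap_count = int(rng.poisson(spec.ap_mean_count))
                crest = seg_t[env > 0.5 * spec.gdp_amplitude]
                for k in range(ap_count):
                    if crest.size == 0:
                        break
                    ta = t0 + crest[0] + (crest[-1] - crest[0]) * (k + 0.5) / max(ap_count, 1)
                    ia = int(ta / spec.dt)
                    w = max(1, int(2.7 / spec.dt))
                    spike = 55.0 * (1 - np.abs(np.linspace(-1, 1, w)))
                    j1 = min(ia + w, n)
                    y[ia:j1] += spike[:j1 - ia]
            rows.append({"kind": "gdp", "onset": t0,
                         "amplitude": spec.gdp_amplitude,
                         "duration": spec.gdp_duration * 1e3,
                         "ap_count": ap_count})
        # subthreshold synaptic fluctuations (mV-scale PSPs)
        for kind, rate, amp, tr, td in (
                ("spsp_gaba", spec.spsc_freq_gaba, 2.0, 5.0, 40.0),
                ("spsp_glu", spec.spsc_freq_glu, 1.0, 3.0, 12.0)):
            for t0 in _poisson_times(rng, rate, dur_ms):
                i0 = int(t0 / spec.dt)
                span = min(int(5 * td / spec.dt), n - i0)
                y[i0:i0 + span] += amp * _biexp(np.arange(span) * spec.dt, tr, td)
                rows.append({"kind": kind, "onset": t0, "amplitude": amp,
                             "duration": td, "ap_count": 0})
    else:
        holding = spec.holding
        amp, charge = _VC_GDP.get(holding, (309.5, 88.0))
        decay = _decay_for_charge(amp, charge)
        sign = 1.0 if holding >= -15.0 else -1.0  # outward at 0, inward at -60
        for t0 in gdp_times:
            i0 = int(t0 / spec.dt)
            span = min(int(8 * decay / spec.dt), n - i0)
            seg_t = np.arange(span) * spec.dt
            env = amp * _biexp(seg_t, _VC_RISE, decay)
            y[i0:i0 + span] += sign * env
            rows.append({"kind": "gdp", "onset": t0, "amplitude": amp,
                         "duration": decay * 3, "ap_count": 0})
        classes = []
        if holding >= -15.0:
            classes.append(("spsc_gaba", spec.spsc_freq_gaba, _SPSC_GABA, 1.0))
        if holding <= -15.0:
            classes.append(("spsc_glu", spec.spsc_freq_glu, _SPSC_GLU, -1.0))
        if -45.0 < holding < -15.0:
            classes.append(("spsc_gaba", spec.spsc_freq_gaba, _SPSC_GABA, 1.0))
        for kind, rate, (a, tr, td), s in classes:
            for t0 in _poisson_times(rng, rate, dur_ms):
                i0 = int(t0 / spec.dt)
                span = min(int(6 * td / spec.dt), n - i0)
                y[i0:i0 + span] += s * a * _biexp(np.arange(span) * spec.dt, tr, td)
                rows.append({"kind": kind, "onset": t0, "amplitude": a,
                             "duration": td, "ap_count": 0})

    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=n)

    trace = Trace(samples=y, dt=spec.dt,
                  mode=spec.mode, units="mV" if cc else "pA",
                  meta={"seed": spec.seed, "holding": spec.holding,
                        "baseline": spec.baseline})
    truth = pd.DataFrame(rows, columns=["kind", "onset", "amplitude",
                                        "duration", "ap_count"])
    return trace, truth.sort_values("onset", ignore_index=True)


def generate_ramp_pair(leak: tuple[float, float], gaba: tuple[float, float],
                       ramp: RampSpec = RampSpec(), noise_sd: float = 0.0,
                       seed: int = 0, dt: float = 0.1
                       ) -> tuple[Trace, Trace]:
    """Ideal-clamp ramp currents for a leaky cell with/without GABA.

    ``leak`` = (g_leak nS, E_leak mV); ``gaba`` = (g_gaba nS, E_rev mV).
    The command is ``ramp``: a pre-step at v_start then a linear ramp to
    v_end.  Currents are i = g_l (V - E_l) [+ g_g (V - E_rev)] + noise.
    """
    rng = np.random.default_rng(seed)
    total = ramp.pre_step_duration + ramp.ramp_duration
    n = int(round(total / dt)) + 1
    t = np.arange(n) * dt
    v = ramp.command(t)
    g_l, e_l = leak
    g_g, e_g = gaba
    i_ctrl = g_l * (v - e_l)
    i_gaba = i_ctrl + g_g * (v - e_g)
    if noise_sd > 0:
        i_ctrl = i_ctrl + rng.normal(0, noise_sd, n)
        i_gaba = i_gaba + rng.normal(0, noise_sd, n)
    meta = {"ramp_start_ms": ramp.pre_step_duration, "seed": seed}
    make = lambda y: Trace(samples=y, dt=dt, mode=RecordingMode.VOLTAGE_CLAMP,
                           units="pA", meta=dict(meta))
    return make(i_ctrl), make(i_gaba)
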