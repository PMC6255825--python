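"""In-silico experiments composed from the cable model.

Four protocols:

* :func:`run_rs_experiment` — how the access resistance of a somatic
  single-electrode clamp affects the ramp-determined GABA reversal
  potential (static ions, 30 mM Cl- / 14.4 mM HCO3-).
* :func:`run_spaceclamp_experiment` — how the dendritic location of the
  GABA synapse biases the apparent [Cl-]i inferred from the ramp (distal
  sites overestimate a high [Cl-]i and underestimate a low one, because
  the attenuated dendritic voltage relaxes toward the leak reversal).
* :func:`run_gdp_simulation` — a GDP as a stochastic barrage of GABA and
  AMPA synapses over the dendritic tree with fully dynamic Cl-/HCO3-.
* :func:`calibrate_gdp_charge` — scales the GABA synapse count so the
  somatically clamped GABA-evoked charge at 0 mV (10 mM [Cl-]i, static)
  matches a target charge.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import ionphys
from .cable import CableModel, ClampSpec, SynapseSpec, TransportParams
from .traces import RampSpec, RecordingMode, Trace, extract_egaba_from_ramp

__all__ = [
    "GdpStimulus",
    "RampExperimentSpec",
    "CalibrationError",
    "run_rs_experiment",
    "run_spaceclamp_experiment",
    "run_gdp_simulation",
    "calibrate_gdp_charge",
]

_SETTLE_MS = 50.0


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class GdpStimulus:
    """The stochastic synaptic barrage of a simulated GDP.

    534 GABA synapses (0.789 nS, 0.5/80 ms) and 107 AMPA synapses
    (0.509 nS, 0.1/11 ms, E_rev 0 mV) are scattered uniformly over
    dendritic membrane area and activated once each, with normally
    distributed onset times truncated to ``window``.  GABA onsets lead
    and glutamatergic activity terminates earlier.
    """

    n_gaba: int = 534
    g_gaba: float = 0.789
    gaba_rise: float = 0.5
    gaba_decay: float = 80.0
    n_ampa: int = 107
    g_ampa: float = 0.509
    ampa_rise: float = 0.1
    ampa_decay: float = 11.0
    gaba_timing: tuple[float, float] = (500.0, 250.0)  # mean, sd (ms)
    ampa_timing: tuple[float, float] = (550.0, 180.0)
    window: tuple[float, float] = (0.0, 1500.0)
    p_split: float = 0.44
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_gaba < 0 or self.n_ampa < 0:
            raise ValueError("synapse counts must be >= 0")
        if self.gaba_timing[1] <= 0 or self.ampa_timing[1] <= 0:
            raise ValueError("timing sd must be > 0")


@dataclass(frozen=True)
class RampExperimentSpec:
    """GABA-application ramp experiment on the model."""

    rs: float = 5.0
    puff_g: float = 10.0         # nS
    puff_decay: float = 100.0    # ms
    puff_rise: float = 0.5       # ms
    ramp: RampSpec = RampSpec()
    static_ions: bool = True


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, n: int) -> np.ndarray:
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled))
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(ok.size, n - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    return out


def _dendritic_sites(model: CableModel, n: int,
                     rng: np.random.Generator) -> list[tuple[int, float]]:
    """Sample (section, position) uniformly over dendritic membrane area."""
    secs = [s for s in model.morph.sections if s.region == "dendrite"]
    if not secs:
        raise ValueError("morphology has no dendrites")
    w = np.array([s.lateral_area for s in secs])
    idx = rng.choice(len(secs), size=n, p=w / w.sum())
    pos = rng.uniform(0.0, 1.0, size=n)
    return [(secs[i].id, float(x)) for i, x in zip(idx, pos)]


def _ramp_command(spec: RampSpec, hold: float):
    """Command: hold, then pre-step at v_start, then the linear ramp."""
    def cmd(t: float) -> float:
        if t < _SETTLE_MS:
            return hold
        tau = t - _SETTLE_MS
        if tau < spec.pre_step_duration:
            return spec.v_start
        frac = min((tau - spec.pre_step_duration) / spec.ramp_duration, 1.0)
        return spec.v_start + frac * (spec.v_end - spec.v_start)
    return cmd


def _run_ramp_trace(model: CableModel, rs: float, spec: RampExperimentSpec,
                    site: tuple[int, float] | None, dt: float = 0.025,
                    record_every: float = 0.25) -> tuple[Trace, np.ndarray]:
    """Simulate one ramp; returns the recorded clamp current as a Trace
    plus the sampled soma potential (the amplifier's voltage readout)."""
    m = copy.deepcopy(model)
    m.freeze_ions(spec.static_ions)
    if site is not None:
        # puff-like synapse: near-stationary conductance during the ramp
        onset = _SETTLE_MS + spec.ramp.pre_step_duration - 20.0
        m.add_synapse(SynapseSpec(section=site[0], position=site[1],
                                  kind="gaba", g_peak=spec.puff_g,
                                  tau_rise=spec.puff_rise,
                                  tau_decay=spec.puff_decay, onset=onset))
    m.attach_clamp(ClampSpec(mode="sevc", rs=rs,
                             command=_ramp_command(spec.ramp,
                                                   model.passive.e_leak)))
    total = (_SETTLE_MS + spec.ramp.pre_step_duration
             + spec.ramp.ramp_duration + 10.0)
    rec = m.advance(total, dt=dt, record_every=record_every)
    trace = Trace(samples=rec["i_clamp"], dt=record_every,
                  mode=RecordingMode.VOLTAGE_CLAMP, units="pA",
                  meta={"ramp_start_ms":
                        _SETTLE_MS + spec.ramp.pre_step_duration - record_every})
    return trace, rec["v_soma"]


def determine_egaba(model: CableModel, rs: float, site: tuple[int, float],
                    spec: RampExperimentSpec | None = None) -> float:
    """Ramp-determined E_GABA (mV) for a synapse at ``site`` under SEVC.

    The crossing of the subtracted current is read against the recorded
    soma potential (a discontinuous SEVC samples the true membrane
    potential, so the I*Rs electrode drop does not enter the voltage
    axis); residual Rs sensitivity comes only from clamp dynamics.
    """
    spec = spec or RampExperimentSpec()
    control, v_ctrl = _run_ramp_trace(model, rs, spec, site=None)
    gaba, _ = _run_ramp_trace(model, rs, spec, site=site)
    return extract_egaba_from_ramp(control, gaba, spec.ramp, voltage=v_ctrl)


def run_rs_experiment(model: CableModel,
                      rs_list: tuple[float, ...] = (0.5, 5, 10, 20, 40),
                      cl_i: float = 30.0, hco3_i: float = 14.4,
                      site: tuple[int, float] | None = None) -> pd.DataFrame:
    """E_GABA determined at each access resistance (static ions).

    The GABA application is emulated by a proximal 10 nS synapse with a
    100 ms decay.  Returns a table (rs, e_gaba).
    """
    m = copy.deepcopy(model)
    m.set_concentrations(cl_i, hco3_i)
    m.freeze_ions(True)
    if site is None:
        site = _proximal_site(m)
    rows = [{"rs": rs, "e_gaba": determine_egaba(m, rs, site)}
            for rs in rs_list]
    return pd.DataFrame(rows)


def _proximal_site(model: CableModel) -> tuple[int, float]:
    dends = [s for s in model.morph.sections
             if s.region == "dendrite" and s.parent_id == model.morph.root.id]
    return (dends[0].id, 0.5)


def proximal_to_distal_sites(model: CableModel,
                             distances: tuple[float, ...] = (15.0, 35.0, 60.0,
                                                             80.0, 100.0)
                             ) -> list[tuple[int, float]]:
    """Synapse sites at given path distances (um) along the longest
    root-to-tip dendrite.

    The default ladder spans the range over which the somatic ramp can
    still drive the local membrane through the GABA reversal; further out
    the subtracted current no longer reverses within the ramp (the
    space-clamp failure the experiment quantifies).
    """
    morph = model.morph
    by_id = {s.id: s for s in morph.sections}
    tip = max((s for s in morph.sections if s.region == "dendrite"),
              key=lambda s: morph.path_distance(s.id))
    chain, cur = [], tip
    while cur.parent_id != -1:
        chain.append(cur)
        cur = by_id[cur.parent_id]
    chain.reverse()
    total = sum(s.length for s in chain)
    sites, walked, i = [], 0.0, 0
    for target in distances:
        target = min(target, total - 1e-6)
        while walked + chain[i].length < target and i < len(chain) - 1:
            walked += chain[i].length
            i += 1
        sites.append((chain[i].id, min((target - walked) / chain[i].length, 1.0)))
    return sites


def run_spaceclamp_experiment(model: CableModel,
                              synapse_sites: list[tuple[int, float]],
                              cl_i: float, hco3_i: float = 14.4,
                              rs: float = 5.0,
                              inversion_state: ionphys.IonState | None = None
                              ) -> pd.DataFrame:
    """Apparent [Cl-]i versus synapse location under somatic SEVC.

    For each site (ordered proximal to distal) the ramp-determined E_GABA
    is inverted through the conductance-split reversal relation
    (:func:`gdpflux.ionphys.cl_from_split_reversal`), the inversion
    consistent with the two-branch synapse the model implements;
    analysis-side constants (14.1 mM internal bicarbonate) unless
    overridden.  Returns a table (section, position, distance, e_gaba,
    apparent_cl).
    """
    m = copy.deepcopy(model)
    m.set_concentrations(cl_i, hco3_i)
    m.freeze_ions(True)
    state = inversion_state or ionphys.IonState()
    rows = []
    by_id = {s.id: s for s in m.morph.sections}
    for sec_id, pos in synapse_sites:
        e = determine_egaba(m, rs, (sec_id, pos))
        dist = (m.morph.path_distance(sec_id)
                - (1.0 - pos) * by_id[sec_id].length)
        rows.append({"section": sec_id, "position": pos, "distance": dist,
                     "e_gaba": e,
                     "apparent_cl": ionphys.cl_from_split_reversal(e, state)})
    return pd.DataFrame(rows)


def _place_stimulus(model: CableModel, stim: GdpStimulus,
                    onset_offset: float = 0.0) -> None:
    rng = np.random.default_rng(stim.seed)
    lo, hi = stim.window
    gaba_sites = _dendritic_sites(model, stim.n_gaba, rng)
    gaba_t = _truncated_normal(rng, *stim.gaba_timing, lo, hi, stim.n_gaba)
    ampa_sites = _dendritic_sites(model, stim.n_ampa, rng)
    ampa_t = _truncated_normal(rng, *stim.ampa_timing, lo, hi, stim.n_ampa)
    for (sec, pos), t0 in zip(gaba_sites, gaba_t):
        model.add_synapse(SynapseSpec(section=sec, position=pos, kind="gaba",
                                      g_peak=stim.g_gaba,
                                      tau_rise=stim.gaba_rise,
                                      tau_decay=stim.gaba_decay,
                                      onset=float(t0) + onset_offset,
                                      p_split=stim.p_split))
    for (sec, pos), t0 in zip(ampa_sites, ampa_t):
        model.add_synapse(SynapseSpec(section=sec, position=pos, kind="ampa",
                                      g_peak=stim.g_ampa,
                                      tau_rise=stim.ampa_rise,
                                      tau_decay=stim.ampa_decay,
                                      onset=float(t0) + onset_offset))


def run_gdp_simulation(model: CableModel, stim: GdpStimulus, cl_init: float,
                       hco3_init: float = 14.1, t_post: float = 5000.0,
                       dt: float = 0.025, dt_post: float = 0.25,
                       record_every: float = 5.0) -> dict[str, np.ndarray]:
    """Simulate a GDP with dynamic anions; return concentration time courses.

    The model starts at rest with uniform ``cl_init``/``hco3_init`` that
    also serve as the transport resting levels, receives the stimulus
    barrage over its window, and runs on for ``t_post`` ms afterwards
    (coarser time step once the synaptic conductances have decayed).
    Returns t (ms), v_soma, mean dendritic cl/hco3, their baseline values
    and delta time courses.
    """
    m = copy.deepcopy(model)
    m.set_concentrations(cl_init, hco3_init)
    m.set_transport(TransportParams(cl_rest=cl_init, hco3_rest=hco3_init))
    m.freeze_ions(False)
    m.attach_clamp(None)
    m.v[:] = m.passive.e_leak
    _place_stimulus(m, stim)
    baseline_cl = m.mean_dendritic_concentration("cl")
    baseline_hco3 = m.mean_dendritic_concentration("hco3")

    t_fast = stim.window[1] + 500.0  # let conductances decay before coarsening
    rec1 = m.advance(t_fast, dt=dt, record_every=record_every)
    rec2 = m.advance(t_post, dt=dt_post, record_every=4 * record_every)
    out = {k: np.concatenate([rec1[k], rec2[k]]) for k in rec1}
    out["baseline_cl"] = baseline_cl
    out["baseline_hco3"] = baseline_hco3
    out["delta_cl"] = out["cl_dend"] - baseline_cl
    out["delta_hco3"] = out["hco3_dend"] - baseline_hco3
    return out


def measure_clamp_charge(model: CableModel, stim: GdpStimulus,
                         hold_mv: float = 0.0, cl_i: float = 10.0,
                         hco3_i: float = 14.1, rs: float = 0.5,
                         dt: float = 0.025) -> float:
    """GABA-evoked somatic clamp charge (pC) under static ions.

    Only the GABA synapses of ``stim`` are placed; the cell is clamped at
    ``hold_mv`` and the clamp-current deflection from its pre-stimulus
    baseline is integrated over the stimulus window plus decay.
    """
    m = copy.deepcopy(model)
    m.set_concentrations(cl_i, hco3_i)
    m.freeze_ions(True)
    m.attach_clamp(ClampSpec(mode="sevc", rs=rs, command=lambda t: hold_mv))
    m.advance(50.0, dt=0.05)  # settle to the holding potential first
    baseline = m._last_i_clamp
    _place_stimulus(m, replace(stim, n_ampa=0), onset_offset=m.t)
    total = stim.window[1] + 6 * stim.gaba_decay
    rec = m.advance(total, dt=dt, record_every=0.5)
    defl = np.abs(rec["i_clamp"] - baseline)
    return float(np.trapezoid(defl, dx=0.5)) / 1e3  # pA*ms -> pC


def calibrate_gdp_charge(model: CableModel, stim: GdpStimulus,
                         target_charge: float = 88.0, tol: float = 0.05,
                         max_iter: int = 8) -> tuple[GdpStimulus, float]:
    """Scale ``n_gaba`` until the clamped GABA charge matches the target.

    The somatic clamp charge grows sublinearly in the synapse count
    (driving-force collapse in poorly clamped dendrites), so the count is
    iterated multiplicatively.  Returns (scaled stimulus, achieved charge
    in pC).  A target of 0 returns a stimulus without GABA synapses.
    """
    if target_charge == 0:
        return replace(stim, n_gaba=0), 0.0
    if target_charge < 0:
        raise CalibrationError("target charge must be >= 0")
    n = max(stim.n_gaba, 1)
    best = None
    for _ in range(max_iter):
        cand = replace(stim, n_gaba=n)
        q = measure_clamp_charge(model, cand)
        if best is None or abs(q - target_charge) < abs(best[1] - target_charge):
            best = (cand, q)
        if abs(q - target_charge) / target_charge <= tol:
            return cand, q
        n_new = max(1, int(round(n * target_charge / q)))
        if n_new == n:
            n_new = n + (1 if q < target_charge else -1)
            if n_new < 1:
                break
        n = n_new
    cand, q = best
    if abs(q - target_charge) / target_charge <= 2 * tol:
        return cand, q
    raise CalibrationError(
        f"could not reach {target_charge} pC with n_gaba >= 1 "
        f"(best {q:.1f} pC at n_gaba = {cand.n_gaba})")
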