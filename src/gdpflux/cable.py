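"""Multicompartment passive cable simulator with dynamic Cl-/HCO3-.

The model is a branched tree of iso-potential segments with leak,
two-exponential synaptic conductances and a single-electrode clamp.  The
GABA-A conductance is split into parallel Cl- and HCO3- branches,

    I_GABA = 1/(1+P) * g * (V - E_Cl)  +  P/(1+P) * g * (V - E_HCO3),

whose reversal potentials are recomputed every step from the Nernst
equation applied to the sub-membrane (outermost shell) concentrations.
Intracellular anion dynamics comprise four processes, operator-split at
the voltage time step:

1. synaptic flux into the outermost shell, d[Ion]/dt = (1/F) I_Ion / vol;
2. radial diffusion across four concentric shells around a cylindrical
   core (exact matrix-exponential propagator per segment -> mass
   conserving and unconditionally stable);
3. longitudinal diffusion between axially adjacent segments, shell-by-
   shell within a section and through the core at branch points;
4. transmembrane transport as a first-order relaxation to a resting
   concentration with a bimodal time constant (uptake when below rest,
   extrusion when above), applied analytically per step.

Voltage is advanced by a backward-Euler solve of the branched cable;
conductances are evaluated at the new time, so the scheme is
unconditionally stable and tolerates the two-decade gap between membrane
(ms) and transport (minutes) time scales.

Units: mV, ms, pA, nS, pF, mM, um; diffusion coefficients in um^2/ms;
specific passive parameters in Ohm*cm, kOhm*cm^2, uF/cm^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.linalg import expm
from scipy.sparse import csr_matrix

from .ionphys import FARADAY, thermal_voltage
from .morphology import Morphology

try:  # O(n) tree solve; pure-numpy fallback below
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f
        return deco(a[0]) if a and callable(a[0]) else deco


@_njit(cache=True)
def _hines_solve(d: np.ndarray, o: np.ndarray, pp: np.ndarray,
                 rhs: np.ndarray) -> None:
    """In-place solve of a symmetric tree-structured system.

    Nodes are ordered parents-before-children; ``pp[i]`` is the position
    of node i's parent and ``o[i]`` the off-diagonal coupling to it.
    """
    n = d.size
    for i in range(n - 1, 0, -1):
        f = o[i] / d[i]
        d[pp[i]] -= f * o[i]
        rhs[pp[i]] -= f * rhs[i]
    rhs[0] /= d[0]
    for i in range(1, n):
        rhs[i] = (rhs[i] - o[i] * rhs[pp[i]]) / d[i]

__all__ = [
    "PassiveParams",
    "SynapseSpec",
    "TransportParams",
    "ClampSpec",
    "CableModel",
    "SolverError",
    "BuildError",
    "discretize",
    "gaba_current",
]

#: mM change per (pA * ms / um^3): d[C]/dt = I/(F vol) with unit conversion.
_FLUX_FACTOR = 1e3 / FARADAY


class BuildError(ValueError):
    pass


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class PassiveParams:
    """Specific passive membrane/axial properties.

    ``e_leak`` is the leak reversal; it is not printed alongside the other
    constants and is set near the measured resting potential (see the
    methods note for why its position between the two GABA reversal
    potentials matters for clamp-bias experiments).
    """

    ra: float = 34.5      # Ohm*cm
    rm: float = 2.0       # kOhm*cm^2
    cm: float = 1.0       # uF/cm^2
    e_leak: float = -50.0  # mV

    def __post_init__(self) -> None:
        if self.ra <= 0 or self.rm <= 0 or self.cm <= 0:
            raise BuildError("ra, rm and cm must be positive")


@dataclass(frozen=True)
class SynapseSpec:
    """A two-exponential conductance synapse.

    ``p_split`` divides a GABA conductance between Cl- (1/(1+P)) and
    HCO3- (P/(1+P)) branches; AMPA synapses use a fixed reversal
    ``e_rev_ampa``.
    """

    section: int
    position: float = 0.5
    kind: str = "gaba"
    g_peak: float = 0.789     # nS
    tau_rise: float = 0.5     # ms
    tau_decay: float = 80.0   # ms
    onset: float = 0.0        # ms
    p_split: float = 0.44
    e_rev_ampa: float = 0.0   # mV

    def __post_init__(self) -> None:
        if not self.tau_decay > self.tau_rise > 0:
            raise BuildError("require tau_decay > tau_rise > 0")
        if self.g_peak < 0:
            raise BuildError("g_peak must be >= 0")
        if self.kind not in ("gaba", "ampa"):
            raise BuildError("kind must be 'gaba' or 'ampa'")

    @property
    def norm(self) -> float:
        """Factor making the difference of exponentials peak at g_peak."""
        tr, td = self.tau_rise, self.tau_decay
        tp = tr * td / (td - tr) * math.log(td / tr)
        return 1.0 / (math.exp(-tp / td) - math.exp(-tp / tr))


@dataclass(frozen=True)
class TransportParams:
    """Bimodal first-order relaxation toward resting concentrations.

    ``tau_uptake`` (s) applies when the concentration is below rest
    (accumulation, NKCC1-like); ``tau_extrusion`` when above rest
    (passive efflux).  Both ions relax with the same pair of taus.
    """

    cl_rest: float = 30.0
    hco3_rest: float = 14.1
    tau_uptake: float = 174.0    # s
    tau_extrusion: float = 321.0  # s

    def __post_init__(self) -> None:
        if self.tau_uptake <= 0 or self.tau_extrusion <= 0:
            raise BuildError("transport taus must be positive")


@dataclass(frozen=True)
class ClampSpec:
    """Somatic electrode: SEVC with explicit access resistance, or
    current injection.

    ``command`` maps time (ms) to the command potential (mV, sevc) or the
    injected current (pA, current_clamp).
    """

    mode: str = "sevc"
    rs: float = 5.0  # MOhm
    command: Callable[[float], float] = lambda t: 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("sevc", "current_clamp"):
            raise BuildError("clamp mode must be 'sevc' or 'current_clamp'")
        if self.mode == "sevc" and self.rs <= 0:
            raise BuildError("rs must be > 0 in sevc mode")


def gaba_current(v: float | np.ndarray, g_t: float | np.ndarray,
                 e_cl: float | np.ndarray, e_hco3: float | np.ndarray,
                 p: float = 0.44):
    """Split a total GABA-A conductance into its two branch currents (pA).

    Returns ``(i_cl, i_hco3)`` with i_cl = g/(1+P) (V-E_Cl) and
    i_hco3 = gP/(1+P) (V-E_HCO3); positive values are outward membrane
    currents, i.e. anion influx.
    """
    if np.any(np.asarray(p) < 0):
        raise BuildError("p must be >= 0")
    i_cl = g_t / (1.0 + p) * (np.asarray(v) - e_cl)
    i_hco3 = g_t * p / (1.0 + p) * (np.asarray(v) - e_hco3)
    return i_cl, i_hco3


def _nseg_dlambda(length: float, diam: float, passive: PassiveParams,
                  d_lambda: float) -> int:
    """Odd segment count per the d_lambda rule at 100 Hz."""
    lam = 1e5 * math.sqrt(diam / (4 * math.pi * 100.0 * passive.ra * passive.cm))
    n = int(length / (d_lambda * lam) + 0.9)
    return n + 1 if n % 2 == 0 else max(n, 1)


def discretize(morph: Morphology, passive: PassiveParams = PassiveParams(),
               nseg_rule: float | int = 0.1, n_shells: int = 4,
               diffusion: float = 2.0, **kwargs) -> "CableModel":
    """Build a :class:`CableModel` from a morphology.

    ``nseg_rule``: a float is the d_lambda fraction (segment length at
    most that fraction of the 100 Hz length constant, odd count); an int
    forces that many segments per section (made odd).
    """
    return CableModel(morph, passive, nseg_rule=nseg_rule, n_shells=n_shells,
                      diffusion=diffusion, **kwargs)


class CableModel:
    """Discretized cable with shell-resolved intracellular anions."""

    def __init__(self, morph: Morphology, passive: PassiveParams = PassiveParams(),
                 nseg_rule: float | int = 0.1, n_shells: int = 4,
                 diffusion: float = 2.0, temperature: float = 31.0,
                 cl_e: float = 133.5, hco3_e: float = 24.0):
        self.morph = morph
        self.passive = passive
        self.n_shells = n_shells
        self.n_zones = n_shells + 1  # core + shells; index 0 = core
        self.diffusion = diffusion
        self.temperature = temperature
        self.vt = thermal_voltage(temperature)
        self.cl_e, self.hco3_e = cl_e, hco3_e
        self._build_geometry(nseg_rule)
        self._build_electrical()
        self._build_shells()
        self._prop_cache: dict[float, np.ndarray] = {}

        n = self.n_seg
        self.v = np.full(n, passive.e_leak)
        self.cl = np.full((n, self.n_zones), 30.0)
        self.hco3 = np.full((n, self.n_zones), 14.1)
        self.transport: TransportParams | None = None
        self.static_ions = False
        self.diffusion_enabled = True
        self.clamp: ClampSpec | None = None
        self.t = 0.0
        # synapse state per kind: aggregated rise/decay exponentials per segment
        self._syn: dict[str, dict] = {}
        self._static_e: tuple[np.ndarray, np.ndarray] | None = None

    # -- construction -----------------------------------------------------

    def _build_geometry(self, nseg_rule) -> None:
        segs = []  # (section_id, region, length, d_prox, d_dist)
        self._sec_segments: dict[int, list[int]] = {}
        for sec in self.morph.sections:
            if isinstance(nseg_rule, int):
                n = max(1, nseg_rule)
                n += 1 - n % 2
            else:
                n = _nseg_dlambda(sec.length, sec.mean_diam, self.passive,
                                  float(nseg_rule))
            ids = []
            for k in range(n):
                f0, f1 = k / n, (k + 1) / n
                dp = sec.diam_prox + f0 * (sec.diam_dist - sec.diam_prox)
                dd = sec.diam_prox + f1 * (sec.diam_dist - sec.diam_prox)
                ids.append(len(segs))
                segs.append((sec.id, sec.region, sec.length / n, dp, dd))
            self._sec_segments[sec.id] = ids
        self.n_seg = len(segs)
        self.seg_section = np.array([s[0] for s in segs])
        self.seg_is_dendrite = np.array([s[1] == "dendrite" for s in segs])
        self.seg_length = np.array([s[2] for s in segs])
        dp = np.array([s[3] for s in segs])
        dd = np.array([s[4] for s in segs])
        r1, r2 = dp / 2, dd / 2
        self.seg_area = np.pi * (r1 + r2) * np.hypot(self.seg_length, r2 - r1)
        self.seg_volume = np.pi * self.seg_length * (r1**2 + r1 * r2 + r2**2) / 3
        if np.any(self.seg_volume <= 0) or np.any(self.seg_area <= 0):
            raise BuildError("degenerate geometry: zero-area or zero-volume segment")
        # equivalent-cylinder radius preserving segment volume
        self.seg_radius = np.sqrt(self.seg_volume / (np.pi * self.seg_length))
        self.seg_cross = np.pi * (0.5 * (dp + dd) / 2) ** 2  # axial cross-section
        self.soma_seg = self._sec_segments[self.morph.root.id][len(
            self._sec_segments[self.morph.root.id]) // 2]

    def _axial_pairs(self) -> list[tuple[int, int]]:
        pairs = []
        for sec in self.morph.sections:
            ids = self._sec_segments[sec.id]
            pairs.extend((ids[k], ids[k + 1]) for k in range(len(ids) - 1))
            if sec.parent_id != -1:
                parent_ids = self._sec_segments[sec.parent_id]
                # attach to the parent segment at parent_position
                k = min(int(sec.parent_position * len(parent_ids)),
                        len(parent_ids) - 1)
                pairs.append((parent_ids[k], ids[0]))
        return pairs

    def _build_electrical(self) -> None:
        p = self.passive
        #: pF = 0.01 * (uF/cm^2) * um^2
        self.seg_c = 0.01 * p.cm * self.seg_area
        #: nS = 0.01 * um^2 / (kOhm*cm^2)
        self.seg_gleak = 0.01 * self.seg_area / p.rm
        rho = p.ra * 1e4  # Ohm*um
        pairs = self._axial_pairs()
        self.pair_a = np.array([a for a, _ in pairs], dtype=int)
        self.pair_b = np.array([b for _, b in pairs], dtype=int)
        # half-cylinder resistances in series
        ra_half = rho * (self.seg_length[self.pair_a] / 2) / self.seg_cross[self.pair_a]
        rb_half = rho * (self.seg_length[self.pair_b] / 2) / self.seg_cross[self.pair_b]
        self.pair_gax = 1e9 / (ra_half + rb_half)  # Ohm -> nS
        # static system matrix (without time step or synapses)
        n = self.n_seg
        G = np.zeros((n, n))
        G[np.arange(n), np.arange(n)] += self.seg_gleak
        for (a, b, g) in zip(self.pair_a, self.pair_b, self.pair_gax):
            G[a, a] += g
            G[b, b] += g
            G[a, b] -= g
            G[b, a] -= g
        self._G_static = G
        self._b_static = self.seg_gleak * p.e_leak
        self._build_tree_order()

    def _build_tree_order(self) -> None:
        """Parents-before-children segment ordering for the O(n) solve."""
        adj: dict[int, list[tuple[int, float]]] = {}
        for a, b, g in zip(self.pair_a, self.pair_b, self.pair_gax):
            adj.setdefault(int(a), []).append((int(b), float(g)))
            adj.setdefault(int(b), []).append((int(a), float(g)))
        root = self._sec_segments[self.morph.root.id][0]
        order, parent_of, g_of = [root], {root: -1}, {root: 0.0}
        stack = [root]
        while stack:
            u = stack.pop()
            for v, g in adj.get(u, ()):  # noqa: B905
                if v not in parent_of:
                    parent_of[v] = u
                    g_of[v] = g
                    order.append(v)
                    stack.append(v)
        if len(order) != self.n_seg:
            raise BuildError("segment graph is not a connected tree")
        self._perm = np.array(order)                       # position -> segment
        pos = np.empty(self.n_seg, dtype=np.int64)
        pos[self._perm] = np.arange(self.n_seg)
        self._parent_pos = np.array(
            [pos[parent_of[s]] if parent_of[s] != -1 else -1
             for s in order], dtype=np.int64)
        self._offdiag = -np.array([g_of[s] for s in order])
        # static diagonal in permuted order: leak + sum of axial couplings
        gax_sum = np.zeros(self.n_seg)
        np.add.at(gax_sum, self.pair_a, self.pair_gax)
        np.add.at(gax_sum, self.pair_b, self.pair_gax)
        self._diag_static = (self.seg_gleak + gax_sum)[self._perm]

    def _build_shells(self) -> None:
        nz = self.n_zones
        r = self.seg_radius[:, None]
        edges = r * np.arange(nz + 1) / nz            # (n_seg, nz+1)
        self.zone_volume = (np.pi * self.seg_length[:, None]
                            * (edges[:, 1:] ** 2 - edges[:, :-1] ** 2))
        self.zone_cross = self.zone_volume / self.seg_length[:, None]
        iface_area = 2 * np.pi * edges[:, 1:-1] * self.seg_length[:, None]
        dr = self.seg_radius / nz
        #: radial exchange coefficient F_k = D*A_k/dr (um^3/ms) per interface
        self._radial_coeff = self.diffusion * iface_area / dr[:, None]
        # longitudinal coupling per pair and zone: D*min(A_zone)/dx (um^3/ms)
        dx = 0.5 * (self.seg_length[self.pair_a] + self.seg_length[self.pair_b])
        a_min = np.minimum(self.zone_cross[self.pair_a], self.zone_cross[self.pair_b])
        coeff = self.diffusion * a_min / dx[:, None]
        same_sec = self.seg_section[self.pair_a] == self.seg_section[self.pair_b]
        # at junctions only the cores exchange
        coeff[~same_sec, 1:] = 0.0
        self._long_coeff = coeff
        # sparse rate operator over flattened (segment, zone) concentrations:
        # dc/dt = T c, rows scaled by the receiving zone volume
        nz = self.n_zones
        rows, cols, vals = [], [], []
        for k, (a, b) in enumerate(zip(self.pair_a, self.pair_b)):
            for z in range(nz):
                c = coeff[k, z]
                if c == 0.0:
                    continue
                ia, ib = a * nz + z, b * nz + z
                va, vb = self.zone_volume[a, z], self.zone_volume[b, z]
                rows += [ia, ia, ib, ib]
                cols += [ia, ib, ib, ia]
                vals += [-c / va, c / va, -c / vb, c / vb]
        self._long_op = csr_matrix((vals, (rows, cols)),
                                   shape=(self.n_seg * nz, self.n_seg * nz))
        self._long_rate = float(np.max(np.abs(self._long_op.diagonal()))) \
            if vals else 0.0

    def _radial_propagator(self, dt: float) -> np.ndarray:
        """(n_seg, nz, nz) matrix exponential of the radial flux operator."""
        if dt in self._prop_cache:
            return self._prop_cache[dt]
        nz = self.n_zones
        props = np.empty((self.n_seg, nz, nz))
        for s in range(self.n_seg):
            M = np.zeros((nz, nz))
            for k in range(nz - 1):
                f = self._radial_coeff[s, k]
                va, vb = self.zone_volume[s, k], self.zone_volume[s, k + 1]
                M[k, k] -= f / va
                M[k, k + 1] += f / va
                M[k + 1, k + 1] -= f / vb
                M[k + 1, k] += f / vb
            props[s] = expm(M * dt)
        self._prop_cache[dt] = props
        return props

    # -- state configuration ----------------------------------------------

    def set_concentrations(self, cl_i: float, hco3_i: float = 14.1) -> None:
        """Uniform initial intracellular concentrations (mM)."""
        if cl_i <= 0 or hco3_i <= 0:
            raise BuildError("concentrations must be > 0")
        self.cl[:] = cl_i
        self.hco3[:] = hco3_i
        self._static_e = None

    def set_transport(self, params: TransportParams | None) -> None:
        self.transport = params

    def freeze_ions(self, frozen: bool = True) -> None:
        """Static-ion mode: concentrations and reversals held fixed."""
        self.static_ions = frozen
        self._static_e = None

    def attach_clamp(self, clamp: ClampSpec | None) -> "CableModel":
        self.clamp = clamp
        return self

    def add_synapse(self, spec: SynapseSpec) -> None:
        ids = self._sec_segments[spec.section]
        seg = ids[min(int(spec.position * len(ids)), len(ids) - 1)]
        st = self._syn.setdefault(spec.kind, {
            "tau_rise": spec.tau_rise, "tau_decay": spec.tau_decay,
            "p": spec.p_split, "e_rev": spec.e_rev_ampa,
            "rise": np.zeros(self.n_seg), "decay": np.zeros(self.n_seg),
            "events": [],
        })
        if (st["tau_rise"], st["tau_decay"]) != (spec.tau_rise, spec.tau_decay):
            raise BuildError(
                f"all {spec.kind} synapses in one model must share kinetics")
        st["events"].append((spec.onset, seg, spec.g_peak * spec.norm))
        st["events"].sort(key=lambda e: e[0])

    def clear_synapses(self) -> None:
        self._syn.clear()

    # -- derived quantities ------------------------------------------------

    def reversal_potentials(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-segment (E_Cl, E_HCO3) in mV from the outermost shell."""
        if self.static_ions and self._static_e is not None:
            return self._static_e
        e_cl = -self.vt * np.log(self.cl_e / self.cl[:, -1])
        e_hco3 = -self.vt * np.log(self.hco3_e / self.hco3[:, -1])
        if self.static_ions:
            self._static_e = (e_cl, e_hco3)
        return e_cl, e_hco3

    def mean_dendritic_concentration(self, ion: str = "cl") -> float:
        """Volume-weighted mean over all dendritic segments and shells (mM)."""
        conc = {"cl": self.cl, "hco3": self.hco3}[ion]
        mask = self.seg_is_dendrite
        if not mask.any():  # soma-only model: average over everything
            mask = np.ones_like(mask)
        vol = self.zone_volume[mask]
        return float(np.sum(conc[mask] * vol) / np.sum(vol))

    def total_moles(self, ion: str = "cl") -> float:
        """Total intracellular content in mM*um^3 (1e-18 mol)."""
        conc = {"cl": self.cl, "hco3": self.hco3}[ion]
        return float(np.sum(conc * self.zone_volume))

    def input_resistance(self) -> float:
        """Somatic input resistance (GOhm) of the passive model."""
        n = self.n_seg
        b = np.zeros(n)
        b[self.soma_seg] = 1.0  # 1 pA
        dv = np.linalg.solve(self._G_static, b)  # mV per pA = GOhm
        return float(dv[self.soma_seg])

    # -- state snapshots ---------------------------------------------------

    _SNAPSHOT_VERSION = 1

    def save_state(self, path) -> None:
        """Full dynamic state (V, concentrations, time) to an .npz file
        with a version field."""
        np.savez(path, version=self._SNAPSHOT_VERSION, t=self.t, v=self.v,
                 cl=self.cl, hco3=self.hco3)

    def load_state(self, path) -> None:
        """Restore a snapshot written by :meth:`save_state` for a model
        of identical discretization."""
        data = np.load(path)
        if int(data["version"]) != self._SNAPSHOT_VERSION:
            raise SolverError(
                f"snapshot version {int(data['version'])} not supported")
        if data["v"].shape != self.v.shape or data["cl"].shape != self.cl.shape:
            raise SolverError("snapshot does not match model discretization")
        self.t = float(data["t"])
        self.v = data["v"].copy()
        self.cl = data["cl"].copy()
        self.hco3 = data["hco3"].copy()
        self._static_e = None

    # -- time stepping -----------------------------------------------------

    def _syn_conductances(self, dt: float) -> dict[str, np.ndarray]:
        """Advance synapse states to t+dt; return per-kind conductance (nS)."""
        t_new = self.t + dt
        out = {}
        for kind, st in self._syn.items():
            fr = math.exp(-dt / st["tau_rise"])
            fd = math.exp(-dt / st["tau_decay"])
            st["rise"] *= fr
            st["decay"] *= fd
            while st["events"] and st["events"][0][0] <= t_new:
                onset, seg, w = st["events"].pop(0)
                # partial decay from onset to t_new keeps onsets sub-step exact
                el = t_new - onset
                st["rise"][seg] += w * math.exp(-el / st["tau_rise"])
                st["decay"][seg] += w * math.exp(-el / st["tau_decay"])
            out[kind] = np.maximum(st["decay"] - st["rise"], 0.0)
        return out

    def step(self, dt: float) -> None:
        """Advance voltage and (unless frozen) ion state by ``dt`` ms."""
        if dt <= 0:
            raise SolverError("dt must be > 0")
        g_syn = self._syn_conductances(dt)
        e_cl, e_hco3 = self.reversal_potentials()

        n = self.n_seg
        g_extra = self.seg_c / dt
        b = g_extra * self.v + self._b_static

        g_gaba = g_syn.get("gaba")
        if g_gaba is not None:
            p = self._syn["gaba"]["p"]
            g_cl = g_gaba / (1.0 + p)
            g_h = g_gaba * p / (1.0 + p)
            g_extra = g_extra + g_cl + g_h
            b += g_cl * e_cl + g_h * e_hco3
        g_ampa = g_syn.get("ampa")
        if g_ampa is not None:
            g_extra = g_extra + g_ampa
            b += g_ampa * self._syn["ampa"]["e_rev"]

        i_clamp = 0.0
        if self.clamp is not None:
            cmd = self.clamp.command(self.t + dt)
            if self.clamp.mode == "sevc":
                g_el = 1e3 / self.clamp.rs  # nS
                g_extra = g_extra.copy()
                g_extra[self.soma_seg] += g_el
                b[self.soma_seg] += g_el * cmd
            else:
                b[self.soma_seg] += cmd  # injected current in pA

        d = self._diag_static + g_extra[self._perm]
        rhs = b[self._perm]
        _hines_solve(d, self._offdiag, self._parent_pos, rhs)
        v_new = np.empty(n)
        v_new[self._perm] = rhs
        if not np.all(np.isfinite(v_new)):
            raise SolverError("non-finite voltage after backward-Euler solve")
        self.v = v_new
        if self.clamp is not None and self.clamp.mode == "sevc":
            i_clamp = (cmd - self.v[self.soma_seg]) / self.clamp.rs * 1e3  # pA
        self._last_i_clamp = i_clamp

        # branch currents at the new voltage (recorded even when frozen)
        if g_gaba is not None:
            i_cl = g_cl * (self.v - e_cl)
            i_hco3 = g_h * (self.v - e_hco3)
        else:
            i_cl = i_hco3 = np.zeros(n)
        self._last_i_cl = float(np.sum(i_cl))
        self._last_i_hco3 = float(np.sum(i_hco3))

        self.t += dt
        if self.static_ions:
            return

        # (1) synaptic flux into the outermost shell
        if g_gaba is not None:
            outer_vol = self.zone_volume[:, -1]
            self.cl[:, -1] += _FLUX_FACTOR * i_cl * dt / outer_vol
            self.hco3[:, -1] += _FLUX_FACTOR * i_hco3 * dt / outer_vol

        if self.diffusion_enabled:
            # (2) radial diffusion: exact propagator
            P = self._radial_propagator(dt)
            self.cl = np.einsum("sij,sj->si", P, self.cl)
            self.hco3 = np.einsum("sij,sj->si", P, self.hco3)
            # (3) longitudinal diffusion (explicit, sub-stepped if needed)
            self._longitudinal(dt)

        # (4) transport relaxation, analytically exact per step
        if self.transport is not None:
            self._relax(self.cl, self.transport.cl_rest, dt)
            self._relax(self.hco3, self.transport.hco3_rest, dt)

        if not (np.all(np.isfinite(self.cl)) and np.all(np.isfinite(self.hco3))):
            raise SolverError("non-finite concentration after ion update")

    def _longitudinal(self, dt: float) -> None:
        if self._long_rate == 0.0:
            return
        n_sub = max(1, int(math.ceil(self._long_rate * dt / 0.25)))
        h = dt / n_sub
        for name in ("cl", "hco3"):
            c = getattr(self, name).ravel()
            for _ in range(n_sub):
                c = c + h * (self._long_op @ c)
            setattr(self, name, c.reshape(self.n_seg, self.n_zones))

    def _relax(self, conc: np.ndarray, rest: float, dt: float) -> None:
        tp = self.transport
        tau = np.where(conc < rest, tp.tau_uptake, tp.tau_extrusion) * 1e3  # ms
        conc += (rest - conc) * (1.0 - np.exp(-dt / tau))

    def advance(self, duration: float, dt: float = 0.025,
                record_every: float | None = None) -> dict[str, np.ndarray]:
        """Run for ``duration`` ms; return recorded time series.

        Recorded: t (ms), v_soma (mV), i_clamp (pA), total GABA branch
        currents i_cl/i_hco3 (pA), and volume-weighted mean dendritic
        concentrations (mM).
        """
        n_steps = int(round(duration / dt))
        if record_every is None:
            record_every = dt
        stride = max(1, int(round(record_every / dt)))
        rec = {k: [] for k in ("t", "v_soma", "i_clamp", "i_cl", "i_hco3",
                               "cl_dend", "hco3_dend")}
        self._last_i_clamp = 0.0
        self._last_i_cl = self._last_i_hco3 = 0.0
        for k in range(n_steps):
            self.step(dt)
            if (k + 1) % stride == 0:
                rec["t"].append(self.t)
                rec["v_soma"].append(self.v[self.soma_seg])
                rec["i_clamp"].append(self._last_i_clamp)
                rec["i_cl"].append(self._last_i_cl)
                rec["i_hco3"].append(self._last_i_hco3)
                rec["cl_dend"].append(self.mean_dendritic_concentration("cl"))
                rec["hco3_dend"].append(self.mean_dendritic_concentration("hco3"))
        return {k: np.asarray(v) for k, v in rec.items()}
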