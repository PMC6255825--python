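# Methods

`gdpflux` models activity-dependent chloride and bicarbonate plasticity in
immature hippocampal CA3 pyramidal neurons: how the massive GABAergic
barrage of a giant depolarizing potential (GDP) moves intracellular Cl⁻
and HCO₃⁻, and how well electrophysiological protocols (voltage ramps
under single-electrode clamp) can read those concentrations back out.
This note records the model, its assumptions, the choices made where the
design was open, and what the synthetic data do and do not establish.

## Ion physics

The GABA_A receptor conducts both Cl⁻ and HCO₃⁻.  Two distinct reversal
relations appear in this problem and the package keeps them explicitly
apart:

* **GHK mixture potential** (used to interpret *measured* reversal
  potentials):

  E_GABA = −(RT/F)·ln[ (P_Cl[Cl⁻]ₑ + P_HCO₃[HCO₃⁻]ₑ) /
                        (P_Cl[Cl⁻]ᵢ + P_HCO₃[HCO₃⁻]ᵢ) ],

  with P_Cl = 1, P_HCO₃ = 0.44, [Cl⁻]ₑ = 133.5 mM, [HCO₃⁻]ₑ = 24 mM,
  [HCO₃⁻]ᵢ = 14.1 mM, T = 31 °C.  `ionphys.cl_from_egaba` is its exact
  algebraic inverse; the round trip is property-tested to 1e-9.

* **Conductance-split reversal** (the synapse the simulator implements):
  two ohmic branches g/(1+P)·(V−E_Cl) and gP/(1+P)·(V−E_HCO₃) with
  Nernstian branch reversals reverse jointly at
  E_rev = (E_Cl + P·E_HCO₃)/(1+P).  This differs from the GHK potential
  of the same gradients by several mV (e.g. −51.4 vs −57.3 mV at 10 mM
  Cl⁻ᵢ).  Apparent concentrations extracted from *simulated* ramp
  experiments are inverted through this relation
  (`ionphys.cl_from_split_reversal`), which is the only inversion
  consistent with the two-branch synapse; inverting such reversals
  through the GHK formula would overestimate a 50 mM cell by ~6 mM even
  under a perfect clamp.

[HCO₃⁻]ᵢ comes from Henderson–Hasselbalch: s·pCO₂·10^(pH−pKs) with
pCO₂ = 38 mmHg, pH 7.2, pKs 6.128 and CO₂ solubility s = 0.0314 mM/mmHg,
giving 14.1 mM.  Note 0.0314 mM/mmHg is the physically standard solubility
at ~37 °C expressed per mmHg; quoted "Henry coefficients" near 0.3 in
other unit systems do not reproduce 14.1 mM and are not used.  Physical
constants: R = 8.314 J mol⁻¹ K⁻¹, F = 96485 C mol⁻¹; both anions carry
z = −1.  Units are repo-wide mV / ms / pA / nS / pF / pC·fC / mM / µm,
enforced at the type boundaries.

## Trace analysis

* **GDP detector**: a strictly causal floating average of the last 50
  membrane-potential samples compared with a preset threshold, emulating
  a microcontroller wired to the amplifier; the event ends when the
  average falls back below threshold, and a trigger is emitted a
  configurable 0.1–20 s later.  The causal average delays detected onsets
  by up to window·dt (5 ms at 10 kHz); this lag is tested, not hidden.
  The sampling rate of the original hardware stream is not documented;
  10 kHz is assumed, so `window_n = 50` spans 5 ms by default.
* **AP counting**: upward dV/dt crossings (default 10 mV/ms) with a 2 ms
  lockout inside the event window.
* **Charge transfer**: trapezoidal integral of |I − baseline| between
  event start and end; baseline is the median of the 200 ms before onset.
  Analytic waveforms (rectangle, exponential) are reproduced to <0.2%.
* **PSC detection** is template-free: percentile baseline (25th/75th by
  polarity — the median itself is biased at ~8 Hz event rates),
  one event per supra-threshold region (regions separated by less than
  `min_separation` merge), 10–90% rise time, single-exponential decay fit
  from the peak, charge integrated to return-to-baseline.
* **Derivative event detection** (for holding potentials where outward
  GABAergic and inward glutamatergic events overlap): smoothed first
  difference thresholded at ±k·MAD of the derivative noise with a
  relative floor of 5% of the largest derivative, which keeps noiseless
  synthetic traces usable and makes onset times exactly invariant under
  amplitude rescaling.
* **Ramp E_GABA extraction**: the control ramp current is subtracted from
  the GABA ramp current and the zero crossing of the difference is
  interpolated against the voltage axis; with several crossings the one
  nearest mid-ramp is used (with a warning), and a least-squares line fit
  is available for noisy differences.  The voltage axis is the nominal
  command by default; the simulated protocols pass the *recorded* soma
  potential instead, because a discontinuous single-electrode amplifier
  samples the true membrane potential between current injections.  This
  distinction is load-bearing: against the command axis the I·Rs drop
  biases E_GABA by tens of mV at 40 MΩ, while against the recorded
  potential the access-resistance series spans <0.1 mV (see below).

## The compartmental model

A branched passive cable with two-exponential synaptic conductances and
dynamic intracellular anions.

**Passive parameters** (model constants): Ra = 34.5 Ω·cm, Rm = 2 kΩ·cm²,
Cm = 1 µF/cm².  These values make the membrane leaky (τ_m = 2 ms), far
from the experimentally measured ~100 ms time constant of these cells;
they are kept because they are the constants of the model being
reproduced.  The passive-sanity test instead verifies the *solver*: with
Rm = 100 kΩ·cm² (the value implied by the measured τ_m at 1 µF/cm²) a
surrogate at the measured 65 pF shows R_in ≈ 0.9–1.75 GΩ and
τ_m ≈ 86–106 ms.

**Leak reversal**: not a published constant.  Set to −50 mV, near the
measured resting potentials (−52.1 mV whole-cell, −53.6 mV perforated).
Its position *between* the two GABA reversal potentials
(E_rev(10 mM) ≈ −51.4 mV, E_rev(50 mM) ≈ −22 mV) is what produces the
space-clamp bias directions: the ramp-determined reversal at a dendritic
site equals the somatic potential at which the attenuated dendritic
voltage (which relaxes toward E_leak) crosses the local reversal, so
distal sites overestimate reversals above E_leak and underestimate
reversals below it.

**Discretization**: sections split into an odd number of segments with
length ≤ 0.1·λ(100 Hz) (the d_lambda rule).  Segment membrane area and
volume use exact frustum formulas, so totals are independent of
refinement.

**Voltage integration**: backward Euler at dt = 0.025 ms, conductances
evaluated at the new time; the tree system is solved in O(n) by
parent-ordered elimination (numba-compiled, with a pure-python fallback).
Unconditional stability matters here because the simulations couple ms
membrane dynamics to minutes-scale transport.

**Ion dynamics**, operator-split at the voltage step:

1. *Synaptic flux*: d[Ion]/dt = (1/F)·I_Ion/vol into the outermost shell
   (the sub-membrane compartment) of the postsynaptic segment, with
   positive (outward) branch current meaning anion influx.
2. *Radial diffusion* across 4 concentric shells plus a cylindrical core
   (equal radial increments of the volume-equivalent cylinder radius;
   inter-shell flux D·A·ΔC/Δr with D = 2 µm²/ms for both ions, the
   HCO₃⁻ cytoplasmic value being unknown and set equal to Cl⁻).  The
   update uses the exact matrix exponential of the per-segment flux
   operator — unconditionally stable and mass-conserving to machine
   precision, which the thin outer shells require at any usable dt.
3. *Longitudinal diffusion* shell-by-shell between axially adjacent
   segments of equal shell index; at branch points only the cores
   exchange.  Explicit Euler with automatic sub-stepping keeps the
   update stable when coarse time steps are used after the stimulus.
4. *Transport*: first-order relaxation to the resting concentration with
   a bimodal time constant — 174 s below rest (NKCC1-like uptake), 321 s
   above rest (passive efflux), identical for HCO₃⁻ (rest 14.1 mM) —
   applied analytically per step, so the e-fold times are exact.

Branch reversal potentials are recomputed every step from the outermost
shell concentrations, except in the static-ion protocols (access
resistance and space clamp), where concentrations are frozen.
Extracellular concentrations are static reservoirs.  There are no
voltage-gated channels, no network interactions, and no mechanistic
transporter kinetics beyond the relaxation law.

**Clamp**: single-electrode voltage clamp injects (V_cmd − V_soma)/Rs at
the soma and reports that current; its recorded voltage is the soma
potential.  The steady-state clamp error on a passive cell equals the
Rs/(Rs+R_in) divider, tested in closed form.

## Protocols

* **Access-resistance scan**: static ions (30 mM Cl⁻ᵢ, 14.4 mM HCO₃⁻ᵢ),
  a proximal 10 nS GABA synapse with 100 ms decay emulating the GABA
  application, ramps −3 → −63 mV after a 100 ms pre-step at −3 mV (Na⁺
  channel inactivation in the original protocol; harmless here), Rs ∈
  {0.5, 5, 10, 20, 40} MΩ.  The determined E_GABA spans <0.1 mV across
  the Rs series and sits within 1 mV of the analytic two-branch reversal.
  The ramp duration default is 200 ms (0.3 mV/ms), slow enough that
  capacitive distortion of the difference current is negligible.
* **Space-clamp scan**: same ramp protocol at Rs = 5 MΩ with the synapse
  stepped along the longest dendrite.  Site ladder defaults to path
  distances of 15–100 µm: beyond that range on a 65 pF surrogate with
  ~0.5 µm dendrites the somatic ramp can no longer drive the local
  membrane through the reversal and the difference current never
  reverses — itself a faithful expression of the space-clamp failure the
  experiment quantifies.  Apparent [Cl⁻]ᵢ rises with distance for a
  50 mM cell and falls for a 10 mM cell, with near-truth proximal values.
* **GDP simulation**: 534 GABA synapses (0.789 nS, 0.5/80 ms, P = 0.44)
  and 107 AMPA synapses (0.509 nS, 0.1/11 ms, E_rev 0 mV) scattered over
  dendritic membrane area, each activated once with normally distributed
  onsets — GABA ~ N(500, 250) ms, AMPA ~ N(550, 180) ms truncated to
  [0, 1500] ms, so GABAergic input leads and glutamatergic input ends
  earlier, as in the recorded event-onset distributions.  Transport rest
  equals the initial concentration.  The run continues 5 s past the
  stimulus window (time step coarsened to 0.25 ms once the conductances
  have decayed; grid-convergence checks put the coarsening error on the
  peak Δ[Cl⁻]ᵢ below 2%).  Reported quantities are volume-weighted means
  over all dendritic shells.
* **Charge calibration**: scales the GABA synapse count until the
  GABA-evoked somatic clamp charge at 0 mV (static 10 mM Cl⁻ᵢ) matches a
  target within 5%; the count is iterated multiplicatively because the
  charge grows sublinearly (driving-force collapse in shared dendrites).

### The 88 pC anchor and what the surrogate can and cannot reproduce

On the original reconstructed cell the 534-synapse barrage reportedly
produced only 88 pC of somatically clamped charge — a ~20-fold
space-clamp suppression relative to the ideal-clamp product of synapse
count, conductance and driving force.  On surrogate morphologies
constrained only by the measured capacitance this suppression is not
reachable: synapses within the first length constant of the soma alone
contribute several hundred pC (574 pC at 534 synapses on the default
surrogate; still ≥200 pC after thinning the tree to an implausible
22 pF).  Because cutting the synapse count to meet the charge anchor
would also cut the concentration changes the GDP protocol exists to
study, the protocol runs the stated barrage and the anchor discrepancy
is documented rather than resolved.

The simulated concentration changes have the right sign structure and
ordering in every seed tested: Cl⁻ influx at 10 mM, efflux at 50 mM, the
smallest change at 30 mM, monotone in the initial concentration, and
HCO₃⁻ falling in all scenarios.  Their magnitudes (≈ +4.1 / −0.4 / −2.9
mM at 10/30/50 mM on the default surrogate) depend inversely on the
dendritic cross-section volume within a diffusion length of the
synapses, which the published capacitance does not constrain; thinner
trees drive the endpoints toward the local electrochemical equilibria
and larger changes.  The HCO₃⁻ minimum is deepest in the *low*-chloride
scenario, where the barrage holds the membrane closest to the (most
negative) GABA mixture reversal and the HCO₃⁻ driving force is largest;
this ordering follows directly from the two-branch current law.

## Surrogate morphology

No reconstruction is available, so surrogates are generated: a 15 µm
soma with 7 primary dendrites, target maximal paths ~700 µm with an
unbranched proximal half (apical-trunk-plus-tuft architecture),
stochastic branching (0.5 per 100 µm beyond the trunk), taper toward
0.2 µm tips, and dendritic diameters rescaled so total membrane area
matches the target capacitance (default 65 pF, the perforated-patch
population mean, the configuration in which the chloride measurements
were made) within 5%.  After rescaling the mean dendritic diameter is
~0.5 µm — within the range of thin immature dendrites.  The
distal-heavy geometry was selected to maximize space-clamp escape (see
the anchor discussion above).  Generators are pure functions of
(spec, seed).

## Synthetic recordings

Current-clamp: Poisson GDPs at 1.3 min⁻¹ (minimum inter-event interval
5 s, a refractoriness assumption), each a difference-of-exponentials
envelope (rise 150 ms, decay 400 ms — the published amplitude and
duration constrain the shape only loosely; these values give ~1.2 s
above half-amplitude) scaled to 24.9 mV, carrying Poisson(6.4)
stereotyped 2.7 ms / 55 mV spikes on the crest when suprathreshold;
superimposed mV-scale PSP trains at 7.8 / 5.8 Hz and Gaussian noise.
Voltage-clamp: GDP current envelopes whose amplitude and integrated
charge match the reported per-holding values (309.5 pA / 88 pC at 0 mV,
79.3 pA / 14.6 pC at −60 mV; the decay constant is solved from the
charge), plus sPSC trains with the reported class-specific amplitude and
kinetics.  Each generator returns the exact injected event table, so
detector tests are parameter-recovery experiments, not visual checks.

What passing these tests shows: the detector recovers every injected GDP
at SNR ≥ 5 across seeds, and rate/amplitude estimators are unbiased on
events of the assumed shape.  What they do not show: robustness to
drifting baselines, seal instabilities, overlapping GDPs, or event
shapes outside the biexponential family — real recordings contain all of
these.

## Numerical and degenerate-input conventions

Zero driving force raises an explicit division error; reversal
potentials implying non-positive concentrations raise an
infeasible-reversal error; a floating-average window longer than the
trace, degenerate geometry, non-tree morphologies and non-finite solver
states are all distinct, named errors.  Multiple ramp crossings warn and
take the mid-ramp-nearest crossing; they are never averaged.  Junction
potential corrections are applied only as documented constants in
synthetic-data metadata, never inside analysis operations.  All
randomness flows through explicit integer seeds.

## Known limitations

* Δ[Cl⁻]ᵢ / Δ[HCO₃⁻]ᵢ magnitudes are surrogate-dependent (volume
  scaling) and undershoot the original reconstruction's values by
  roughly one-third to one-half at the default geometry; signs and
  orderings are morphology-independent in all tested seeds.
* The somatic-charge anchor of the GDP barrage cannot be met jointly
  with the stated synapse count on capacitance-plausible surrogates.
* The PSC decay fit assumes a single exponential; strongly overlapping
  events are split heuristically at the inter-peak minimum.
* HCO₃⁻ transport shares the Cl⁻ relaxation constants; carbonic
  anhydrase kinetics and pH coupling are out of scope.
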