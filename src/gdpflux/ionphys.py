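"""Closed-form anion physics for GABA-A signalling.

The GABA-A receptor is permeable to both Cl- and HCO3-, so its reversal
potential (E_GABA) is a Goldman-Hodgkin-Katz mixture of the two anion
gradients rather than the chloride Nernst potential alone.  This module
collects the small set of closed-form relations used throughout the
package:

* the Henderson-Hasselbalch estimate of intracellular bicarbonate from a
  blood-gas style CO2 pressure and intracellular pH,
* Nernst and GHK reversal potentials (anion convention: a higher internal
  anion concentration makes the reversal *less* negative),
* the exact algebraic inversion of the GHK relation that recovers [Cl-]i
  from a measured E_GABA,
* driving force, Ohmic conductance and synaptic-input-count bookkeeping.

Units follow the repo-wide convention: mV, ms, pA, nS, pC/fC, mM, degC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "R_GAS",
    "FARADAY",
    "IonState",
    "CarbonateParams",
    "DrivingForceResult",
    "InvalidParameterError",
    "InfeasibleReversalError",
    "thermal_voltage",
    "hco3_from_blood_gas",
    "nernst",
    "ghk_egaba",
    "cl_from_egaba",
    "split_reversal",
    "cl_from_split_reversal",
    "driving_force",
    "conductance_from_current",
    "equivalent_input_count",
]

#: Gas constant, J mol-1 K-1.
R_GAS = 8.314
#: Faraday constant, C mol-1.
FARADAY = 96485.0


class InvalidParameterError(ValueError):
    """A physical parameter is outside its admissible domain."""


class InfeasibleReversalError(ValueError):
    """The requested reversal potential implies a non-positive [Cl-]i."""


def thermal_voltage(temperature: float) -> float:
    """RT/F in mV at ``temperature`` degC (~26.2 mV at 31 degC)."""
    if not 0.0 < temperature < 45.0:
        raise InvalidParameterError(
            f"temperature must be in (0, 45) degC, got {temperature}"
        )
    return R_GAS * (temperature + 273.15) / FARADAY * 1e3


@dataclass(frozen=True)
class IonState:
    """Concentrations and permeabilities entering the GHK reversal.

    P_Cl is fixed at 1; ``p_hco3`` is the relative permeability
    P_HCO3/P_Cl of the GABA-A channel (0.44 in hippocampal neurons).
    Both anions carry valence -1.
    """

    cl_i: float = 30.0
    cl_e: float = 133.5
    hco3_i: float = 14.1
    hco3_e: float = 24.0
    p_hco3: float = 0.44
    temperature: float = 31.0

    def __post_init__(self) -> None:
        for name in ("cl_i", "cl_e", "hco3_i", "hco3_e"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.p_hco3 < 0:
            raise InvalidParameterError("p_hco3 must be >= 0")
        thermal_voltage(self.temperature)  # validates range

    def with_cl_i(self, cl_i: float) -> "IonState":
        return replace(self, cl_i=cl_i)


@dataclass(frozen=True)
class CarbonateParams:
    """Inputs of the Henderson-Hasselbalch bicarbonate estimate.

    ``co2_solubility`` is the CO2 solubility in mM/mmHg; the default
    0.0314 mM/mmHg reproduces the standard 14.1 mM [HCO3-]i at
    pCO2 = 38 mmHg, pH 7.2, pKs 6.128.
    """

    pco2: float = 38.0
    ph_i: float = 7.2
    pks: float = 6.128
    co2_solubility: float = 0.0314

    def __post_init__(self) -> None:
        if self.pco2 <= 0:
            raise InvalidParameterError("pco2 must be > 0")
        if not 6.0 < self.ph_i < 8.0:
            raise InvalidParameterError("ph_i must be in (6, 8)")
        if self.co2_solubility <= 0:
            raise InvalidParameterError("co2_solubility must be > 0")


@dataclass(frozen=True)
class DrivingForceResult:
    """DF_Cl = E_m - E_GABA; a positive value drives anion influx."""

    e_gaba: float
    e_m: float
    df_cl: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "df_cl", self.e_m - self.e_gaba)


def hco3_from_blood_gas(params: CarbonateParams = CarbonateParams()) -> float:
    """[HCO3-]i (mM) from Henderson-Hasselbalch.

    [HCO3-]i = s * pCO2 * 10**(pH_i - pKs), with s the CO2 solubility
    in mM/mmHg.  Defaults give 14.1 mM.
    """
    return params.co2_solubility * params.pco2 * 10.0 ** (params.ph_i - params.pks)


def nernst(c_in: float, c_out: float, valence: int = -1,
           temperature: float = 31.0) -> float:
    """Nernst potential (mV): (RT/zF) * ln(c_out/c_in)."""
    if c_in <= 0 or c_out <= 0:
        raise InvalidParameterError("concentrations must be > 0")
    if valence == 0:
        raise InvalidParameterError("valence must be non-zero")
    return thermal_voltage(temperature) / valence * math.log(c_out / c_in)


def ghk_egaba(state: IonState) -> float:
    """GHK reversal potential (mV) of the mixed Cl-/HCO3- GABA-A current.

    E_GABA = -(RT/F) * ln[(Cl_e + p*HCO3_e) / (Cl_i + p*HCO3_i)]
    for two monovalent anions with relative permeability p.  Raising the
    internal anion load makes E_GABA less negative.
    """
    num = state.cl_e + state.p_hco3 * state.hco3_e
    den = state.cl_i + state.p_hco3 * state.hco3_i
    return -thermal_voltage(state.temperature) * math.log(num / den)


def cl_from_egaba(e_gaba: float, state: IonState = IonState()) -> float:
    """Invert :func:`ghk_egaba` for [Cl-]i (mM) at a measured E_GABA.

    The inversion is exact: Cl_i = (Cl_e + p*HCO3_e) * exp(E/Vt) - p*HCO3_i.
    ``state.cl_i`` is ignored.  E_GABA values so positive that the implied
    [Cl-]i would be non-positive raise :class:`InfeasibleReversalError`.
    """
    vt = thermal_voltage(state.temperature)
    num = state.cl_e + state.p_hco3 * state.hco3_e
    cl_i = num * math.exp(e_gaba / vt) - state.p_hco3 * state.hco3_i
    if cl_i <= 0:
        raise InfeasibleReversalError(
            f"E_GABA = {e_gaba:.2f} mV implies [Cl-]i = {cl_i:.3f} mM <= 0"
        )
    return cl_i


def split_reversal(e_cl: float, e_hco3: float, p: float = 0.44) -> float:
    """Reversal of a parallel Cl-/HCO3- conductance pair (mV).

    The two-branch synapse model reverses at the conductance-weighted
    mean (E_Cl + p E_HCO3)/(1 + p), which differs from the GHK mixture
    potential of the same gradients by a few mV.
    """
    return (e_cl + p * e_hco3) / (1.0 + p)


def cl_from_split_reversal(e_rev: float, state: IonState = IonState()) -> float:
    """[Cl-]i (mM) from a measured two-branch (conductance-split) reversal.

    Inverts :func:`split_reversal` for E_Cl and then the chloride Nernst
    relation; the consistent inversion when the underlying channel is
    modelled as parallel Cl- and HCO3- conductances.
    """
    vt = thermal_voltage(state.temperature)
    e_hco3 = -vt * math.log(state.hco3_e / state.hco3_i)
    e_cl = (1.0 + state.p_hco3) * e_rev - state.p_hco3 * e_hco3
    cl_i = state.cl_e * math.exp(e_cl / vt)
    if cl_i <= 0:  # pragma: no cover - exp is always positive
        raise InfeasibleReversalError("non-positive [Cl-]i")
    return cl_i


def driving_force(e_m: float, e_gaba: float) -> DrivingForceResult:
    """Chloride driving force DF_Cl = E_m - E_GABA."""
    return DrivingForceResult(e_gaba=e_gaba, e_m=e_m)


def conductance_from_current(i_peak: float, e_m: float, e_rev: float) -> float:
    """Ohmic conductance |i/(E_m - E_rev)| in nS from a peak current in pA."""
    df = e_m - e_rev
    if df == 0:
        raise ZeroDivisionError(
            "zero driving force: e_m equals e_rev, conductance is undefined"
        )
    return abs(i_peak / df)


def equivalent_input_count(event_charge_pc: float, unitary_charge_fc: float) -> int:
    """Number of unitary synaptic events carrying ``event_charge_pc``.

    The event charge is given in pC, the unitary charge in fC; the ratio
    is rounded to the nearest integer.
    """
    if unitary_charge_fc <= 0:
        raise InvalidParameterError("unitary charge must be > 0")
    return round(event_charge_pc * 1e3 / unitary_charge_fc)
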