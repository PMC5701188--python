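"""Thermodynamic and kinetic primitives for protein unfolding transitions.

A reversible unfolding step is described by an equilibrium constant

    K(T) = exp(-dG(T) / (R T)),   dG(T) = dH(T) - T dS(T),

with the constant-dCp conventions dH(T) = dH(Tm) + dCp (T - Tm) and
dS(T) = dH(Tm)/Tm + dCp ln(T/Tm), so that dG(Tm) = 0 and K(Tm) = 1: Tm is
the melting temperature at which half the protein has crossed the step.

An irreversible step is described by an Arrhenius rate constant

    k(T) = exp(-(E/R) (1/T - 1/Tf)),

where Tf is the temperature at which k = 1 s^-1 and E the activation
energy.  Tm and Tf are the reference ("ground state") temperatures at
which the step enthalpies dH_ref are quoted.

All quantities are SI internally: temperatures in K, energies in J mol^-1,
heat capacities in J mol^-1 K^-1.  I/O layers convert from degC and kJ.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "R",
    "EquilibriumParams",
    "ArrheniusParams",
    "enthalpy_at",
    "equilibrium_constant",
    "rate_constant",
    "gibbs_energy",
]

#: Gas constant, J mol^-1 K^-1.
R = 8.3145

_log = logging.getLogger(__name__)

# Fitted reference temperatures occasionally land far outside the
# experimental range when a step is poorly constrained (e.g. a Tf of a few
# thousand K); these are legal but worth flagging.
_T_SUSPICIOUS_LOW = 250.0
_T_SUSPICIOUS_HIGH = 500.0


def _check_temperature(T: float, name: str = "T") -> None:
    if not T > 0.0:
        raise ValueError(f"{name} must be a positive absolute temperature, got {T!r}")


def _warn_if_suspicious(T: float, name: str) -> None:
    if T < _T_SUSPICIOUS_LOW or T > _T_SUSPICIOUS_HIGH:
        _log.warning(
            "%s = %.6g K lies outside the typical DSC range (%g-%g K); "
            "this usually indicates a poorly constrained step",
            name, T, _T_SUSPICIOUS_LOW, _T_SUSPICIOUS_HIGH,
        )


@dataclass(frozen=True)
class EquilibriumParams:
    """Parameters of a reversible (equilibrium) unfolding step.

    Parameters
    ----------
    Tm : float
        Melting temperature of the step (K); K(Tm) = 1.
    dH_ref : float
        Calorimetric enthalpy change at Tm (J mol^-1); sets the heat
        (peak area) the step contributes.
    dCp : float, optional
        Heat-capacity change of the step (J mol^-1 K^-1), assumed
        temperature-independent.
    dH_vh : float, optional
        Van't Hoff enthalpy (J mol^-1).  When given, it replaces dH_ref
        inside K(T) — controlling the sharpness of the transition — while
        dH_ref keeps controlling the calorimetric amplitude.
    """

    Tm: float
    dH_ref: float
    dCp: float = 0.0
    dH_vh: float | None = None

    def __post_init__(self) -> None:
        _check_temperature(self.Tm, "Tm")
        if not math.isfinite(self.dCp):
            raise ValueError("dCp must be finite")
        if not math.isfinite(self.dH_ref):
            raise ValueError("dH_ref must be finite")
        _warn_if_suspicious(self.Tm, "Tm")

    @property
    def dH_K(self) -> float:
        """Enthalpy used inside K(T): van't Hoff value when provided."""
        return self.dH_ref if self.dH_vh is None else self.dH_vh


@dataclass(frozen=True)
class ArrheniusParams:
    """Parameters of an irreversible (kinetically controlled) step.

    Parameters
    ----------
    E : float
        Activation energy (J mol^-1).
    Tf : float
        Temperature at which the rate constant equals 1 s^-1 (K).
    dH_ref : float
        Enthalpy change of the step at Tf (J mol^-1); may be negative for
        exothermic (e.g. aggregation) steps.
    dCp : float, optional
        Heat-capacity change of the step (J mol^-1 K^-1).
    """

    E: float
    Tf: float
    dH_ref: float = 0.0
    dCp: float = 0.0

    def __post_init__(self) -> None:
        _check_temperature(self.Tf, "Tf")
        if not math.isfinite(self.E):
            raise ValueError("E must be finite")
        _warn_if_suspicious(self.Tf, "Tf")


def enthalpy_at(dH_ref: float, dCp: float, T_ref: float, T) -> float:
    """Step enthalpy at temperature ``T`` for constant ``dCp``.

    dH(T) = dH_ref + dCp (T - T_ref); ``T`` may be an array.
    """
    _check_temperature(T_ref, "T_ref")
    if np.any(np.asarray(T) <= 0.0):
        raise ValueError("T must be a positive absolute temperature")
    return dH_ref + dCp * (T - T_ref)


def gibbs_energy(p: EquilibriumParams, T: float) -> float:
    """Gibbs energy change of an equilibrium step at ``T`` (J mol^-1).

    dG(Tm) = 0 by construction; when dH_vh is set the van't Hoff enthalpy
    governs dG (and hence K) instead of the calorimetric one.
    """
    _check_temperature(T)
    dH = p.dH_K + p.dCp * (T - p.Tm)
    dS = p.dH_K / p.Tm + p.dCp * math.log(T / p.Tm)
    return dH - T * dS


def equilibrium_constant(p: EquilibriumParams, T: float) -> float:
    """Equilibrium constant K(T) = exp(-dG(T)/(R T)) of a reversible step."""
    return math.exp(-gibbs_energy(p, T) / (R * T))


def rate_constant(p: ArrheniusParams, T: float) -> float:
    """Arrhenius rate constant k(T) = exp(-(E/R)(1/T - 1/Tf)) in s^-1."""
    _check_temperature(T)
    return math.exp(-(p.E / R) * (1.0 / T - 1.0 / p.Tf))
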