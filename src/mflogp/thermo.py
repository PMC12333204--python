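"""Partition-coefficient thermodynamics.

The toluene/water partition coefficient of a neutral solute can be written
three equivalent ways:

* from equilibrium concentrations,  logP = log10([S]_tol / [S]_w);
* from solvation free energies,     logP = (dG_w - dG_tol) / (R T ln 10),
  where dG_w - dG_tol is the transfer free energy from water to toluene;
* at infinite dilution, from activity coefficients and liquid molar volumes,
  logP = log10((gamma_w/gamma_tol) * (v_w/v_tol)).

Units are kcal/mol and Kelvin throughout. These relations also give the error
model for computed (low-fidelity) labels: independent Gaussian uncertainties
on the two solvation free energies propagate to
sqrt(s_w^2 + s_tol^2) / (R T ln 10) log units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

R_KCAL = 1.98720e-3  # gas constant, kcal mol^-1 K^-1
T_DEFAULT = 298.15  # 25 degC, K
LN10 = math.log(10.0)


class ThermoError(ValueError):
    pass


@dataclass(frozen=True)
class ConcentrationPair:
    """Equilibrium solute concentrations in the two phases (same units)."""

    c_tol: float
    c_w: float

    def __post_init__(self):
        if self.c_tol <= 0 or self.c_w <= 0:
            raise ThermoError("concentrations must be strictly positive")


@dataclass(frozen=True)
class SolvationPair:
    """Solvation free energies of one solute in water and toluene, kcal/mol."""

    dG_w: float
    dG_tol: float
    T: float = T_DEFAULT

    def __post_init__(self):
        if self.T <= 0:
            raise ThermoError("temperature must be positive")
        if not (math.isfinite(self.dG_w) and math.isfinite(self.dG_tol)):
            raise ThermoError("solvation free energies must be finite")


@dataclass(frozen=True)
class ActivityState:
    """Infinite-dilution activity coefficients and liquid molar volumes (L/mol)."""

    gamma_w_inf: float
    gamma_tol_inf: float
    v_w: float
    v_tol: float

    def __post_init__(self):
        if min(self.gamma_w_inf, self.gamma_tol_inf, self.v_w, self.v_tol) <= 0:
            raise ThermoError("activity coefficients and molar volumes must be positive")


def logp_from_concentrations(c: ConcentrationPair) -> float:
    """log10 of the toluene/water concentration ratio."""
    return math.log10(c.c_tol / c.c_w)


def logp_from_solvation(s: SolvationPair) -> float:
    """Transfer free energy (water → toluene) divided by R·T·ln10."""
    return (s.dG_w - s.dG_tol) / (R_KCAL * s.T * LN10)


def logp_from_activity(a: ActivityState) -> float:
    """Infinite-dilution form from activity-coefficient and molar-volume ratios."""
    return math.log10((a.gamma_w_inf / a.gamma_tol_inf) * (a.v_w / a.v_tol))


def propagate_logp_uncertainty(
    sigma_w: float, sigma_tol: float, T: float = T_DEFAULT
) -> float:
    """1-sigma logP uncertainty from independent solvation-energy uncertainties.

    With 0.45 kcal/mol on each solvation free energy at 298.15 K this gives
    0.47 log units — the nominal error of the computed low-fidelity labels.
    """
    if sigma_w < 0 or sigma_tol < 0:
        raise ThermoError("uncertainties must be non-negative")
    if T <= 0:
        raise ThermoError("temperature must be positive")
    return math.sqrt(sigma_w**2 + sigma_tol**2) / (R_KCAL * T * LN10)
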