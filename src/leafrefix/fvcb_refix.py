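"""Forward FvCB photosynthesis model with mesophyll resistance, plus the
resistance-partition model of (photo)respiratory CO2 refixation.

Units are fixed throughout the package:

* partial pressures in Pa (O2 in kPa),
* rates in umol m-2 s-1,
* resistances in m2 s Pa umol-1.

Net assimilation under a given limitation state solves the implicit coupling

    A = W(Cc) * (1 - gamma_star / Cc) - Rd,      Cc = Ci - rm * A,

where ``W`` is the gross carboxylation rate of the active limitation:
Rubisco-limited ``Wc = Vcmax * Cc / (Cc + Kc * (1 + O / Ko))``, RuBP-limited
``Wj = J * Cc / (4 * Cc + 8 * gamma_star)``, while under triose-phosphate-use
limitation the net rate is ``A = 3 * TPU - Rd`` independent of Cc.

The refixation fraction balances the two diffusion fluxes leaving the
cytosol: refixation through the chloroplast and carboxylation resistances
against escape through the wall/membrane and stomatal resistances.  The
cytosolic CO2 partial pressure cancels in the ratio.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "KineticConstants",
    "FvCBParams",
    "ResistanceState",
    "OperatingPoint",
    "InfeasibleOperatingPointError",
    "LIMITATION_STATES",
    "net_assimilation",
    "model_curve",
    "refix_fraction",
    "carboxylation_resistance",
    "rm_pressure_from_molar",
    "rm_molar_from_pressure",
    "partition_rm",
    "stomatal_resistance",
    "refixation_state",
    "refix_percent",
]

LIMITATION_STATES = ("rubisco", "rubp", "tpu")

#: Ratio of binary diffusivities of water vapour and CO2 in air.
H2O_CO2_DIFFUSIVITY_RATIO = 1.6


class InfeasibleOperatingPointError(ValueError):
    """Raised when no physically meaningful (positive-Cc) solution exists."""


@dataclass(frozen=True)
class KineticConstants:
    """Rubisco kinetics and gas composition at the 25 degC block temperature.

    Defaults are the widely used tobacco-derived in-vivo values; all fields
    are configurable.
    """

    Kc: float = 27.2  # Michaelis constant for CO2, Pa
    Ko: float = 16.6  # Michaelis constant for O2, kPa
    gamma_star: float = 3.74  # CO2 compensation point sans day respiration, Pa
    O: float = 21.0  # chloroplast O2 partial pressure, kPa

    def __post_init__(self) -> None:
        for name in ("Kc", "Ko", "gamma_star", "O"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not self.gamma_star < self.Kc:
            raise ValueError("gamma_star must be smaller than Kc")

    @property
    def Km(self) -> float:
        """Effective Michaelis constant Kc * (1 + O / Ko), Pa."""
        return self.Kc * (1.0 + self.O / self.Ko)


@dataclass(frozen=True)
class FvCBParams:
    """Parameter set of the coupled FvCB + mesophyll-resistance model."""

    Vcmax: float  # maximum carboxylation rate, umol m-2 s-1
    Jmax: float  # electron transport rate at measurement irradiance
    TPU: float  # triose phosphate use, umol m-2 s-1
    Rd: float  # day respiration, umol m-2 s-1
    rm: float = 0.0  # mesophyll resistance, m2 s Pa umol-1
    kinetics: KineticConstants = field(default_factory=KineticConstants)

    def __post_init__(self) -> None:
        for name in ("Vcmax", "Jmax", "TPU", "Rd"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.rm < 0:
            raise ValueError("rm must be non-negative")

    def with_rm(self, rm: float) -> "FvCBParams":
        return replace(self, rm=rm)


@dataclass(frozen=True)
class ResistanceState:
    """Resistances seen by a cytosol-released CO2 molecule.

    ``x_py`` (cytosolic partial pressure of (photo)respiratory CO2) is carried
    for flux bookkeeping only; it cancels in the refixation fraction.
    """

    r_wp: float  # cell wall + plasma membrane resistance
    r_ch: float  # chloroplast resistance
    r_sc: float  # stomatal resistance (CO2)
    k_inv: float  # carboxylation resistance Cc / Vc
    x_py: float = 1.0

    def __post_init__(self) -> None:
        for name in ("r_wp", "r_ch", "r_sc", "k_inv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.x_py <= 0:
            raise ValueError("x_py must be strictly positive")


@dataclass(frozen=True)
class OperatingPoint:
    """One solved point of the forward model."""

    Ci: float  # intercellular CO2 partial pressure, Pa
    Cc: float  # chloroplast CO2 partial pressure, Pa
    A: float  # net assimilation, umol m-2 s-1
    Vc: float  # gross carboxylation rate, umol m-2 s-1 (nan if ill-defined)
    limitation: str
    flagged: bool = False  # Cc <= gamma_star: Vc ill-defined, A still valid


def _state_xy(params: FvCBParams, limitation: str) -> tuple[float, float]:
    """Map a limitation state onto (X, Y) of A = X*(Cc-G*)/(Cc+Y) - Rd."""
    kin = params.kinetics
    if limitation == "rubisco":
        return params.Vcmax, kin.Km
    if limitation == "rubp":
        return params.Jmax / 4.0, 2.0 * kin.gamma_star
    raise ValueError(f"unknown limitation state {limitation!r}")


def net_assimilation(Ci: float, params: FvCBParams, limitation: str) -> OperatingPoint:
    """Solve net assimilation at intercellular pressure ``Ci`` for one state.

    For the rubisco and rubp states the implicit coupling through
    ``Cc = Ci - rm * A`` yields a quadratic in A; the lesser root is the
    physical branch (verified against a bisection oracle in the test suite).

    Raises
    ------
    InfeasibleOperatingPointError
        If no root with positive Cc exists.
    """
    if not Ci > 0:
        raise ValueError("Ci must be strictly positive")
    if limitation not in LIMITATION_STATES:
        raise ValueError(f"unknown limitation state {limitation!r}")
    kin = params.kinetics
    rm = params.rm
    Rd = params.Rd

    if limitation == "tpu":
        A = 3.0 * params.TPU - Rd
        Cc = Ci - rm * A
        if Cc <= 0:
            raise InfeasibleOperatingPointError(
                f"TPU-limited rate drives Cc to {Cc:.4g} Pa <= 0 at Ci={Ci:.4g}"
            )
    else:
        X, Y = _state_xy(params, limitation)
        if rm == 0.0:
            A = X * (Ci - kin.gamma_star) / (Ci + Y) - Rd
            Cc = Ci
        else:
            # rm*A^2 - (Ci + Y + rm*(X - Rd))*A + X*(Ci - G*) - Rd*(Ci + Y) = 0
            b = -(Ci + Y + rm * (X - Rd))
            c = X * (Ci - kin.gamma_star) - Rd * (Ci + Y)
            disc = b * b - 4.0 * rm * c
            if disc < 0:
                raise InfeasibleOperatingPointError(
                    f"no real operating point at Ci={Ci:.4g} ({limitation})"
                )
            # lesser root, computed stably
            A = (-b - math.sqrt(disc)) / (2.0 * rm)
            Cc = Ci - rm * A
            if Cc <= 0:
                raise InfeasibleOperatingPointError(
                    f"no positive-Cc root at Ci={Ci:.4g} ({limitation})"
                )

    flagged = Cc <= kin.gamma_star * (1.0 + 1e-9)
    if flagged:
        Vc = math.nan
    else:
        Vc = (A + Rd) * Cc / (Cc - kin.gamma_star)
    return OperatingPoint(Ci=Ci, Cc=Cc, A=A, Vc=Vc, limitation=limitation, flagged=flagged)


def net_assimilation_min(Ci: float, params: FvCBParams) -> OperatingPoint:
    """Net assimilation with the minimum-rate state active at ``Ci``."""
    best: OperatingPoint | None = None
    for state in LIMITATION_STATES:
        try:
            pt = net_assimilation(Ci, params, state)
        except InfeasibleOperatingPointError:
            continue
        if best is None or pt.A < best.A:
            best = pt
    if best is None:
        raise InfeasibleOperatingPointError(f"no feasible state at Ci={Ci:.4g}")
    return best


def model_curve(ci_values: Sequence[float], params: FvCBParams) -> list[OperatingPoint]:
    """Vectorised forward model: minimum-rate state selected per point.

    Limitation labels are expected to be monotone non-decreasing in the order
    rubisco -> rubp -> tpu along increasing Ci under the standard
    parameterisation; violations are reported as warnings, not errors.
    """
    ci_values = list(ci_values)
    if not ci_values:
        raise ValueError("ci_values must be nonempty")
    if any(not ci > 0 for ci in ci_values):
        raise ValueError("all Ci values must be strictly positive")
    points = [net_assimilation_min(ci, params) for ci in ci_values]

    order = np.argsort(ci_values, kind="stable")
    rank = {state: i for i, state in enumerate(LIMITATION_STATES)}
    ranks = [rank[points[i].limitation] for i in order]
    if any(b < a for a, b in zip(ranks, ranks[1:])):
        warnings.warn(
            "limitation labels are not monotone along increasing Ci",
            RuntimeWarning,
            stacklevel=2,
        )
    return points


def refix_fraction(state: ResistanceState) -> float:
    """Fraction of cytosol-released CO2 refixed rather than escaping.

    The refixation flux is ``x_py / (r_ch + k_inv)`` and the escape flux is
    ``x_py / (r_wp + r_sc)``; the refixed fraction is the refixation flux over
    their sum, in which ``x_py`` cancels:

        P_r = (r_wp + r_sc) / ((r_wp + r_sc) + (r_ch + k_inv))

    Strictly increasing in the escape-path resistance ``r_wp + r_sc`` and
    strictly decreasing in the refixation-path resistance ``r_ch + k_inv``.
    """
    escape_r = state.r_wp + state.r_sc
    refix_r = state.r_ch + state.k_inv
    if escape_r == 0.0 and refix_r == 0.0:
        raise ValueError("refixation undefined when both resistance sums are zero")
    if escape_r == 0.0:
        return 0.0
    if refix_r == 0.0:
        return 1.0
    return escape_r / (escape_r + refix_r)


def carboxylation_resistance(point: OperatingPoint) -> float:
    """Carboxylation resistance k^-1 = Cc / Vc, m2 s Pa umol-1."""
    if math.isnan(point.Vc) or point.Vc <= 0:
        raise ValueError("carboxylation resistance undefined for Vc <= 0")
    return point.Cc / point.Vc


def rm_pressure_from_molar(rm_molar: float, P: float) -> float:
    """Convert a resistance from m2 s mol-1 to m2 s Pa umol-1.

    ``r[m2 s Pa umol-1] = P * 1e-6 * r[m2 s mol-1]`` with P the atmospheric
    pressure in Pa.
    """
    if not P > 0:
        raise ValueError("P must be strictly positive")
    return P * 1e-6 * rm_molar


def rm_molar_from_pressure(rm_pressure: float, P: float) -> float:
    """Inverse of :func:`rm_pressure_from_molar`."""
    if not P > 0:
        raise ValueError("P must be strictly positive")
    return rm_pressure / (P * 1e-6)


def partition_rm(rm: float, phi_wall: float) -> tuple[float, float]:
    """Split mesophyll resistance into wall/membrane and chloroplast parts.

    ``r_wp = phi_wall * rm`` and ``r_ch = (1 - phi_wall) * rm``; the sum is
    conserved exactly.  The split ratio is not an observable of the gas
    exchange data, hence configurable (default 0.5 upstream).
    """
    if not 0.0 <= phi_wall <= 1.0:
        raise ValueError("phi_wall must lie in [0, 1]")
    if rm < 0:
        raise ValueError("rm must be non-negative")
    r_wp = phi_wall * rm
    return r_wp, rm - r_wp


def stomatal_resistance(gsw: float, P: float) -> float:
    """CO2 stomatal resistance from stomatal conductance to water vapour.

    gsw (mol m-2 s-1) is converted to a CO2 conductance by the diffusivity
    ratio 1.6, inverted to a molar resistance and expressed in pressure
    units via :func:`rm_pressure_from_molar`.
    """
    if not gsw > 0:
        raise ValueError("gsw must be strictly positive")
    gsc = gsw / H2O_CO2_DIFFUSIVITY_RATIO
    return rm_pressure_from_molar(1.0 / gsc, P)


def refixation_state(
    params: FvCBParams,
    point: OperatingPoint,
    gsw: float,
    P: float,
    phi_wall: float = 0.5,
) -> ResistanceState:
    """Assemble the full resistance partition at a solved operating point."""
    r_wp, r_ch = partition_rm(params.rm, phi_wall)
    r_sc = stomatal_resistance(gsw, P)
    k_inv = carboxylation_resistance(point)
    return ResistanceState(r_wp=r_wp, r_ch=r_ch, r_sc=r_sc, k_inv=k_inv)


def refix_percent(
    params: FvCBParams,
    point: OperatingPoint,
    gsw: float,
    P: float,
    phi_wall: float = 0.5,
) -> float:
    """Refixation percentage (0-100) at a solved operating point."""
    return 100.0 * refix_fraction(refixation_state(params, point, gsw, P, phi_wall))
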