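"""Coupled carbon and water exchange of a single leaf.

Objective side
--------------
The assimilation rate per leaf area follows the linearized biochemical model

    GPP(r_es) = Ca*a1 / (1.6*cons3*a1*r_es + a2 + S*Ca),

strictly decreasing in the stomatal resistance ``r_es``; the whole-leaf net
carbon gain is

    NPP_leaf(LA, r_es) = GPP*LA - R*LA**1.5,

the 3/2 exponent expressing that construction/respiration cost scales with
leaf volume at fixed geometry.

Constraint side
---------------
Transpiration is stomatally controlled: the vapor mass flux per leaf area is
E = cons2*(e_sat - e_a)/r_es.  The water transpired by the strip of leaf
served by one terminal minor vein (area l_T * k_Z*Z/2) funnels through that
vein's conduit cross-section M_T*pi*r_T**2, giving the terminal conduit mass
flux density J_x = E*(l_T*k_Z*Z/2)/(M_T*pi*r_T**2).  The potential drop from
petiole to terminal vein is Psi_loss = J_x * r_Xtotal(LA).

The interior vapor path (diffusion through the mesophyll from the minor vein
to the evaporating surface, with the Table-type diffusivity D_m and saturated
tissue concentration w0) is exposed separately as :func:`mesophyll_state`: a
two-resistor series solution reporting the airspace vapor pressure ``e_l``
and the evaporating-surface concentration ``w_1``.  It is a diagnostic of the
leaf's internal water status, not part of the constraint, which is set by the
much larger stomatal resistance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import EnvironmentParams, LeafTraits, ParameterSet
from .venation import xylem_resistance_closed, xylem_resistance_dLA

__all__ = [
    "FluxState",
    "gpp",
    "gpp_dres",
    "gpp_max",
    "npp_leaf",
    "npp_dLA",
    "transpiration_mass_flux",
    "mesophyll_state",
    "conduit_area_ratio",
    "conduit_flux",
    "psi_loss",
    "psi_loss_dLA",
    "psi_loss_dres",
    "res_at_constraint",
    "flux_state",
]


def gpp(r_es, traits: LeafTraits, env: EnvironmentParams):
    """Net carbon assimilation per unit leaf area, mol m^-2 s^-1."""
    r_es = np.asarray(r_es, dtype=float)
    if np.any(r_es < 0):
        raise ValueError("r_es must be non-negative")
    out = env.Ca * traits.a1 / (
        1.6 * env.cons3 * traits.a1 * r_es + traits.a2 + traits.S * env.Ca)
    return out.item() if out.ndim == 0 else out


def gpp_max(traits: LeafTraits, env: EnvironmentParams) -> float:
    """Supremum of GPP, attained at fully open stomata (r_es = 0)."""
    return env.Ca * traits.a1 / (traits.a2 + traits.S * env.Ca)


def gpp_dres(r_es, traits: LeafTraits, env: EnvironmentParams):
    """Analytic derivative dGPP/dr_es (negative)."""
    c = 1.6 * env.cons3 * traits.a1
    denom = c * np.asarray(r_es, dtype=float) + traits.a2 + traits.S * env.Ca
    out = -env.Ca * traits.a1 * c / denom**2
    return out.item() if np.ndim(out) == 0 else out


def npp_leaf(LA, r_es, traits: LeafTraits, env: EnvironmentParams):
    """Whole-leaf net carbon gain NPP_leaf = GPP*LA - R*LA**1.5, mol/s."""
    LA = np.asarray(LA, dtype=float)
    if np.any(LA <= 0):
        raise ValueError("LA must be strictly positive")
    out = gpp(r_es, traits, env) * LA - traits.R * LA**1.5
    return out.item() if out.ndim == 0 else out


def npp_dLA(LA, r_es, traits: LeafTraits, env: EnvironmentParams):
    """Analytic partial dNPP_leaf/dLA = GPP - 1.5*R*sqrt(LA)."""
    LA = np.asarray(LA, dtype=float)
    out = gpp(r_es, traits, env) - 1.5 * traits.R * np.sqrt(LA)
    return out.item() if np.ndim(out) == 0 else out


def transpiration_mass_flux(r_es, traits: LeafTraits, env: EnvironmentParams):
    """Transpiration mass flux per leaf area, E = cons2*(e_sat - e_a)/r_es.

    Stomatally controlled; kg m^-2 s^-1.  E -> inf as r_es -> 0 (an open
    vapor path can spend any potential budget) and E -> 0 as r_es -> inf or
    when the air is vapor-saturated.
    """
    r_es = np.asarray(r_es, dtype=float)
    if np.any(r_es < 0):
        raise ValueError("r_es must be non-negative")
    with np.errstate(divide="ignore"):
        out = env.cons2 * (env.e_sat - env.e_a) / r_es
    return out.item() if out.ndim == 0 else out


def mesophyll_state(r_es, traits: LeafTraits, env: EnvironmentParams):
    """Two-resistor series solution of the interior vapor path (diagnostic).

    A mesophyll diffusion leg of resistance (k_Z*Z/2)*e_sat/(cons1*D_m*w0)
    (liquid diffusion from the minor vein across half the inter-vein spacing,
    with the surface equilibrium w_1 = w0*e_l/e_sat) in series with the
    stomatal leg r_es/cons2.  Returns ``(E_series, e_l, w_1)`` where the
    series flux satisfies continuity through both legs and
    e_a <= e_l <= e_sat, 0 <= w_1 <= w0.
    """
    r_es = np.asarray(r_es, dtype=float)
    if np.any(r_es < 0):
        raise ValueError("r_es must be non-negative")
    R_meso = (traits.k_Z * traits.Z / 2.0) * env.e_sat / (
        env.cons1 * env.D_m * env.w0)
    R_stom = r_es / env.cons2
    E_series = (env.e_sat - env.e_a) / (R_meso + R_stom)
    e_l = env.e_sat - E_series * R_meso
    w_1 = env.w0 * e_l / env.e_sat
    if np.ndim(E_series) == 0:
        return float(E_series), float(e_l), float(w_1)
    return E_series, e_l, w_1


def conduit_area_ratio(traits: LeafTraits) -> float:
    """Leaf-strip to conduit cross-section ratio (l_T*k_Z*Z/2)/(M_T*pi*r_T**2)."""
    return (traits.l_T * traits.k_Z * traits.Z / 2.0) / (
        traits.M_T * math.pi * traits.r_T**2)


def conduit_flux(E, traits: LeafTraits):
    """Terminal conduit mass flux density J_x = E * conduit_area_ratio."""
    E = np.asarray(E, dtype=float)
    if np.any(E < 0):
        raise ValueError("E must be non-negative")
    out = E * conduit_area_ratio(traits)
    return out.item() if out.ndim == 0 else out


def psi_loss(LA, r_es, traits: LeafTraits, env: EnvironmentParams):
    """Total xylem potential loss petiole -> terminal vein, Pa.

    Psi_loss = J_x(r_es) * r_Xtotal(LA): strictly increasing in LA, strictly
    decreasing in r_es.
    """
    E = transpiration_mass_flux(r_es, traits, env)
    rX = xylem_resistance_closed(LA, traits, env)
    out = np.asarray(E, dtype=float) * conduit_area_ratio(traits) * rX
    return out.item() if np.ndim(out) == 0 else out


def psi_loss_dLA(LA, r_es, traits: LeafTraits, env: EnvironmentParams):
    """Analytic partial dPsi_loss/dLA (positive)."""
    E = transpiration_mass_flux(r_es, traits, env)
    out = (np.asarray(E, dtype=float) * conduit_area_ratio(traits)
           * xylem_resistance_dLA(LA, traits, env))
    return out.item() if np.ndim(out) == 0 else out


def psi_loss_dres(LA, r_es, traits: LeafTraits, env: EnvironmentParams):
    """Analytic partial dPsi_loss/dr_es = -Psi_loss/r_es (negative)."""
    out = -np.asarray(psi_loss(LA, r_es, traits, env)) \
        / np.asarray(r_es, dtype=float)
    return out.item() if np.ndim(out) == 0 else out


def res_at_constraint(LA, dPsi_Lmax, traits: LeafTraits,
                      env: EnvironmentParams):
    """The unique r_es with Psi_loss(LA, r_es) = dPsi_Lmax, in closed form.

    r_es = cons2*(e_sat - e_a)*A*r_Xtotal(LA)/dPsi_Lmax with A the conduit
    area ratio.  Under stomatal control this is positive for every finite
    positive budget, strictly decreasing in dPsi_Lmax and increasing in LA.
    """
    if np.any(np.asarray(dPsi_Lmax) <= 0):
        raise ValueError("dPsi_Lmax must be strictly positive")
    rX = xylem_resistance_closed(LA, traits, env)
    out = env.cons2 * (env.e_sat - env.e_a) * conduit_area_ratio(traits) \
        * np.asarray(rX) / np.asarray(dPsi_Lmax, dtype=float)
    return out.item() if np.ndim(out) == 0 else out


@dataclass(frozen=True)
class FluxState:
    """All fluxes and potentials of one leaf at a given (LA, r_es)."""

    LA: float         # leaf area, m^2
    r_es: float       # stomatal resistance, s/m
    GPP: float        # assimilation per leaf area, mol m^-2 s^-1
    E: float          # transpiration mass flux per leaf area, kg m^-2 s^-1
    Jx: float         # terminal conduit mass flux density, kg m^-2 s^-1
    Psi_loss: float   # total xylem potential loss, Pa
    NPP_leaf: float   # whole-leaf net carbon gain, mol/s
    e_l: float        # interior airspace vapor pressure (diagnostic), Pa
    w_1: float        # evaporating-surface water concentration (diagnostic), mol/m^3


def flux_state(LA: float, r_es: float, params: ParameterSet) -> FluxState:
    """Evaluate the full :class:`FluxState` at one operating point."""
    traits, env = params.traits, params.env
    E = transpiration_mass_flux(r_es, traits, env)
    _, e_l, w_1 = mesophyll_state(r_es, traits, env)
    return FluxState(
        LA=float(LA),
        r_es=float(r_es),
        GPP=gpp(r_es, traits, env),
        E=E,
        Jx=conduit_flux(E, traits) if np.isfinite(E) else math.inf,
        Psi_loss=psi_loss(LA, r_es, traits, env),
        NPP_leaf=npp_leaf(LA, r_es, traits, env),
        e_l=e_l,
        w_1=w_1,
    )
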