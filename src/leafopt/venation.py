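"""Venation network scaling: from leaf shape and size to xylem resistance.

The vein system is a dendritic, space-filling hierarchy in the tradition of
metabolic scaling theory.  Orders run from 0 (the major vein / midrib) to T
(the terminal minor veins where water leaves the xylem).  Three ratios define
the hierarchy:

* ``gamma``  — vein length ratio between consecutive orders, tied to leaf
  shape as gamma = k_SP/2 (half the width-to-length ratio);
* ``beta``   — conduit radius ratio between consecutive orders; conservation
  of total conduit cross-sectional area makes the conduit branching ratio
  m = 1/beta**2;
* ``n``      — vein branching ratio.  Space filling in two dimensions means
  each vein of order k serves a territory scaling with its length squared,
  hence n = 1/gamma**2.

The total order T follows from requiring the hierarchy to shrink from the
major vein length l0 = sqrt(LA/k_SP) down to the terminal vein length l_T:
T = log_gamma(l_T/l0), an identity with the expanded form
T = (-2 ln l_T - ln k_SP + ln LA) / (2 ln 2 - 2 ln k_SP).

Water enters the xylem only at the terminal veins, so the mass flux per unit
conduit cross-section grows by a factor n at every upstream branching while
per-vein conduit area stays conserved.  Referencing the whole flow path to
the terminal flux density J_x therefore gives a geometric series for the
effective Poiseuille resistance:

    r_Xtotal = (8 mu / rho_w) * (l_T / r_T**2) * sum_{j=0..T} q**j,
    q = n * beta**2 / gamma,

in Pa per unit terminal mass-flux density (kg m^-2 s^-1).  The 1/rho_w factor
converts mass flux to the mean conduit velocity of Hagen-Poiseuille flow; the
pair (J_x, r_Xtotal) is unit-coupled through it.  T is treated as a
continuous real; the explicit per-order sum (:func:`xylem_resistance_sum`) is
the brute-force oracle at integer T.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import EnvironmentParams, LeafTraits

__all__ = [
    "VenationSummary",
    "gamma_from_shape",
    "vein_branching_ratio",
    "major_vein_length",
    "vein_order",
    "conduit_scaling",
    "terminal_vein_spacing",
    "resistance_series_ratio",
    "xylem_resistance_closed",
    "xylem_resistance_sum",
    "xylem_resistance_dLA",
    "summarize",
]

# Relative width of the neighbourhood of q = 1 inside which the closed form
# switches to its (T+1)-term limit to avoid 0/0 cancellation.
_Q_LIMIT_TOL = 1e-12


def gamma_from_shape(k_SP):
    """Vein length ratio gamma = k_SP/2 (proportionality constant 1).

    This is the value that turns the total-order formula into an exact
    algebraic identity with l0 = sqrt(LA/k_SP).
    """
    k_SP = np.asarray(k_SP, dtype=float)
    if np.any(k_SP <= 0) or np.any(k_SP >= 2):
        raise ValueError("k_SP must lie in (0, 2) so that gamma = k_SP/2 < 1")
    out = k_SP / 2.0
    return out.item() if out.ndim == 0 else out


def vein_branching_ratio(k_SP):
    """Vein branching ratio n = 1/gamma**2 of a space-filling dendritic net."""
    g = gamma_from_shape(k_SP)
    return 1.0 / g**2


def major_vein_length(LA, k_SP):
    """Major vein (midrib) length l0 = sqrt(LA/k_SP), i.e. the leaf length L
    under LA = W*L = k_SP*L**2."""
    LA = np.asarray(LA, dtype=float)
    if np.any(LA <= 0):
        raise ValueError("LA must be strictly positive")
    out = np.sqrt(LA / k_SP)
    return out.item() if out.ndim == 0 else out


def vein_order(LA, k_SP, l_T):
    """Total vein order T = log_gamma(l_T / l0), continuous-valued.

    Strictly increasing in k_SP at fixed (LA, l_T): a broader leaf needs more
    orders because its veins shorten more slowly.
    """
    l0 = major_vein_length(LA, k_SP)
    if np.any(np.asarray(l_T) > l0):
        raise ValueError(
            "degenerate leaf: terminal vein length l_T must be shorter than "
            "the major vein l0 = sqrt(LA/k_SP)")
    g = gamma_from_shape(k_SP)
    out = np.log(np.asarray(l_T, dtype=float) / l0) / math.log(g)
    return out.item() if np.ndim(out) == 0 else out


def terminal_vein_spacing(Z, k_Z):
    """Distance between adjacent terminal minor veins, d_T = k_Z*Z/2."""
    if np.any(np.asarray(Z) <= 0):
        raise ValueError("Z must be strictly positive")
    if np.any(np.asarray(k_Z) < 1):
        raise ValueError("k_Z must be >= 1")
    return k_Z * Z / 2.0


def resistance_series_ratio(traits: LeafTraits) -> float:
    """Per-order resistance ratio q = n*beta**2/gamma of the flow path.

    beta**2/gamma is the per-order growth of l/r**2 toward the terminal end;
    the factor n accounts for the n-fold drop of per-conduit-area flux at
    each downstream branching.
    """
    g = gamma_from_shape(traits.k_SP)
    return vein_branching_ratio(traits.k_SP) * traits.beta**2 / g


def _single_segment_resistance(traits: LeafTraits,
                               env: EnvironmentParams) -> float:
    return (8.0 * env.mu / env.rho_w) * traits.l_T / traits.r_T**2


def _series_sum(q: float, T):
    """sum_{j=0..T} q**j for continuous T, stable in log space."""
    T = np.asarray(T, dtype=float)
    if abs(q - 1.0) <= _Q_LIMIT_TOL:
        out = T + 1.0
    else:
        # (q**(T+1) - 1)/(q - 1), computed via expm1 to survive large T.
        out = np.expm1((T + 1.0) * math.log(q)) / (q - 1.0)
    return out.item() if out.ndim == 0 else out


def xylem_resistance_closed(LA, traits: LeafTraits, env: EnvironmentParams):
    """Total flow-path resistance r_Xtotal(LA), closed geometric-series form.

    Strictly increasing in LA at fixed traits (more vein orders), and
    decreasing in k_SP at fixed LA (a broadleaf's veins shorten more slowly,
    so its path is dominated by fewer, wider upstream conduits).
    """
    T = vein_order(LA, traits.k_SP, traits.l_T)
    q = resistance_series_ratio(traits)
    return _single_segment_resistance(traits, env) * _series_sum(q, T)


def xylem_resistance_sum(T_int: int, traits: LeafTraits,
                         env: EnvironmentParams) -> float:
    """Brute-force per-order resistance sum at integer total order.

    Order k in 0..T has segment length l_T*gamma**(k-T) and conduit radius
    r_T*beta**(k-T); the per-conduit-area flux there exceeds the terminal
    value by n**(T-k).  Summing the per-order potential drops and dividing by
    the terminal flux density reproduces the closed form exactly at integer T.
    """
    if not float(T_int).is_integer() or T_int < 0:
        raise ValueError("T_int must be a non-negative integer")
    T_int = int(T_int)
    g = gamma_from_shape(traits.k_SP)
    n = vein_branching_ratio(traits.k_SP)
    terms = []
    for k in range(T_int + 1):
        j = T_int - k  # orders upstream of the terminal vein
        length = traits.l_T * g ** (k - T_int)
        radius = traits.r_T * traits.beta ** (k - T_int)
        flux_factor = n ** j
        terms.append((8.0 * env.mu / env.rho_w)
                     * length / radius**2 * flux_factor)
    return math.fsum(terms)


def xylem_resistance_dLA(LA, traits: LeafTraits, env: EnvironmentParams):
    """Analytic derivative d r_Xtotal / d LA (via dT/dLA).

    dT/dLA = 1 / (LA * 2*ln(2/k_SP)); d/dT of the series is
    q**(T+1)*ln(q)/(q-1) (or 1 at the q->1 limit).
    """
    T = vein_order(LA, traits.k_SP, traits.l_T)
    q = resistance_series_ratio(traits)
    base = _single_segment_resistance(traits, env)
    dT_dLA = 1.0 / (np.asarray(LA, dtype=float)
                    * 2.0 * math.log(2.0 / traits.k_SP))
    if abs(q - 1.0) <= _Q_LIMIT_TOL:
        dsum_dT = 1.0
    else:
        dsum_dT = np.exp((np.asarray(T) + 1.0) * math.log(q)) \
            * math.log(q) / (q - 1.0)
    out = base * dsum_dT * dT_dLA
    return out.item() if np.ndim(out) == 0 else out


@dataclass(frozen=True)
class VenationSummary:
    """Derived network quantities for one (LA, shape) combination."""

    gamma: float      # consecutive-order vein length ratio
    n: float          # vein branching ratio (1/gamma**2, space filling)
    T: float          # total vein order (continuous)
    m: float          # conduit branching ratio 1/beta**2
    l0: float         # major vein length, m
    M0: float         # conduit count of the major vein (real-valued)
    r0: float         # major-vein conduit radius, m
    d_T: float        # spacing of adjacent terminal minor veins, m
    r_Xtotal: float   # effective flow-path resistance, Pa/(kg m^-2 s^-1)


def conduit_scaling(T: float, traits: LeafTraits) -> tuple[float, float, float]:
    """Conduit branching ratio m, major-vein count M0 and radius r0.

    Radii widen upstream, r0 = r_T/beta**T, while conservation of a vein's
    total conduit cross-section fixes the count: the number of conduits
    multiplies by m = 1/beta**2 at each downstream branching, so the major
    vein carries M0 = M_T*beta**(2T) (real-valued) and
    M0*r0**2 = M_T*r_T**2 holds exactly.  A narrower leaf (fewer orders T)
    thus has more, smaller conduits in its major vein than a broadleaf of
    the same area.
    """
    if T < 0:
        raise ValueError("T must be >= 0")
    m = 1.0 / traits.beta**2
    M0 = traits.M_T * traits.beta ** (2.0 * T)
    r0 = traits.r_T / traits.beta**T
    return m, M0, r0


def summarize(LA: float, traits: LeafTraits,
              env: EnvironmentParams) -> VenationSummary:
    """Full :class:`VenationSummary` for one leaf."""
    g = gamma_from_shape(traits.k_SP)
    T = vein_order(LA, traits.k_SP, traits.l_T)
    m, M0, r0 = conduit_scaling(T, traits)
    return VenationSummary(
        gamma=g,
        n=vein_branching_ratio(traits.k_SP),
        T=T,
        m=m,
        l0=major_vein_length(LA, traits.k_SP),
        M0=M0,
        r0=r0,
        d_T=terminal_vein_spacing(traits.Z, traits.k_Z),
        r_Xtotal=xylem_resistance_closed(LA, traits, env),
    )
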