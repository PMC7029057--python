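"""Constrained maximization of whole-leaf net carbon gain.

At an optimum the leaf is equally limited by the water-potential cost of
opening stomata and of growing area: the marginal NPP per marginal potential
loss is the same along both controls,

    (dNPP/dr_es)/(dPsi/dr_es) = (dNPP/dLA)/(dPsi/dLA),   Psi_loss = dPsi_Lmax.

Because both NPP and Psi_loss are monotone in r_es, the constraint is active
at the optimum, so the problem reduces to one dimension: substitute
r_es = res_at_constraint(LA, dPsi_Lmax) and maximize over LA.  The reduced
derivative is available in closed form, and the stationary point is located
by root bracketing on log(LA) — more robust than a symbolic-numeric solve of
the stationarity system, with the same fixed point.  The marginal-ratio
(first-order) condition is verified a posteriori from the analytic partials.

A brute-force log-grid search (:func:`grid_oracle`) serves as an independent
cross-check of the reduced solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from . import exchange, venation
from .params import ParameterSet

__all__ = ["OptimumResult", "optimize", "grid_oracle", "kkt_report"]

DEFAULT_LA_BRACKET = (1e-6, 1.0)  # m^2, log-scale search interval


@dataclass(frozen=True)
class OptimumResult:
    LA_opt: float                 # optimal leaf area, m^2
    res_opt: float                # optimal stomatal resistance, s/m
    NPP_max: float                # maximized net leaf carbon gain, mol/s
    GPP_opt: float                # assimilation rate at the optimum, mol m^-2 s^-1
    constraint_residual: float    # |Psi_loss - dPsi_Lmax| / dPsi_Lmax
    marginal_ratio_residual: float  # relative residual of the marginal-ratio condition
    method: str
    converged: bool
    n_evals: int
    message: str = ""
    params: ParameterSet | None = field(default=None, repr=False, compare=False)

    def to_dict(self) -> dict:
        d = {
            "LA_opt": self.LA_opt,
            "res_opt": self.res_opt,
            "NPP_max": self.NPP_max,
            "GPP_opt": self.GPP_opt,
            "constraint_residual": self.constraint_residual,
            "marginal_ratio_residual": self.marginal_ratio_residual,
            "method": self.method,
            "converged": self.converged,
            "n_evals": self.n_evals,
            "message": self.message,
        }
        if self.params is not None:
            d["params"] = self.params.to_dict()
        return d


def _reduced_dnpp_dLA(LA, params: ParameterSet):
    """Derivative of NPP_leaf along the active constraint, d/dLA of
    NPP(LA, res_at_constraint(LA))."""
    traits, env = params.traits, params.env
    d = params.constraint.dPsi_Lmax
    s = exchange.res_at_constraint(LA, d, traits, env)
    # ds/dLA follows from Psi_loss(LA, s(LA)) = d: s is proportional to
    # r_Xtotal(LA), so ds/dLA = cons2*(e_sat-e_a)*A*rX'(LA)/d.
    ds = env.cons2 * (env.e_sat - env.e_a) \
        * exchange.conduit_area_ratio(traits) \
        * np.asarray(venation.xylem_resistance_dLA(LA, traits, env)) / d
    out = exchange.gpp_dres(s, traits, env) * ds * np.asarray(LA) \
        + exchange.gpp(s, traits, env) \
        - 1.5 * traits.R * np.sqrt(np.asarray(LA, dtype=float))
    return out.item() if np.ndim(out) == 0 else out


def _marginal_ratio_residual(LA: float, r_es: float,
                             params: ParameterSet) -> float:
    """Relative mismatch of the two marginal-NPP-per-marginal-Psi ratios."""
    traits, env = params.traits, params.env
    dN_dr = exchange.gpp_dres(r_es, traits, env) * LA
    dN_dL = exchange.npp_dLA(LA, r_es, traits, env)
    dP_dr = exchange.psi_loss_dres(LA, r_es, traits, env)
    dP_dL = exchange.psi_loss_dLA(LA, r_es, traits, env)
    ratio_r = dN_dr / dP_dr
    ratio_L = dN_dL / dP_dL
    scale = max(abs(ratio_r), abs(ratio_L))
    return abs(ratio_r - ratio_L) / scale if scale > 0 else 0.0


def optimize(params: ParameterSet,
             la_bracket: tuple[float, float] = DEFAULT_LA_BRACKET,
             n_scan: int = 256) -> OptimumResult:
    """Solve the constrained optimum by 1-D reduction on log(LA).

    The search bracket is scanned for a sign change of the reduced
    derivative; the stationary point is then polished with Brent's method.
    A maximum at a bracket edge is reported with ``converged=False`` rather
    than silently returned.
    """
    traits, env = params.traits, params.env
    d = params.constraint.dPsi_Lmax
    lo, hi = la_bracket
    xs = np.linspace(math.log(lo), math.log(hi), n_scan)
    las = np.exp(xs)
    derivs = _reduced_dnpp_dLA(las, params)
    n_evals = n_scan

    sign_changes = np.nonzero(np.diff(np.sign(derivs)) < 0)[0]
    if sign_changes.size == 0:
        edge = "upper" if derivs[-1] > 0 else "lower"
        return _result_at(las[-1] if edge == "upper" else las[0], params,
                          method="reduced-1d", converged=False,
                          n_evals=n_evals,
                          message=(f"no interior maximum: reduced derivative "
                                   f"does not change sign in LA bracket "
                                   f"[{lo:g}, {hi:g}] m^2 ({edge}-edge max)"))

    best = None
    for i in sign_changes:
        root = brentq(lambda x: _reduced_dnpp_dLA(math.exp(x), params),
                      xs[i], xs[i + 1], xtol=1e-13, rtol=1e-15)
        n_evals += 60
        LA = math.exp(root)
        npp = exchange.npp_leaf(
            LA, exchange.res_at_constraint(LA, d, traits, env), traits, env)
        if best is None or npp > best[1]:
            best = (LA, npp)
    LA_opt = best[0]
    return _result_at(LA_opt, params, method="reduced-1d", converged=True,
                      n_evals=n_evals)


def _result_at(LA: float, params: ParameterSet, method: str, converged: bool,
               n_evals: int, message: str = "") -> OptimumResult:
    traits, env = params.traits, params.env
    d = params.constraint.dPsi_Lmax
    r_es = exchange.res_at_constraint(LA, d, traits, env)
    psi = exchange.psi_loss(LA, r_es, traits, env)
    return OptimumResult(
        LA_opt=float(LA),
        res_opt=float(r_es),
        NPP_max=exchange.npp_leaf(LA, r_es, traits, env),
        GPP_opt=exchange.gpp(r_es, traits, env),
        constraint_residual=abs(psi - d) / d,
        marginal_ratio_residual=_marginal_ratio_residual(LA, r_es, params),
        method=method,
        converged=converged,
        n_evals=n_evals,
        message=message,
        params=params,
    )


def grid_oracle(params: ParameterSet,
                LA_grid: tuple[float, float, int] = (1e-6, 1.0, 200),
                res_grid: tuple[float, float, int] = (1e1, 1e7, 200),
                ) -> OptimumResult:
    """Brute-force maximization of NPP_leaf over a log-spaced (LA, r_es) grid
    subject to Psi_loss <= dPsi_Lmax.

    Independent of the reduced solver: evaluates the objective exhaustively
    on feasible grid points and returns the argmax.  The monotone trade-off
    pushes the argmax to (within one grid step of) the constraint boundary.
    """
    traits, env = params.traits, params.env
    d = params.constraint.dPsi_Lmax
    las = np.geomspace(*LA_grid[:2], int(LA_grid[2]))
    ress = np.geomspace(*res_grid[:2], int(res_grid[2]))
    LA2, RES2 = np.meshgrid(las, ress, indexing="ij")
    psi = exchange.psi_loss(LA2, RES2, traits, env)
    feasible = psi <= d
    if not feasible.any():
        raise ValueError("empty feasible grid: every grid point violates the "
                         "water-potential constraint")
    npp = exchange.npp_leaf(LA2, RES2, traits, env)
    npp = np.where(feasible, npp, -np.inf)
    i, j = np.unravel_index(np.argmax(npp), npp.shape)
    LA, r_es = las[i], ress[j]
    interior = 0 < i < len(las) - 1 and 0 < j < len(ress) - 1
    return OptimumResult(
        LA_opt=float(LA),
        res_opt=float(r_es),
        NPP_max=float(npp[i, j]),
        GPP_opt=exchange.gpp(r_es, traits, env),
        constraint_residual=abs(psi[i, j] - d) / d,
        marginal_ratio_residual=_marginal_ratio_residual(LA, r_es, params),
        method="grid",
        converged=bool(interior),
        n_evals=int(LA2.size),
        message="" if interior else "grid argmax on grid boundary",
        params=params,
    )


def kkt_report(params: ParameterSet, result: OptimumResult) -> dict:
    """Recompute first-order residuals and the implied multiplier at a result.

    ``lambda`` = (dNPP/dLA)/(dPsi/dLA) is the marginal carbon value of one
    pascal of potential budget; it is positive whenever the water-potential
    constraint is limiting, and ~0 at an interior (slack) optimum.
    """
    traits, env = params.traits, params.env
    LA, r_es = result.LA_opt, result.res_opt
    d = params.constraint.dPsi_Lmax
    psi = exchange.psi_loss(LA, r_es, traits, env)
    lam = exchange.npp_dLA(LA, r_es, traits, env) \
        / exchange.psi_loss_dLA(LA, r_es, traits, env)
    return {
        "constraint_residual": abs(psi - d) / d,
        "marginal_ratio_residual": _marginal_ratio_residual(LA, r_es, params),
        "lambda": float(lam),
        "constraint_active": bool(abs(psi - d) / d < 1e-6),
    }
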