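"""Sweeps, isolines and resistance curves over the model's trait space.

These drivers reproduce the model's characteristic predictions as tables:

* :func:`sweep_constraint` — constrained optima over grids of the potential
  budget dPsi_Lmax, the shape ratio k_SP, and the thickness Z.  Broadleaves
  (larger k_SP) dominate narrowleaves in NPP, leaf area and stomatal
  conductance at every budget; thick leaves have higher optimal resistance
  and smaller optimal area than thin ones; all optima move monotonically
  with the budget.
* :func:`isolines` — level sets of the objective (NPP_leaf) or the
  constraint (Psi_loss) in the (stomatal conductance, leaf area) plane, the
  graphical reading of the optimization: the optimum is where the highest
  reachable NPP isoline touches the budget's Psi_loss isoline.
* :func:`resistance_curves` — total xylem resistance versus leaf area per
  shape ratio.

All tables carry the generating :class:`~leafopt.params.ParameterSet` as
provenance (``DataFrame.attrs`` in memory, a JSON comment header on disk).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import measure

from . import exchange, venation
from .optimize import OptimumResult, optimize
from .params import ParameterSet

__all__ = [
    "PAPER_NPP_SCALE",
    "Isoline",
    "IsolineSet",
    "default_sweep_spec",
    "sweep_constraint",
    "shape_delta_npp",
    "isolines",
    "resistance_curves",
    "write_table",
    "read_table",
]

#: Output scale mapping SI NPP_leaf (mol/s) onto the published figures' NPP
#: axis, whose unit normalization is not derivable from the printed
#: parameter set.  Calibrated once, against a single anchor point: the
#: increase of maximized NPP_leaf from shape ratio 0.28 to 0.35 at a
#: 3 kPa potential budget, reported as 0.47 on that axis.  Every scaled
#: output shares this one factor; ratios and orderings are unaffected by it.
PAPER_NPP_SCALE = 2.868e8


def default_sweep_spec() -> dict:
    """The sweep grids used for the model's headline tables."""
    return {
        "dPsi_list": list(np.geomspace(1e3, 1e4, 10)),
        "k_SP_list": [0.28, 0.35],
        "Z_list": [250e-6, 300e-6, 350e-6],
    }


def sweep_constraint(params: ParameterSet,
                     dPsi_list,
                     k_SP_list=None,
                     Z_list=None) -> pd.DataFrame:
    """Constrained optimum for every (dPsi_Lmax, k_SP, Z) combination.

    Single-valued lists collapse to the base parameter values; per-row solver
    failures are recorded in the ``converged``/``message`` columns and the
    sweep continues.
    """
    dPsi_list = list(np.atleast_1d(dPsi_list))
    k_SP_list = [params.traits.k_SP] if k_SP_list is None else list(k_SP_list)
    Z_list = [params.traits.Z] if Z_list is None else list(Z_list)
    if not (dPsi_list and k_SP_list and Z_list):
        raise ValueError("sweep lists must be nonempty")
    rows = []
    for k_SP in k_SP_list:
        for Z in Z_list:
            for dPsi in dPsi_list:
                p = params.replace(**{"traits.k_SP": k_SP, "traits.Z": Z,
                                      "constraint.dPsi_Lmax": float(dPsi)})
                try:
                    r = optimize(p)
                    msg = r.message
                except Exception as err:  # record, keep sweeping
                    r = None
                    msg = str(err)
                rows.append({
                    "dPsi_Lmax": float(dPsi),
                    "k_SP": k_SP,
                    "Z": Z,
                    "LA_opt": r.LA_opt if r else np.nan,
                    "res_opt": r.res_opt if r else np.nan,
                    "conductance": 1.0 / r.res_opt if r and r.res_opt > 0
                    else np.nan,
                    "GPP_opt": r.GPP_opt if r else np.nan,
                    "NPP_max": r.NPP_max if r else np.nan,
                    "NPP_per_area": r.NPP_max / r.LA_opt if r else np.nan,
                    "constraint_residual": r.constraint_residual if r
                    else np.nan,
                    "marginal_ratio_residual": r.marginal_ratio_residual if r
                    else np.nan,
                    "converged": bool(r.converged) if r else False,
                    "message": msg,
                })
    df = pd.DataFrame(rows)
    df.attrs["params"] = params.to_dict()
    return df


def shape_delta_npp(params: ParameterSet, dPsi_Lmax: float,
                    k_SP_pair=(0.28, 0.35)) -> float:
    """Increase of maximized NPP_leaf (SI, mol/s) from the narrower to the
    broader shape of ``k_SP_pair`` at one potential budget."""
    lo, hi = k_SP_pair
    vals = {}
    for k in (lo, hi):
        p = params.replace(**{"traits.k_SP": k,
                              "constraint.dPsi_Lmax": float(dPsi_Lmax)})
        r = optimize(p)
        if not r.converged:
            raise RuntimeError(f"optimum did not converge at k_SP={k}: "
                               f"{r.message}")
        vals[k] = r.NPP_max
    return vals[hi] - vals[lo]


# ---------------------------------------------------------------------------
# Isolines
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Isoline:
    which: str                    # "objective" (NPP_leaf) or "constraint" (Psi_loss)
    level: float
    vertices: np.ndarray          # (N, 2): columns (conductance s^-1 m, LA m^2)


@dataclass(frozen=True)
class IsolineSet:
    isolines: list[Isoline]
    params: ParameterSet = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for seg_id, iso in enumerate(self.isolines):
            for g, la in iso.vertices:
                rows.append({"which": iso.which, "level": iso.level,
                             "segment": seg_id, "conductance": g, "LA": la})
        df = pd.DataFrame(rows)
        df.attrs["params"] = self.params.to_dict()
        return df


def _field_on_grid(which: str, G, LA, params: ParameterSet):
    traits, env = params.traits, params.env
    if which == "constraint":
        return exchange.psi_loss(LA, 1.0 / G, traits, env)
    if which == "objective":
        return exchange.npp_leaf(LA, 1.0 / G, traits, env)
    raise ValueError("which must be 'objective' or 'constraint'")


def _newton_refine(which: str, g: float, la: float, level: float,
                   params: ParameterSet) -> float:
    """One Newton step on LA (at fixed conductance) toward the level set."""
    traits, env = params.traits, params.env
    f = _field_on_grid(which, g, la, params) - level
    if which == "constraint":
        df = exchange.psi_loss_dLA(la, 1.0 / g, traits, env)
    else:
        df = exchange.npp_dLA(la, 1.0 / g, traits, env)
    if df == 0 or not np.isfinite(df):
        return la
    step = f / df
    if abs(step) > 0.5 * la:  # stay within the cell; refinement only
        return la
    return la - step


def isolines(params: ParameterSet,
             which: str = "constraint",
             levels=(1e3, 3e3, 1e4),
             g_range: tuple[float, float] = (1e-6, 1e-2),
             la_range: tuple[float, float] = (1e-5, 1e-1),
             n: int = 200,
             refine: bool = True) -> IsolineSet:
    """Level-set polylines of NPP_leaf or Psi_loss in the (conductance, LA)
    plane.

    The field is evaluated on an ``n`` x ``n`` log-spaced grid, contours are
    extracted by marching squares with linear cell-edge interpolation, and
    each vertex takes one Newton refinement step in LA.  Isolines of both
    functions move northeast with increasing level.  A level outside the
    grid's value range yields no polyline (with a warning entry skipped).
    """
    gs = np.geomspace(*g_range, n)
    las = np.geomspace(*la_range, n)
    G, LAg = np.meshgrid(gs, las, indexing="ij")
    F = np.asarray(_field_on_grid(which, G, LAg, params), dtype=float)
    out: list[Isoline] = []
    lg, lla = np.log(gs), np.log(las)
    for level in np.atleast_1d(levels):
        for contour in measure.find_contours(F, float(level)):
            # fractional grid indices -> log-space coordinates
            gi = np.interp(contour[:, 0], np.arange(n), lg)
            li = np.interp(contour[:, 1], np.arange(n), lla)
            verts = np.column_stack([np.exp(gi), np.exp(li)])
            if refine:
                verts = np.array([
                    (g, _newton_refine(which, g, la, float(level), params))
                    for g, la in verts])
            out.append(Isoline(which=which, level=float(level),
                               vertices=verts))
    return IsolineSet(isolines=out, params=params)


def resistance_curves(params: ParameterSet,
                      k_SP_list=(0.1, 0.2, 0.3, 0.4, 0.5),
                      LA_range: tuple[float, float] = (1e-4, 1e-2),
                      n: int = 50) -> pd.DataFrame:
    """Total xylem resistance versus leaf area, one curve per shape ratio."""
    if LA_range[0] <= 0:
        raise ValueError("LA_range must be positive")
    las = np.geomspace(*LA_range, n)
    rows = []
    for k_SP in np.atleast_1d(k_SP_list):
        traits = params.replace(**{"traits.k_SP": float(k_SP)}).traits
        rX = venation.xylem_resistance_closed(las, traits, params.env)
        for la, r in zip(las, np.atleast_1d(rX)):
            rows.append({"k_SP": float(k_SP), "LA": float(la),
                         "r_Xtotal": float(r)})
    df = pd.DataFrame(rows)
    df.attrs["params"] = params.to_dict()
    return df


# ---------------------------------------------------------------------------
# Table I/O with provenance
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a CSV with the generating ParameterSet as a JSON comment header."""
    path = Path(path)
    header = ""
    if "params" in df.attrs:
        header = "# params: " + json.dumps(df.attrs["params"]) + "\n"
    with open(path, "w", newline="") as fh:
        fh.write(header)
        # %.17g round-trips IEEE doubles exactly
        df.to_csv(fh, index=False, float_format="%.17g")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table`, restoring provenance."""
    path = Path(path)
    params_dict = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# params: "):
            params_dict = json.loads(first[len("# params: "):])
            df = pd.read_csv(fh, float_precision="round_trip")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, float_precision="round_trip")
    if params_dict is not None:
        df.attrs["params"] = params_dict
    return df
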