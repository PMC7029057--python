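"""Parameter handling for the leaf optimization model.

All quantities are SI (Pa, m, s, mol, kg).  A :class:`ParameterSet` bundles
the environmental constants, the leaf traits, and the water-potential
constraint into a single validated record that every other module consumes.
Values can be overridden from a flat YAML config file or from dotted
``section.field`` assignments (the CLI's ``--set``).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterator

import yaml

__all__ = [
    "EnvironmentParams",
    "LeafTraits",
    "ConstraintSetting",
    "ParameterSet",
    "ParameterError",
    "default_params",
    "load_params",
    "loads_params",
    "validate",
]


class ParameterError(ValueError):
    """Raised when a parameter record violates one or more invariants.

    ``errors`` lists every violated invariant, each naming the offending
    field, so a bad config surfaces all problems at once.
    """

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


@dataclass(frozen=True)
class EnvironmentParams:
    """Physical and atmospheric constants, fixed at 25 degC.

    ``cons1``/``cons2``/``cons3`` are the unit-conversion constants of the
    coupled vapor/CO2 flux formulation: molar mass of water, inverse specific
    gas constant of water vapor, and the mass-to-molar stomatal-resistance
    conversion.  ``D_e`` (vapor diffusivity in air) is stored for completeness
    but unused by the implemented equations.
    """

    e_sat: float = 3169.0        # saturated vapor pressure, Pa
    e_a: float = 1584.5          # ambient vapor pressure (RH 50% at 25 degC), Pa
    Ca: float = 0.0004           # ambient CO2 mole fraction, mol/mol
    cons1: float = 0.01801528    # molar mass of water, kg/mol
    cons2: float = 7.27e-6       # 1/(R_w*T), s^2/m^2
    cons3: float = 0.025         # mass->molar stomatal resistance conversion, m^3/mol
    mu: float = 8.90e-4          # dynamic viscosity of water, kg m^-1 s^-1
    rho_w: float = 1000.0        # density of water, kg/m^3
    D_m: float = 8.5e-10         # water diffusivity in mesophyll, m^2/s
    w0: float = 40.0             # saturated mesophyll water concentration, mol/m^3
    D_e: float = 24e-6           # vapor diffusivity in air, m^2/s (stored, unused)

    def invariant_errors(self) -> list[str]:
        errs = []
        for name in ("e_sat", "e_a", "Ca", "cons1", "cons2", "cons3",
                     "mu", "rho_w", "D_m", "w0", "D_e"):
            if not getattr(self, name) > 0:
                errs.append(f"env.{name} must be strictly positive")
        if not self.e_a < self.e_sat:
            errs.append("e_a < e_sat violated (ambient vapor pressure must be "
                        "below saturation)")
        return errs


@dataclass(frozen=True)
class LeafTraits:
    """Biochemical and architectural traits of the leaf.

    ``k_SP`` is the width-to-length ratio W/L; it sets the vein length ratio
    gamma = k_SP/2.  ``beta`` is the conduit radius ratio between consecutive
    vein orders; total conduit cross-section is conserved, so the conduit
    branching ratio is m = 1/beta^2.  ``Psi_C`` is the critical (cavitation /
    turgor-loss) xylem water potential and must be negative.
    """

    a1: float = 60e-6            # maximum carboxylation capacity, mol m^-2 s^-1
    a2: float = 510e-6           # biochemical constant Kc(1+Coa/Ko), mol/mol
    S: float = 0.6               # leaf-to-air CO2 concentration ratio
    R: float = 0.9e-6            # carbon cost per leaf volume, mol m^-3 s^-1
    k_SP: float = 0.28           # leaf shape parameter W/L
    Z: float = 300e-6            # leaf thickness, m
    k_Z: float = 1.0             # minor-vein-distance-to-thickness ratio (>=1)
    l_T: float = 150e-6          # terminal minor vein length, m
    r_T: float = 3e-6            # terminal conduit radius, m
    M_T: float = 1.0             # conduit count of one terminal minor vein
    beta: float = 0.30           # conduit radius ratio between orders
    Psi_C: float = -5e6          # critical xylem water potential, Pa

    def invariant_errors(self) -> list[str]:
        errs = []
        for name in ("a1", "a2", "S", "R", "Z", "l_T", "r_T"):
            if not getattr(self, name) > 0:
                errs.append(f"traits.{name} must be strictly positive")
        if not 0 < self.k_SP <= 2:
            errs.append("k_SP must satisfy 0 < k_SP <= 2")
        if not 0 < self.k_SP / 2 < 1:
            errs.append("gamma = k_SP/2 must lie in (0, 1)")
        if not 0 < self.beta < 1:
            errs.append("beta must satisfy 0 < beta < 1")
        if not self.k_Z >= 1:
            errs.append("k_Z must be >= 1")
        if not self.M_T >= 1:
            errs.append("M_T must be >= 1")
        if not self.Psi_C < 0:
            errs.append("Psi_C < 0 violated (critical potential is a suction)")
        return errs


@dataclass(frozen=True)
class ConstraintSetting:
    """Water-potential budget of the flow path.

    ``dPsi_Lmax`` is the maximum total xylem potential loss allowed from the
    petiole to the terminal minor vein.  When the petiole potential ``Psi_P``
    is given instead, the budget is Psi_P - Psi_C.
    """

    dPsi_Lmax: float = 3e3       # allowable potential loss, Pa (positive)
    Psi_P: float | None = None   # petiole xylem potential, Pa (optional)

    def invariant_errors(self, Psi_C: float | None = None) -> list[str]:
        errs = []
        if not self.dPsi_Lmax > 0:
            errs.append("dPsi_Lmax must be strictly positive")
        if self.Psi_P is not None and Psi_C is not None:
            implied = self.Psi_P - Psi_C
            if not math.isclose(self.dPsi_Lmax, implied, rel_tol=1e-12):
                errs.append(
                    "dPsi_Lmax inconsistent with Psi_P - Psi_C "
                    f"({self.dPsi_Lmax!r} != {implied!r})")
        return errs


@dataclass(frozen=True)
class ParameterSet:
    env: EnvironmentParams = field(default_factory=EnvironmentParams)
    traits: LeafTraits = field(default_factory=LeafTraits)
    constraint: ConstraintSetting = field(default_factory=ConstraintSetting)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict[str, dict[str, Any]]:
        return {
            "env": dataclasses.asdict(self.env),
            "traits": dataclasses.asdict(self.traits),
            "constraint": dataclasses.asdict(self.constraint),
        }

    def to_json(self, **kwargs: Any) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ParameterSet":
        return cls(
            env=EnvironmentParams(**d.get("env", {})),
            traits=LeafTraits(**d.get("traits", {})),
            constraint=ConstraintSetting(**d.get("constraint", {})),
        )

    def replace(self, **dotted: Any) -> "ParameterSet":
        """Return a copy with dotted or bare field overrides applied.

        Accepts ``traits.k_SP=0.35`` style keys (here spelled with ``__`` or
        passed via :meth:`replace_items`) as well as bare field names, which
        are resolved to their unique section.
        """
        return self.replace_items(dotted.items())

    def replace_items(self, items) -> "ParameterSet":
        d = self.to_dict()
        for key, value in items:
            section, field_name = _resolve_key(key)
            d[section][field_name] = value
        p = ParameterSet.from_dict(d)
        return validate(p)


_SECTIONS = {
    "env": EnvironmentParams,
    "traits": LeafTraits,
    "constraint": ConstraintSetting,
}

_FIELD_TO_SECTION: dict[str, str] = {}
for _sec, _cls in _SECTIONS.items():
    for _f in dataclasses.fields(_cls):
        _FIELD_TO_SECTION[_f.name] = _sec


def _resolve_key(key: str) -> tuple[str, str]:
    """Map ``section.field`` or a bare field name to (section, field)."""
    if "." in key:
        section, _, field_name = key.partition(".")
        if section not in _SECTIONS:
            raise ParameterError([f"unknown section {section!r} in key {key!r}"])
        names = {f.name for f in dataclasses.fields(_SECTIONS[section])}
        if field_name not in names:
            raise ParameterError([f"unknown parameter {key!r}"])
        return section, field_name
    if key not in _FIELD_TO_SECTION:
        raise ParameterError([f"unknown parameter {key!r}"])
    return _FIELD_TO_SECTION[key], key


def default_params() -> ParameterSet:
    """The model's default parameter record (all defaults built in)."""
    return ParameterSet()


def validate(p: ParameterSet) -> ParameterSet:
    """Return ``p`` unchanged if every invariant holds, else raise.

    All violations are aggregated into a single :class:`ParameterError`.
    """
    errs = (p.env.invariant_errors()
            + p.traits.invariant_errors()
            + p.constraint.invariant_errors(Psi_C=p.traits.Psi_C))
    if errs:
        raise ParameterError(errs)
    return p


def _coerce_items(data: dict[str, Any]) -> Iterator[tuple[str, float]]:
    for key, value in data.items():
        if value is None:
            continue
        if not isinstance(value, (int, float)):
            try:
                value = float(value)
            except (TypeError, ValueError):
                raise ParameterError(
                    [f"parameter {key!r} has non-numeric value {value!r}"])
        yield key, float(value)


def loads_params(text: str) -> ParameterSet:
    """Parse a flat YAML ``key: value`` config into a validated ParameterSet.

    Keys are bare field names (``k_SP: 0.35``) or dotted
    (``constraint.dPsi_Lmax: 4e3``).  Unknown keys are errors.  Fields absent
    from the file keep their defaults.
    """
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ParameterError(["config must be a flat key: value mapping"])
    base = default_params()
    if any(isinstance(v, dict) for v in data.values()):
        # Nested section form, as emitted by ParameterSet.to_dict().
        flat: dict[str, Any] = {}
        for sec, sub in data.items():
            if not isinstance(sub, dict):
                raise ParameterError(
                    [f"section {sec!r} must be a mapping in nested config"])
            for k, v in sub.items():
                flat[f"{sec}.{k}"] = v
        data = flat
    # Derive dPsi_Lmax from Psi_P when only the petiole potential is given.
    items = dict(_coerce_items(data))
    psi_p_key = next((k for k in items if k.split(".")[-1] == "Psi_P"), None)
    if psi_p_key is not None and not any(
            k.split(".")[-1] == "dPsi_Lmax" for k in items):
        psi_c = items.get("Psi_C", items.get("traits.Psi_C",
                                             base.traits.Psi_C))
        items["constraint.dPsi_Lmax"] = items[psi_p_key] - psi_c
    return base.replace_items(items.items())


def load_params(path: str | Path) -> ParameterSet:
    """Load a config file (see :func:`loads_params` for the dialect)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    return loads_params(path.read_text())
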