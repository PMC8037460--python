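"""Fluid and porous-medium property registry.

Presets cover the three chamber fillings compared in the model: aqueous
humor (AH), balanced salt solution (BSS) and the 1% sodium-hyaluronate
viscoelastic Healon.  Density and thermal expansivity are printed only for
AH; both BSS and Healon are near-water fluids and reuse them.  The printed
heat capacities (4.2 and 2.5 in J/kg/K) are read as kJ/kg/K — water-like
fluids have cp near 4200 J/kg/K, and the literal values would give
unphysical thermal diffusivities; the literal reading stays available via
``literal_cp=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace


class MaterialLookupError(KeyError):
    pass


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid constants (SI units)."""

    name: str
    mu: float      # dynamic viscosity [Pa s]
    rho: float     # density [kg m^-3]
    k: float       # thermal conductivity [W m^-1 K^-1]
    cp: float      # heat capacity [J kg^-1 K^-1]
    alpha: float   # thermal expansion [K^-1]

    def __post_init__(self):
        for f in ("mu", "rho", "k", "cp", "alpha"):
            if not getattr(self, f) > 0:
                raise ValueError(f"{f} must be strictly positive")

    @property
    def prandtl(self) -> float:
        return self.mu * self.cp / self.k

    @property
    def thermal_diffusivity(self) -> float:
        """k / (rho cp) [m^2 s^-1]."""
        return self.k / (self.rho * self.cp)


@dataclass(frozen=True)
class PorousProperties:
    """Brinkman porous-medium constants for the trabecular meshwork."""

    eps_p: float = 0.1       # porosity [-]
    kappa: float = 5e-15     # permeability [m^2]
    beta_f: float = 0.0      # Forchheimer coefficient (0: term vanishes)
    q_m: float = 0.0         # mass source [kg m^-3 s^-1]

    def __post_init__(self):
        if not 0 < self.eps_p <= 1:
            raise ValueError("eps_p must lie in (0, 1]")
        if not self.kappa > 0:
            raise ValueError("kappa must be strictly positive")


_WATER_RHO = 998.0
_WATER_ALPHA = 3e-4

_PRESETS: dict[str, FluidProperties] = {
    "AH": FluidProperties("AH", mu=7.5e-4, rho=_WATER_RHO, k=0.58,
                          cp=4200.0, alpha=_WATER_ALPHA),
    "BSS": FluidProperties("BSS", mu=1.02e-3, rho=_WATER_RHO, k=0.65,
                           cp=2500.0, alpha=_WATER_ALPHA),
    "Healon": FluidProperties("Healon", mu=200.0, rho=_WATER_RHO, k=0.47,
                              cp=2500.0, alpha=_WATER_ALPHA),
}

_LITERAL_CP = {"AH": 4.2, "BSS": 2.5, "Healon": 2.5}

_user_registry: dict[str, FluidProperties] = {}


def get_fluid(name: str, literal_cp: bool = False) -> FluidProperties:
    """Look up a fluid preset (AH, BSS, Healon) or a registered fluid.

    ``literal_cp=True`` returns the heat capacity exactly as printed
    (numerals in J/kg/K) instead of the kJ/kg/K interpretation.
    """
    if name in _user_registry:
        return _user_registry[name]
    if name not in _PRESETS:
        avail = sorted(set(_PRESETS) | set(_user_registry))
        raise MaterialLookupError(
            f"unknown fluid {name!r}; available: {avail}")
    props = _PRESETS[name]
    if literal_cp and name in _LITERAL_CP:
        props = replace(props, cp=_LITERAL_CP[name])
    return props


def register_fluid(props: FluidProperties) -> None:
    """Register (or overwrite) a user fluid under ``props.name``."""
    _user_registry[props.name] = props


def get_porous() -> PorousProperties:
    """Trabecular-meshwork constants (porosity 0.1, permeability 5e-15 m^2)."""
    return PorousProperties()
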