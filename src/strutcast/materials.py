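"""Material property models for melt-extrusion printing of polymer blends.

Temperature dependence of each component's melt viscosity follows the
Williams–Landel–Ferry (WLF) shift with the universal constants C1 = 8.86 and
C2 = 101.6 °C.  Blend viscosity is predicted with the Refutas
viscosity-blending-index method on weight fractions; densities follow the
rule of mixtures with thermal expansion; surface tension and substrate
contact angle are mixed linearly by weight fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

__all__ = [
    "Material",
    "Blend",
    "MaterialError",
    "WLFDomainError",
    "RefutasDomainError",
    "wlf_viscosity",
    "refutas_blend",
    "blend_viscosity",
    "density_at_T",
    "mixture_density",
    "mixture_surface_tension",
    "mixture_contact_angle",
]

# WLF universal constants (dimensionless / °C)
WLF_C1 = 8.86
WLF_C2 = 101.6

# Refutas blending-index constants (working viscosity in cSt or cP)
REFUTAS_A = 14.534
REFUTAS_B = 10.975
REFUTAS_C = 0.8

# ln(ln(v + 0.8)) needs v + 0.8 > 1, i.e. working-basis viscosity > 0.2
REFUTAS_DOMAIN_EDGE = 0.2

Basis = Literal["kinematic_cSt", "dynamic_cP"]


class MaterialError(ValueError):
    """Invalid material data or mixing-rule input."""


class WLFDomainError(MaterialError):
    """WLF denominator 101.6 + T - T_ref is not positive."""


class RefutasDomainError(MaterialError):
    """Working-basis viscosity at or below 0.2 (log-of-nonpositive)."""


@dataclass(frozen=True)
class Material:
    """One printable component and its reference-state properties.

    Parameters
    ----------
    density_ref : mass density in kg/m^3 at ``T_ref_density`` (°C).
    cte : linear coefficient of thermal expansion, 1/°C.
    eta_ref : dynamic viscosity in Pa·s at ``T_ref_visc`` (°C).
    surface_tension : N/m.
    contact_angle : equilibrium angle on the print substrate, degrees.
    """

    name: str
    density_ref: float
    T_ref_density: float
    cte: float
    eta_ref: float
    T_ref_visc: float
    surface_tension: float
    contact_angle: float

    def __post_init__(self) -> None:
        if self.density_ref <= 0:
            raise MaterialError(f"{self.name}: density must be positive")
        if self.eta_ref <= 0:
            raise MaterialError(f"{self.name}: reference viscosity must be positive")
        if not 0.0 < self.contact_angle < 180.0:
            raise MaterialError(f"{self.name}: contact angle must lie in (0, 180) deg")
        if self.surface_tension <= 0:
            raise MaterialError(f"{self.name}: surface tension must be positive")
        if self.cte < 0:
            raise MaterialError(f"{self.name}: CTE must be non-negative")


@dataclass(frozen=True)
class Blend:
    """Weight-fraction composition of one or more :class:`Material`."""

    components: tuple[tuple[Material, float], ...]

    def __post_init__(self) -> None:
        if not self.components:
            raise MaterialError("blend needs at least one component")
        fractions = [x for _, x in self.components]
        if any(x < 0 for x in fractions):
            raise MaterialError("weight fractions must be non-negative")
        if abs(sum(fractions) - 1.0) > 1e-9:
            raise MaterialError(f"weight fractions sum to {sum(fractions)}, not 1")

    @classmethod
    def of(cls, *pairs: tuple[Material, float]) -> "Blend":
        return cls(tuple(pairs))

    @property
    def materials(self) -> tuple[Material, ...]:
        return tuple(m for m, _ in self.components)

    @property
    def fractions(self) -> tuple[float, ...]:
        return tuple(x for _, x in self.components)


def wlf_viscosity(eta_ref: float, T_ref: float, T: float) -> float:
    """WLF-shifted viscosity: eta_ref * exp(-8.86 dT / (101.6 + dT)), dT = T - T_ref.

    Strictly decreasing in T for T > T_ref - 101.6 °C.
    """
    if eta_ref <= 0:
        raise MaterialError("eta_ref must be positive")
    dT = T - T_ref
    denom = WLF_C2 + dT
    if denom <= 0:
        raise WLFDomainError(
            f"WLF denominator 101.6 + (T - T_ref) = {denom:.3g} <= 0 at T = {T} degC"
        )
    return eta_ref * math.exp(-WLF_C1 * dT / denom)


def _blend_index(v: float) -> float:
    """Refutas per-component index A_i = 14.534 ln(ln(v + 0.8)) + 10.975."""
    inner = math.log(v + REFUTAS_C)
    return REFUTAS_A * math.log(inner) + REFUTAS_B


def _index_to_viscosity(A: float) -> float:
    """Inverse map v = exp(exp((A - 10.975)/14.534)) - 0.8."""
    return math.exp(math.exp((A - REFUTAS_B) / REFUTAS_A)) - REFUTAS_C


def refutas_blend(
    viscosities: Sequence[float],
    weight_fractions: Sequence[float],
    densities: Sequence[float],
    basis: Basis = "kinematic_cSt",
    floor: float | None = None,
    names: Sequence[str] | None = None,
) -> float:
    """Blend dynamic viscosities (Pa·s) with the Refutas index method.

    The correlation works on a *working basis*: kinematic viscosity in cSt
    (the standard form, default) or dynamic viscosity in cP.  Each component
    maps to an index ``A_i = 14.534 ln(ln(v_i + 0.8)) + 10.975``; indices mix
    linearly by weight fraction and the blend index maps back.  On the
    kinematic basis the blend kinematic viscosity is converted to dynamic
    with the specific-volume mixture density.

    Parameters
    ----------
    floor : working-basis viscosity floor (cSt or cP).  ``None`` (default)
        raises :class:`RefutasDomainError` when a component viscosity is at
        or below 0.2 on the working basis, where ln(ln(v+0.8)) is undefined.

    Returns
    -------
    Blend dynamic viscosity in Pa·s.
    """
    n = len(viscosities)
    if not (len(weight_fractions) == len(densities) == n) or n == 0:
        raise MaterialError("viscosities, fractions and densities must have equal length")
    if abs(sum(weight_fractions) - 1.0) > 1e-9:
        raise MaterialError("weight fractions must sum to 1")
    if any(eta <= 0 for eta in viscosities):
        raise MaterialError("all viscosities must be positive")
    if basis not in ("kinematic_cSt", "dynamic_cP"):
        raise MaterialError(f"unknown basis {basis!r}")
    names = list(names) if names is not None else [f"component {i}" for i in range(n)]

    working: list[float] = []
    for i, (eta, rho) in enumerate(zip(viscosities, densities)):
        if basis == "kinematic_cSt":
            v = eta / rho * 1e6  # m^2/s -> cSt
        else:
            v = eta * 1e3  # Pa·s -> cP
        if floor is not None:
            v = max(v, floor)
        if v <= REFUTAS_DOMAIN_EDGE:
            raise RefutasDomainError(
                f"{names[i]}: working-basis viscosity {v:.4g} <= 0.2 "
                f"({basis}); ln(ln(v+0.8)) undefined"
            )
        working.append(v)

    A = sum(x * _blend_index(v) for v, x in zip(working, weight_fractions))
    v_blend = _index_to_viscosity(A)

    if basis == "kinematic_cSt":
        rho_blend = 1.0 / sum(x / rho for x, rho in zip(weight_fractions, densities))
        return v_blend * 1e-6 * rho_blend
    return v_blend * 1e-3


def density_at_T(
    material: Material,
    T: float,
    expansion_mode: Literal["volumetric_from_linear", "linear_as_volumetric"] = "volumetric_from_linear",
) -> float:
    """Density at temperature T from thermal expansion: rho_ref / (1 + k dT).

    ``volumetric_from_linear`` (default) treats the tabulated CTE as linear
    and uses k = 3*cte for volume; ``linear_as_volumetric`` uses k = cte.
    """
    k = 3.0 * material.cte if expansion_mode == "volumetric_from_linear" else material.cte
    denom = 1.0 + k * (T - material.T_ref_density)
    if denom <= 0:
        raise MaterialError(
            f"{material.name}: expansion denominator {denom:.3g} <= 0 at T = {T} degC"
        )
    return material.density_ref / denom


def mixture_density(
    blend: Blend,
    T: float,
    mode: Literal["specific_volume", "linear"] = "specific_volume",
    expansion_mode: Literal["volumetric_from_linear", "linear_as_volumetric"] = "volumetric_from_linear",
) -> float:
    """Rule-of-mixtures blend density at temperature T (kg/m^3).

    Default mixes specific volumes (1/rho = sum x_i/rho_i), the rigorous rule
    for mass fractions; ``linear`` mixes densities directly.
    """
    rhos = [density_at_T(m, T, expansion_mode) for m in blend.materials]
    xs = blend.fractions
    if mode == "specific_volume":
        return 1.0 / sum(x / rho for x, rho in zip(xs, rhos))
    if mode == "linear":
        return sum(x * rho for x, rho in zip(xs, rhos))
    raise MaterialError(f"unknown density mixing mode {mode!r}")


def mixture_surface_tension(blend: Blend) -> float:
    """Weight-fraction linear mixture surface tension, N/m."""
    return sum(x * m.surface_tension for m, x in blend.components)


def mixture_contact_angle(blend: Blend) -> float:
    """Weight-fraction linear mixture substrate contact angle, degrees.

    A pragmatic interpolation between the components' measured angles; a
    measured per-blend angle should be preferred when available.
    """
    return sum(x * m.contact_angle for m, x in blend.components)


def blend_viscosity(
    blend: Blend,
    T: float,
    basis: Basis = "kinematic_cSt",
    floor: float | None = 1.0,
    validity_window: tuple[float, float] = (100.0, 160.0),
) -> float:
    """Blend dynamic viscosity at temperature T (Pa·s).

    Each component is WLF-shifted from its own (eta_ref, T_ref_visc) to T,
    then the shifted viscosities are Refutas-blended by weight fraction.  A
    pure single-component blend reduces exactly to :func:`wlf_viscosity`.

    ``floor`` (working-basis units) defaults to 1.0 here: very thin diluents
    fall below the Refutas ln·ln domain once WLF-shifted to high T, and the
    floor caps their thinning power instead of failing the whole blend.  Pass
    ``floor=None`` for the strict behaviour of :func:`refutas_blend`.
    """
    lo, hi = validity_window
    if not lo <= T <= hi:
        raise MaterialError(
            f"T = {T} degC outside the configured validity window [{lo}, {hi}]"
        )
    etas = [wlf_viscosity(m.eta_ref, m.T_ref_visc, T) for m in blend.materials]
    if len(etas) == 1:
        return etas[0]
    rhos = [density_at_T(m, T) for m in blend.materials]
    return refutas_blend(
        etas,
        blend.fractions,
        rhos,
        basis=basis,
        floor=floor,
        names=[m.name for m in blend.materials],
    )
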