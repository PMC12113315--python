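"""Pressure-driven laminar melt flow through a barrel-and-nozzle channel.

The channel is a sequence of coaxial cylinder and cone segments.  Flow is
treated as fully developed generalized Poiseuille flow in each segment
(lubrication approximation in the tapers), and the volumetric rate Q is the
root of  sum_k dP_k(Q) = P_gauge,  which is unique because every segment's
pressure drop is strictly increasing in Q.  The quantity consumed downstream
is the mean outlet velocity Q / (pi R_out^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

from scipy import integrate, optimize

from .materials import Blend, blend_viscosity

__all__ = [
    "Segment",
    "NozzleGeometry",
    "Rheology",
    "FlowSolution",
    "ExtrusionError",
    "segment_pressure_drop",
    "solve_flow",
    "rheology_from_blend",
    "wall_shear_rate",
    "default_geometry",
]


class ExtrusionError(ValueError):
    """Invalid geometry/rheology or flow-solver failure."""


@dataclass(frozen=True)
class Segment:
    """One axisymmetric channel segment. Radii and length in metres."""

    kind: Literal["cylinder", "cone"]
    r_in: float
    r_out: float
    length: float

    def __post_init__(self) -> None:
        if self.r_in <= 0 or self.r_out <= 0 or self.length <= 0:
            raise ExtrusionError("segment radii and length must be positive")
        if self.kind == "cylinder" and not math.isclose(self.r_in, self.r_out, rel_tol=1e-12):
            raise ExtrusionError("cylinder segment must have r_in == r_out")
        if self.kind not in ("cylinder", "cone"):
            raise ExtrusionError(f"unknown segment kind {self.kind!r}")


@dataclass(frozen=True)
class NozzleGeometry:
    """Ordered segments from barrel inlet to nozzle outlet."""

    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ExtrusionError("geometry needs at least one segment")
        for a, b in zip(self.segments, self.segments[1:]):
            if not math.isclose(a.r_out, b.r_in, rel_tol=1e-9):
                raise ExtrusionError(
                    f"segment radii mismatch: {a.r_out} m -> {b.r_in} m"
                )

    @property
    def outlet_radius(self) -> float:
        return self.segments[-1].r_out


@dataclass(frozen=True)
class Rheology:
    """Shear rheology: newtonian (eta) or power-law (m, n).

    power-law apparent viscosity is m * shear_rate**(n-1); n = 1 with m = eta
    reduces exactly to the newtonian model.
    """

    model: Literal["newtonian", "power_law"]
    eta: float | None = None
    m: float | None = None
    n: float | None = None

    def __post_init__(self) -> None:
        if self.model == "newtonian":
            if self.eta is None or self.eta <= 0:
                raise ExtrusionError("newtonian rheology needs eta > 0")
        elif self.model == "power_law":
            if self.m is None or self.m <= 0 or self.n is None or not 0 < self.n <= 1:
                raise ExtrusionError("power-law rheology needs m > 0 and 0 < n <= 1")
        else:
            raise ExtrusionError(f"unknown rheology model {self.model!r}")

    @classmethod
    def newtonian(cls, eta: float) -> "Rheology":
        return cls("newtonian", eta=eta)

    @classmethod
    def power_law(cls, m: float, n: float) -> "Rheology":
        return cls("power_law", m=m, n=n)


@dataclass(frozen=True)
class FlowSolution:
    """Solved channel flow."""

    Q: float  # volumetric rate, m^3/s
    v_mean_outlet: float  # m/s
    segment_dp: tuple[float, ...]  # Pa, one per segment
    wall_shear_rate_outlet: float  # 1/s


def _dpdz_cylinder(Q: float, r: float, rheology: Rheology) -> float:
    """Local fully developed pressure gradient (Pa/m) at radius r."""
    if rheology.model == "newtonian":
        return 8.0 * rheology.eta * Q / (math.pi * r**4)
    m, n = rheology.m, rheology.n
    return (2.0 * m / r) * ((3.0 * n + 1.0) / n * Q / (math.pi * r**3)) ** n


def segment_pressure_drop(Q: float, segment: Segment, rheology: Rheology) -> float:
    """Pressure drop (Pa) across one segment at volumetric rate Q.

    Cylinders use the closed-form Hagen–Poiseuille / power-law laws; cones
    integrate the local-radius cylinder law along the taper (lubrication
    approximation).  Strictly increasing in Q; zero at Q = 0.
    """
    if Q < 0:
        raise ExtrusionError("Q must be non-negative")
    if Q == 0.0:
        return 0.0
    if segment.kind == "cylinder":
        return _dpdz_cylinder(Q, segment.r_in, rheology) * segment.length
    r_in, r_out, L = segment.r_in, segment.r_out, segment.length

    def dpdz(z: float) -> float:
        r = r_in + (r_out - r_in) * z / L
        return _dpdz_cylinder(Q, r, rheology)

    dp, _ = integrate.quad(dpdz, 0.0, L, epsrel=1e-11, limit=200)
    return dp


def wall_shear_rate(Q: float, R: float, n: float = 1.0) -> float:
    """Rabinowitsch–Mooney wall shear rate ((3n+1)/(4n)) * 4Q/(pi R^3), 1/s."""
    if R <= 0 or n <= 0:
        raise ExtrusionError("R and n must be positive")
    if Q < 0:
        raise ExtrusionError("Q must be non-negative")
    return (3.0 * n + 1.0) / (4.0 * n) * 4.0 * Q / (math.pi * R**3)


def solve_flow(
    geometry: NozzleGeometry,
    rheology: Rheology,
    P_gauge: float,
    rtol: float = 1e-10,
    max_expand: int = 200,
) -> FlowSolution:
    """Find the volumetric rate Q with total channel pressure drop = P_gauge.

    The total drop is strictly increasing in Q, so the root is bracketed by
    doubling from an outlet-capillary Poiseuille estimate and refined with
    Brent's method.
    """
    if P_gauge < 0:
        raise ExtrusionError("P_gauge must be non-negative")
    R_out = geometry.outlet_radius
    if P_gauge == 0.0:
        return FlowSolution(0.0, 0.0, tuple(0.0 for _ in geometry.segments), 0.0)

    def total_dp(Q: float) -> float:
        return sum(segment_pressure_drop(Q, s, rheology) for s in geometry.segments)

    # initial scale from the outlet segment alone (an under-resistance, so an
    # over-estimate of Q; still only a starting point for bracketing)
    last = geometry.segments[-1]
    if rheology.model == "newtonian":
        Q_hi = P_gauge * math.pi * last.r_out**4 / (8.0 * rheology.eta * last.length)
    else:
        m, n = rheology.m, rheology.n
        Q_hi = (
            math.pi
            * last.r_out**3
            * n
            / (3.0 * n + 1.0)
            * (P_gauge * last.r_out / (2.0 * m * last.length)) ** (1.0 / n)
        )
    Q_hi = max(Q_hi, 1e-30)
    for _ in range(max_expand):
        if total_dp(Q_hi) >= P_gauge:
            break
        Q_hi *= 2.0
    else:
        raise ExtrusionError(
            f"could not bracket Q: dp({Q_hi:.3g}) = {total_dp(Q_hi):.3g} < {P_gauge:.3g} Pa"
        )

    Q = optimize.brentq(
        lambda q: total_dp(q) - P_gauge, 0.0, Q_hi, rtol=max(rtol, 4e-16), xtol=1e-300
    )
    seg_dp = tuple(segment_pressure_drop(Q, s, rheology) for s in geometry.segments)
    n_eff = 1.0 if rheology.model == "newtonian" else rheology.n
    return FlowSolution(
        Q=Q,
        v_mean_outlet=Q / (math.pi * R_out**2),
        segment_dp=seg_dp,
        wall_shear_rate_outlet=wall_shear_rate(Q, R_out, n_eff),
    )


def rheology_from_blend(
    blend: Blend,
    T: float,
    mode: Literal["newtonian", "power_law"] = "newtonian",
    n: float = 0.7,
    reference_shear_rate: float = 100.0,
    **visc_kwargs,
) -> Rheology:
    """Build a Rheology from the blend's temperature-shifted viscosity.

    newtonian: eta = blend_viscosity(blend, T).  power_law: consistency m is
    anchored so the apparent viscosity at ``reference_shear_rate`` equals the
    blend viscosity, m = eta * gdot_ref**(1 - n).
    """
    eta = blend_viscosity(blend, T, **visc_kwargs)
    if mode == "newtonian":
        return Rheology.newtonian(eta)
    if mode == "power_law":
        return Rheology.power_law(eta * reference_shear_rate ** (1.0 - n), n)
    raise ExtrusionError(f"unknown rheology mode {mode!r}")


def default_geometry() -> NozzleGeometry:
    """Barrel (R 4 mm x 60 mm) -> conical taper (15 mm) -> capillary (R 225 um x 5 mm).

    A documented stand-in for a pneumatic syringe barrel feeding a 450 um
    inner-diameter nozzle; all dimensions are configurable.
    """
    return NozzleGeometry(
        (
            Segment("cylinder", 4.0e-3, 4.0e-3, 60.0e-3),
            Segment("cone", 4.0e-3, 225.0e-6, 15.0e-3),
            Segment("cylinder", 225.0e-6, 225.0e-6, 5.0e-3),
        )
    )
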