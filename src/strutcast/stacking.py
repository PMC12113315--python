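"""Equilibrium cross-section of a deposited strut on a flat substrate.

A freshly extruded strut relaxes to a static shape set by the balance of
surface tension against the hydrostatic pressure inside the melt
(Young–Laplace with P(y) = P0 - rho*g*y).  The section is symmetric about
the vertical mid-plane (horizontal tangent at the apex) and meets the
substrate at the equilibrium contact angle theta2; its area is fixed by mass
conservation between the nozzle and the deposited line.

Two routes compute the same profile:

* :func:`solve_profile` — the normative solver.  The interface is
  parametrized by the tangent angle psi; curvature grows linearly with depth,
  kappa(y) = c0 + (rho*g/gamma)*(h - y), and the two free scalars (apex
  curvature c0, height h) are shot so the substrate is met at theta2 with the
  prescribed enclosed area.
* :func:`profile_elliptic` — a closed form for a given height h.  The first
  integral of the balance, cos(psi) = 1 - c0*u - (rho*g/2gamma)*u^2 with
  u the depth below the apex, reduces x(psi) to a combination of incomplete
  elliptic integrals of the first and second kind.  Used as an independent
  cross-check of the ODE solution.

The flattening strength is the dimensionless gravity number
H = rho*g*h^2 / (2*gamma); sub-millimetre polymer struts have H ~ 1e-2, so
their sections are nearly circular arcs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import ellipeinc, ellipkinc

__all__ = [
    "StackingInput",
    "StrutProfile",
    "StackingError",
    "EllipticDomainError",
    "strut_area_from_flow",
    "compute_H",
    "solve_profile",
    "profile_elliptic",
    "strut_metrics",
    "circular_segment",
]


class StackingError(ValueError):
    """Invalid stacking input or profile-solver failure."""


class EllipticDomainError(StackingError):
    """Closed-form profile undefined (apex curvature not positive)."""


@dataclass(frozen=True)
class StackingInput:
    """Inputs of the cross-section equilibrium.

    A_target : strut cross-sectional area, m^2
    rho      : melt density, kg/m^3
    gamma    : surface tension, N/m
    theta2   : substrate contact angle, degrees
    g        : gravitational acceleration, m/s^2
    """

    A_target: float
    rho: float
    gamma: float
    theta2: float
    g: float = 9.81

    def __post_init__(self) -> None:
        if self.A_target <= 0:
            raise StackingError("A_target must be positive")
        if not 0.0 < self.theta2 < 180.0:
            raise StackingError("theta2 must lie in (0, 180) degrees")
        if self.gamma <= 0:
            raise StackingError("gamma must be positive")
        if self.rho <= 0:
            raise StackingError("rho must be positive")
        if self.g < 0:
            raise StackingError("g must be non-negative")


@dataclass(frozen=True, eq=False)
class StrutProfile:
    """Solved cross-section.  Coordinates in metres, substrate at y = 0.

    psi_grid runs from -theta2 (left contact) through 0 (apex) to +theta2
    (right contact); x and y trace the full mirrored interface, alpha = x/h
    and beta = y/h are the dimensionless coordinates.
    """

    psi_grid: np.ndarray
    x: np.ndarray
    y: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    h: float
    contact_width: float
    diameter: float
    H: float
    area: float
    apex_curvature: float


def strut_area_from_flow(v_extrusion: float, nozzle_radius: float, stage_speed: float) -> float:
    """Deposited cross-section area from volume conservation, m^2.

    A = v_extrusion * pi * R^2 / stage_speed: melt leaving the nozzle at
    v_extrusion is drawn into a line at the stage speed.
    """
    if stage_speed <= 0:
        raise StackingError("stage_speed must be positive")
    if v_extrusion <= 0 or nozzle_radius <= 0:
        raise StackingError("v_extrusion and nozzle_radius must be positive")
    return v_extrusion * math.pi * nozzle_radius**2 / stage_speed


def compute_H(rho: float, g: float, h: float, gamma: float) -> float:
    """Dimensionless gravity number H = rho*g*h^2 / (2*gamma)."""
    if gamma <= 0:
        raise StackingError("gamma must be positive")
    return rho * g * h**2 / (2.0 * gamma)


def circular_segment(A: float, theta2_deg: float) -> tuple[float, float, float, float]:
    """Zero-gravity closed form: (R, h, contact_width, diameter).

    With g = 0 the Young–Laplace section is a circular arc of radius R
    subtending the contact angle: A = R^2 (theta - sin(theta)cos(theta)),
    h = R (1 - cos(theta)), contact width 2 R sin(theta); the maximum width is
    the chord for theta <= 90 deg and the full diameter 2R beyond.
    """
    theta = math.radians(theta2_deg)
    R = math.sqrt(A / (theta - math.sin(theta) * math.cos(theta)))
    h = R * (1.0 - math.cos(theta))
    w = 2.0 * R * math.sin(theta)
    d = w if theta <= math.pi / 2 else 2.0 * R
    return R, h, w, d


def _integrate_half(
    c0: float, h: float, B: float, theta: float, n_steps: int, trajectory: bool = False
):
    """RK4 integration of the tangent-angle ODE over psi in [0, theta].

    States (x, y, a): dx/dpsi = cos/k, dy/dpsi = -sin/k, da/dpsi = x sin/k
    with k = c0 + B (h - y).  All quantities dimensionless (lengths scaled by
    sqrt(A_target)).  Returns endpoint (x, y, a) or full arrays.
    """
    dpsi = theta / n_steps
    x = 0.0
    y = h
    a = 0.0
    if trajectory:
        xs = np.empty(n_steps + 1)
        ys = np.empty(n_steps + 1)
        xs[0], ys[0] = x, y
    cos = math.cos
    sin = math.sin
    psi = 0.0
    for i in range(n_steps):
        # RK4 stage derivatives
        def f(p: float, xx: float, yy: float):
            k = c0 + B * (h - yy)
            s = sin(p)
            inv = 1.0 / k
            return cos(p) * inv, -s * inv, xx * s * inv

        k1 = f(psi, x, y)
        k2 = f(psi + 0.5 * dpsi, x + 0.5 * dpsi * k1[0], y + 0.5 * dpsi * k1[1])
        k3 = f(psi + 0.5 * dpsi, x + 0.5 * dpsi * k2[0], y + 0.5 * dpsi * k2[1])
        k4 = f(psi + dpsi, x + dpsi * k3[0], y + dpsi * k3[1])
        x += dpsi / 6.0 * (k1[0] + 2.0 * k2[0] + 2.0 * k3[0] + k4[0])
        y += dpsi / 6.0 * (k1[1] + 2.0 * k2[1] + 2.0 * k3[1] + k4[1])
        a += dpsi / 6.0 * (k1[2] + 2.0 * k2[2] + 2.0 * k3[2] + k4[2])
        psi += dpsi
        if trajectory:
            xs[i + 1], ys[i + 1] = x, y
    if trajectory:
        return xs, ys, a
    return x, y, a


def _seed(theta: float, B: float, n_steps: int) -> tuple[float, float]:
    """Initial (c0_hat, h_hat) for the shooting, dimensionless.

    g = 0 uses the exact circular arc.  Otherwise a 1-D bisection over h in
    (0, h_max) — with the apex curvature slaved to h through the first
    integral cos(theta2) = 1 - c0 h - B h^2/2 — locates area = 1; the
    enclosed area grows monotonically from 0 (h -> 0) to infinity (the puddle
    limit h -> h_max where c0 -> 0).
    """
    seg = theta - math.sin(theta) * math.cos(theta)
    R_arc = 1.0 / math.sqrt(seg)
    if B == 0.0:
        return 1.0 / R_arc, R_arc * (1.0 - math.cos(theta))

    d = 1.0 - math.cos(theta)
    h_max = math.sqrt(2.0 * d / B)

    def c0_of(h: float) -> float:
        return (d - 0.5 * B * h * h) / h

    def area_err(h: float) -> float:
        _, _, a = _integrate_half(c0_of(h), h, B, theta, n_steps)
        return 2.0 * a - 1.0

    lo, hi = 1e-8 * h_max, (1.0 - 1e-12) * h_max
    if area_err(hi) < 0.0:  # cannot happen analytically; numeric safety
        return c0_of(hi), hi
    h0 = optimize.brentq(area_err, lo, hi, rtol=1e-12)
    return c0_of(h0), h0


def solve_profile(
    inp: StackingInput,
    n_psi: int = 2001,
    residual_tol: float = 1e-8,
) -> StrutProfile:
    """Solve the equilibrium cross-section by tangent-angle shooting.

    The interface is integrated in the tangent angle psi from the apex
    (horizontal tangent on the symmetry axis) to the substrate (psi =
    theta2).  The apex curvature c0 and the height h are solved jointly (in
    log-space, Powell hybrid) so that the substrate is reached exactly at
    psi = theta2 (y = 0) and the enclosed area equals ``inp.A_target``.

    n_psi sets the output grid over [-theta2, theta2]; the integration uses
    (n_psi - 1) / 2 RK4 steps for the half profile.
    """
    theta = math.radians(inp.theta2)
    L0 = math.sqrt(inp.A_target)
    B = inp.rho * inp.g * L0 * L0 / inp.gamma  # Bond-like number on the area scale
    n_half = max((n_psi - 1) // 2, 50)

    c0_seed, h_seed = _seed(theta, B, n_half)

    def residuals(z: np.ndarray) -> np.ndarray:
        c0 = math.exp(z[0])
        h = math.exp(z[1])
        x_e, y_e, a = _integrate_half(c0, h, B, theta, n_half)
        return np.array([y_e / h_seed, 2.0 * a - 1.0])

    sol = optimize.root(
        residuals, np.array([math.log(c0_seed), math.log(h_seed)]), method="hybr", tol=1e-14
    )
    res = residuals(sol.x)
    if not sol.success and np.max(np.abs(res)) > residual_tol:
        raise StackingError(
            f"profile shooting did not converge: residuals {res}, message: {sol.message}"
        )
    if np.max(np.abs(res)) > residual_tol:
        raise StackingError(f"profile residuals {res} above tolerance {residual_tol}")

    c0_hat = math.exp(sol.x[0])
    h_hat = math.exp(sol.x[1])
    xs, ys, a_half = _integrate_half(c0_hat, h_hat, B, theta, n_half, trajectory=True)
    return _assemble_profile(inp, theta, L0, c0_hat / L0, h_hat * L0, xs * L0, ys * L0,
                             2.0 * a_half * L0 * L0, n_half)


def _assemble_profile(
    inp: StackingInput,
    theta: float,
    L0: float,
    c0: float,
    h: float,
    xs_half: np.ndarray,
    ys_half: np.ndarray,
    area: float,
    n_half: int,
) -> StrutProfile:
    """Mirror a half profile (apex -> right contact) into a full StrutProfile."""
    ys_half = np.maximum(ys_half, 0.0)  # substrate residual is O(tol)
    phi = np.linspace(0.0, theta, n_half + 1)
    psi = np.concatenate([-phi[::-1], phi[1:]])
    x = np.concatenate([-xs_half[::-1], xs_half[1:]])
    y = np.concatenate([ys_half[::-1], ys_half[1:]])
    contact_width = 2.0 * float(xs_half[-1])
    diameter = 2.0 * float(np.max(xs_half))
    return StrutProfile(
        psi_grid=psi,
        x=x,
        y=y,
        alpha=x / h,
        beta=y / h,
        h=h,
        contact_width=contact_width,
        diameter=diameter,
        H=compute_H(inp.rho, inp.g, h, inp.gamma),
        area=area,
        apex_curvature=c0,
    )


def profile_elliptic(inp: StackingInput, h: float, n_psi: int = 2001) -> StrutProfile:
    """Closed-form cross-section for a prescribed height h.

    From the first integral of the hydrostatic Young–Laplace balance,
    cos(psi) = 1 - c0*u - (b/2)*u^2 with u = h - y and b = rho*g/gamma, the
    apex curvature is pinned by the contact condition,
    c0 = (1 - cos(theta2) - H) / h with H = b*h^2/2, and the horizontal
    coordinate reduces to incomplete elliptic integrals F and E:

        x(psi) = (2/k_max) * [ (2/m)(S - E_part) - S ],
        S      = F(pi/2 | m) - F(pi/2 - psi/2 | m),
        E_part = E(pi/2 | m) - E(pi/2 - psi/2 | m),
        m      = 4b / (c0^2 + 4b),   k_max = sqrt(c0^2 + 4b).

    Defined only while the apex curvature stays positive (h below the puddle
    limit sqrt(2*gamma*(1 - cos theta2)/(rho g))); otherwise
    :class:`EllipticDomainError` is raised.
    """
    if h <= 0:
        raise StackingError("h must be positive")
    theta = math.radians(inp.theta2)
    b = inp.rho * inp.g / inp.gamma
    H = 0.5 * b * h * h
    d = 1.0 - math.cos(theta)
    c0 = (d - H) / h
    if c0 <= 0.0:
        raise EllipticDomainError(
            f"apex curvature {c0:.3g} <= 0: h = {h:.3g} m exceeds the puddle height "
            f"{math.sqrt(2.0 * d / b) if b > 0 else math.inf:.3g} m"
        )
    n_half = max((n_psi - 1) // 2, 50)
    phi = np.linspace(0.0, theta, n_half + 1)

    m = 4.0 * b / (c0 * c0 + 4.0 * b)
    if m < 1e-9:
        # gravity-free limit: circular arc of curvature c0
        xs = np.sin(phi) / c0
        ys = h - (1.0 - np.cos(phi)) / c0
    else:
        k_max = math.sqrt(c0 * c0 + 4.0 * b)
        t = 0.5 * phi
        S = ellipkinc(0.5 * math.pi, m) - ellipkinc(0.5 * math.pi - t, m)
        E_part = ellipeinc(0.5 * math.pi, m) - ellipeinc(0.5 * math.pi - t, m)
        xs = (2.0 / k_max) * ((2.0 / m) * (S - E_part) - S)
        kappa = np.sqrt(c0 * c0 + 4.0 * b * np.sin(t) ** 2)
        ys = h - (kappa - c0) / b

    area = -2.0 * float(np.trapezoid(xs, ys))  # y runs h -> 0 along the half profile
    L0 = math.sqrt(inp.A_target)
    return _assemble_profile(inp, theta, L0, c0, h, xs, ys, area, n_half)


def strut_metrics(profile: StrutProfile) -> dict[str, float]:
    """Height, substrate contact width, and maximum width (strut diameter), m.

    Computed from the profile coordinates, so they are invariant under
    mirroring x -> -x.
    """
    height = float(np.max(profile.y))
    diameter = float(np.max(profile.x) - np.min(profile.x))
    contact_width = float(abs(profile.x[-1] - profile.x[0]))
    return {"height": height, "contact_width": contact_width, "diameter": diameter}
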