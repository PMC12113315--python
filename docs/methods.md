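# Methods

This note records the model assumptions, parameter choices, and numerical
decisions behind strutcast, and what the shipped fixtures do and do not
represent.

## Viscosity model

Component melt viscosities are WLF-shifted from a single reference
temperature, `η(T) = η_r exp(−8.86 ΔT / (101.6 + ΔT))` with the universal
constants fixed (they are not fitted). The operation takes the reference
temperature explicitly; the shipped table references both PCL and DMSO₂ at
120 °C. The shift is singular at ΔT = −101.6 °C and the implementation
raises below it; `blend_viscosity` additionally enforces a configurable
validity window (default 100–160 °C) because WLF extrapolation far from the
reference is not trustworthy.

Blending uses the Refutas index, defined on kinematic viscosity in cSt; a
`basis` switch also accepts dynamic cP, since published blend tables for this
system appear to have been computed on dynamic viscosities. Two facts matter
in practice:

* **Domain.** The index `14.534 ln(ln(v + 0.8)) + 10.975` requires v > 0.2
  on the working basis. DMSO₂'s melt viscosity (0.00114 Pa·s ≈ 0.8 cSt at
  120 °C) drops below that once WLF-shifted above ≈ 127 °C. `refutas_blend`
  raises a domain error naming the component; `blend_viscosity` instead
  applies a documented working-basis floor (default 1.0 cSt/cP) so that
  temperature sweeps over the full printing window remain defined. The floor
  caps the diluent's thinning power; pass `floor=None` for strict behaviour.
* **Sensitivity.** With a six-decade viscosity contrast between PCL and
  DMSO₂, the double-log index is extremely steep: 10 wt% DMSO₂ drops the
  predicted blend viscosity from 2211 Pa·s to ≈ 42 Pa·s at 120 °C. Published
  measurements for comparable blends fall much less steeply (and are in fact
  mutually inconsistent with the pure-component table shipped here — the
  packaged `viscosity_table2.csv` is reference data only and is never used as
  a computed target). Treat multi-component absolute viscosities as
  order-of-magnitude; the monotone composition ordering is robust.

Densities use the rule of mixtures on specific volume (the rigorous rule for
mass fractions; a `linear` mode exists), with each component expanded from
its reference density. Tabulated CTEs are treated as *linear* coefficients
and tripled for volumetric expansion by default (`expansion_mode` switches
this off). Surface tension and substrate contact angle mix linearly by
weight fraction — a pragmatic interpolation, not a thermodynamic law; a
measured per-blend contact angle should be supplied when available
(`theta2` argument / `theta2_deg` config key).

## Extrusion model

The commercial-CFD stage this replaces only feeds one number downstream: the
mean outlet velocity. The channel is therefore modelled as a series of
axisymmetric segments in fully developed laminar flow. Cylinders use
Hagen–Poiseuille (`ΔP = 8ηLQ/πR⁴`) or its power-law generalization
(`ΔP = (2mL/R)((3n+1)/n · Q/πR³)ⁿ`); cones integrate the local-radius law
along the taper (lubrication approximation) with adaptive quadrature. The
flow solver brackets and Brent-solves the strictly monotone total-drop
equation to 10⁻¹⁰ relative. Entrance/exit losses, die swell, melt
compressibility, recirculation, and in-nozzle temperature gradients are
neglected.

Default geometry: barrel R 4 mm × 60 mm, conical taper 15 mm down to the
capillary R 225 µm × 5 mm (a 450 µm inner-diameter nozzle). This is a
documented stand-in for an unpublished printer geometry — over 94 % of the
resistance sits in the capillary, so predictions are dominated by the
(known) nozzle dimensions. The default rheology is newtonian at the
WLF/Refutas shear viscosity; a power-law mode (default n = 0.7, consistency
anchored so the apparent viscosity at a reference shear rate of 100 s⁻¹
matches the blend viscosity) exists for sensitivity studies, since no
measured flow index is available for these blends.

## Stacking model

The strut cross-section is the translationally invariant sessile shape: the
in-plane curvature satisfies `γκ(y) = P₀ − P_a − ρg y`, i.e. κ varies
linearly with height. The profile is integrated in tangent-angle
parametrization from the apex (horizontal tangent on the symmetry axis — the
90° mid-plane condition) to the substrate. Two scalars are free, the apex
curvature c₀ and the height h; they are solved (Powell hybrid in log-space,
guaranteeing positivity) so the tangent meets the substrate at exactly θ₂
and the enclosed area equals the conserved target. Residual tolerance 10⁻⁸
relative; integration is fixed-step classical RK4 with (n_psi − 1)/2 steps
for the half profile (default n_psi = 2001, i.e. 1000 steps; the
printability sweep uses 201 for speed — RK4 discretization error is ≈ 10⁻⁸
relative even there).

The solver is seeded from the zero-gravity circular arc and, when gravity
matters, refined by a 1-D bisection over h with c₀ slaved to h through the
first integral `cos θ₂ = 1 − c₀h − H` — this makes very flat, high-Bond
"puddle" sections (thin blends at high pressure deposit cm-scale areas)
converge reliably. Within the model, a solution exists for every area: h is
bounded by the puddle height `√(2γ(1 − cos θ₂)/ρg)` while the width grows
without bound.

The closed-form cross-check evaluates the same first integral analytically.
With b = ρg/γ and depth u = h − y, `cos ψ = 1 − c₀u − (b/2)u²`, so
κ(ψ) = √(c₀² + 4b sin²(ψ/2)) and

    x(ψ) = (2/κ_max) [ (2/m)(S − E_part) − S ],  m = 4b/(c₀² + 4b),

with S and E_part differences of incomplete elliptic integrals of the first
and second kind (scipy `ellipkinc`/`ellipeinc`). Below m = 10⁻⁹ the
circular-arc limit is used to avoid cancellation. The two routes agree to
machine precision on sub-millimetre struts and to < 1 % everywhere tested;
the ODE solver is normative, the elliptic form is the validated
reconstruction (the available printed form of this closed solution is
typographically corrupted, so it was re-derived from the balance equations).

Conventions: curvature is positive for a section convex toward the air; the
reported **diameter** is the maximum horizontal extent (equal to the contact
width for θ₂ ≤ 90°, larger beyond); contact-line pinning and dynamic contact
angles are not modelled (θ₂ is the equilibrium Young angle); layer height is
accepted in the run config for forward compatibility but plays no role in
single-strut equilibrium. Multi-layer stacking, strut fusion, and
solidification during spreading are out of scope.

## Printability

The sweep chains viscosity → flow → conservation → cross-section on each
(T, P) cell. Defaults mirror the studied process window: T ∈ {120…140} °C in
5 °C steps, P ∈ 150–600 kPa in 25 kPa steps, stage speed 0.8 mm/s, strut
pitch 700 µm, minimum straight-line velocity 0.21 mm/s. Both criteria are
closed (v ≥ v_min passes; diameter ≤ pitch passes). Because velocity and
diameter both increase monotonically with pressure, the printable set along
any fixed-temperature row is one contiguous pressure interval — entered
through the velocity line and left through the pitch line. Per-cell solver
failures (e.g. a temperature outside the viscosity validity window) are
recorded as unprintable `failed` cells rather than aborting the sweep.
`printable_mask` re-thresholds a solved sweep without re-solving.

## Fixtures and what passing tests show

The packaged material table holds published reference properties for PCL and
DMSO₂ (densities, 120 °C viscosities, CTEs, surface tensions). The contact
angles in it (PCL 75°, DMSO₂ 40°) are **placeholders** chosen to be
representative of a partially wetting polymer melt and a higher-surface-
energy additive; the underlying wettability measurements are not published.
Consequently the test suite validates the *model chain* — exact oracles for
each stage, conservation laws, and the directional responses to composition,
temperature, and pressure that the real system exhibits — not absolute
agreement with any measured strut. Absolute widths and printable-area
boundaries shift with θ₂, the unpublished barrel geometry, and the blend
viscosity model; the qualitative band structure does not.

Problem sizes in the shipped tests and acceptance script (10×10 oracle
grids, 5×5 area-conservation grid, 3 T × 10 P sweeps per blend, 5 T × 19 P
acceptance sweep) were chosen as comfortably convergent for these smooth,
low-dimensional solvers; the full suite runs in a few seconds.

## Known limitations

* Refutas blending across a six-decade viscosity contrast is an
  extrapolation; blend-viscosity absolutes (and everything downstream of
  them for the DMSO₂ blends) are order-of-magnitude.
* The newtonian default ignores shear thinning inside the nozzle; the
  power-law option brackets its effect but no measured index is shipped.
* The deposition model is quasi-static and isothermal: it gives the
  equilibrium shape the melt would reach before solidifying, an upper bound
  on spreading.
* Single strut only; no strut-to-strut fusion, layer stacking, or end
  effects of finite printed lines.
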