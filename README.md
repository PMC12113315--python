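# strutcast

A nozzle-to-deposition process model for pneumatic melt-extrusion 3D printing
of polymer bio-scaffolds. Given the material properties of a polymer blend —
here polycaprolactone (PCL) thinned with dimethyl sulfone (DMSO₂) — and the
printing conditions (temperature, pneumatic pressure, stage speed), the
package predicts:

1. the blend's melt viscosity at the printing temperature,
2. the mean **extrusion velocity** out of the nozzle,
3. the equilibrium **cross-section of the deposited strut** (height, substrate
   contact width, strut diameter), and
4. the **printable region** of the temperature–pressure plane for a scaffold
   with a given strut pitch.

It is written for people tuning extrusion bioprinters or screening candidate
biomaterials: the strut cross-section sets the scaffold's pore size and
porosity, so predicting it from process parameters replaces print-and-measure
iteration.

## The model

**Viscosity.** Each component's melt viscosity is shifted from its reference
temperature with the Williams–Landel–Ferry (WLF) equation,

    ln(η(T)/η_r) = −8.86 (T − T_r) / (101.6 + T − T_r),

and the blend viscosity follows the Refutas viscosity-blending-index method
on weight fractions x_i:

    A_i = 14.534 ln(ln(v_i + 0.8)) + 10.975,   A = Σ x_i A_i,
    v   = exp(exp((A − 10.975)/14.534)) − 0.8,

with v_i on a working basis of kinematic cSt (standard) or dynamic cP.
Densities follow the rule of mixtures with thermal expansion.

**Extrusion.** The barrel + tapered nozzle is a series of axisymmetric
segments; each contributes a generalized Hagen–Poiseuille pressure drop
(newtonian or power-law, lubrication approximation in the taper), and the
volumetric rate Q solves Σ ΔP_k(Q) = P_gauge. The mean outlet velocity is
v = Q / (π R²).

**Deposition.** The strut cross-section is the static Young–Laplace shape:
the pressure jump across the surface equals γκ, with hydrostatic interior
pressure P(y) = P₀ − ρg y, symmetry at the apex, the substrate met at the
equilibrium contact angle θ₂, and the enclosed area fixed by volume
conservation A = v_extrusion π R² / v_stage. Flattening by gravity is
governed by the dimensionless number **H = ρ g h² / (2γ)**; sub-millimetre
polymer struts have H ≈ 10⁻², nearly circular arcs. The solver shoots on the
tangent-angle ODE; an independent closed form in incomplete elliptic
integrals cross-checks it.

**Printability.** A condition prints well when v ≥ 0.21 mm/s (slower
extrusion lays wavy lines) and the strut diameter stays within the 700 µm
strut pitch (wider struts close the pores). Both thresholds are inclusive
and configurable.

## Worked example

```bash
python examples/strut_cross_section.py
```

```
extrusion velocity   :   0.1863 mm/s
conserved strut area :   0.0370 mm^2
strut height         :    138.5 um
contact width        :    361.6 um
strut diameter       :    361.6 um
gravity number H     : 0.002572
elliptic-form deviation: 4.00e-14 (fraction of height)
```

Molten PCL (2211.35 Pa·s at 120 °C) pushed at 345 kPa through a 450 µm
nozzle extrudes at 0.186 mm/s; drawn into a line at 0.8 mm/s it deposits a
0.037 mm² section that relaxes to a 362 µm-wide, 139 µm-tall cap. H ≈ 0.003
says gravity barely flattens it, and the elliptic-integral closed form
reproduces the shooting solution to machine precision.

The other examples print the blend-viscosity table
(`examples/blend_viscosity.py`), the velocity–pressure response
(`examples/extrusion_velocity.py`), and an ASCII printability map
(`examples/printability_map.py`) whose printable band climbs to lower
pressures as temperature rises:

```
P (kPa):  150  200  250  300  350  400  450  500  550  600
  120 C     .    .    .    .    .    #    #    #    #    #
  125 C     .    .    .    #    #    #    #    #    #    #
  130 C     .    #    #    #    #    #    #    #    #    x
  135 C     #    #    #    #    #    #    x    x    x    x
  140 C     #    #    #    x    x    x    x    x    x    x
```

The same chain is scriptable from the shell:

```bash
strutcast viscosity --blend pcl_d10 --temp 125
strutcast extrude --blend pcl --temp 120 --pressure-kpa 345
strutcast stack --area-mm2 0.159 --rho 1145 --gamma 0.040 --theta2 75
strutcast printmap --blend pcl --out map.csv
```

Note: the shipped material table carries published reference properties for
PCL and DMSO₂, but the substrate contact angles in it are documented
placeholders — absolute widths are illustrative until you supply measured
wettability values (see `docs/methods.md`).

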