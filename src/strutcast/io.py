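"""Material tables, fixtures, run configuration, and the pipeline driver.

Interface units are practical (°C, kPa, mm/s, µm, mm²); everything below
this boundary is SI.  The shipped material table carries the published
reference properties of PCL and DMSO2; the substrate contact angles in that
table are documented representative placeholders (the underlying wettability
measurements are not published), so treat absolute strut widths computed
from them as illustrative.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from .extrusion import NozzleGeometry, Segment, rheology_from_blend, solve_flow
from .materials import Blend, Material
from .printability import ProcessGrid, sweep
from .stacking import StackingInput, solve_profile, strut_area_from_flow, strut_metrics

__all__ = [
    "MATERIAL_TABLE_COLUMNS",
    "SchemaError",
    "load_material_table",
    "load_default_materials",
    "material_index",
    "blend_from_spec",
    "geometry_from_spec",
    "default_blends",
    "generate_fixtures",
    "RunConfig",
    "run_pipeline",
]

log = logging.getLogger("strutcast")

MATERIAL_TABLE_COLUMNS = [
    "name",
    "density_ref_kg_m3",
    "T_ref_density_C",
    "cte_per_C",
    "eta_ref_Pa_s",
    "T_ref_visc_C",
    "surface_tension_N_m",
    "contact_angle_deg",
]

# Reference material table. Densities, viscosities at 120 degC, CTEs and
# surface tensions are the published values for PCL and DMSO2; the contact
# angles are placeholder estimates (PCL melts wet steel/glass partially;
# DMSO2's higher surface energy wets better).
MATERIALS_TABLE1_CSV = """\
name,density_ref_kg_m3,T_ref_density_C,cte_per_C,eta_ref_Pa_s,T_ref_visc_C,surface_tension_N_m,contact_angle_deg
PCL,1145,25,165e-6,2211.35,120,0.040,75
DMSO2,1450,25,88e-6,0.00114,120,0.060,40
"""

# Published blend shear viscosities (Pa·s) over the printing window, shipped
# as reference data only: they are not consistent with the reference table
# above under the WLF + Refutas model and are never a computed target.
VISCOSITY_TABLE2_CSV = """\
T_C,PCL,PCL_D10,PCL_D20,PCL_D30
120,1286.6,863.0,696.9,333.8
125,1094.4,816.3,662.1,316.6
130,1018.9,762.7,622.2,286.5
135,946.0,749.7,577.1,251.1
140,889.5,720.1,526.9,229.1
"""

DEFAULT_GEOMETRY_YAML = """\
# Barrel + taper + capillary stand-in for a pneumatic syringe feeding a
# 450 um inner-diameter nozzle. Dimensions in millimetres.
segments:
- {kind: cylinder, r_in_mm: 4.0, r_out_mm: 4.0, length_mm: 60.0}
- {kind: cone, r_in_mm: 4.0, r_out_mm: 0.225, length_mm: 15.0}
- {kind: cylinder, r_in_mm: 0.225, r_out_mm: 0.225, length_mm: 5.0}
"""

BLENDS_YAML = """\
# PCL matrix with 0/10/20/30 wt% DMSO2.
blends:
  pcl:
    components:
    - {name: PCL, weight_fraction: 1.0}
  pcl_d10:
    components:
    - {name: PCL, weight_fraction: 0.9}
    - {name: DMSO2, weight_fraction: 0.1}
  pcl_d20:
    components:
    - {name: PCL, weight_fraction: 0.8}
    - {name: DMSO2, weight_fraction: 0.2}
  pcl_d30:
    components:
    - {name: PCL, weight_fraction: 0.7}
    - {name: DMSO2, weight_fraction: 0.3}
"""

FIXTURE_FILES = {
    "materials_table1.csv": MATERIALS_TABLE1_CSV,
    "viscosity_table2.csv": VISCOSITY_TABLE2_CSV,
    "default_geometry.yaml": DEFAULT_GEOMETRY_YAML,
    "blends.yaml": BLENDS_YAML,
}


class SchemaError(ValueError):
    """Input file does not match the documented schema."""


def load_material_table(path: str | Path) -> list[Material]:
    """Read a material-property CSV into validated :class:`Material` records.

    Expected header: ``name,density_ref_kg_m3,T_ref_density_C,cte_per_C,
    eta_ref_Pa_s,T_ref_visc_C,surface_tension_N_m,contact_angle_deg``.
    Raises :class:`SchemaError` naming the offending row/column; nothing is
    returned on partial failure.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise SchemaError(f"{path}: not a parseable material table ({exc})") from exc
    missing = [c for c in MATERIAL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if df.empty:
        raise SchemaError(f"{path}: no material rows")
    materials: list[Material] = []
    for i, row in df.iterrows():
        try:
            vals = {c: float(row[c]) for c in MATERIAL_TABLE_COLUMNS[1:]}
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: row {i} ({row['name']}): non-numeric value") from exc
        if vals["surface_tension_N_m"] > 1.0:
            raise SchemaError(
                f"{path}: row {i} ({row['name']}): surface tension "
                f"{vals['surface_tension_N_m']} N/m fails unit sanity (> 1 N/m)"
            )
        try:
            materials.append(
                Material(
                    name=str(row["name"]),
                    density_ref=vals["density_ref_kg_m3"],
                    T_ref_density=vals["T_ref_density_C"],
                    cte=vals["cte_per_C"],
                    eta_ref=vals["eta_ref_Pa_s"],
                    T_ref_visc=vals["T_ref_visc_C"],
                    surface_tension=vals["surface_tension_N_m"],
                    contact_angle=vals["contact_angle_deg"],
                )
            )
        except ValueError as exc:
            raise SchemaError(f"{path}: row {i}: {exc}") from exc
    return materials


def _packaged(name: str) -> Path:
    return Path(str(resources.files("strutcast").joinpath("data", name)))


def load_default_materials() -> list[Material]:
    """Materials from the packaged reference table."""
    return load_material_table(_packaged("materials_table1.csv"))


def material_index(materials: Sequence[Material]) -> dict[str, Material]:
    return {m.name: m for m in materials}


def blend_from_spec(materials: Sequence[Material], spec: dict[str, Any]) -> Blend:
    """Build a Blend from ``{"components": [{"name", "weight_fraction"}, ...]}``."""
    idx = material_index(materials)
    pairs = []
    for comp in spec["components"]:
        name = comp["name"]
        if name not in idx:
            raise SchemaError(f"unknown material {name!r}; have {sorted(idx)}")
        pairs.append((idx[name], float(comp["weight_fraction"])))
    return Blend(tuple(pairs))


def default_blends(materials: Sequence[Material] | None = None) -> dict[str, Blend]:
    """The packaged blend set: pcl, pcl_d10, pcl_d20, pcl_d30."""
    materials = materials if materials is not None else load_default_materials()
    specs = yaml.safe_load(BLENDS_YAML)["blends"]
    return {name: blend_from_spec(materials, spec) for name, spec in specs.items()}


def geometry_from_spec(spec: dict[str, Any]) -> NozzleGeometry:
    """Build a NozzleGeometry from mm-unit segment dicts."""
    segments = tuple(
        Segment(
            kind=s["kind"],
            r_in=float(s["r_in_mm"]) * 1e-3,
            r_out=float(s["r_out_mm"]) * 1e-3,
            length=float(s["length_mm"]) * 1e-3,
        )
        for s in spec["segments"]
    )
    return NozzleGeometry(segments)


def load_default_geometry() -> NozzleGeometry:
    return geometry_from_spec(yaml.safe_load(DEFAULT_GEOMETRY_YAML))


def generate_fixtures(out_dir: str | Path) -> list[Path]:
    """Write the packaged fixture set into ``out_dir``; idempotent (byte-identical)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, content in FIXTURE_FILES.items():
        p = out / name
        p.write_text(content)
        written.append(p)
    return written


@dataclass
class RunConfig:
    """One pipeline run: materials + blend + geometry + process (+ outputs).

    Practical units throughout: °C, kPa, mm/s, µm.  ``T_C``/``P_kPa`` may be
    scalars (single-condition run) or lists (printability grid).  ``seed`` is
    accepted for interface stability; the model is deterministic.
    """

    material_table: str | Path | None = None
    blend: dict[str, Any] | str = "pcl"
    geometry: dict[str, Any] | None = None
    T_C: float | list[float] = 120.0
    P_kPa: float | list[float] = 345.0
    stage_speed_mm_s: float = 0.8
    strut_pitch_um: float = 700.0
    v_min_mm_s: float = 0.21
    g: float = 9.81
    theta2_deg: float | None = None
    layer_height_um: float | None = None  # accepted, unused by the single-strut model
    basis: str = "kinematic_cSt"
    floor: float | None = 1.0
    n_psi: int = 2001
    metrics_json: str | Path | None = None
    profile_csv: str | Path | None = None
    map_csv: str | Path | None = None
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise SchemaError(f"{path}: config must be a mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def resolve(self) -> tuple[Blend, NozzleGeometry]:
        materials = (
            load_material_table(self.material_table)
            if self.material_table
            else load_default_materials()
        )
        if isinstance(self.blend, str):
            blends = default_blends(materials)
            if self.blend not in blends:
                raise SchemaError(f"unknown blend {self.blend!r}; have {sorted(blends)}")
            blend = blends[self.blend]
        else:
            blend = blend_from_spec(materials, self.blend)
        geometry = (
            geometry_from_spec(self.geometry) if self.geometry else load_default_geometry()
        )
        return blend, geometry


def _write_profile_csv(profile, path: Path) -> None:
    pd.DataFrame(
        {
            "psi_rad": profile.psi_grid,
            "x_mm": profile.x * 1e3,
            "y_mm": profile.y * 1e3,
            "alpha": profile.alpha,
            "beta": profile.beta,
        }
    ).to_csv(path, index=False)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute materials -> extrusion -> stacking (-> printability for grids).

    Single condition: returns (and optionally writes) a metrics dict with
    every intermediate.  Grid condition: returns the printability table and
    optionally writes it as CSV.  Intermediates are logged at INFO.
    """
    from .materials import (
        blend_viscosity,
        mixture_contact_angle,
        mixture_density,
        mixture_surface_tension,
    )

    blend, geometry = config.resolve()
    grid_mode = isinstance(config.T_C, (list, tuple)) or isinstance(config.P_kPa, (list, tuple))

    if grid_mode:
        Ts = config.T_C if isinstance(config.T_C, (list, tuple)) else [config.T_C]
        Ps = config.P_kPa if isinstance(config.P_kPa, (list, tuple)) else [config.P_kPa]
        grid = ProcessGrid(
            T_values=tuple(float(t) for t in Ts),
            P_values=tuple(float(p) * 1e3 for p in Ps),
            stage_speed=config.stage_speed_mm_s * 1e-3,
            strut_pitch=config.strut_pitch_um * 1e-6,
            v_min=config.v_min_mm_s * 1e-3,
        )
        pmap = sweep(
            blend,
            geometry,
            grid,
            theta2=config.theta2_deg,
            g=config.g,
            basis=config.basis,
            floor=config.floor,
        )
        df = pmap.to_dataframe()
        n_printable = int(df["printable"].sum())
        log.info("printability sweep: %d/%d cells printable", n_printable, len(df))
        if config.map_csv:
            df.to_csv(Path(config.map_csv), index=False)
        return {"mode": "grid", "map": df, "n_printable": n_printable}

    T = float(config.T_C)
    P = float(config.P_kPa) * 1e3
    stage_speed = config.stage_speed_mm_s * 1e-3

    eta = blend_viscosity(blend, T, basis=config.basis, floor=config.floor)
    log.info("blend viscosity at %.1f degC: %.4g Pa·s", T, eta)
    rheo = rheology_from_blend(blend, T, basis=config.basis, floor=config.floor)
    flow = solve_flow(geometry, rheo, P)
    log.info(
        "flow: Q = %.4g m^3/s, v_mean_outlet = %.4g mm/s", flow.Q, flow.v_mean_outlet * 1e3
    )
    A = strut_area_from_flow(flow.v_mean_outlet, geometry.outlet_radius, stage_speed)
    log.info("conserved strut area: %.4g mm^2", A * 1e6)
    rho = mixture_density(blend, T)
    gamma = mixture_surface_tension(blend)
    theta2 = config.theta2_deg if config.theta2_deg is not None else mixture_contact_angle(blend)
    profile = solve_profile(
        StackingInput(A_target=A, rho=rho, gamma=gamma, theta2=theta2, g=config.g),
        n_psi=config.n_psi,
    )
    metrics = strut_metrics(profile)
    log.info(
        "strut: h = %.1f um, contact width = %.1f um, diameter = %.1f um, H = %.4g",
        profile.h * 1e6,
        profile.contact_width * 1e6,
        profile.diameter * 1e6,
        profile.H,
    )
    report = {
        "mode": "single",
        "T_C": T,
        "P_kPa": P / 1e3,
        "eta_Pa_s": eta,
        "rho_kg_m3": rho,
        "gamma_N_m": gamma,
        "theta2_deg": theta2,
        "Q_m3_s": flow.Q,
        "v_mm_s": flow.v_mean_outlet * 1e3,
        "area_mm2": A * 1e6,
        "height_um": metrics["height"] * 1e6,
        "contact_width_um": metrics["contact_width"] * 1e6,
        "diameter_um": metrics["diameter"] * 1e6,
        "H": profile.H,
    }
    if config.metrics_json:
        Path(config.metrics_json).write_text(
            json.dumps({k: v for k, v in report.items() if k != "mode"}, indent=2)
        )
    if config.profile_csv:
        _write_profile_csv(profile, Path(config.profile_csv))
    return report
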