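"""Printability maps over the (temperature, pressure) plane.

A condition prints well when the strut comes out fast enough to lay a
straight (non-wavy) line and thin enough to leave open pores between
neighbouring struts.  Both thresholds are closed: v >= v_min passes and
diameter <= pitch passes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .extrusion import NozzleGeometry, rheology_from_blend, solve_flow, ExtrusionError
from .materials import (
    Blend,
    MaterialError,
    mixture_contact_angle,
    mixture_density,
    mixture_surface_tension,
)
from .stacking import StackingError, StackingInput, solve_profile, strut_area_from_flow

__all__ = ["ProcessGrid", "CellResult", "PrintabilityMap", "sweep", "printable_mask"]

Criterion = Literal["ok", "too_slow", "too_wide", "failed"]

# defaults mirroring the studied process window
DEFAULT_T_VALUES = (120.0, 125.0, 130.0, 135.0, 140.0)  # degC
DEFAULT_P_VALUES = tuple(float(p) for p in range(150_000, 600_001, 25_000))  # Pa
DEFAULT_STAGE_SPEED = 0.8e-3  # m/s
DEFAULT_STRUT_PITCH = 700e-6  # m
DEFAULT_V_MIN = 0.21e-3  # m/s: slower extrusion lays wavy lines


@dataclass(frozen=True)
class ProcessGrid:
    """Sweep grid and printability thresholds (SI units)."""

    T_values: tuple[float, ...] = DEFAULT_T_VALUES
    P_values: tuple[float, ...] = DEFAULT_P_VALUES
    stage_speed: float = DEFAULT_STAGE_SPEED
    strut_pitch: float = DEFAULT_STRUT_PITCH
    v_min: float = DEFAULT_V_MIN

    def __post_init__(self) -> None:
        for name, vals in (("T_values", self.T_values), ("P_values", self.P_values)):
            if len(vals) == 0:
                raise ValueError(f"{name} must be non-empty")
            if any(b <= a for a, b in zip(vals, vals[1:])):
                raise ValueError(f"{name} must be strictly increasing")
        if self.stage_speed <= 0 or self.strut_pitch <= 0:
            raise ValueError("stage_speed and strut_pitch must be positive")


@dataclass(frozen=True)
class CellResult:
    """Outcome at one (T, P) grid cell."""

    T: float  # degC
    P: float  # Pa gauge
    v_extrusion: float  # m/s
    diameter: float  # m (nan when the profile solve failed)
    printable: bool
    limiting_criterion: Criterion


@dataclass(frozen=True)
class PrintabilityMap:
    """All cell results of one sweep, row-major over (T, P)."""

    grid: ProcessGrid
    cells: tuple[CellResult, ...]

    def to_dataframe(self) -> pd.DataFrame:
        """Practical-unit table: T_C, P_kPa, v_mm_s, diameter_um, printable, limiting_criterion."""
        return pd.DataFrame(
            {
                "T_C": [c.T for c in self.cells],
                "P_kPa": [c.P / 1e3 for c in self.cells],
                "v_mm_s": [c.v_extrusion * 1e3 for c in self.cells],
                "diameter_um": [c.diameter * 1e6 for c in self.cells],
                "printable": [c.printable for c in self.cells],
                "limiting_criterion": [c.limiting_criterion for c in self.cells],
            }
        )

    def cell(self, T: float, P: float) -> CellResult:
        for c in self.cells:
            if c.T == T and c.P == P:
                return c
        raise KeyError(f"no cell at T={T}, P={P}")


def _classify(v: float, d: float, v_min: float, pitch: float) -> tuple[bool, Criterion]:
    if v < v_min:
        return False, "too_slow"
    if d > pitch:
        return False, "too_wide"
    return True, "ok"


def sweep(
    blend: Blend,
    geometry: NozzleGeometry,
    grid: ProcessGrid,
    theta2: float | None = None,
    g: float = 9.81,
    n_psi: int = 201,
    **rheology_kwargs,
) -> PrintabilityMap:
    """Chain extrusion -> deposition over every (T, P) cell and classify.

    theta2 defaults to the weight-fraction mixture of the component contact
    angles.  Cells where a stage solver fails are recorded as unprintable
    with ``limiting_criterion = "failed"`` rather than aborting the sweep.
    """
    R = geometry.outlet_radius
    th2 = mixture_contact_angle(blend) if theta2 is None else theta2
    gamma = mixture_surface_tension(blend)
    cells: list[CellResult] = []
    for T in grid.T_values:
        try:
            rheo = rheology_from_blend(blend, T, **rheology_kwargs)
            rho = mixture_density(blend, T)
        except MaterialError:
            for P in grid.P_values:
                cells.append(CellResult(T, P, math.nan, math.nan, False, "failed"))
            continue
        for P in grid.P_values:
            try:
                v = solve_flow(geometry, rheo, P).v_mean_outlet
            except ExtrusionError:
                cells.append(CellResult(T, P, math.nan, math.nan, False, "failed"))
                continue
            try:
                A = strut_area_from_flow(v, R, grid.stage_speed)
                profile = solve_profile(
                    StackingInput(A_target=A, rho=rho, gamma=gamma, theta2=th2, g=g),
                    n_psi=n_psi,
                )
                d = profile.diameter
            except StackingError:
                cells.append(CellResult(T, P, v, math.nan, False, "failed"))
                continue
            printable, crit = _classify(v, d, grid.v_min, grid.strut_pitch)
            cells.append(CellResult(T, P, v, d, printable, crit))
    return PrintabilityMap(grid=grid, cells=tuple(cells))


def printable_mask(pmap: PrintabilityMap, v_min: float, pitch: float) -> np.ndarray:
    """Re-threshold a solved sweep: boolean grid shaped (len(T), len(P)).

    Identical to the sweep's own flags when the thresholds match; failed
    cells are always False.  Raising v_min or lowering pitch can only shrink
    the printable set.
    """
    nT, nP = len(pmap.grid.T_values), len(pmap.grid.P_values)
    mask = np.zeros((nT, nP), dtype=bool)
    for idx, c in enumerate(pmap.cells):
        if c.limiting_criterion == "failed":
            continue
        mask[idx // nP, idx % nP] = c.v_extrusion >= v_min and c.diameter <= pitch
    return mask
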