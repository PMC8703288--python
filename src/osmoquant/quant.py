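"""Calibration-based quantification and normalization to cellular units.

The chain: XIC peak area -> extract concentration (uM) via an external,
through-origin calibration curve -> per-cell amount (fmol/cell) using the
sample context (cells filtered, extract volume, dilution) -> intracellular
concentration (mM) by dividing by the geometric cell volume.  The unit
identity doing the last step is fmol/pL = mM.

LOD and LOQ follow the ICH convention, 3.3x and 10x the calibration
residual SD over the slope.  Concentrations below these limits are
*flagged*, never imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .quant_shapes import cell_volume_from_shape  # re-export  # noqa: F401
from .run_io import SyntheticRun
from .screening import DEFAULT_TOL_PPM, XIC, extract_xic
from .simulate import AnalyteDef

__all__ = [
    "CalibrationCurve",
    "SampleContext",
    "CensorFlag",
    "QuantResult",
    "integrate_peak",
    "fit_calibration",
    "concentration_from_area",
    "per_cell_amount",
    "intracellular_concentration",
    "cell_volume_from_shape",
    "quantify_run",
]


class CensorFlag(str, Enum):
    """Reporting status relative to the calibration limits."""

    QUANTIFIABLE = "quantifiable"
    BELOW_LOQ = "below_loq"      # signal present but below LOQ: printed "+"
    BELOW_LOD = "below_lod"      # printed "-"


@dataclass(frozen=True)
class CalibrationCurve:
    """A fitted external calibration: y = slope * x (through origin)."""

    analyte: str
    slope: float
    r: float
    residual_sd: float
    lod_um: float
    loq_um: float
    n_points: int
    intercept: float = 0.0
    through_origin: bool = True

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be > 0")
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValueError("correlation r must be in [-1, 1]")
        if self.residual_sd > 0 and not 0 < self.lod_um < self.loq_um:
            raise ValueError("need 0 < LOD < LOQ when residual SD > 0")


@dataclass(frozen=True)
class SampleContext:
    """What links an extract concentration back to the cells it came from."""

    cells_filtered: float
    extract_volume_ml: float
    dilution_factor: float
    cell_volume_pl: float

    def __post_init__(self) -> None:
        for name in ("cells_filtered", "extract_volume_ml",
                     "dilution_factor", "cell_volume_pl"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class QuantResult:
    """Quantification of one analyte in one sample, in all three units."""

    analyte: str
    sample_id: str
    area: float
    extract_conc_um: float
    per_cell_fmol: float
    intracellular_mm: float
    flag: CensorFlag
    condition: str = ""


def integrate_peak(
    xic: XIC,
    rt_window: tuple[float, float],
    baseline: str = "linear",
) -> float:
    """Trapezoidal area of an XIC over an RT window, baseline-subtracted.

    ``baseline="linear"`` subtracts the straight line between the window
    endpoints; ``"none"`` integrates the raw trace.  Area units are
    intensity x minutes.
    """
    t0, t1 = rt_window
    if t1 <= t0:
        raise ValueError("empty RT window")
    if t0 < xic.times_min[0] - 1e-9 or t1 > xic.times_min[-1] + 1e-9:
        raise ValueError("RT window outside the XIC time range")
    mask = (xic.times_min >= t0) & (xic.times_min <= t1)
    if mask.sum() < 2:
        raise ValueError("RT window contains fewer than 2 scans")
    t = xic.times_min[mask]
    y = xic.intensity[mask].astype(float)
    if baseline == "linear":
        base = y[0] + (y[-1] - y[0]) * (t - t[0]) / (t[-1] - t[0])
        y = y - base
    elif baseline != "none":
        raise ValueError(f"unknown baseline mode {baseline!r}")
    return float(max(np.trapezoid(y, t), 0.0))


def fit_calibration(
    points: list[tuple[float, float]],
    analyte: str = "",
    through_origin: bool = True,
) -> CalibrationCurve:
    """Least-squares calibration fit with LOD/LOQ.

    Through-origin by default (the published curves are all of the form
    y = m x): slope = sum(xy)/sum(x^2), residual SD with n-1 degrees of
    freedom.  ``r`` is the Pearson correlation of the points.  LOD and
    LOQ are 3.3 and 10 times residual SD over slope.
    """
    if len(points) < 3:
        raise ValueError(f"need >= 3 calibration points, got {len(points)}")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.any(x <= 0):
        raise ValueError("calibration concentrations must be > 0")
    if np.allclose(x, x[0]):
        raise ValueError("calibration concentrations are all identical")
    if through_origin:
        slope = float(np.sum(x * y) / np.sum(x * x))
        intercept = 0.0
        dof = x.size - 1
    else:
        slope, intercept = (float(v) for v in np.polyfit(x, y, 1))
        dof = x.size - 2
    residuals = y - (slope * x + intercept)
    residual_sd = float(math.sqrt(np.sum(residuals ** 2) / dof))
    r = float(np.corrcoef(x, y)[0, 1])
    lod = 3.3 * residual_sd / slope
    loq = 10.0 * residual_sd / slope
    return CalibrationCurve(
        analyte=analyte, slope=slope, r=r, residual_sd=residual_sd,
        lod_um=lod, loq_um=loq, n_points=x.size,
        intercept=intercept, through_origin=through_origin,
    )


def concentration_from_area(
    area: float, curve: CalibrationCurve
) -> tuple[float, CensorFlag]:
    """Invert the calibration and censor against LOD/LOQ.

    Returns ``(concentration in uM, flag)``; the flag mirrors the survey
    reporting convention ("+" for a signal between LOD and LOQ).
    """
    if area < 0:
        raise ValueError("area must be >= 0")
    conc = max((area - curve.intercept) / curve.slope, 0.0)
    if conc < curve.lod_um:
        flag = CensorFlag.BELOW_LOD
    elif conc < curve.loq_um:
        flag = CensorFlag.BELOW_LOQ
    else:
        flag = CensorFlag.QUANTIFIABLE
    return conc, flag


def per_cell_amount(extract_conc_um: float, ctx: SampleContext) -> float:
    """Per-cell amount in fmol/cell.

    (measured uM x dilution factor x extract volume) / cells filtered,
    using 1 uM in 1 mL = 1e6 fmol.
    """
    total_fmol = (extract_conc_um * ctx.dilution_factor
                  * ctx.extract_volume_ml * 1e6)
    return total_fmol / ctx.cells_filtered


def intracellular_concentration(per_cell_fmol: float, cell_volume_pl: float) -> float:
    """Intracellular concentration in mM: fmol/cell over pL is exactly mM."""
    if cell_volume_pl <= 0:
        raise ValueError("cell volume must be > 0")
    return per_cell_fmol / cell_volume_pl


def quantify_run(
    run: SyntheticRun,
    analyte: AnalyteDef,
    curve: CalibrationCurve,
    ctx: SampleContext,
    tol_ppm: float = DEFAULT_TOL_PPM,
    rt_halfwidth_min: float = 0.25,
) -> QuantResult:
    """Targeted quantification of one analyte in one run.

    Extracts the XIC at the analyte m/z, integrates over RT +- the half
    width with a linear baseline, inverts the calibration, and normalizes
    to fmol/cell and mM.
    """
    xic = extract_xic(run, analyte.mz, tol_ppm=tol_ppm)
    t0 = max(analyte.rt_min - rt_halfwidth_min, float(xic.times_min[0]))
    t1 = min(analyte.rt_min + rt_halfwidth_min, float(xic.times_min[-1]))
    area = integrate_peak(xic, (t0, t1))
    conc, flag = concentration_from_area(area, curve)
    per_cell = per_cell_amount(conc, ctx)
    return QuantResult(
        analyte=analyte.name,
        sample_id=str(run.metadata.get("sample_id", "")),
        area=area,
        extract_conc_um=conc,
        per_cell_fmol=per_cell,
        intracellular_mm=intracellular_concentration(per_cell, ctx.cell_volume_pl),
        flag=flag,
        condition=str(run.metadata.get("condition", "")),
    )
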