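"""Calibration-curve analysis, limit of detection, and pathlength scaling.

The detection limit follows the common calibration-based definition
LOD = factor * sigma_resid / slope with factor 3.3 by default (3.0 available);
sigma_resid is the residual SD of the ordinary-least-squares response line
with an n-2 denominator.  Under Beer-Lambert the slope is proportional to
pathlength, so at fixed absorbance noise the LOD scales inversely with
pathlength — the basis of the long-pathlength sensitivity gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationSeries",
    "LodResult",
    "calibration_fit",
    "lod",
    "sensitivity_ratio",
    "pathlength_scaling",
]


@dataclass
class CalibrationSeries:
    """Concentration/response pairs with their fitted straight line."""

    concentration_uM: np.ndarray
    response_od: np.ndarray
    pathlength_um: float | None = None
    slope: float = float("nan")  # OD per uM
    slope_se: float = float("nan")
    intercept: float = float("nan")
    intercept_se: float = float("nan")
    sigma_resid: float = float("nan")  # OD, n-2 denominator
    r_squared: float = float("nan")

    @property
    def n_levels(self) -> int:
        return int(self.concentration_uM.size)


@dataclass
class LodResult:
    """Limit of detection with the factor and inputs recorded."""

    lod_uM: float
    factor: float
    sigma_resid: float
    slope: float
    pathlength_um: float | None = None


def calibration_fit(concentration_uM: Sequence[float],
                    response_od: Sequence[float],
                    pathlength_um: float | None = None) -> CalibrationSeries:
    """Ordinary least squares of response versus concentration."""
    c = np.asarray(concentration_uM, dtype=float)
    r = np.asarray(response_od, dtype=float)
    if c.size != r.size:
        raise ValueError("concentration and response lengths differ")
    if c.size < 3:
        raise ValueError("a calibration fit needs at least 3 levels")
    if np.ptp(c) == 0:
        raise ValueError("all concentrations identical: rank-deficient design")
    fit = stats.linregress(c, r)
    resid = r - (fit.intercept + fit.slope * c)
    sigma = float(np.sqrt(np.sum(np.square(resid)) / (c.size - 2)))
    return CalibrationSeries(
        concentration_uM=c,
        response_od=r,
        pathlength_um=pathlength_um,
        slope=float(fit.slope),
        slope_se=float(fit.stderr),
        intercept=float(fit.intercept),
        intercept_se=float(fit.intercept_stderr),
        sigma_resid=sigma,
        r_squared=float(fit.rvalue) ** 2,
    )


def lod(series: CalibrationSeries, factor: float = 3.3) -> LodResult:
    """LOD = factor * sigma_resid / slope (factor recorded in the result)."""
    if not np.isfinite(series.slope):
        raise ValueError("calibration series has no fitted slope")
    if series.slope <= 0:
        raise ValueError("slope must be > 0 for a real absorber")
    if factor <= 0:
        raise ValueError("factor must be > 0")
    return LodResult(
        lod_uM=factor * series.sigma_resid / series.slope,
        factor=factor,
        sigma_resid=series.sigma_resid,
        slope=series.slope,
        pathlength_um=series.pathlength_um,
    )


def sensitivity_ratio(lod_a: LodResult | float, lod_b: LodResult | float) -> float:
    """Fold improvement of configuration b over configuration a: lod_a / lod_b."""
    a = lod_a.lod_uM if isinstance(lod_a, LodResult) else float(lod_a)
    b = lod_b.lod_uM if isinstance(lod_b, LodResult) else float(lod_b)
    if a <= 0 or b <= 0:
        raise ValueError("LODs must be > 0")
    return a / b


def pathlength_scaling(lod_ref_uM: float, pathlength_ref_um: float,
                       pathlength_new_um: float) -> float:
    """Predicted LOD at a new pathlength under equal absorbance noise.

    Beer-Lambert: slope scales with L, so LOD_new = LOD_ref * L_ref / L_new.
    """
    if pathlength_ref_um <= 0 or pathlength_new_um <= 0:
        raise ValueError("pathlengths must be > 0")
    return lod_ref_uM * pathlength_ref_um / pathlength_new_um
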