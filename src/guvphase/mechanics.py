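"""Stress–strain analysis of GUV deformation assays.

GUVs trapped in tapered microfluidic channels elongate under an applied
pressure drop; over the assay's 100–1000 Pa range the elongation (strain,
ΔL/L₀) is linear in pressure. The slope of an ordinary least-squares
strain-vs-pressure regression is the compliance of the vesicle; the
relative elastic modulus of a sample condition is the ratio of a
reference condition's slope to the sample's slope (stiffer membranes
deform less per Pa), with naked GUVs conventionally the reference = 1.
A forth/back consistency record compares the regressions from the two
push directions and pools them when they agree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .errors import FitFailureError, ParameterError

__all__ = [
    "DeformationSeries",
    "StiffnessFit",
    "ForthBackRecord",
    "fit_stress_strain",
    "relative_modulus",
    "forth_back_consistency",
    "PRESSURE_RANGE_PA",
]

#: Pressure-drop range of the deformation assay (Pa).
PRESSURE_RANGE_PA = (100.0, 1000.0)


@dataclass
class DeformationSeries:
    """(pressure, strain) table for one GUV condition and push direction."""

    pressures_Pa: np.ndarray
    strains: np.ndarray
    direction: str = "forth"
    condition: str = ""

    def __post_init__(self) -> None:
        self.pressures_Pa = np.asarray(self.pressures_Pa, dtype=float)
        self.strains = np.asarray(self.strains, dtype=float)
        if self.pressures_Pa.shape != self.strains.shape:
            raise ParameterError("pressure and strain lengths differ")
        if self.direction not in ("forth", "back"):
            raise ParameterError("direction must be 'forth' or 'back'")
        if np.any(self.strains < 0):
            raise ParameterError("strains must be non-negative")


@dataclass
class StiffnessFit:
    """OLS strain ~ pressure fit. ``e_rel`` is set by
    :func:`relative_modulus` once a reference condition is chosen."""

    slope: float           # strain per Pa (compliance)
    intercept: float
    r_squared: float
    slope_se: float
    intercept_se: float
    n: int
    e_rel: Optional[float] = None


@dataclass
class ForthBackRecord:
    """Forth/back agreement record: slope/intercept differences with
    standard errors, a consistency flag, and the pooled fit (fit of the
    concatenated data) when the directions agree."""

    slope_difference: float
    slope_difference_se: float
    intercept_difference: float
    intercept_difference_se: float
    consistent: bool
    pooled: Optional[StiffnessFit]


def fit_stress_strain(series: DeformationSeries) -> StiffnessFit:
    """Ordinary least squares of strain against pressure.

    Requires ≥ 3 points with ≥ 2 distinct pressures; raises
    :class:`FitFailureError` otherwise.
    """
    p, s = series.pressures_Pa, series.strains
    if len(p) < 3:
        raise FitFailureError("need at least 3 points for a stress-strain fit")
    if len(np.unique(p)) < 2:
        raise FitFailureError("zero pressure variance")
    res = stats.linregress(p, s)
    return StiffnessFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        slope_se=float(res.stderr),
        intercept_se=float(res.intercept_stderr),
        n=len(p),
    )


def relative_modulus(sample: StiffnessFit, reference: StiffnessFit) -> float:
    """Relative elastic modulus E_rel = slope(reference) / slope(sample).

    A stiffer membrane has a smaller compliance slope, hence a larger
    E_rel; E_rel of the reference against itself is 1, and
    relative_modulus(a, b) · relative_modulus(b, a) = 1. Invariant to a
    consistent rescaling of pressure units.
    """
    if sample.slope <= 0 or reference.slope <= 0:
        raise FitFailureError("relative modulus requires positive slopes")
    e_rel = reference.slope / sample.slope
    sample.e_rel = e_rel
    return e_rel


def forth_back_consistency(
    forth: DeformationSeries,
    back: DeformationSeries,
    n_se: float = 2.0,
) -> ForthBackRecord:
    """Compare the forth and back regressions and pool them if consistent.

    The directions are called consistent when both the slope and intercept
    differences are within ``n_se`` combined standard errors — the
    statistics needed for a full ANCOVA are exposed in the record so the
    test can be run externally.
    """
    fit_f = fit_stress_strain(forth)
    fit_b = fit_stress_strain(back)
    d_slope = fit_b.slope - fit_f.slope
    d_slope_se = float(np.hypot(fit_f.slope_se, fit_b.slope_se))
    d_int = fit_b.intercept - fit_f.intercept
    d_int_se = float(np.hypot(fit_f.intercept_se, fit_b.intercept_se))
    consistent = (abs(d_slope) <= n_se * d_slope_se or d_slope == 0) and \
        (abs(d_int) <= n_se * d_int_se or d_int == 0)
    pooled = None
    if consistent:
        pooled = fit_stress_strain(
            DeformationSeries(
                pressures_Pa=np.concatenate([forth.pressures_Pa, back.pressures_Pa]),
                strains=np.concatenate([forth.strains, back.strains]),
                direction="forth",
                condition=forth.condition,
            )
        )
    return ForthBackRecord(
        slope_difference=float(d_slope),
        slope_difference_se=d_slope_se,
        intercept_difference=float(d_int),
        intercept_difference_se=d_int_se,
        consistent=bool(consistent),
        pooled=pooled,
    )
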