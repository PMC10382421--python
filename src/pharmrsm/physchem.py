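"""Partition behaviour, bioanalytical validation and calibration statistics.

Small exactly-testable calculators: the n-octanol/water partition
coefficient P = Co/Cw and Log P; protein-precipitation extraction recovery
and matrix effect ratios; and calibration-curve statistics with detection
limits from the ICH sigma/S rules (LOD = 3.3 sigma/S, LOQ = 10 sigma/S,
sigma the residual SD of the regression line and S its slope).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SolubilityPair",
    "CalibrationResult",
    "SystemSuitability",
    "partition_coefficient",
    "log_p",
    "extraction_recovery",
    "matrix_effect",
    "lod_loq",
    "fit_calibration",
]


@dataclass(frozen=True)
class SolubilityPair:
    """Saturated solubilities (µg/mL) of a compound in n-octanol and water."""

    c_octanol: float
    c_water: float

    def __post_init__(self) -> None:
        if self.c_octanol < 0:
            raise ValueError(f"octanol solubility must be >= 0, got {self.c_octanol}")
        if self.c_water <= 0:
            raise ValueError(f"water solubility must be > 0, got {self.c_water}")


def partition_coefficient(pair: SolubilityPair) -> float:
    """P = Co / Cw."""
    return pair.c_octanol / pair.c_water


def log_p(pair: SolubilityPair) -> float:
    """log10 of the partition coefficient."""
    p = partition_coefficient(pair)
    if p <= 0:
        raise ValueError("Log P undefined for non-positive partition coefficient")
    return float(np.log10(p))


def extraction_recovery(pre_extracted: float, post_extracted: float) -> float:
    """Extraction recovery in percent: pre-extracted / post-extracted * 100."""
    if post_extracted <= 0:
        raise ValueError("post-extracted response must be > 0")
    return pre_extracted / post_extracted * 100.0


def matrix_effect(post_extracted: float, post_neat: float) -> float:
    """Matrix effect ratio: post-extracted / post-neat."""
    if post_neat <= 0:
        raise ValueError("post-neat response must be > 0")
    return post_extracted / post_neat


def lod_loq(sd_residuals: float, slope: float) -> tuple[float, float]:
    """ICH detection/quantification limits (3.3 and 10 x sigma/S)."""
    if slope == 0:
        raise ValueError("LOD/LOQ undefined for zero slope")
    if sd_residuals < 0:
        raise ValueError("residual SD must be >= 0")
    return 3.3 * sd_residuals / abs(slope), 10.0 * sd_residuals / abs(slope)


@dataclass(frozen=True)
class CalibrationResult:
    slope: float
    intercept: float
    r: float
    sd_residuals: float
    lod: float
    loq: float
    range_low: float
    range_high: float

    def __post_init__(self) -> None:
        if self.sd_residuals > 0 and not self.lod < self.loq:
            raise ValueError("LOD must be < LOQ")
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"correlation coefficient {self.r} outside [-1, 1]")


def fit_calibration(
    concentrations: Sequence[float], relative_peak_areas: Sequence[float]
) -> CalibrationResult:
    """OLS calibration line of relative peak area vs concentration.

    sd_residuals = sqrt(SS_res / (n - 2)); detection limits via the ICH
    sigma/S rules. Needs >= 3 points at >= 3 distinct concentrations.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(relative_peak_areas, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("concentrations and responses must be equal-length vectors")
    if len(x) < 3 or len(np.unique(x)) < 3:
        raise ValueError("calibration needs at least 3 distinct concentrations")
    fit = stats.linregress(x, y)
    residuals = y - (fit.intercept + fit.slope * x)
    sd_res = float(np.sqrt(residuals @ residuals / (len(x) - 2)))
    lod, loq = lod_loq(sd_res, fit.slope) if fit.slope != 0 else (0.0, 0.0)
    return CalibrationResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        sd_residuals=sd_res,
        lod=lod,
        loq=loq,
        range_low=float(x.min()),
        range_high=float(x.max()),
    )


@dataclass(frozen=True)
class SystemSuitability:
    """User-entered chromatographic system-suitability values, echoed in reports.

    These come from the instrument software, not from raw chromatograms, so
    the package only stores and reports them.
    """

    retention_time_min: float | None = None
    tailing_factor: float | None = None
    capacity_factor: float | None = None
    plate_number: float | None = None
    hetp: float | None = None
    resolution: float | None = None
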