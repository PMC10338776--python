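"""VOI statistics, SUVR, Centiloid conversion and calibration validation.

The Centiloid (CL) scale anchors amyloid burden to 0 for young controls
and 100 for typical AD.  For florbetapir with a whole-cerebellum
reference the published direct conversion is

    CL = 175.2 * SUVR - 182.2

A quantification pipeline is considered calibrated when regressing its
CL values on reference CL values gives slope in [0.98, 1.02], intercept
within +/- 2 CL and R^2 above 0.98 (the standard acceptance bounds for
Centiloid implementations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from centiz.volume_io import Volume3D, VOIMask, resample

logger = logging.getLogger(__name__)

__all__ = [
    "CL_SLOPE",
    "CL_INTERCEPT",
    "QuantResult",
    "CalibrationReport",
    "voi_mean",
    "compute_suvr",
    "suvr_to_centiloid",
    "centiloid_to_suvr",
    "validate_calibration",
]

CL_SLOPE = 175.2
CL_INTERCEPT = -182.2

# Klunk-style calibration acceptance bounds
SLOPE_BOUNDS = (0.98, 1.02)
INTERCEPT_BOUNDS = (-2.0, 2.0)
R2_MIN = 0.98


@dataclass
class QuantResult:
    """SUVR / CL quantification for one subject."""

    mean_target: float
    mean_reference: float
    suvr: float
    cl: float
    voi_coverage: float

    def to_dict(self) -> dict:
        return {
            "mean_target": self.mean_target,
            "mean_reference": self.mean_reference,
            "suvr": self.suvr,
            "cl": self.cl,
            "voi_coverage": self.voi_coverage,
        }


@dataclass
class CalibrationReport:
    """OLS agreement of computed vs reference CL plus pass/fail flags."""

    slope: float
    intercept: float
    r2: float
    pass_slope: bool
    pass_intercept: bool
    pass_r2: bool
    pass_all: bool
    n: int

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def suvr_to_centiloid(suvr: float):
    """Direct conversion CL = 175.2 * SUVR - 182.2 (exact affine map)."""
    suvr = np.asarray(suvr, dtype=float)
    if not np.all(np.isfinite(suvr)):
        raise ValueError("SUVR must be finite")
    out = CL_SLOPE * suvr + CL_INTERCEPT
    return float(out) if out.ndim == 0 else out


def centiloid_to_suvr(cl: float):
    """Inverse of :func:`suvr_to_centiloid`: SUVR = (CL + 182.2) / 175.2."""
    cl = np.asarray(cl, dtype=float)
    out = (cl - CL_INTERCEPT) / CL_SLOPE
    return float(out) if out.ndim == 0 else out


def voi_mean(vol: Volume3D, mask: VOIMask, coverage_floor: float = 0.9):
    """Unweighted mean of the volume over the mask.

    The mask is resampled (nearest-neighbour) onto the volume's grid if
    the geometries differ.  ``coverage`` is the fraction of mask voxels
    carrying finite, in-field (nonzero-sampled footprint) data; a
    coverage below ``coverage_floor`` raises.

    Returns ``(mean, coverage)``.
    """
    mask.require_nonempty()
    if not mask.same_grid(vol):
        if mask.shape == vol.shape and np.allclose(mask.affine, vol.affine, atol=1e-3):
            pass  # within tolerance: treat as the same grid
        else:
            mask = resample(mask, vol.affine, vol.shape, None)
            mask.require_nonempty()
    n_total = mask.n_voxels()
    if n_total == 0:
        raise ValueError("mask is empty after resampling to the volume grid")
    values = vol.data[mask.data]
    used = np.isfinite(values)
    coverage = float(used.sum()) / n_total
    if coverage <= 0:
        raise ValueError(f"mask {mask.name!r} lies entirely outside the data field")
    if coverage < coverage_floor:
        raise ValueError(
            f"mask {mask.name!r} coverage {coverage:.3f} below floor {coverage_floor:.3f}"
        )
    return float(values[used].mean()), coverage


def compute_suvr(
    pet_template_space: Volume3D,
    ctx: VOIMask,
    whlcbl: VOIMask,
    coverage_floor: float = 0.9,
) -> QuantResult:
    """SUVR = mean(CTX) / mean(WhlCbl) and its Centiloid value.

    The PET must already be in template space (where the standard VOIs
    live).  Raises if the reference mean is not positive.
    """
    mean_t, cov_t = voi_mean(pet_template_space, ctx, coverage_floor)
    mean_r, cov_r = voi_mean(pet_template_space, whlcbl, coverage_floor)
    if mean_r <= 0:
        raise ValueError(f"reference VOI mean must be positive, got {mean_r}")
    suvr = mean_t / mean_r
    return QuantResult(
        mean_target=mean_t,
        mean_reference=mean_r,
        suvr=suvr,
        cl=suvr_to_centiloid(suvr),
        voi_coverage=min(cov_t, cov_r),
    )


def validate_calibration(computed_cl, reference_cl) -> CalibrationReport:
    """Regress computed CL on reference CL and check calibration bounds.

    Ordinary least squares with the reference on the x-axis; R^2 is the
    squared Pearson correlation (identical to OLS R^2 for simple
    regression).  Slope/intercept bounds are inclusive; the R^2 bound is
    strict ("exceed 0.98").
    """
    y = np.asarray(computed_cl, dtype=float)
    x = np.asarray(reference_cl, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("computed and reference CL must be equal-length 1D sequences")
    n = x.size
    if n < 3:
        raise ValueError("calibration needs n >= 3 pairs")
    sx = x.std(ddof=0)
    if sx == 0:
        raise ValueError("reference CL values are constant")
    xc, yc = x - x.mean(), y - y.mean()
    slope = float((xc * yc).sum() / (xc * xc).sum())
    intercept = float(y.mean() - slope * x.mean())
    sy = y.std(ddof=0)
    r2 = 1.0 if sy == 0 and slope == 0 else float(((xc * yc).sum() / (n * sx * sy)) ** 2)
    pass_slope = SLOPE_BOUNDS[0] <= slope <= SLOPE_BOUNDS[1]
    pass_intercept = INTERCEPT_BOUNDS[0] <= intercept <= INTERCEPT_BOUNDS[1]
    pass_r2 = r2 > R2_MIN
    return CalibrationReport(
        slope=slope,
        intercept=intercept,
        r2=r2,
        pass_slope=pass_slope,
        pass_intercept=pass_intercept,
        pass_r2=pass_r2,
        pass_all=pass_slope and pass_intercept and pass_r2,
        n=n,
    )
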