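"""Global calibration of calculated spectra onto the experimental axis.

TD-DFT transition energies carry a large systematic offset and their
oscillator strengths live on an arbitrary scale, so calculated spectra
are mapped onto the experimental axis by one global energy shift and
one intensity scale.  The pair is fitted once against the untreated S2
reference and then frozen and applied identically to every candidate
model, keeping the comparison between models unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .spectra import Spectrum, StickSpectrum, resample

__all__ = ["CalibrationParams", "apply_calibration", "fit_calibration"]


@dataclass(frozen=True)
class CalibrationParams:
    """Energy shift (eV, added to calculated energies) and positive
    intensity scale (multiplies calculated intensities)."""

    shift: float
    scale: float

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError(f"intensity scale must be positive, got {self.scale}")

    def inverse(self) -> "CalibrationParams":
        return CalibrationParams(shift=-self.shift, scale=1.0 / self.scale)


def apply_calibration(x, p: CalibrationParams):
    """Shift energies by ``p.shift`` and scale intensities by ``p.scale``.

    Works on :class:`Spectrum` (records the calibration in ``meta``)
    and :class:`StickSpectrum` alike.
    """
    if isinstance(x, Spectrum):
        meta = {**x.meta, "calibration_shift_eV": p.shift, "calibration_scale": p.scale}
        return Spectrum(x.energies + p.shift, x.intensities * p.scale, meta)
    if isinstance(x, StickSpectrum):
        return StickSpectrum(x.site, x.energies + p.shift, x.intensities * p.scale)
    raise TypeError(f"cannot calibrate object of type {type(x).__name__}")


def _scale_and_rms(
    calc: Spectrum, exp_y: np.ndarray, grid: np.ndarray, shift: float
) -> tuple[float, float]:
    """Closed-form least-squares scale and resulting RMS at one shift."""
    shifted = Spectrum(calc.energies + shift, calc.intensities)
    yc = resample(shifted, grid).intensities
    denom = float(yc @ yc)
    if denom <= 0:
        raise ValueError("calculated spectrum is identically zero over the region")
    scale = float(exp_y @ yc) / denom
    rms = float(np.sqrt(np.mean((scale * yc - exp_y) ** 2)))
    return scale, rms


def fit_calibration(
    calc: Spectrum,
    exp_ref: Spectrum,
    region: Sequence[float],
    shift_bounds: Sequence[float] = (30.0, 40.0),
    coarse_step: float = 0.05,
) -> CalibrationParams:
    """Fit the global (shift, scale) aligning ``calc`` onto ``exp_ref``.

    Minimizes the RMS residual over ``region``: a coarse scan over the
    shift (default 0.05 eV step) with the optimal scale at each shift
    given in closed form (``scale* = sum(y_exp * y_calc) / sum(y_calc^2)``
    on the common grid), followed by bounded local refinement of the
    shift.  Deterministic; the scale is never fitted independently of
    the shift.
    """
    lo, hi = float(region[0]), float(region[1])
    if not hi > lo:
        raise ValueError("region is empty or inverted")
    b0, b1 = float(shift_bounds[0]), float(shift_bounds[1])
    if not b1 > b0:
        raise ValueError("shift_bounds are empty or inverted")
    span = calc.span
    if span[0] + b0 > lo or span[1] + b1 < hi:
        # guard only the worst case; per-shift coverage checked by resample
        if span[0] + b1 > lo or span[1] + b0 < hi:
            raise ValueError(
                "calculated spectrum cannot cover the region for shifts in bounds"
            )
    grid = exp_ref.energies[(exp_ref.energies >= lo) & (exp_ref.energies <= hi)]
    if grid.size < 2:
        raise ValueError("experimental reference has < 2 points in the region")
    exp_y = resample(exp_ref, grid).intensities

    shifts = np.arange(b0, b1 + coarse_step / 2, coarse_step)
    rms_values = np.array([_scale_and_rms(calc, exp_y, grid, sh)[1] for sh in shifts])
    best = int(np.argmin(rms_values))
    lo_ref = shifts[max(best - 1, 0)]
    hi_ref = shifts[min(best + 1, len(shifts) - 1)]
    if hi_ref > lo_ref:
        res = minimize_scalar(
            lambda sh: _scale_and_rms(calc, exp_y, grid, sh)[1],
            bounds=(lo_ref, hi_ref),
            method="bounded",
            options={"xatol": 1e-6},
        )
        shift = float(res.x)
    else:
        shift = float(shifts[best])
    scale, _ = _scale_and_rms(calc, exp_y, grid, shift)
    if scale <= 0:
        raise ValueError(
            "fitted intensity scale is non-positive; spectra are anti-correlated"
        )
    return CalibrationParams(shift=shift, scale=scale)
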