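"""Model discrimination by difference-spectrum RMSD.

Every candidate structural model yields a calculated pre-edge spectrum
(broadened, summed over the four Mn sites, globally calibrated).  The
model's treated-minus-native difference spectrum is compared with the
experimental difference spectrum on a common grid — by default 240
equally spaced energies over 6538–6544.5 eV — via the root-mean-square
deviation

    RMSD = sqrt( (1/N) * sum_i (y_i,calc - y_i,exp)^2 )

and models are ranked by ascending RMSD.  Models whose absolute
pre-edge intensity over 6540–6543 eV significantly exceeds the native
spectrum are screened out before ranking (they keep their score but no
rank).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .calibrate import CalibrationParams, apply_calibration
from .spectra import (
    MN_SITES,
    BroadeningKernel,
    Spectrum,
    StickSpectrum,
    area,
    broaden_sticks,
    resample,
)

__all__ = [
    "RMSD_REGION",
    "EXCESS_REGION",
    "ModelEntry",
    "DifferencePair",
    "RankingResult",
    "build_common_grid",
    "rmsd_score",
    "model_spectrum",
    "preedge_excess",
    "rank_models",
]

# Default evaluation regions (eV) for the ranking statistic and the
# intensity-excess exclusion screen.
RMSD_REGION = (6538.0, 6544.5)
EXCESS_REGION = (6540.0, 6543.0)


@dataclass(frozen=True)
class ModelEntry:
    """One candidate structural model: four per-site stick spectra plus
    an ammonia-binding-mode class label."""

    model_id: str
    site_sticks: tuple[StickSpectrum, ...]
    binding_mode_class: str = "unknown"

    def __post_init__(self) -> None:
        sticks = tuple(self.site_sticks)
        sites = tuple(s.site for s in sticks)
        if sorted(sites) != sorted(MN_SITES):
            raise ValueError(
                f"model {self.model_id!r} must provide exactly the four sites "
                f"{MN_SITES}, got {sites}"
            )
        object.__setattr__(
            self, "site_sticks", tuple(sorted(sticks, key=lambda s: s.site))
        )

    def site(self, name: str) -> StickSpectrum:
        for s in self.site_sticks:
            if s.site == name:
                return s
        raise KeyError(name)


@dataclass(frozen=True)
class DifferencePair:
    """Experimental and calculated difference spectra resampled onto one
    common grid over ``region``."""

    exp_diff: Spectrum
    calc_diff: Spectrum
    region: tuple[float, float]
    n_points: int

    def __post_init__(self) -> None:
        if self.exp_diff.energies.shape != self.calc_diff.energies.shape or not np.allclose(
            self.exp_diff.energies, self.calc_diff.energies, rtol=0, atol=1e-9
        ):
            raise ValueError("difference spectra must share one common grid")
        if len(self.exp_diff) != self.n_points:
            raise ValueError("n_points does not match the grid length")


@dataclass(frozen=True)
class RankingResult:
    """Per-model score: RMSD, rank (None when excluded) and the
    exclusion flag with its reason."""

    model_id: str
    rmsd: float
    rank: int | None
    excluded: bool = False
    exclusion_reason: str = ""
    binding_mode_class: str = "unknown"
    excess: float = 0.0


def build_common_grid(
    region: Sequence[float] = RMSD_REGION, n_points: int = 240
) -> np.ndarray:
    """``n_points`` equally spaced energies spanning ``region`` inclusive."""
    lo, hi = float(region[0]), float(region[1])
    if not hi > lo:
        raise ValueError(f"region [{lo}, {hi}] is empty or inverted")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    return np.linspace(lo, hi, n_points)


def rmsd_score(d: DifferencePair) -> float:
    """Root-mean-square deviation between the two difference spectra
    over the common grid.  Symmetric; zero iff pointwise equal."""
    r = d.calc_diff.intensities - d.exp_diff.intensities
    return float(np.sqrt(np.mean(r**2)))


def model_spectrum(
    model: ModelEntry,
    kernel: BroadeningKernel,
    calibration: CalibrationParams,
    grid: np.ndarray,
    pad: float | None = None,
) -> Spectrum:
    """Broadened, site-summed, calibrated spectrum of ``model`` on ``grid``.

    Sticks are broadened on a fine native-axis grid covering
    ``grid - shift`` (padded by 5 FWHM), the four site curves are summed,
    the global calibration applied, and the result resampled onto ``grid``.
    """
    if pad is None:
        pad = 5.0 * kernel.fwhm
    lo = grid[0] - calibration.shift - pad
    hi = grid[-1] - calibration.shift + pad
    step = min(kernel.fwhm / 10.0, float(np.min(np.diff(grid))))
    fine = np.arange(lo, hi + step / 2, step)
    summed = broaden_sticks(model.site_sticks, kernel, fine)
    calibrated = apply_calibration(summed, calibration)
    out = resample(calibrated, grid)
    return out.with_intensities(out.intensities, model_id=model.model_id)


def preedge_excess(
    model_calc: Spectrum,
    native_calc: Spectrum,
    region: Sequence[float] = EXCESS_REGION,
    threshold: float = 0.25,
) -> tuple[float, bool]:
    """Relative pre-edge intensity excess of a model over the native
    spectrum, and whether it trips the exclusion screen.

    ``excess = (area_model - area_native) / area_native`` over
    ``region``; the model is excluded when the relative excess is larger
    than ``threshold``.
    """
    a_native = area(native_calc, region)
    if a_native <= 0:
        raise ValueError("native spectrum has non-positive area over the region")
    a_model = area(model_calc, region)
    excess = (a_model - a_native) / a_native
    return float(excess), bool(excess > threshold)


def rank_models(
    models: Iterable[ModelEntry],
    native: ModelEntry,
    exp_diff: Spectrum,
    kernel: BroadeningKernel,
    calibration: CalibrationParams,
    region: Sequence[float] = RMSD_REGION,
    n_points: int = 240,
    excess_region: Sequence[float] = EXCESS_REGION,
    excess_threshold: float = 0.25,
    apply_exclusion: bool = True,
) -> list[RankingResult]:
    """Score and rank candidate models against the experimental
    difference spectrum.

    For each model: broaden + sum the four site stick spectra, apply
    the frozen global calibration, subtract the native calculated
    spectrum, resample onto the common grid and compute the RMSD
    against ``exp_diff``.  Results are sorted by ascending RMSD with
    ties broken by ``model_id``; excluded models keep their score but
    receive no rank.
    """
    grid = build_common_grid(region, n_points)
    exp_on_grid = resample(exp_diff, grid)
    native_calc = model_spectrum(native, kernel, calibration, grid)

    scored: list[RankingResult] = []
    errors: dict[str, str] = {}
    for model in models:
        try:
            calc = model_spectrum(model, kernel, calibration, grid)
        except Exception as exc:  # missing site, coverage, ...
            errors[model.model_id] = str(exc)
            continue
        calc_diff = calc.with_intensities(calc.intensities - native_calc.intensities)
        pair = DifferencePair(
            exp_diff=exp_on_grid, calc_diff=calc_diff, region=tuple(grid[[0, -1]]),
            n_points=n_points,
        )
        score = rmsd_score(pair)
        excess, tripped = preedge_excess(
            calc, native_calc, excess_region, excess_threshold
        )
        excluded = bool(tripped and apply_exclusion)
        scored.append(
            RankingResult(
                model_id=model.model_id,
                rmsd=score,
                rank=None,
                excluded=excluded,
                exclusion_reason=(
                    f"pre-edge intensity excess {excess:.3f} > {excess_threshold:g} "
                    f"over {tuple(excess_region)} eV"
                    if excluded
                    else ""
                ),
                binding_mode_class=model.binding_mode_class,
                excess=excess,
            )
        )
    if errors and not scored:
        raise ValueError(f"all models failed: {errors}")

    scored.sort(key=lambda r: (r.rmsd, r.model_id))
    results: list[RankingResult] = []
    next_rank = 1
    for r in scored:
        if r.excluded:
            results.append(r)
        else:
            results.append(
                RankingResult(
                    model_id=r.model_id,
                    rmsd=r.rmsd,
                    rank=next_rank,
                    excluded=False,
                    exclusion_reason="",
                    binding_mode_class=r.binding_mode_class,
                    excess=r.excess,
                )
            )
            next_rank += 1
    for mid, msg in errors.items():
        results.append(
            RankingResult(
                model_id=mid,
                rmsd=float("nan"),
                rank=None,
                excluded=True,
                exclusion_reason=f"scoring failed: {msg}",
            )
        )
    return results
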