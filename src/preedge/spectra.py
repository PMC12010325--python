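"""Core spectrum representation and manipulations.

A :class:`Spectrum` is the universal currency of the pipeline: an
energy grid (eV, strictly increasing) with intensities in arbitrary
units.  A :class:`StickSpectrum` holds discrete calculated transitions
(energy, intensity) for a single Mn site before lineshape broadening.

Operations here are deliberately simple and well defined: linear
resampling, boxcar binning, trapezoidal integration, area
normalization, pointwise arithmetic and unit-area kernel broadening.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Spectrum",
    "StickSpectrum",
    "BroadeningKernel",
    "MN_SITES",
    "resample",
    "boxcar_bin",
    "area",
    "area_normalize",
    "subtract_spectra",
    "sum_spectra",
    "broaden_sticks",
]

MN_SITES = ("Mn1", "Mn2", "Mn3", "Mn4")


@dataclass(frozen=True)
class Spectrum:
    """An intensity curve on a strictly increasing energy grid (eV).

    Parameters
    ----------
    energies : array-like of float
        Strictly increasing photon energies in eV.
    intensities : array-like of float
        Intensities in arbitrary units.  Negative values are allowed
        (difference spectra); all values must be finite.
    meta : dict
        Free-form labels, e.g. ``state`` (S1/S2/unknown), ``treatment``
        (native/NH3/synthetic), provenance strings, applied calibration.
    """

    energies: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if e.ndim != 1 or y.ndim != 1:
            raise ValueError("energies and intensities must be 1-D")
        if e.size != y.size:
            raise ValueError(
                f"length mismatch: {e.size} energies vs {y.size} intensities"
            )
        if e.size == 0:
            raise ValueError("spectrum must contain at least one point")
        if not (np.all(np.isfinite(e)) and np.all(np.isfinite(y))):
            raise ValueError("spectrum contains non-finite values")
        if e.size > 1 and not np.all(np.diff(e) > 0):
            raise ValueError("energies must be strictly increasing")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "intensities", y)
        object.__setattr__(self, "meta", dict(self.meta))

    def __len__(self) -> int:
        return self.energies.size

    @property
    def span(self) -> tuple[float, float]:
        return float(self.energies[0]), float(self.energies[-1])

    def with_intensities(self, intensities: np.ndarray, **meta_updates) -> "Spectrum":
        """New spectrum on the same grid with replaced intensities."""
        meta = {**self.meta, **meta_updates}
        return Spectrum(self.energies, np.asarray(intensities, dtype=float), meta)

    def copy(self) -> "Spectrum":
        return Spectrum(self.energies.copy(), self.intensities.copy(), dict(self.meta))


@dataclass(frozen=True)
class StickSpectrum:
    """Discrete transitions for one Mn site: (energy eV, intensity >= 0)."""

    site: str
    energies: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        if self.site not in MN_SITES:
            raise ValueError(f"unknown site {self.site!r}; expected one of {MN_SITES}")
        e = np.asarray(self.energies, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if e.shape != y.shape or e.ndim != 1:
            raise ValueError("transition energies/intensities must be matching 1-D arrays")
        if e.size and not (np.all(np.isfinite(e)) and np.all(np.isfinite(y))):
            raise ValueError("stick spectrum contains non-finite values")
        if np.any(y < 0):
            raise ValueError("stick intensities must be non-negative")
        order = np.argsort(e, kind="stable")
        object.__setattr__(self, "energies", e[order])
        object.__setattr__(self, "intensities", y[order])

    def __len__(self) -> int:
        return self.energies.size

    @property
    def total_intensity(self) -> float:
        return float(self.intensities.sum())


@dataclass(frozen=True)
class BroadeningKernel:
    """Unit-area lineshape used to broaden stick spectra.

    ``shape`` is one of ``gaussian``, ``lorentzian`` or ``pseudo_voigt``;
    ``fwhm`` is the full width at half maximum in eV.  For
    ``pseudo_voigt``, ``mixing`` is the Lorentzian fraction eta in
    [0, 1] of the standard linear combination
    ``eta * L(fwhm) + (1 - eta) * G(fwhm)``.
    """

    shape: str = "gaussian"
    fwhm: float = 1.0
    mixing: float = 0.5

    def __post_init__(self) -> None:
        if self.shape not in ("gaussian", "lorentzian", "pseudo_voigt"):
            raise ValueError(f"unknown kernel shape {self.shape!r}")
        if not (self.fwhm > 0):
            raise ValueError("kernel fwhm must be > 0")
        if not (0.0 <= self.mixing <= 1.0):
            raise ValueError("pseudo-Voigt mixing must be in [0, 1]")

    def profile(self, delta: np.ndarray) -> np.ndarray:
        """Evaluate the unit-area kernel at offsets ``delta`` (eV)."""
        d = np.asarray(delta, dtype=float)
        if self.shape == "gaussian":
            return _gaussian_profile(d, self.fwhm)
        if self.shape == "lorentzian":
            return _lorentzian_profile(d, self.fwhm)
        return (
            self.mixing * _lorentzian_profile(d, self.fwhm)
            + (1.0 - self.mixing) * _gaussian_profile(d, self.fwhm)
        )


def _gaussian_profile(d: np.ndarray, fwhm: float) -> np.ndarray:
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.exp(-0.5 * (d / sigma) ** 2) / (sigma * np.sqrt(2.0 * np.pi))


def _lorentzian_profile(d: np.ndarray, fwhm: float) -> np.ndarray:
    hwhm = fwhm / 2.0
    return hwhm / (np.pi * (d**2 + hwhm**2))


def resample(s: Spectrum, grid: Sequence[float]) -> Spectrum:
    """Piecewise-linear interpolation of ``s`` onto ``grid``.

    The grid must lie within the span of ``s``; extrapolation is never
    performed.  Metadata is preserved.
    """
    g = np.asarray(grid, dtype=float)
    if g.ndim != 1 or g.size == 0:
        raise ValueError("grid must be a non-empty 1-D sequence")
    if g.size > 1 and not np.all(np.diff(g) > 0):
        raise ValueError("grid must be strictly increasing")
    lo, hi = s.span
    if g[0] < lo - 1e-12 or g[-1] > hi + 1e-12:
        raise ValueError(
            f"grid [{g[0]:.4f}, {g[-1]:.4f}] exceeds spectrum span "
            f"[{lo:.4f}, {hi:.4f}]; extrapolation is not allowed"
        )
    y = np.interp(np.clip(g, lo, hi), s.energies, s.intensities)
    return Spectrum(g, y, dict(s.meta))


def boxcar_bin(s: Spectrum, window: int) -> Spectrum:
    """Centered moving average with an odd ``window``; grid unchanged.

    At the edges the window is truncated to the available points, so
    e.g. intensities [0, 1, 2, 3, 4] with window 3 become
    [0.5, 1, 2, 3, 3.5].
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be an odd positive integer")
    n = len(s)
    if window > n:
        raise ValueError(f"window {window} exceeds spectrum length {n}")
    if window == 1:
        return s.with_intensities(s.intensities.copy())
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(s.intensities)))
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    y = (csum[hi] - csum[lo]) / (hi - lo)
    return s.with_intensities(y)


def _region_slice(s: Spectrum, region: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Grid points inside ``region`` with interpolated endpoints added."""
    a, b = float(region[0]), float(region[1])
    if not b > a:
        raise ValueError(f"region [{a}, {b}] is empty or inverted")
    lo, hi = s.span
    if a < lo - 1e-12 or b > hi + 1e-12:
        raise ValueError(f"region [{a}, {b}] outside spectrum span [{lo}, {hi}]")
    a, b = max(a, lo), min(b, hi)
    inside = (s.energies > a) & (s.energies < b)
    e = np.concatenate(([a], s.energies[inside], [b]))
    y = np.interp(e, s.energies, s.intensities)
    return e, y


def area(s: Spectrum, region: Sequence[float]) -> float:
    """Trapezoidal integral of ``s`` over ``region`` (endpoints by
    linear interpolation)."""
    e, y = _region_slice(s, region)
    return float(np.trapezoid(y, e))


def area_normalize(
    s: Spectrum, region: Sequence[float], target_area: float = 1.0
) -> Spectrum:
    """Scale intensities so the integral over ``region`` equals
    ``target_area``."""
    if not target_area > 0:
        raise ValueError("target_area must be positive")
    current = area(s, region)
    if current <= 0:
        raise ValueError(f"area over region is {current}; cannot normalize")
    factor = target_area / current
    return s.with_intensities(s.intensities * factor, normalized_region=tuple(region))


def subtract_spectra(a: Spectrum, b: Spectrum) -> Spectrum:
    """Pointwise ``a - b`` on ``a``'s grid; ``b`` is resampled first if
    the grids differ.  Result may be negative."""
    if b.energies.shape != a.energies.shape or not np.allclose(
        b.energies, a.energies, rtol=0, atol=1e-9
    ):
        b = resample(b, a.energies)
    return a.with_intensities(a.intensities - b.intensities)


def sum_spectra(parts: Iterable[Spectrum]) -> Spectrum:
    """Pointwise sum of spectra sharing one grid (others are resampled
    to the first grid)."""
    parts = list(parts)
    if not parts:
        raise ValueError("cannot sum an empty sequence of spectra")
    first = parts[0]
    total = first.intensities.copy()
    for p in parts[1:]:
        if p.energies.shape != first.energies.shape or not np.allclose(
            p.energies, first.energies, rtol=0, atol=1e-9
        ):
            p = resample(p, first.energies)
        total += p.intensities
    return first.with_intensities(total)


def broaden_sticks(
    sticks: StickSpectrum | Iterable[StickSpectrum],
    kernel: BroadeningKernel,
    grid: Sequence[float],
) -> Spectrum:
    """Convolve discrete transitions with a unit-area kernel on ``grid``.

    The result is ``sum_t I_t * K(E - E_t)``; because the kernel has
    unit area, the integral over an enclosing region equals the total
    stick intensity.  An empty transition list yields a zero spectrum.
    """
    g = np.asarray(grid, dtype=float)
    if g.ndim != 1 or g.size < 2:
        raise ValueError("grid must contain at least two points")
    if not np.all(np.diff(g) > 0):
        raise ValueError("grid must be strictly increasing")
    if isinstance(sticks, StickSpectrum):
        stick_list = [sticks]
    else:
        stick_list = list(sticks)
    y = np.zeros_like(g)
    for st in stick_list:
        if len(st) == 0:
            continue
        # (n_grid, n_transitions) offsets; fine for TD-DFT-sized tables
        delta = g[:, None] - st.energies[None, :]
        y += kernel.profile(delta) @ st.intensities
    meta = {"kernel": kernel.shape, "fwhm_eV": kernel.fwhm}
    if len(stick_list) == 1:
        meta["site"] = stick_list[0].site
    return Spectrum(g, y, meta)
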