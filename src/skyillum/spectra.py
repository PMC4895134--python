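"""Wavelength-grid primitives shared by every pipeline stage.

A :class:`Spectrum` is a strictly ascending wavelength grid (nm) with one
value per grid point and a units tag.  All downstream stages (calibration,
colorimetry, model fitting) work on spectra resampled to a common 1-nm grid,
so the operations here are deliberately small and well specified:
linear resampling, moving-window median filtering, L2 normalisation,
band (trapezoidal) integration and single-wavelength anchoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np

__all__ = [
    "Units",
    "Spectrum",
    "WavelengthBand",
    "VIS_BAND",
    "UVA_BAND",
    "UVB_BAND",
    "resample_1nm",
    "median_filter",
    "l2_normalize",
    "band_irradiance",
    "normalize_at",
]


class Units:
    """Canonical units tags for spectra."""

    COUNTS = "counts"
    COUNTS_PER_S = "counts_per_s"
    RADIANCE = "radiance_W_m2_sr_nm"
    IRRADIANCE = "irradiance_W_m2_nm"
    RELATIVE = "relative"

    ALL = (COUNTS, COUNTS_PER_S, RADIANCE, IRRADIANCE, RELATIVE)


class SpectrumError(ValueError):
    """Raised for malformed or degenerate spectra."""


class RangeError(SpectrumError):
    """Requested wavelength range not covered by the source grid."""


class UnitsError(SpectrumError):
    """Operation applied to a spectrum with incompatible units."""


@dataclass(frozen=True)
class Spectrum:
    """A sampled spectrum: strictly ascending wavelengths (nm) and values.

    Parameters
    ----------
    wavelengths_nm :
        Strictly increasing array of sample wavelengths in nanometres.
    values :
        Array of the same length; must be finite.
    units :
        One of the :class:`Units` tags.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    units: str = Units.RELATIVE

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)
        if wl.ndim != 1 or vals.ndim != 1 or wl.size != vals.size:
            raise SpectrumError("wavelengths and values must be 1-D and same length")
        if wl.size < 2:
            raise SpectrumError("a spectrum needs at least 2 samples")
        if not np.all(np.diff(wl) > 0):
            raise SpectrumError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(vals)):
            raise SpectrumError("values must be finite")
        if self.units not in Units.ALL:
            raise UnitsError(f"unknown units tag {self.units!r}")

    def with_values(self, values: np.ndarray, units: str | None = None) -> "Spectrum":
        return Spectrum(self.wavelengths_nm, np.asarray(values, float),
                        self.units if units is None else units)

    def value_at(self, wavelength_nm: float) -> float:
        """Exact grid-point lookup (no interpolation)."""
        idx = np.flatnonzero(np.isclose(self.wavelengths_nm, wavelength_nm,
                                        rtol=0.0, atol=1e-9))
        if idx.size == 0:
            raise RangeError(f"{wavelength_nm} nm is not a grid point")
        return float(self.values[idx[0]])


@dataclass(frozen=True)
class WavelengthBand:
    """A labelled closed wavelength interval [lo_nm, hi_nm]."""

    lo_nm: float
    hi_nm: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.lo_nm < self.hi_nm:
            raise SpectrumError("band requires lo_nm < hi_nm")


VIS_BAND = WavelengthBand(400.0, 800.0, "VIS")
UVA_BAND = WavelengthBand(315.0, 400.0, "UV-A")
UVB_BAND = WavelengthBand(280.0, 315.0, "UV-B")


def resample_1nm(s: Spectrum, lo_nm: float, hi_nm: float) -> Spectrum:
    """Linearly interpolate a spectrum onto the 1-nm grid ``lo, lo+1, ..., hi``.

    The requested range must lie within the support of the source grid
    (no extrapolation).  Units are preserved.
    """
    if lo_nm >= hi_nm:
        raise RangeError("lo_nm must be < hi_nm")
    wl = s.wavelengths_nm
    if lo_nm < wl[0] - 1e-9 or hi_nm > wl[-1] + 1e-9:
        raise RangeError(
            f"requested [{lo_nm}, {hi_nm}] nm outside source support "
            f"[{wl[0]}, {wl[-1]}] nm")
    grid = np.arange(float(lo_nm), float(hi_nm) + 0.5, 1.0)
    vals = np.interp(grid, wl, s.values)
    return Spectrum(grid, vals, s.units)


def median_filter(s: Spectrum, order: int = 8) -> Spectrum:
    """Moving-window median with window length ``order + 1``.

    Windows are truncated at the array boundaries: each output sample is the
    median of the available samples in the symmetric window, so no data is
    fabricated beyond the grid.  For even windows the usual midpoint-average
    median applies.
    """
    if order < 1:
        raise SpectrumError("order must be >= 1")
    n = s.values.size
    half_lo = order // 2
    half_hi = order - half_lo  # window = [i - half_lo, i + half_hi]
    out = np.empty(n)
    v = s.values
    window = order + 1
    if n >= window:
        # full (untruncated) windows, vectorised
        sw = np.lib.stride_tricks.sliding_window_view(v, window)
        out[half_lo:n - half_hi] = np.median(sw, axis=1)
        edge = [i for i in range(half_lo)] + [i for i in range(n - half_hi, n)]
    else:
        edge = range(n)
    for i in edge:
        lo = max(0, i - half_lo)
        hi = min(n, i + half_hi + 1)
        out[i] = np.median(v[lo:hi])
    return s.with_values(out)


def l2_normalize(s: Spectrum) -> Tuple[Spectrum, float]:
    """Divide a spectrum by its Euclidean (L2) norm; return (unit spectrum, norm)."""
    norm = float(np.linalg.norm(s.values))
    if norm == 0.0:
        raise SpectrumError("cannot L2-normalise an all-zero spectrum")
    return s.with_values(s.values / norm), norm


def band_irradiance(s: Spectrum, band: WavelengthBand) -> float:
    """Trapezoidal integral of spectral irradiance over a band, in W·m⁻².

    The spectrum must carry irradiance units and overlap the band.  Grid
    points outside the band are excluded; the band edges themselves are
    included by interpolation when they fall inside the grid support.
    """
    if s.units != Units.IRRADIANCE:
        raise UnitsError(f"band_irradiance needs irradiance units, got {s.units!r}")
    wl, v = s.wavelengths_nm, s.values
    lo = max(band.lo_nm, wl[0])
    hi = min(band.hi_nm, wl[-1])
    if lo >= hi:
        raise RangeError(f"band [{band.lo_nm}, {band.hi_nm}] nm does not overlap grid")
    inside = (wl > lo) & (wl < hi)
    xs = np.concatenate([[lo], wl[inside], [hi]])
    ys = np.concatenate([[np.interp(lo, wl, v)], v[inside], [np.interp(hi, wl, v)]])
    return float(np.trapezoid(ys, xs))


def normalize_at(s: Spectrum, anchor_nm: float = 555.0) -> Spectrum:
    """Scale a spectrum so its value at the anchor wavelength is exactly 1.

    The anchor must be an exact grid point (resample to 1 nm first) with a
    strictly positive value.
    """
    anchor_value = s.value_at(anchor_nm)
    if anchor_value <= 0.0:
        raise SpectrumError(
            f"value at {anchor_nm} nm is {anchor_value}; must be > 0 to anchor")
    return s.with_values(s.values / anchor_value, Units.RELATIVE)
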