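"""CIE 1931 colorimetry: tristimulus integration, chromaticity, the daylight
locus generator and sRGB pseudo-colour rendering of binned sky spectra.

The 2° standard-observer colour-matching functions and the daylight
components S0/S1/S2 are shipped as data tables (5-nm and 10-nm tabulations
of the published standards) and interpolated to the working 1-nm grid at
load time.  The daylight generator follows the standard construction: the
CCT → x_D polynomial, the daylight-locus parabola y_D(x_D), the M1/M2
weights, and S(λ) = S0 + M1·S1 + M2·S2 with the classical (un-normalised)
component scaling.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .spectra import RangeError, Spectrum, SpectrumError, Units

__all__ = [
    "ChromaticityPoint", "ColorMatchingFunctions", "load_cmf",
    "load_daylight_components", "xyz_from_spectrum", "xy_from_xyz",
    "daylight_chromaticity", "cie_daylight_spectrum", "daylight_locus",
    "render_srgb", "CMF_RANGE_NM",
]

CMF_RANGE_NM = (360.0, 830.0)

# linear sRGB (D65) matrix, IEC 61966-2-1
_XYZ_TO_SRGB = np.array([
    [3.2406, -1.5372, -0.4986],
    [-0.9689, 1.8758, 0.0415],
    [0.0557, -0.2040, 1.0570],
])


@dataclass(frozen=True)
class ChromaticityPoint:
    x: float
    y: float

    def __post_init__(self) -> None:
        if not (0.0 < self.x < 1.0 and 0.0 < self.y < 1.0 and
                self.x + self.y < 1.0):
            raise SpectrumError(f"({self.x}, {self.y}) is not a valid chromaticity")


@dataclass(frozen=True)
class ColorMatchingFunctions:
    """x̄, ȳ, z̄ tabulated on a 1-nm grid."""

    wavelengths_nm: np.ndarray
    xbar: np.ndarray
    ybar: np.ndarray
    zbar: np.ndarray


def _data_table(name: str) -> pd.DataFrame:
    with resources.files("skyillum.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


@lru_cache(maxsize=1)
def load_cmf() -> ColorMatchingFunctions:
    """CIE 1931 2° observer CMFs, interpolated 5 nm → 1 nm over 360–830 nm."""
    tab = _data_table("cie_1931_2deg_cmf_5nm.csv")
    grid = np.arange(CMF_RANGE_NM[0], CMF_RANGE_NM[1] + 0.5, 1.0)
    wl = tab["wavelength_nm"].to_numpy(float)
    cols = [np.interp(grid, wl, tab[c].to_numpy(float))
            for c in ("xbar", "ybar", "zbar")]
    return ColorMatchingFunctions(grid, *cols)


@lru_cache(maxsize=1)
def load_daylight_components() -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Classical (un-normalised) S0, S1, S2 splined 10 nm → 1 nm, 360–830 nm.

    Returns (grid, S0, S1, S2).
    """
    tab = _data_table("cie_daylight_components_10nm.csv")
    grid = np.arange(CMF_RANGE_NM[0], CMF_RANGE_NM[1] + 0.5, 1.0)
    wl = tab["wavelength_nm"].to_numpy(float)
    comps = tuple(
        CubicSpline(wl, tab[c].to_numpy(float))(grid) for c in ("S0", "S1", "S2"))
    return (grid,) + comps


def xyz_from_spectrum(s: Spectrum,
                      cmf: ColorMatchingFunctions | None = None
                      ) -> Tuple[float, float, float]:
    """Tristimulus values X, Y, Z as CMF-weighted sums over the common grid."""
    cmf = cmf or load_cmf()
    wl = s.wavelengths_nm
    lo = max(wl[0], cmf.wavelengths_nm[0])
    hi = min(wl[-1], cmf.wavelengths_nm[-1])
    if lo > hi:
        raise RangeError("spectrum does not overlap the CMF range")
    sel_s = (wl >= lo) & (wl <= hi)
    sel_c = (cmf.wavelengths_nm >= lo) & (cmf.wavelengths_nm <= hi)
    if sel_s.sum() != sel_c.sum() or not np.allclose(
            wl[sel_s], cmf.wavelengths_nm[sel_c]):
        raise RangeError("spectrum must be on the 1-nm grid to integrate CMFs")
    v = s.values[sel_s]
    return (float(np.sum(v * cmf.xbar[sel_c])),
            float(np.sum(v * cmf.ybar[sel_c])),
            float(np.sum(v * cmf.zbar[sel_c])))


def xy_from_xyz(X: float, Y: float, Z: float) -> ChromaticityPoint:
    total = X + Y + Z
    if total <= 0:
        raise SpectrumError("cannot form chromaticity from non-positive X+Y+Z")
    return ChromaticityPoint(X / total, Y / total)


def daylight_chromaticity(cct_K: float) -> ChromaticityPoint:
    """Chromaticity on the CIE daylight locus for a given CCT in kelvin."""
    T = float(cct_K)
    if not 4000.0 <= T <= 25000.0:
        raise SpectrumError("CCT must lie in [4000, 25000] K")
    if T <= 7000.0:
        x = (0.244063 + 0.09911e3 / T + 2.9678e6 / T ** 2
             - 4.6070e9 / T ** 3)
    else:
        x = (0.237040 + 0.24748e3 / T + 1.9018e6 / T ** 2
             - 2.0064e9 / T ** 3)
    y = -3.000 * x * x + 2.870 * x - 0.275
    return ChromaticityPoint(x, y)


def cie_daylight_spectrum(cct_K: float) -> Spectrum:
    """CIE daylight spectral power distribution at a given CCT (relative units).

    Standard construction: x_D from the CCT polynomial, y_D from the locus
    parabola, weights M1, M2 from (x_D, y_D), and the classical
    (un-normalised) components combined as S0 + M1·S1 + M2·S2 on the 1-nm
    360–830 nm grid.
    """
    p = daylight_chromaticity(cct_K)
    M = 0.0241 + 0.2562 * p.x - 0.7341 * p.y
    M1 = (-1.3515 - 1.7703 * p.x + 5.9114 * p.y) / M
    M2 = (0.0300 - 31.4424 * p.x + 30.0717 * p.y) / M
    grid, S0, S1, S2 = load_daylight_components()
    return Spectrum(grid, S0 + M1 * S1 + M2 * S2, Units.RELATIVE)


def daylight_locus(cct_grid: Sequence[float]) -> List[ChromaticityPoint]:
    """Chromaticities of CIE daylight spectra along a CCT grid."""
    out = []
    for T in cct_grid:
        s = cie_daylight_spectrum(T)
        out.append(xy_from_xyz(*xyz_from_spectrum(s)))
    return out


def _gamma_encode(c: np.ndarray) -> np.ndarray:
    c = np.clip(c, 0.0, None)
    return np.where(c <= 0.0031308, 12.92 * c,
                    1.055 * np.power(c, 1.0 / 2.4) - 0.055)


def render_srgb(binned: Sequence[Tuple[float, Spectrum, float]]
                ) -> List[Tuple[float, float, float, float]]:
    """Pseudo-colour swatches for binned spectra.

    ``binned`` is a sequence of ``(bin_center_deg, unit_spectrum, norm)``
    where the spectrum is L2-normalised and ``norm`` is its pre-normalisation
    L2 norm.  log10 of the norms is rescaled into [0.3, 1]; each unit
    spectrum is multiplied by its scale, converted to XYZ, mapped through
    the linear sRGB matrix with per-channel gamut clipping, and gamma
    encoded.  Returns ``(bin_center_deg, R, G, B)`` rows with channels in
    [0, 1].
    """
    if len(binned) < 2:
        raise SpectrumError("need at least 2 bins to scale the rendering")
    norms = np.array([n for _, _, n in binned], float)
    if np.any(norms <= 0):
        raise SpectrumError("norms must be positive")
    logs = np.log10(norms)
    span = logs.max() - logs.min()
    if span == 0:
        scales = np.ones_like(logs)
    else:
        scales = 0.3 + 0.7 * (logs - logs.min()) / span
    out = []
    # normalise overall luminance so the brightest bin renders near full scale
    ymax = None
    xyzs = []
    for (center, unit, _), scale in zip(binned, scales):
        X, Y, Z = xyz_from_spectrum(unit)
        xyzs.append(np.array([X, Y, Z]) * scale)
    ymax = max(v[1] for v in xyzs)
    if ymax <= 0:
        raise SpectrumError("all rendered spectra have zero luminance")
    for (center, _, _), xyz in zip(binned, xyzs):
        rgb_lin = _XYZ_TO_SRGB @ (xyz / ymax)
        rgb = _gamma_encode(np.clip(rgb_lin, 0.0, 1.0))
        out.append((center, float(rgb[0]), float(rgb[1]), float(rgb[2])))
    return out
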