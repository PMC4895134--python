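"""Linear basis-model fitting of L2-normalised irradiance spectra.

The workhorse of the analysis: ordinary least squares (no intercept) of a
unit-norm measured spectrum on a set of unit-norm basis components, with the
goodness of fit reported as the squared Pearson correlation between the
fitted and measured values across wavelengths.  The squared-correlation R²
is the quantity tracked against solar elevation; the SSE-based coefficient
of determination is computed alongside because the two differ when the fit
is biased, and only the SSE is guaranteed monotone under basis nesting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .colorimetry import load_daylight_components
from .ephemeris import ObservationRecord, bin_by_elevation
from .spectra import Spectrum, SpectrumError, Units, l2_normalize, resample_1nm

__all__ = ["BasisSet", "FitResult", "load_cie_basis", "fit_spectrum",
           "fit_set", "FitError"]

_COND_LIMIT = 1e10


class FitError(ValueError):
    pass


@dataclass(frozen=True)
class BasisSet:
    """Named ordered set of unit-L2-norm component spectra on a shared 1-nm grid."""

    name: str
    wavelengths_nm: np.ndarray
    components: Tuple[np.ndarray, ...]
    component_names: Tuple[str, ...]
    fit_range_nm: Tuple[float, float] = (360.0, 830.0)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, float)
        comps = tuple(np.asarray(c, float) for c in self.components)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "components", comps)
        if len(comps) != len(self.component_names):
            raise FitError("component/name count mismatch")
        for c in comps:
            if c.shape != wl.shape:
                raise FitError("all components must share the wavelength grid")
            if abs(np.linalg.norm(c) - 1.0) > 1e-10:
                raise FitError("components must be L2-normalised to 1")
        lo, hi = self.fit_range_nm
        if lo < wl[0] - 1e-9 or hi > wl[-1] + 1e-9:
            raise FitError("fit range outside basis grid")

    @property
    def n_components(self) -> int:
        return len(self.components)

    def design_matrix(self) -> np.ndarray:
        """Components restricted to the fit range, stacked as columns."""
        lo, hi = self.fit_range_nm
        sel = (self.wavelengths_nm >= lo) & (self.wavelengths_nm <= hi)
        return np.column_stack([c[sel] for c in self.components])

    def fit_wavelengths(self) -> np.ndarray:
        lo, hi = self.fit_range_nm
        sel = (self.wavelengths_nm >= lo) & (self.wavelengths_nm <= hi)
        return self.wavelengths_nm[sel]

    def extended(self, component: np.ndarray, name: str, new_name: str
                 ) -> "BasisSet":
        """Append one unit-norm component, returning a new basis set."""
        comp = np.asarray(component, float)
        return BasisSet(new_name, self.wavelengths_nm,
                        self.components + (comp,),
                        self.component_names + (name,), self.fit_range_nm)


@dataclass(frozen=True)
class FitResult:
    """Least-squares weights on the unit-norm spectrum, the L2 scale of the
    raw spectrum, and both goodness-of-fit statistics."""

    weights: np.ndarray
    scale: float
    r_squared: float       # squared Pearson correlation (reported statistic)
    r_squared_sse: float   # 1 - SSE/SST
    sse: float
    fitted: np.ndarray
    residual: np.ndarray


def load_cie_basis(fit_range_nm: Tuple[float, float] = (360.0, 830.0)
                   ) -> BasisSet:
    """The 3-component CIE daylight basis (S0, S1, S2), splined to 1 nm over
    360–830 nm and L2-normalised for fitting."""
    grid, S0, S1, S2 = load_daylight_components()
    comps = []
    for c in (S0, S1, S2):
        comps.append(c / np.linalg.norm(c))
    return BasisSet("CIE", grid, tuple(comps), ("S0", "S1", "S2"),
                    fit_range_nm)


def fit_spectrum(basis: BasisSet, s: Spectrum) -> FitResult:
    """Fit one spectrum with a basis set.

    The spectrum is resampled to the basis fit range, L2-normalised (the
    norm is recorded as the scale factor) and regressed on the components by
    ordinary least squares without an intercept.  R² is the squared Pearson
    correlation between fitted and measured values across wavelengths.
    """
    lo, hi = basis.fit_range_nm
    rs = resample_1nm(s, lo, hi)
    if not np.array_equal(rs.wavelengths_nm, basis.fit_wavelengths()):
        raise FitError("resampled spectrum does not align with basis grid")
    unit, scale = l2_normalize(rs)
    A = basis.design_matrix()
    if np.linalg.cond(A) > _COND_LIMIT:
        raise FitError("basis is rank-deficient for fitting")
    y = unit.values
    w, *_ = np.linalg.lstsq(A, y, rcond=None)
    fitted = A @ w
    resid = y - fitted
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2_sse = 1.0 - sse / sst if sst > 0 else float("nan")
    sf, sy = fitted.std(), y.std()
    # an (almost) constant fitted vector carries no wavelength structure;
    # its correlation with the data is numerical noise, so report 0
    if sy == 0 or sf <= 1e-10 * sy:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(fitted, y)[0, 1]) ** 2
    return FitResult(weights=w, scale=scale, r_squared=r2,
                     r_squared_sse=r2_sse, sse=sse, fitted=fitted,
                     residual=resid)


def fit_set(basis: BasisSet, records: Iterable[ObservationRecord],
            bin_width_deg: float = 2.0) -> pd.DataFrame:
    """Fit every record and aggregate by solar-elevation bin.

    Returns a DataFrame with one row per non-empty bin: the per-component
    mean and SD of the weights, the mean scale factor, the mean R² and the
    record count.
    """
    bins = bin_by_elevation(records, bin_width_deg)
    rows = []
    for center, recs in bins.items():
        fits = [fit_spectrum(basis, r.spectrum) for r in recs]
        W = np.array([f.weights for f in fits])
        row: Dict[str, float] = {"bin_center_deg": center, "n_records": len(recs)}
        for k, name in enumerate(basis.component_names):
            row[f"weight_{name}_mean"] = float(W[:, k].mean())
            row[f"weight_{name}_sd"] = float(W[:, k].std(ddof=0))
        row["scale_mean"] = float(np.mean([f.scale for f in fits]))
        row["r2_mean"] = float(np.mean([f.r_squared for f in fits]))
        rows.append(row)
    return pd.DataFrame(rows)
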