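"""Iterative residual extension of the CIE daylight basis.

The CIE daylight model describes daylight well but fails through twilight
and at night.  The extension procedure grows it empirically, one component
per illumination regime, by fitting the current model and averaging the
fit residuals of the unit-norm spectra:

* stage 1 — fit the 3-component CIE basis to all daylight spectra
  (θs ≥ 0°, both locations pooled); the normalised mean residual becomes
  the CIE+1 component;
* stage 2 — fit the CIE+1 model to all civil-twilight spectra
  (−6° < θs < 0°, both locations pooled); the normalised mean residual
  becomes the CIE+2 component;
* stage 3 — fit the CIE+2 model to astronomical-twilight spectra
  (−18° < θs < −12°) separately per location; the normalised mean residuals
  become the location-specific sixth components, yielding the CIE+3R
  (rural) and CIE+3C (city) 6-component models.

Residuals are averaged across spectra first and the mean is then divided by
its Euclidean norm; components are appended without orthogonalisation and
with their sign as computed (downstream weights absorb the sign).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .ephemeris import ObservationRecord, bin_by_elevation
from .fitting import BasisSet, FitError, fit_spectrum
from .spectra import Spectrum, Units, l2_normalize, resample_1nm

__all__ = ["ExtensionStage", "ExtensionError", "mean_residual", "extend_cie",
           "compare_models", "mean_spectrum_benchmark"]

_DEGENERATE_NORM = 1e-12

# regime windows used for component derivation (strict inequalities; the
# nautical band is evaluated but never used for derivation)
STAGE_REGIMES = {
    1: ("daylight", lambda th: th >= 0.0),
    2: ("civil twilight", lambda th: -6.0 < th < 0.0),
    3: ("astronomical twilight", lambda th: -18.0 < th < -12.0),
}


class ExtensionError(ValueError):
    pass


@dataclass(frozen=True)
class ExtensionStage:
    stage_index: int
    regime_label: str
    locations: Tuple[str, ...]
    n_records: int
    derived_component: np.ndarray

    def __post_init__(self) -> None:
        if abs(np.linalg.norm(self.derived_component) - 1.0) > 1e-9:
            raise ExtensionError("derived component must be unit norm")


def mean_residual(basis: BasisSet, records: Sequence[ObservationRecord]
                  ) -> np.ndarray:
    """Unit-norm mean fit residual of a record subset under a basis.

    Each unit-norm spectrum is fitted by least squares; the residuals are
    averaged across spectra and the average is divided by its Euclidean
    norm.  Raises if the subset is empty or the mean residual is
    numerically zero (spectra lie in the basis span, or residuals cancel).
    """
    if len(records) == 0:
        raise ExtensionError("cannot extract a residual from an empty subset")
    acc = None
    for r in records:
        res = fit_spectrum(basis, r.spectrum).residual
        acc = res if acc is None else acc + res
    mean = acc / len(records)
    norm = float(np.linalg.norm(mean))
    if norm < _DEGENERATE_NORM:
        raise ExtensionError("mean residual is degenerate (within basis span)")
    return mean / norm


def _select(records: Iterable[ObservationRecord], stage: int
            ) -> List[ObservationRecord]:
    _, pred = STAGE_REGIMES[stage]
    return [r for r in records if pred(r.solar_elevation_deg)]


def extend_cie(rural_records: Sequence[ObservationRecord],
               city_records: Sequence[ObservationRecord],
               cie: BasisSet
               ) -> Tuple[BasisSet, BasisSet, List[ExtensionStage]]:
    """Run the three-stage residual extension.

    Rural records are expected to be pre-filtered for lunar fraction < 0.3.
    Returns the two 6-component models (CIE+3R, CIE+3C) and the stage
    provenance list.
    """
    stages: List[ExtensionStage] = []

    pooled = list(rural_records) + list(city_records)

    def run_stage(idx: int, basis: BasisSet,
                  records: Sequence[ObservationRecord],
                  locations: Tuple[str, ...]) -> np.ndarray:
        label, _ = STAGE_REGIMES[idx]
        subset = _select(records, idx)
        if not subset:
            raise ExtensionError(
                f"stage {idx}: no records in the {label} regime "
                f"for locations {locations}")
        comp = mean_residual(basis, subset)
        stages.append(ExtensionStage(idx, label, locations, len(subset), comp))
        return comp

    # pad stage components from the fit range back onto the full basis grid
    def on_grid(basis: BasisSet, comp: np.ndarray) -> np.ndarray:
        lo, hi = basis.fit_range_nm
        sel = (basis.wavelengths_nm >= lo) & (basis.wavelengths_nm <= hi)
        full = np.zeros_like(basis.wavelengths_nm)
        full[sel] = comp
        return full

    c1 = run_stage(1, cie, pooled, ("rural", "city"))
    cie1 = cie.extended(on_grid(cie, c1), "CIE+1", "CIE+1")
    c2 = run_stage(2, cie1, pooled, ("rural", "city"))
    cie2 = cie1.extended(on_grid(cie1, c2), "CIE+2", "CIE+2")
    c3r = run_stage(3, cie2, list(rural_records), ("rural",))
    c3c = run_stage(3, cie2, list(city_records), ("city",))
    cie3r = cie2.extended(on_grid(cie2, c3r), "CIE+3R", "CIE+3R")
    cie3c = cie2.extended(on_grid(cie2, c3c), "CIE+3C", "CIE+3C")
    return cie3r, cie3c, stages


def compare_models(models: Sequence[BasisSet],
                   records: Sequence[ObservationRecord],
                   bin_width_deg: float = 2.0) -> pd.DataFrame:
    """Per-bin mean R² profiles for several models over the same records.

    Returns a tidy DataFrame (model, bin_center_deg, r2_mean, n_records).
    """
    rows = []
    bins = bin_by_elevation(records, bin_width_deg)
    for model in models:
        for center, recs in bins.items():
            r2 = [fit_spectrum(model, r.spectrum).r_squared for r in recs]
            rows.append({"model": model.name, "bin_center_deg": center,
                         "r2_mean": float(np.mean(r2)),
                         "n_records": len(recs)})
    return pd.DataFrame(rows)


def mean_spectrum_benchmark(records: Sequence[ObservationRecord]
                            ) -> Tuple[float, BasisSet]:
    """Noise-floor reference: fit each spectrum with the subset's own mean.

    The mean of the unit-norm spectra (itself renormalised) is used as a
    single-component basis; the returned value is the mean R² across
    records.  To the extent the underlying illumination is unchanging, this
    quantifies measurement variability in R² terms.
    """
    if not records:
        raise ExtensionError("empty record set")
    template = None
    fr = None
    first = records[0].spectrum
    # resample all spectra onto the common fit grid of the CIE range
    lo, hi = 360.0, 830.0
    for r in records:
        unit, _ = l2_normalize(resample_1nm(r.spectrum, lo, hi))
        template = unit.values if template is None else template + unit.values
    template = template / np.linalg.norm(template)
    grid = np.arange(lo, hi + 0.5, 1.0)
    basis = BasisSet("mean-spectrum", grid, (template,), ("mean",), (lo, hi))
    r2 = [fit_spectrum(basis, r.spectrum).r_squared for r in records]
    return float(np.mean(r2)), basis
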