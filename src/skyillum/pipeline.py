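"""End-to-end analysis driver: calibration → ephemeris join → lunar filter →
colorimetry, CIE fits and basis extension, with tabular report outputs.

The stages mirror the measurement campaign's processing order and can be
run individually (see :mod:`skyillum.cli`) or in one call via
:func:`run_pipeline` on an in-memory :class:`~skyillum.synthetic.GeneratedDataset`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .calibration import (CorrectionFactors, HG_AR_LINES, RawFrame,
                          estimate_wavelength_shift, qc_filter)
from .colorimetry import render_srgb, xy_from_xyz, xyz_from_spectrum
from .ephemeris import (ObservationRecord, assign_sequence, bin_by_elevation,
                        interpolate_ephemeris, lunar_filter)
from .extension import compare_models, extend_cie
from .fitting import fit_set, load_cie_basis
from .spectra import (Spectrum, UVA_BAND, UVB_BAND, VIS_BAND, band_irradiance,
                      l2_normalize, resample_1nm)
from .synthetic import GeneratedDataset

__all__ = ["calibrate_campaign", "run_pipeline", "PipelineReport",
           "band_intensity_table", "chromaticity_table"]


def calibrate_campaign(ds: GeneratedDataset,
                       lunar_max_fraction: float = 0.3
                       ) -> Tuple[Dict[str, List[ObservationRecord]],
                                  pd.DataFrame]:
    """Calibrate every raw frame and join the observing geometry.

    Estimates each instrument's wavelength shift from its line-lamp frame,
    runs the QC screen and the counts → irradiance chain, attaches
    interpolated ephemeris values, labels dawn/dusk, and applies the lunar
    fraction filter (rural only).  Returns records per location plus a QC
    log DataFrame.
    """
    shifts = {iid: estimate_wavelength_shift(frame, HG_AR_LINES)[0]
              for iid, frame in ds.line_frames.items()}
    qc_rows = []
    records: Dict[str, List[ObservationRecord]] = {}
    meta = ds.frame_meta.set_index("frame_id")
    for location, frames in ds.raw_frames.items():
        tab = ds.ephemeris[location]
        recs: List[ObservationRecord] = []
        for iid in sorted({f.instrument_id for f in frames}):
            inst = ds.instrument(iid)
            cf = CorrectionFactors(ds.correction_factors[iid])
            subset = [f for f in frames if f.instrument_id == iid]
            kept, rejected = qc_filter(subset, ds.dark_libraries[iid],
                                       shifts[iid], cf, inst.output_range_nm)
            for raw, reason in rejected:
                qc_rows.append({"frame_id": raw.frame_id,
                                "location": location, "status": reason})
            for raw, spectrum in kept:
                m = meta.loc[raw.frame_id]
                theta, lunar, fraction = interpolate_ephemeris(
                    tab, m["timestamp"])
                recs.append(ObservationRecord(
                    spectrum=spectrum, timestamp=m["timestamp"],
                    location_id=location, solar_elevation_deg=theta,
                    lunar_elevation_deg=lunar, fraction_illuminated=fraction,
                    record_id=raw.frame_id))
                qc_rows.append({"frame_id": raw.frame_id,
                                "location": location, "status": "kept"})
        recs = assign_sequence(recs)
        records[location] = lunar_filter(recs, lunar_max_fraction)
    return records, pd.DataFrame(qc_rows)


def band_intensity_table(records: Sequence[ObservationRecord],
                         bin_width_deg: float = 2.0) -> pd.DataFrame:
    """Mean log10 band irradiance (VIS / UV-A / UV-B) per elevation bin,
    split by dawn/dusk sequence.  Bands a record's grid does not cover are
    reported as NaN (the daylight instrument has no UV-B coverage)."""
    rows = []
    for center, recs in bin_by_elevation(records, bin_width_deg).items():
        for sequence in ("dawn", "dusk"):
            sub = [r for r in recs if r.sequence == sequence]
            if not sub:
                continue
            row = {"bin_center_deg": center, "sequence": sequence,
                   "n_records": len(sub)}
            for band in (VIS_BAND, UVA_BAND, UVB_BAND):
                vals = []
                for r in sub:
                    wl = r.spectrum.wavelengths_nm
                    if wl[0] <= band.lo_nm and wl[-1] >= band.hi_nm:
                        vals.append(band_irradiance(r.spectrum, band))
                row[f"log10_{band.label}"] = (
                    float(np.log10(np.mean(vals))) if vals and
                    np.mean(vals) > 0 else float("nan"))
            rows.append(row)
    return pd.DataFrame(rows)


def chromaticity_table(records: Sequence[ObservationRecord],
                       bin_width_deg: float = 2.0) -> pd.DataFrame:
    """Mean CIE 1931 (x, y) chromaticity per solar-elevation bin."""
    rows = []
    for center, recs in bin_by_elevation(records, bin_width_deg).items():
        xs, ys = [], []
        for r in recs:
            s = resample_1nm(r.spectrum, 360.0, 830.0)
            p = xy_from_xyz(*xyz_from_spectrum(s))
            xs.append(p.x)
            ys.append(p.y)
        rows.append({"bin_center_deg": center, "x_mean": float(np.mean(xs)),
                     "y_mean": float(np.mean(ys)), "n_records": len(recs)})
    return pd.DataFrame(rows)


def srgb_table(records: Sequence[ObservationRecord],
               bin_width_deg: float = 2.0) -> pd.DataFrame:
    """sRGB pseudo-colour swatch per elevation bin (mean spectrum per bin,
    L2-normalised, log-norm intensity scaling)."""
    binned = []
    for center, recs in bin_by_elevation(records, bin_width_deg).items():
        mean = None
        for r in recs:
            s = resample_1nm(r.spectrum, 360.0, 830.0)
            mean = s.values if mean is None else mean + s.values
        mean = mean / len(recs)
        spec = Spectrum(np.arange(360.0, 831.0), mean, "irradiance_W_m2_nm")
        unit, norm = l2_normalize(spec)
        binned.append((center, unit, norm))
    rows = [{"bin_center_deg": c, "R": r, "G": g, "B": b}
            for c, r, g, b in render_srgb(binned)]
    return pd.DataFrame(rows)


@dataclass
class PipelineReport:
    """Bundle of every analysis table produced by one pipeline run."""

    records: Dict[str, List[ObservationRecord]]
    qc_log: pd.DataFrame
    band_intensity: Dict[str, pd.DataFrame]
    chromaticity: Dict[str, pd.DataFrame]
    srgb: Dict[str, pd.DataFrame]
    cie_fits: Dict[str, pd.DataFrame]
    model_comparison: Dict[str, pd.DataFrame]
    extended_bases: Dict[str, "BasisSet"]  # noqa: F821
    stages: list


def run_pipeline(ds: GeneratedDataset, bin_width_deg: float = 2.0,
                 lunar_max_fraction: float = 0.3) -> PipelineReport:
    """Run the full analysis on a generated campaign."""
    records, qc_log = calibrate_campaign(ds, lunar_max_fraction)
    cie = load_cie_basis()
    cie3r, cie3c, stages = extend_cie(records["rural"], records["city"], cie)
    report = PipelineReport(
        records=records, qc_log=qc_log, band_intensity={}, chromaticity={},
        srgb={}, cie_fits={}, model_comparison={},
        extended_bases={"CIE+3R": cie3r, "CIE+3C": cie3c}, stages=stages)
    for location, recs in records.items():
        report.band_intensity[location] = band_intensity_table(recs,
                                                               bin_width_deg)
        report.chromaticity[location] = chromaticity_table(recs, bin_width_deg)
        report.srgb[location] = srgb_table(recs, bin_width_deg)
        report.cie_fits[location] = fit_set(cie, recs, bin_width_deg)
        model = cie3r if location == "rural" else cie3c
        report.model_comparison[location] = compare_models(
            [cie, model], recs, bin_width_deg)
    return report
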