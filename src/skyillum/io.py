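"""CSV/JSON/YAML readers and writers binding the pipeline stages together.

All tabular data is plain CSV (UTF-8, '.' decimal separator) with floats
written at 17 significant digits so write → read round trips are lossless.
Spectra tables put the wavelength grid in the first column
(``wavelength_nm``) and one column per measurement id; units and
acquisition state live in a sidecar metadata table.  Ledgers and basis
provenance are JSON; configuration is accepted as YAML or JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, replace
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .calibration import DarkFrame, DarkLibrary, RawFrame
from .ephemeris import EphemerisTable, ObservationRecord
from .fitting import BasisSet
from .spectra import Spectrum, Units
from .synthetic import (GeneratedDataset, InstrumentConfig, SkySimConfig)

__all__ = [
    "write_spectra_csv", "read_spectra_csv", "write_ephemeris_csv",
    "read_ephemeris_csv", "write_basis_csv", "read_basis_csv",
    "write_dataset", "read_dataset", "load_config", "config_hash",
    "write_records_csv", "read_records_csv",
]

_FLOAT_FMT = "%.17g"


class ParseError(ValueError):
    pass


def _write_df(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_spectra_csv(path: str | Path, spectra: Dict[str, Spectrum]) -> None:
    """Write spectra sharing one grid as a wide CSV (wavelength + ids)."""
    items = list(spectra.items())
    if not items:
        raise ParseError("no spectra to write")
    wl = items[0][1].wavelengths_nm
    data = {"wavelength_nm": wl}
    for sid, s in items:
        if not np.array_equal(s.wavelengths_nm, wl):
            raise ParseError(f"spectrum {sid!r} is on a different grid")
        data[sid] = s.values
    _write_df(pd.DataFrame(data), Path(path))


def read_spectra_csv(path: str | Path,
                     units: str = Units.RELATIVE) -> Dict[str, Spectrum]:
    df = pd.read_csv(path, float_precision="round_trip")
    if "wavelength_nm" not in df.columns:
        raise ParseError(f"{path}: missing wavelength_nm column")
    wl = df["wavelength_nm"].to_numpy(float)
    out = {}
    for col in df.columns:
        if col == "wavelength_nm":
            continue
        vals = df[col].to_numpy(float)
        if vals.size != wl.size:
            raise ParseError(f"{path}: column {col} length mismatch")
        out[col] = Spectrum(wl, vals, units)
    return out


def write_ephemeris_csv(path: str | Path, table: EphemerisTable) -> None:
    df = table.to_frame()
    df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S.%f%z")
    _write_df(df, Path(path))


def read_ephemeris_csv(path: str | Path) -> EphemerisTable:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"timestamp", "solar_elevation_deg", "lunar_elevation_deg",
                "fraction_illuminated"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return EphemerisTable(
        pd.DatetimeIndex(pd.to_datetime(df["timestamp"], utc=True)),
        df["solar_elevation_deg"].to_numpy(float),
        df["lunar_elevation_deg"].to_numpy(float),
        df["fraction_illuminated"].to_numpy(float))


def write_basis_csv(path: str | Path, basis: BasisSet,
                    provenance: dict | None = None) -> None:
    data = {"wavelength_nm": basis.wavelengths_nm}
    for name, comp in zip(basis.component_names, basis.components):
        data[name] = comp
    _write_df(pd.DataFrame(data), Path(path))
    side = {"name": basis.name, "fit_range_nm": list(basis.fit_range_nm),
            "component_names": list(basis.component_names)}
    if provenance:
        side["provenance"] = provenance
    Path(path).with_suffix(".json").write_text(json.dumps(side, indent=2))


def read_basis_csv(path: str | Path) -> BasisSet:
    df = pd.read_csv(path, float_precision="round_trip")
    if "wavelength_nm" not in df.columns:
        raise ParseError(f"{path}: missing wavelength_nm column")
    side_path = Path(path).with_suffix(".json")
    if side_path.exists():
        side = json.loads(side_path.read_text())
        name = side.get("name", Path(path).stem)
        fit_range = tuple(side.get("fit_range_nm", (360.0, 830.0)))
    else:
        name, fit_range = Path(path).stem, (360.0, 830.0)
    comps = [c for c in df.columns if c != "wavelength_nm"]
    wl = df["wavelength_nm"].to_numpy(float)
    arrays = []
    for c in comps:
        a = df[c].to_numpy(float)
        if a.size != wl.size:
            raise ParseError(f"{path}: component {c} grid length mismatch")
        arrays.append(a / np.linalg.norm(a))
    return BasisSet(name, wl, tuple(arrays), tuple(comps), fit_range)


def write_records_csv(dirpath: str | Path, location: str,
                      records: Sequence[ObservationRecord]) -> None:
    """Calibrated spectra + metadata for one location."""
    dirpath = Path(dirpath)
    # records from different instruments cover different 1-nm spans; store
    # them on the union grid, padding missing coverage with NaN
    grids = [r.spectrum.wavelengths_nm for r in records]
    union = np.unique(np.concatenate(grids)) if grids else np.array([])
    data = {"wavelength_nm": union}
    for r in records:
        col = np.full(union.size, np.nan)
        idx = np.searchsorted(union, r.spectrum.wavelengths_nm)
        col[idx] = r.spectrum.values
        data[r.record_id] = col
    _write_df(pd.DataFrame(data), dirpath / f"calibrated_{location}.csv")
    meta = pd.DataFrame([{
        "record_id": r.record_id,
        "timestamp": r.timestamp.strftime("%Y-%m-%dT%H:%M:%S.%f%z"),
        "location": r.location_id,
        "solar_elevation_deg": r.solar_elevation_deg,
        "lunar_elevation_deg": r.lunar_elevation_deg,
        "fraction_illuminated": r.fraction_illuminated,
        "sequence": r.sequence,
    } for r in records])
    _write_df(meta, dirpath / f"calibrated_{location}_meta.csv")


def read_records_csv(dirpath: str | Path, location: str
                     ) -> List[ObservationRecord]:
    dirpath = Path(dirpath)
    df = pd.read_csv(dirpath / f"calibrated_{location}.csv", float_precision="round_trip")
    if "wavelength_nm" not in df.columns:
        raise ParseError(f"calibrated_{location}.csv: missing wavelength_nm")
    union = df["wavelength_nm"].to_numpy(float)
    spectra = {}
    for col in df.columns:
        if col == "wavelength_nm":
            continue
        vals = df[col].to_numpy(float)
        ok = np.isfinite(vals)  # NaN marks wavelengths outside coverage
        spectra[col] = Spectrum(union[ok], vals[ok], Units.IRRADIANCE)
    meta = pd.read_csv(dirpath / f"calibrated_{location}_meta.csv", float_precision="round_trip")
    valid = {"rural", "city"}
    out = []
    for _, m in meta.iterrows():
        if m["location"] not in valid:
            raise ParseError(f"unknown location id {m['location']!r}")
        if m["record_id"] not in spectra:
            raise ParseError(f"record {m['record_id']!r} missing spectrum")
        out.append(ObservationRecord(
            spectrum=spectra[m["record_id"]],
            timestamp=pd.Timestamp(m["timestamp"]),
            location_id=m["location"],
            solar_elevation_deg=float(m["solar_elevation_deg"]),
            lunar_elevation_deg=float(m["lunar_elevation_deg"]),
            fraction_illuminated=float(m["fraction_illuminated"]),
            sequence=str(m["sequence"]), record_id=m["record_id"]))
    return out


# ---------------------------------------------------------------------------
# generated-campaign directory layout
# ---------------------------------------------------------------------------

def write_dataset(dirpath: str | Path, ds: GeneratedDataset) -> None:
    """Serialise a generated campaign to a directory of CSV/JSON tables."""
    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    for loc, table in ds.ephemeris.items():
        write_ephemeris_csv(d / f"ephemeris_{loc}.csv", table)
    for loc, frames in ds.raw_frames.items():
        by_inst: Dict[str, List[RawFrame]] = {}
        for f in frames:
            by_inst.setdefault(f.instrument_id, []).append(f)
        for iid, fs in by_inst.items():
            write_spectra_csv(d / f"raw_{loc}_{iid}.csv",
                              {f.frame_id: f.counts for f in fs})
    meta = ds.frame_meta.copy()
    meta["timestamp"] = pd.to_datetime(meta["timestamp"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%S.%f%z")
    _write_df(meta, d / "frames_meta.csv")
    for iid, lib in ds.dark_libraries.items():
        rows = {"wavelength_nm": lib.frames[0].dark_counts.wavelengths_nm}
        dark_meta = []
        for k, f in enumerate(lib.frames):
            col = f"dark_{k:03d}"
            rows[col] = f.dark_counts.values
            dark_meta.append({"id": col,
                              "integration_time_s": f.integration_time_s,
                              "board_temp_C": f.board_temp_C})
        _write_df(pd.DataFrame(rows), d / f"darks_{iid}.csv")
        _write_df(pd.DataFrame(dark_meta), d / f"darks_{iid}_meta.csv")
    for iid, s in ds.line_frames.items():
        write_spectra_csv(d / f"lines_{iid}.csv", {"line_lamp": s})
    for iid, s in ds.correction_factors.items():
        write_spectra_csv(d / f"correction_{iid}.csv", {"factor": s})
    instruments = {iid: asdict(ds.instrument(iid)) for iid in ("A", "B")}
    (d / "instruments.json").write_text(json.dumps(instruments, indent=2))
    (d / "ground_truth.json").write_text(json.dumps(ds.ground_truth, indent=2))
    (d / "config.json").write_text(json.dumps(_config_to_dict(ds.config),
                                              indent=2))


def read_dataset(dirpath: str | Path) -> GeneratedDataset:
    """Reload a campaign directory written by :func:`write_dataset`.

    Truth spectra are not stored on disk; they are reproducible from the
    config + ground-truth ledger and are left empty on reload.
    """
    d = Path(dirpath)
    cfg = _config_from_dict(json.loads((d / "config.json").read_text()))
    ephemeris = {loc: read_ephemeris_csv(d / f"ephemeris_{loc}.csv")
                 for loc in ("rural", "city")}
    meta = pd.read_csv(d / "frames_meta.csv", float_precision="round_trip")
    meta["timestamp"] = pd.to_datetime(meta["timestamp"], utc=True)
    frame_info = meta.set_index("frame_id")
    raw_frames: Dict[str, List[RawFrame]] = {"rural": [], "city": []}
    for loc in ("rural", "city"):
        for iid in ("A", "B"):
            p = d / f"raw_{loc}_{iid}.csv"
            if not p.exists():
                continue
            inst = cfg.instrument_a if iid == "A" else cfg.instrument_b
            for fid, s in read_spectra_csv(p, units=Units.COUNTS).items():
                info = frame_info.loc[fid]
                raw_frames[loc].append(RawFrame(
                    counts=s,
                    integration_time_s=float(info["integration_time_s"]),
                    board_temp_C=float(info["board_temp_C"]),
                    instrument_id=iid,
                    saturation_level=inst.saturation_level, frame_id=fid))
        raw_frames[loc].sort(key=lambda f: f.frame_id)
    dark_libraries = {}
    for iid in ("A", "B"):
        spectra = read_spectra_csv(d / f"darks_{iid}.csv", units=Units.COUNTS)
        dmeta = pd.read_csv(d / f"darks_{iid}_meta.csv", float_precision="round_trip").set_index("id")
        frames = [DarkFrame(float(dmeta.loc[k, "integration_time_s"]),
                            float(dmeta.loc[k, "board_temp_C"]), s)
                  for k, s in spectra.items()]
        dark_libraries[iid] = DarkLibrary(frames)
    line_frames = {iid: read_spectra_csv(d / f"lines_{iid}.csv",
                                         units=Units.COUNTS)["line_lamp"]
                   for iid in ("A", "B")}
    correction = {iid: read_spectra_csv(d / f"correction_{iid}.csv")["factor"]
                  for iid in ("A", "B")}
    ground_truth = json.loads((d / "ground_truth.json").read_text())
    return GeneratedDataset(
        config=cfg, ephemeris=ephemeris, raw_frames=raw_frames,
        frame_meta=meta, truth_spectra={}, dark_libraries=dark_libraries,
        line_frames=line_frames, correction_factors=correction,
        ground_truth=ground_truth)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def _config_to_dict(cfg: SkySimConfig) -> dict:
    return asdict(cfg)


def _config_from_dict(data: dict) -> SkySimConfig:
    data = dict(data)
    for key in ("instrument_a", "instrument_b"):
        if key in data and isinstance(data[key], dict):
            sub = dict(data[key])
            for tkey in ("integration_times_s", "output_range_nm"):
                if tkey in sub:
                    sub[tkey] = tuple(sub[tkey])
            data[key] = InstrumentConfig(**sub)
    return SkySimConfig(**data)


def load_config(path: str | Path) -> SkySimConfig:
    """Load a simulation config from YAML or JSON (keys override defaults)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return _config_from_dict(data)


def config_hash(cfg: SkySimConfig) -> str:
    """Stable short hash of a config, stamped into every output."""
    payload = json.dumps(_config_to_dict(cfg), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
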