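"""Seeded generator of a two-location sky-spectrum observation campaign.

Emulates the statistical structure of downwelling illumination across a
full diel cycle at a dark rural site and a light-polluted city site,
together with the two-spectrometer acquisition chain, so the entire
calibration → ephemeris → fitting → basis-extension pipeline can be
exercised end to end with known ground truth:

* a smooth daylight term: CIE daylight spectrum at a CCT that rises as the
  sun sinks, with total VIS intensity following a sigmoid in solar
  elevation spanning ~8 decades;
* Chappuis-type ozone absorption (Gaussian band near 600 nm) whose optical
  depth peaks near −12° solar elevation, producing the twilight "blue hour";
* location-specific night floors — a rural airglow floor with the 558 nm
  atomic-oxygen line, and a city light-pollution floor ~100× brighter
  dominated by sodium-lamp features (570–615 nm band, 819 nm line);
* additive moonlight scaled as a power law of the fraction of the moon
  illuminated, anchored at 3.29% of full-moon brightness at fraction 0.3,
  and zero when the moon is below the horizon;
* a two-instrument forward model (high-sensitivity night unit 'A',
  daylight unit 'B') with temperature- and integration-time-dependent dark
  counts, read and shot noise, saturation, automatic integration-time
  selection, and a small additive wavelength-calibration error.

Fixed seed ⇒ byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .calibration import (DarkFrame, DarkLibrary, HG_AR_LINES, RawFrame)
from .colorimetry import daylight_chromaticity, _data_table
from .ephemeris import EphemerisTable
from .spectra import Spectrum, Units, VIS_BAND, band_irradiance

__all__ = ["SkySimConfig", "InstrumentConfig", "GeneratedDataset",
            "true_spectrum", "moon_brightness", "instrument_forward",
            "generate_campaign", "MASTER_GRID_NM"]

MASTER_GRID_NM = np.arange(280.0, 1031.0, 1.0)


class SimConfigError(ValueError):
    pass


def _gauss(x: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - center) / sigma) ** 2)


@dataclass(frozen=True)
class InstrumentConfig:
    """Forward model of one USB spectrometer."""

    instrument_id: str
    # reported (factory) wavelength polynomial: lambda = a0 + a1*p + a2*p^2
    n_pixels: int
    a0: float
    a1: float
    a2: float
    wavelength_shift_nm: float       # true λ = reported λ + shift
    sensitivity: float               # base of the correction-factor curve
    read_noise_counts: float
    dark_offset_counts: float        # mean dark = (d0 + d1*t)*(1 + kT*(T-25))
    dark_rate_counts_per_s: float
    dark_temp_coeff_per_C: float
    saturation_level: float
    integration_times_s: Tuple[float, ...]
    output_range_nm: Tuple[float, float]  # 1-nm calibrated output span

    def reported_grid(self) -> np.ndarray:
        p = np.arange(self.n_pixels, dtype=float)
        return self.a0 + self.a1 * p + self.a2 * p * p

    def true_grid(self) -> np.ndarray:
        return self.reported_grid() + self.wavelength_shift_nm

    def correction_factors_at(self, wl_nm: np.ndarray) -> np.ndarray:
        """Smooth, strictly positive counts·s⁻¹ → radiance factor curve."""
        wl = np.asarray(wl_nm, float)
        return self.sensitivity * (1.0 + 0.35 * np.sin((wl - 250.0) / 120.0)
                                   + 0.25 * ((wl - 600.0) / 400.0) ** 2)

    def mean_dark(self, t_int: float, temp_C: float) -> np.ndarray:
        p = np.arange(self.n_pixels, dtype=float)
        pattern = 1.0 + 0.05 * np.sin(p / 40.0)
        base = (self.dark_offset_counts + self.dark_rate_counts_per_s * t_int)
        return base * (1.0 + self.dark_temp_coeff_per_C * (temp_C - 25.0)) * pattern


def _default_instrument_a() -> InstrumentConfig:
    return InstrumentConfig(
        instrument_id="A", n_pixels=1880, a0=180.0, a1=0.36, a2=5.0e-6,
        wavelength_shift_nm=-0.79, sensitivity=5.0e-9,
        read_noise_counts=12.0, dark_offset_counts=40.0,
        dark_rate_counts_per_s=2.0, dark_temp_coeff_per_C=0.01,
        saturation_level=65535.0,
        integration_times_s=(0.005, 0.03, 0.2, 1.2, 8.0, 60.0),
        output_range_nm=(280.0, 840.0))


def _default_instrument_b() -> InstrumentConfig:
    return InstrumentConfig(
        instrument_id="B", n_pixels=1850, a0=340.0, a1=0.36, a2=2.0e-6,
        wavelength_shift_nm=-0.98, sensitivity=5.0e-6,
        read_noise_counts=8.0, dark_offset_counts=40.0,
        dark_rate_counts_per_s=2.0, dark_temp_coeff_per_C=0.01,
        saturation_level=65535.0,
        integration_times_s=(0.001, 0.006, 0.04, 0.25, 1.5, 10.0, 60.0),
        output_range_nm=(360.0, 840.0))


@dataclass(frozen=True)
class SkySimConfig:
    """All generator parameters.  The defaults encode the study conditions:
    a ~8-decade day/night intensity swing, a rural night floor 100× dimmer
    than the city floor, a twilight blue shift peaking near −12°, and the
    airglow/sodium night signatures."""

    seed: int = 0
    noise: bool = True

    # intensity sigmoid: log10 VIS irradiance of the (sun-driven) term
    log10_day_vis: float = 2.5          # W·m⁻² over 400–800 nm at high sun
    log10_sigmoid_floor: float = -12.0  # asymptote well below the night floors
    sigmoid_center_deg: float = -13.0
    sigmoid_width_deg: float = 5.0

    # daylight CCT map: bluer sky as the sun sinks
    cct_day_K: float = 6500.0
    cct_twilight_slope_K_per_deg: float = 800.0

    # Chappuis-type absorption band
    chappuis_center_nm: float = 600.0
    chappuis_sigma_nm: float = 50.0
    chappuis_tau_max: float = 1.2
    chappuis_peak_elev_deg: float = -12.0
    chappuis_elev_sigma_deg: float = 3.0

    # night floors: total VIS irradiance (log10 W·m⁻²)
    rural_log10_floor_vis: float = -5.5
    city_log10_floor_vis: float = -3.5
    airglow_line_nm: float = 558.0
    airglow_line_sigma_nm: float = 2.5
    airglow_line_amp: float = 6.0
    sodium_nir_line_nm: float = 819.0

    # moonlight
    moon_full_log10_vis: float = -3.5
    moon_anchor_fraction: float = 0.3
    moon_anchor_brightness: float = 0.0329
    moon_cct_K: float = 4500.0

    instrument_a: InstrumentConfig = field(default_factory=_default_instrument_a)
    instrument_b: InstrumentConfig = field(default_factory=_default_instrument_b)

    # campaign/session structure
    start_utc: str = "2014-07-01T00:00:00Z"
    duration_h: float = 24.0
    cadence_s: float = 60.0
    ephemeris_cadence_s: float = 600.0
    elevation_mean_deg: float = -6.0
    elevation_amplitude_deg: float = 24.0
    exposure_target: float = 0.85

    def __post_init__(self) -> None:
        if self.log10_sigmoid_floor >= self.log10_day_vis:
            raise SimConfigError("sigmoid floor must be below the day level")
        if self.rural_log10_floor_vis >= self.city_log10_floor_vis:
            raise SimConfigError("rural floor must be dimmer than city floor")
        if not 0.0 < self.moon_anchor_fraction < 1.0:
            raise SimConfigError("moon anchor fraction must be in (0, 1)")


# ---------------------------------------------------------------------------
# spectral building blocks (pure functions of config — the ground-truth
# ledger plus the config reproduces every truth spectrum)
# ---------------------------------------------------------------------------

_DAYLIGHT_CACHE: Dict[int, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def _daylight_components_master() -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """S0, S1, S2 splined onto the master grid (edge-hold outside 300–830 nm)."""
    if 0 not in _DAYLIGHT_CACHE:
        tab = _data_table("cie_daylight_components_10nm.csv")
        wl = tab["wavelength_nm"].to_numpy(float)
        comps = []
        for c in ("S0", "S1", "S2"):
            cs = CubicSpline(wl, tab[c].to_numpy(float))
            clipped = np.clip(MASTER_GRID_NM, wl[0], wl[-1])
            comps.append(cs(clipped))
        _DAYLIGHT_CACHE[0] = tuple(comps)
    return _DAYLIGHT_CACHE[0]


def _vis_integral(values: np.ndarray) -> float:
    sel = (MASTER_GRID_NM >= VIS_BAND.lo_nm) & (MASTER_GRID_NM <= VIS_BAND.hi_nm)
    return float(np.trapezoid(values[sel], MASTER_GRID_NM[sel]))


def _daylight_shape(cct_K: float) -> np.ndarray:
    """Non-negative CIE daylight spectrum on the master grid, VIS-normalised."""
    p = daylight_chromaticity(cct_K)
    M = 0.0241 + 0.2562 * p.x - 0.7341 * p.y
    M1 = (-1.3515 - 1.7703 * p.x + 5.9114 * p.y) / M
    M2 = (0.0300 - 31.4424 * p.x + 30.0717 * p.y) / M
    S0, S1, S2 = _daylight_components_master()
    shape = np.clip(S0 + M1 * S1 + M2 * S2, 0.0, None)
    return shape / _vis_integral(shape)


def _rural_floor(cfg: SkySimConfig) -> np.ndarray:
    wl = MASTER_GRID_NM
    continuum = 1.0 + 0.4 * _gauss(wl, 740.0, 180.0)
    line = cfg.airglow_line_amp * _gauss(wl, cfg.airglow_line_nm,
                                         cfg.airglow_line_sigma_nm)
    shape = continuum + line
    return shape * (10.0 ** cfg.rural_log10_floor_vis / _vis_integral(shape))


def _city_floor(cfg: SkySimConfig) -> np.ndarray:
    wl = MASTER_GRID_NM
    continuum = 0.12 * (1.0 + 0.5 * _gauss(wl, 650.0, 250.0))
    peaks = (0.30 * _gauss(wl, 435.8, 2.5)      # mercury
             + 0.50 * _gauss(wl, 546.1, 2.5)    # mercury
             + 0.70 * _gauss(wl, 577.0, 4.0)    # high-pressure sodium band
             + 1.60 * _gauss(wl, 589.0, 4.0)    # sodium D
             + 0.70 * _gauss(wl, 600.0, 5.0)
             + 0.60 * _gauss(wl, 615.0, 4.0)
             + 1.10 * _gauss(wl, cfg.sodium_nir_line_nm, 2.5))  # NIR sodium
    shape = continuum + peaks
    return shape * (10.0 ** cfg.city_log10_floor_vis / _vis_integral(shape))


def moon_brightness(fraction: float, cfg: SkySimConfig | None = None) -> float:
    """Relative moonlight brightness as a function of fraction illuminated.

    Power law b(f) = f^γ with γ chosen so that b(1) = 1 and
    b(anchor_fraction) = anchor_brightness (default: 3.29% at 0.3).
    Monotone increasing with b(0) = 0.
    """
    cfg = cfg or SkySimConfig()
    if not 0.0 <= fraction <= 1.0:
        raise SimConfigError("fraction illuminated must lie in [0, 1]")
    gamma = math.log(cfg.moon_anchor_brightness) / math.log(cfg.moon_anchor_fraction)
    return float(fraction ** gamma)


def _cct_of_elevation(theta_deg: float, cfg: SkySimConfig) -> float:
    cct = cfg.cct_day_K + cfg.cct_twilight_slope_K_per_deg * max(0.0, -theta_deg)
    return float(np.clip(cct, 4000.0, 25000.0))


def true_spectrum(theta_deg: float, lunar_elev_deg: float, fraction: float,
                  location: str, cfg: SkySimConfig | None = None) -> Spectrum:
    """Noise-free downwelling spectral irradiance on the master grid.

    Sum of the sigmoid-scaled, Chappuis-attenuated daylight term, the
    location night floor and the moonlight term (W·m⁻²·nm⁻¹).
    """
    cfg = cfg or SkySimConfig()
    if not -90.0 <= theta_deg <= 90.0:
        raise SimConfigError("solar elevation outside [-90, 90] degrees")
    if location not in ("rural", "city"):
        raise SimConfigError(f"unknown location {location!r}")

    # daylight term: logistic in log10 total VIS irradiance
    span = cfg.log10_day_vis - cfg.log10_sigmoid_floor
    z = (theta_deg - cfg.sigmoid_center_deg) / cfg.sigmoid_width_deg
    log10_vis = cfg.log10_sigmoid_floor + span / (1.0 + np.exp(-z))
    shape = _daylight_shape(_cct_of_elevation(theta_deg, cfg))
    tau = cfg.chappuis_tau_max * _gauss(
        np.array([theta_deg]), cfg.chappuis_peak_elev_deg,
        cfg.chappuis_elev_sigma_deg)[0]
    absorption = np.exp(-tau * _gauss(MASTER_GRID_NM, cfg.chappuis_center_nm,
                                      cfg.chappuis_sigma_nm))
    daylight = (10.0 ** log10_vis) * shape * absorption

    floor = _rural_floor(cfg) if location == "rural" else _city_floor(cfg)

    moon = np.zeros_like(MASTER_GRID_NM)
    if lunar_elev_deg > 0.0 and fraction > 0.0:
        moon = (10.0 ** cfg.moon_full_log10_vis * moon_brightness(fraction, cfg)
                * _daylight_shape(cfg.moon_cct_K))

    return Spectrum(MASTER_GRID_NM, daylight + floor + moon, Units.IRRADIANCE)


# ---------------------------------------------------------------------------
# instrument forward model
# ---------------------------------------------------------------------------

def _signal_counts_per_s(truth: Spectrum, inst: InstrumentConfig) -> np.ndarray:
    """Noise-free signal rate on the reported pixel grid."""
    true_wl = inst.true_grid()
    irr = np.interp(true_wl, truth.wavelengths_nm, truth.values,
                    left=0.0, right=0.0)
    cf = inst.correction_factors_at(true_wl)
    return irr / cf / math.pi


def select_integration_time(truth: Spectrum, inst: InstrumentConfig,
                            temp_C: float, target: float = 0.85) -> float:
    """Longest available integration time keeping the predicted maximum
    counts at or below ``target`` × saturation; falls back to the shortest."""
    rate = _signal_counts_per_s(truth, inst)
    for t in sorted(inst.integration_times_s, reverse=True):
        peak = float(np.max(rate * t + inst.mean_dark(t, temp_C)))
        if peak <= target * inst.saturation_level:
            return t
    return min(inst.integration_times_s)


def instrument_forward(truth: Spectrum, inst: InstrumentConfig, t_int: float,
                       temp_C: float, rng: np.random.Generator | None = None,
                       noise: bool = True, frame_id: str = "") -> RawFrame:
    """Simulate one raw frame from a truth spectrum.

    counts = truth/(cf·π)·t + dark(t, T) [+ Gaussian read noise and
    Gaussian-approximated shot noise], clipped to [0, saturation].
    """
    signal = _signal_counts_per_s(truth, inst) * t_int
    dark = inst.mean_dark(t_int, temp_C)
    counts = signal + dark
    if noise:
        if rng is None:
            raise SimConfigError("noise requires an rng")
        sigma = np.sqrt(inst.read_noise_counts ** 2 + np.clip(counts, 0, None))
        counts = counts + rng.normal(0.0, 1.0, counts.size) * sigma
    counts = np.clip(counts, 0.0, inst.saturation_level)
    return RawFrame(
        counts=Spectrum(inst.reported_grid(), counts, Units.COUNTS),
        integration_time_s=t_int, board_temp_C=temp_C,
        instrument_id=inst.instrument_id,
        saturation_level=inst.saturation_level, frame_id=frame_id)


def line_source_frame(inst: InstrumentConfig, amplitude: float = 20000.0,
                      line_sigma_nm: float = 1.0) -> Spectrum:
    """Noise-free Hg/Ar line-lamp measurement as seen by an instrument
    (lines appear displaced by the instrument's wavelength error)."""
    rep = inst.reported_grid()
    v = np.full(rep.size, 10.0)
    for line in HG_AR_LINES.known_lines_nm:
        v = v + amplitude * _gauss(rep + inst.wavelength_shift_nm, line,
                                   line_sigma_nm)
    return Spectrum(rep, v, Units.COUNTS)


# ---------------------------------------------------------------------------
# campaign generation
# ---------------------------------------------------------------------------

@dataclass
class GeneratedDataset:
    """A complete simulated campaign plus its ground-truth ledger."""

    config: SkySimConfig
    ephemeris: Dict[str, EphemerisTable]
    raw_frames: Dict[str, List[RawFrame]]          # per location
    frame_meta: pd.DataFrame                       # frame_id, timestamp, ...
    truth_spectra: Dict[str, Spectrum]             # per frame_id
    dark_libraries: Dict[str, DarkLibrary]         # per instrument id
    line_frames: Dict[str, Spectrum]               # per instrument id
    correction_factors: Dict[str, Spectrum]        # true cf on 1-nm output grid
    ground_truth: Dict

    def instrument(self, instrument_id: str) -> InstrumentConfig:
        return (self.config.instrument_a if instrument_id == "A"
                else self.config.instrument_b)


def _dark_library(inst: InstrumentConfig,
                  temps_C: Sequence[float] = (10.0, 25.0, 40.0)) -> DarkLibrary:
    rep = inst.reported_grid()
    frames = [DarkFrame(t, T, Spectrum(rep, inst.mean_dark(t, T), Units.COUNTS))
              for t in inst.integration_times_s for T in temps_C]
    return DarkLibrary(frames)


def _make_ephemeris(cfg: SkySimConfig, location: str) -> EphemerisTable:
    start = pd.Timestamp(cfg.start_utc)
    n = int(cfg.duration_h * 3600.0 / cfg.ephemeris_cadence_s) + 1
    ts = start + pd.to_timedelta(np.arange(n) * cfg.ephemeris_cadence_s, unit="s")
    th = np.arange(n) * cfg.ephemeris_cadence_s / 3600.0
    solar = (cfg.elevation_mean_deg + cfg.elevation_amplitude_deg
             * np.cos(2.0 * np.pi * (th - 12.0) / 24.0))
    if location == "rural":
        lunar = -12.0 + 28.0 * np.cos(2.0 * np.pi * (th - 13.0) / 24.8)
        fraction = 0.18 + 0.04 * np.sin(2.0 * np.pi * th / 24.0)
    else:
        lunar = -5.0 + 30.0 * np.cos(2.0 * np.pi * (th - 11.0) / 24.8)
        fraction = 0.62 + 0.03 * np.sin(2.0 * np.pi * th / 24.0)
    return EphemerisTable(pd.DatetimeIndex(ts), solar, lunar,
                          np.clip(fraction, 0.0, 1.0))


def generate_campaign(cfg: SkySimConfig | None = None) -> GeneratedDataset:
    """Generate the full two-location campaign described by a config.

    Per-minute records over a diel solar-elevation track at each location,
    acquired with the daylight instrument 'B' above the horizon and the
    high-sensitivity instrument 'A' below it, under automatic
    integration-time selection.  Deterministic for a fixed seed.
    """
    cfg = cfg or SkySimConfig()
    rng = np.random.default_rng(cfg.seed)
    instruments = {"A": cfg.instrument_a, "B": cfg.instrument_b}

    ephemeris = {loc: _make_ephemeris(cfg, loc) for loc in ("rural", "city")}
    dark_libs = {iid: _dark_library(inst) for iid, inst in instruments.items()}
    line_frames = {iid: line_source_frame(inst)
                   for iid, inst in instruments.items()}

    correction_factors = {}
    for iid, inst in instruments.items():
        lo, hi = inst.output_range_nm
        grid = np.arange(lo, hi + 0.5, 1.0)
        correction_factors[iid] = Spectrum(
            grid, inst.correction_factors_at(grid), Units.RELATIVE)

    raw_frames: Dict[str, List[RawFrame]] = {"rural": [], "city": []}
    truth_spectra: Dict[str, Spectrum] = {}
    meta_rows = []
    n_rec = int(cfg.duration_h * 3600.0 / cfg.cadence_s)
    start = pd.Timestamp(cfg.start_utc)

    for location in ("rural", "city"):
        tab = ephemeris[location]
        xs = (tab.timestamps - tab.timestamps[0]).total_seconds().to_numpy(float)
        for i in range(n_rec):
            t_s = i * cfg.cadence_s
            ts = start + pd.Timedelta(seconds=t_s)
            theta = float(np.interp(t_s, xs, tab.solar_elevation_deg))
            lunar = float(np.interp(t_s, xs, tab.lunar_elevation_deg))
            fraction = float(np.interp(t_s, xs, tab.fraction_illuminated))
            truth = true_spectrum(theta, lunar, fraction, location, cfg)
            iid = "B" if theta >= 0.0 else "A"
            inst = instruments[iid]
            t_h = t_s / 3600.0
            temp = 25.0 + 6.0 * np.sin(2.0 * np.pi * t_h / 24.0)
            t_int = select_integration_time(truth, inst, temp,
                                            cfg.exposure_target)
            frame_id = f"{location}-{i:04d}"
            frame = instrument_forward(truth, inst, t_int, temp, rng=rng,
                                       noise=cfg.noise, frame_id=frame_id)
            raw_frames[location].append(frame)
            truth_spectra[frame_id] = truth
            meta_rows.append({
                "frame_id": frame_id, "timestamp": ts, "location": location,
                "instrument": iid, "integration_time_s": t_int,
                "board_temp_C": float(temp),
                "solar_elevation_deg": theta,
                "lunar_elevation_deg": lunar,
                "fraction_illuminated": fraction,
            })

    ground_truth = {
        "seed": cfg.seed,
        "wavelength_shifts_nm": {iid: inst.wavelength_shift_nm
                                 for iid, inst in instruments.items()},
        "airglow_line_nm": cfg.airglow_line_nm,
        "sodium_nir_line_nm": cfg.sodium_nir_line_nm,
        "sodium_band_nm": [570.0, 615.0],
        "rural_log10_floor_vis": cfg.rural_log10_floor_vis,
        "city_log10_floor_vis": cfg.city_log10_floor_vis,
        "chappuis_peak_elev_deg": cfg.chappuis_peak_elev_deg,
        "moon_anchor": [cfg.moon_anchor_fraction, cfg.moon_anchor_brightness],
    }

    return GeneratedDataset(
        config=cfg, ephemeris=ephemeris, raw_frames=raw_frames,
        frame_meta=pd.DataFrame(meta_rows), truth_spectra=truth_spectra,
        dark_libraries=dark_libs, line_frames=line_frames,
        correction_factors=correction_factors, ground_truth=ground_truth)
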