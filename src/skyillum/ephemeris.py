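"""Solar/lunar geometry handling: ephemeris interpolation, twilight regimes,
lunar-phase filtering, dawn/dusk labelling and solar-elevation binning.

Twilight regimes follow the standard solar-elevation bands: day (θs ≥ 0°),
civil twilight (−6° ≤ θs < 0°), nautical (−12° ≤ θs < −6°), astronomical
(−18° ≤ θs < −12°) and night (θs < −18°).  Elevations are true (geometric)
elevations; no atmospheric refraction correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .spectra import Spectrum

__all__ = [
    "Regime", "EphemerisTable", "ObservationRecord", "interpolate_ephemeris",
    "classify_regime", "lunar_filter", "assign_sequence", "bin_by_elevation",
    "REGIME_BOUNDARIES",
]

REGIME_BOUNDARIES = (-18.0, -12.0, -6.0, 0.0)


class Regime:
    DAY = "day"
    CIVIL = "civil"
    NAUTICAL = "nautical"
    ASTRONOMICAL = "astronomical"
    NIGHT = "night"

    ALL = (DAY, CIVIL, NAUTICAL, ASTRONOMICAL, NIGHT)


class EphemerisError(ValueError):
    pass


@dataclass
class EphemerisTable:
    """Time-indexed solar/lunar geometry: strictly increasing UTC timestamps
    with solar elevation, lunar elevation (deg) and fraction of the moon
    illuminated."""

    timestamps: pd.DatetimeIndex
    solar_elevation_deg: np.ndarray
    lunar_elevation_deg: np.ndarray
    fraction_illuminated: np.ndarray

    def __post_init__(self) -> None:
        ts = pd.DatetimeIndex(self.timestamps)
        if not ts.is_monotonic_increasing or ts.has_duplicates:
            raise EphemerisError("timestamps must be strictly increasing")
        self.timestamps = ts
        for name in ("solar_elevation_deg", "lunar_elevation_deg",
                     "fraction_illuminated"):
            arr = np.asarray(getattr(self, name), float)
            if arr.size != len(ts):
                raise EphemerisError(f"{name} length mismatch")
            setattr(self, name, arr)
        if np.any(np.abs(self.solar_elevation_deg) > 90) or np.any(
                np.abs(self.lunar_elevation_deg) > 90):
            raise EphemerisError("elevations must lie in [-90, 90] degrees")
        if np.any((self.fraction_illuminated < 0) |
                  (self.fraction_illuminated > 1)):
            raise EphemerisError("fraction illuminated must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "timestamp": self.timestamps,
            "solar_elevation_deg": self.solar_elevation_deg,
            "lunar_elevation_deg": self.lunar_elevation_deg,
            "fraction_illuminated": self.fraction_illuminated,
        })


@dataclass
class ObservationRecord:
    """A calibrated irradiance spectrum joined with its observing geometry."""

    spectrum: Spectrum
    timestamp: pd.Timestamp
    location_id: str  # "rural" or "city"
    solar_elevation_deg: float
    lunar_elevation_deg: float
    fraction_illuminated: float
    sequence: str = ""  # "dawn" or "dusk"
    record_id: str = ""

    def __post_init__(self) -> None:
        if abs(self.solar_elevation_deg) > 90 or abs(self.lunar_elevation_deg) > 90:
            raise EphemerisError("elevations must lie in [-90, 90] degrees")

    @property
    def regime(self) -> str:
        return classify_regime(self.solar_elevation_deg)


def interpolate_ephemeris(table: EphemerisTable, t: pd.Timestamp
                          ) -> Tuple[float, float, float]:
    """Linear interpolation of (solar elevation, lunar elevation, fraction)
    at time ``t``; no extrapolation outside the table's span."""
    t = pd.Timestamp(t)
    ts = table.timestamps
    if t < ts[0] or t > ts[-1]:
        raise EphemerisError(f"{t} outside ephemeris span [{ts[0]}, {ts[-1]}]")
    x = (t - ts[0]).total_seconds()
    xs = (ts - ts[0]).total_seconds().to_numpy(dtype=float)
    return (float(np.interp(x, xs, table.solar_elevation_deg)),
            float(np.interp(x, xs, table.lunar_elevation_deg)),
            float(np.interp(x, xs, table.fraction_illuminated)))


def classify_regime(solar_elevation_deg: float) -> str:
    """Map a solar elevation to its illumination regime (half-open bands)."""
    th = float(solar_elevation_deg)
    if not -90.0 <= th <= 90.0:
        raise EphemerisError("solar elevation outside [-90, 90] degrees")
    if th >= 0.0:
        return Regime.DAY
    if th >= -6.0:
        return Regime.CIVIL
    if th >= -12.0:
        return Regime.NAUTICAL
    if th >= -18.0:
        return Regime.ASTRONOMICAL
    return Regime.NIGHT


def lunar_filter(records: Iterable[ObservationRecord],
                 max_fraction: float = 0.3) -> List[ObservationRecord]:
    """Moonlight screen: rural records are kept only when the fraction of the
    moon illuminated is strictly below ``max_fraction``; city records are kept
    unconditionally (light pollution dominates the moon there)."""
    out = []
    for r in records:
        if r.location_id == "rural" and r.fraction_illuminated >= max_fraction:
            continue
        out.append(r)
    return out


def assign_sequence(records: Sequence[ObservationRecord]
                    ) -> List[ObservationRecord]:
    """Label each record dawn or dusk from the sign of dθs/dt.

    Records are treated as one time-sorted session; where the local finite
    difference of solar elevation is zero the preceding trend carries over
    (and the following trend seeds the start of the session).
    """
    recs = sorted(records, key=lambda r: r.timestamp)
    if not recs:
        return []
    theta = np.array([r.solar_elevation_deg for r in recs])
    d = np.diff(theta)
    signs = np.sign(d)
    # forward-fill zero differences with the previous trend, then back-fill
    for i in range(1, signs.size):
        if signs[i] == 0:
            signs[i] = signs[i - 1]
    for i in range(signs.size - 2, -1, -1):
        if signs[i] == 0:
            signs[i] = signs[i + 1]
    labels = ["dawn" if s > 0 else "dusk" for s in signs]
    labels.append(labels[-1] if labels else "dusk")
    for r, lab in zip(recs, labels):
        r.sequence = lab
    return recs


def bin_by_elevation(records: Iterable[ObservationRecord], width_deg: float
                     ) -> Dict[float, List[ObservationRecord]]:
    """Group records into half-open solar-elevation bins [k·w, (k+1)·w),
    keyed by bin center.  Bin edges sit at integer multiples of the width."""
    if width_deg <= 0:
        raise EphemerisError("bin width must be > 0")
    out: Dict[float, List[ObservationRecord]] = {}
    for r in records:
        k = np.floor(r.solar_elevation_deg / width_deg)
        center = (k + 0.5) * width_deg
        out.setdefault(float(center), []).append(r)
    return dict(sorted(out.items()))
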