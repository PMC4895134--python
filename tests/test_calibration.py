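import math

import numpy as np
import pytest

from skyillum.calibration import (CalibrationError, CorrectionFactors,
                                  DarkFrame, DarkLibrary, HG_AR_LINES,
                                  LineSourceReference, RawFrame,
                                  derive_correction_factors,
                                  estimate_wavelength_shift, lookup_dark,
                                  process_raw, qc_filter, splice_corrections,
                                  window_snr)
from skyillum.spectra import RangeError, Spectrum, Units


def counts_spec(wl, v):
    return Spectrum(np.asarray(wl, float), np.asarray(v, float), Units.COUNTS)


@pytest.fixture
def toy_library():
    wl = np.arange(400.0, 410.0)
    frames = []
    for t in (1.0, 10.0):
        for T, level in ((20.0, 10.0), (30.0, 20.0)):
            frames.append(DarkFrame(t, T, counts_spec(wl, np.full(10, level * t))))
    return DarkLibrary(frames)


class TestDarkLookup:
    def test_exact_temperature_returns_frame(self, toy_library):
        out = lookup_dark(toy_library, 1.0, 20.0)
        assert np.allclose(out.values, 10.0)

    def test_midway_temperature_averages(self, toy_library):
        out = lookup_dark(toy_library, 10.0, 25.0)
        assert np.allclose(out.values, 150.0)

    def test_clamps_outside_range(self, toy_library):
        assert np.allclose(lookup_dark(toy_library, 1.0, 99.0).values, 20.0)
        assert np.allclose(lookup_dark(toy_library, 1.0, -10.0).values, 10.0)

    def test_missing_integration_time_raises(self, toy_library):
        with pytest.raises(CalibrationError):
            lookup_dark(toy_library, 2.5, 25.0)

    def test_library_requires_two_temperatures(self):
        wl = np.arange(400.0, 410.0)
        with pytest.raises(CalibrationError):
            DarkLibrary([DarkFrame(1.0, 20.0, counts_spec(wl, np.ones(10)))])


def line_lamp_spectrum(shift_nm, grid_step=0.3, sigma=1.0):
    """Gaussian lines displaced by ``-shift_nm`` on the reported grid."""
    wl = np.arange(380.0, 800.0, grid_step)
    v = np.full(wl.size, 5.0)
    for line in HG_AR_LINES.known_lines_nm:
        v = v + 2e4 * np.exp(-0.5 * ((wl - (line - shift_nm)) / sigma) ** 2)
    return counts_spec(wl, v)


class TestWavelengthShift:
    def test_recovers_injected_negative_shift(self):
        shift, sd = estimate_wavelength_shift(line_lamp_spectrum(-0.8),
                                              HG_AR_LINES)
        assert shift == pytest.approx(-0.8, abs=0.05)
        assert sd < 0.05

    def test_zero_shift_within_grid_resolution(self):
        shift, _ = estimate_wavelength_shift(line_lamp_spectrum(0.0),
                                             HG_AR_LINES)
        assert abs(shift) < 0.3

    def test_too_few_lines_raises(self):
        wl = np.arange(380.0, 800.0, 0.3)
        v = np.full(wl.size, 5.0)
        v += 2e4 * np.exp(-0.5 * ((wl - 546.1) / 1.0) ** 2)
        with pytest.raises(CalibrationError):
            estimate_wavelength_shift(counts_spec(wl, v), HG_AR_LINES)

    def test_reference_lines_must_be_sorted(self):
        with pytest.raises(CalibrationError):
            LineSourceReference((500.0, 400.0))


class TestCorrectionFactors:
    grid = np.arange(400.0, 701.0)

    def test_identity_when_measured_equals_reference(self):
        s = Spectrum(self.grid, np.full(self.grid.size, 2.0), Units.RELATIVE)
        cf = derive_correction_factors(s, s)
        assert np.allclose(cf.factors.values, 1.0)

    def test_half_measured_gives_factor_two(self):
        ref = Spectrum(self.grid, np.full(self.grid.size, 2.0), Units.RELATIVE)
        half = Spectrum(self.grid, ref.values / 2.0, Units.RELATIVE)
        cf = derive_correction_factors(half, ref)
        assert np.allclose(cf.factors.values, 2.0)

    def test_recovers_constructed_factor_curve(self):
        f = 1.0 + 0.5 * np.sin(self.grid / 50.0) ** 2
        ref = Spectrum(self.grid, 10.0 + (self.grid - 400) / 30.0,
                       Units.RELATIVE)
        measured = Spectrum(self.grid, ref.values / f, Units.RELATIVE)
        cf = derive_correction_factors(measured, ref)
        assert np.allclose(cf.factors.values, f, rtol=1e-12)

    def test_disjoint_ranges_raise(self):
        a = Spectrum(np.arange(400.0, 501.0), np.ones(101), Units.RELATIVE)
        b = Spectrum(np.arange(600.0, 701.0), np.ones(101), Units.RELATIVE)
        with pytest.raises(RangeError):
            derive_correction_factors(a, b)


def make_cf(grid, values):
    return CorrectionFactors(Spectrum(np.asarray(grid, float),
                                      np.asarray(values, float),
                                      Units.RELATIVE))


class TestSplice:
    grid = np.arange(300.0, 901.0)

    def test_identical_sets_unchanged(self):
        base = 2.0 + np.sin(self.grid / 80.0) ** 2
        cf = make_cf(self.grid, base)
        out = splice_corrections(cf, cf, cf)
        assert np.allclose(out.factors.values, base, rtol=1e-12)

    def test_proportional_long_segment_rescaled_onto_mid(self):
        base = 2.0 + np.sin(self.grid / 80.0) ** 2
        mid = make_cf(self.grid, base)
        long3 = make_cf(self.grid, 3.0 * base)
        out = splice_corrections(mid, mid, long3)
        # least-squares scalar for proportional vectors is exactly 1/3,
        # so the blend reduces to the mid curve everywhere
        assert np.allclose(out.factors.values, base, rtol=1e-10)

    def test_equal_weighting_at_transition(self):
        short_vals = 1.2 + 0.3 * np.sin(self.grid / 41.0)
        mid_vals = 2.0 + 0.2 * np.cos(self.grid / 67.0)
        out = splice_corrections(make_cf(self.grid, short_vals),
                                 make_cf(self.grid, mid_vals),
                                 make_cf(self.grid, mid_vals))
        # independent least-squares scalar over the +/-20 nm window at 400 nm
        win = (self.grid >= 380.0) & (self.grid <= 420.0)
        s = np.dot(short_vals[win], mid_vals[win]) / np.dot(
            short_vals[win], short_vals[win])
        at_400 = out.factors.values[self.grid == 400.0][0]
        expected = 0.5 * s * short_vals[self.grid == 400.0][0] + \
            0.5 * mid_vals[self.grid == 400.0][0]
        assert at_400 == pytest.approx(expected, rel=1e-12)

    def test_blend_is_continuous_across_transition(self):
        rng = np.random.default_rng(5)
        mid = make_cf(self.grid, 2.0 + 0.3 * np.sin(self.grid / 37.0))
        short = make_cf(self.grid, 1.5 + 0.2 * np.cos(self.grid / 53.0))
        long_ = make_cf(self.grid, 2.5 + 0.1 * np.sin(self.grid / 91.0))
        out = splice_corrections(short, mid, long_)
        assert np.max(np.abs(np.diff(out.factors.values))) < 0.1


class TestWindowSnr:
    def test_smooth_spectrum_near_one(self):
        wl = np.arange(400.0, 601.0)
        snr = window_snr(Spectrum(wl, (wl / 100.0) ** 2, Units.RELATIVE))
        assert np.nanmin(snr) > 0.99

    def test_pure_noise_near_zero_on_average(self):
        rng = np.random.default_rng(0)
        wl = np.arange(400.0, 501.0)
        vals = []
        for _ in range(200):
            s = Spectrum(wl, rng.standard_normal(wl.size), Units.RELATIVE)
            vals.append(np.nanmean(window_snr(s)))
        # |r| of independent noise is small but positive-biased; the mean
        # over seeds must sit far below any smooth-signal value
        assert np.mean(vals) < 0.35

    def test_constant_spectrum_flagged_undefined(self):
        wl = np.arange(400.0, 501.0)
        snr = window_snr(Spectrum(wl, np.ones(wl.size), Units.RELATIVE))
        assert np.all(np.isnan(snr))


class TestProcessRaw:
    def setup_method(self):
        self.wl = np.arange(350.0, 901.0, 0.5)
        self.lib = DarkLibrary([
            DarkFrame(2.0, 15.0, counts_spec(self.wl, np.full(self.wl.size, 50.0))),
            DarkFrame(2.0, 35.0, counts_spec(self.wl, np.full(self.wl.size, 70.0))),
        ])
        self.cf = make_cf(np.arange(360.0, 841.0), np.full(481, 0.25))

    def make_frame(self, net_rate):
        dark = 60.0  # temp 25 -> midpoint of the library
        counts = net_rate * 2.0 + dark
        return RawFrame(counts_spec(self.wl, np.full(self.wl.size, counts)),
                        integration_time_s=2.0, board_temp_C=25.0,
                        instrument_id="A")

    def test_unit_radiance_becomes_pi_irradiance(self):
        # counts chosen so post-correction radiance is exactly 1 everywhere
        frame = self.make_frame(net_rate=4.0)  # 4 counts/s * 0.25 = 1
        out = process_raw(frame, self.lib, 0.0, self.cf, (360.0, 840.0))
        assert out.units == Units.IRRADIANCE
        assert np.allclose(out.values, math.pi, rtol=1e-12)

    def test_dark_frame_input_gives_zero(self):
        frame = self.make_frame(net_rate=0.0)
        out = process_raw(frame, self.lib, 0.0, self.cf, (360.0, 840.0))
        assert np.allclose(out.values, 0.0)

    def test_homogeneous_degree_one_in_net_counts(self):
        out1 = process_raw(self.make_frame(3.0), self.lib, 0.0, self.cf,
                           (360.0, 840.0))
        out2 = process_raw(self.make_frame(6.0), self.lib, 0.0, self.cf,
                           (360.0, 840.0))
        assert np.allclose(out2.values, 2.0 * out1.values, rtol=1e-12)

    def test_shift_moves_features(self):
        v = np.full(self.wl.size, 60.0)
        v += 1e4 * np.exp(-0.5 * ((self.wl - 599.0) / 3.0) ** 2)
        frame = RawFrame(counts_spec(self.wl, v), 2.0, 25.0, "A")
        out = process_raw(frame, self.lib, 1.0, self.cf, (360.0, 840.0),
                          median_order=None)
        peak = out.wavelengths_nm[np.argmax(out.values)]
        assert peak == pytest.approx(600.0, abs=0.5)


class TestQcFilter:
    def setup_method(self):
        self.wl = np.arange(350.0, 901.0, 0.5)
        n = self.wl.size
        self.lib = DarkLibrary([
            DarkFrame(1.0, 15.0, counts_spec(self.wl, np.full(n, 50.0))),
            DarkFrame(1.0, 35.0, counts_spec(self.wl, np.full(n, 50.0))),
        ])
        self.cf = make_cf(np.arange(360.0, 841.0), np.full(481, 0.25))

    def frame(self, values, frame_id):
        return RawFrame(counts_spec(self.wl, values), 1.0, 25.0, "A",
                        frame_id=frame_id)

    def test_toy_set_keeps_and_rejects_with_reasons(self):
        n = self.wl.size
        good = np.full(n, 300.0)
        saturated = np.full(n, 300.0)
        saturated[5] = 65535.0
        dark_only = np.full(n, 50.0)
        frames = [self.frame(good, "g1"), self.frame(saturated, "sat"),
                  self.frame(dark_only, "dk"), self.frame(good * 2, "g2"),
                  self.frame(good * 3, "g3")]
        kept, rejected = qc_filter(frames, self.lib, 0.0, self.cf,
                                   (360.0, 840.0))
        assert {f.frame_id for f, _ in kept} == {"g1", "g2", "g3"}
        reasons = {f.frame_id: r for f, r in rejected}
        assert reasons == {"sat": "saturated", "dk": "all_zero_after_dark"}

    def test_empty_input_gives_empty_output(self):
        kept, rejected = qc_filter([], self.lib, 0.0, self.cf, (360.0, 840.0))
        assert kept == [] and rejected == []

    def test_negative_post_dark_values_clamped_not_rejected(self):
        n = self.wl.size
        v = np.full(n, 300.0)
        v[100] = 10.0  # below the dark level -> negative after subtraction
        kept, rejected = qc_filter([self.frame(v, "neg")], self.lib, 0.0,
                                   self.cf, (360.0, 840.0))
        assert len(kept) == 1 and not rejected
        assert np.all(kept[0][1].values >= 0.0)
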