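import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from skyillum.calibration import CorrectionFactors, process_raw, qc_filter
from skyillum.colorimetry import xy_from_xyz, xyz_from_spectrum
from skyillum.ephemeris import Regime, classify_regime
from skyillum.spectra import Spectrum, Units, VIS_BAND, band_irradiance, resample_1nm
from skyillum.synthetic import (SimConfigError, SkySimConfig,
                                generate_campaign, instrument_forward,
                                moon_brightness, true_spectrum)


class TestMoonBrightness:
    def test_printed_anchors(self):
        assert moon_brightness(1.0) == pytest.approx(1.0)
        assert moon_brightness(0.3) == pytest.approx(0.0329, rel=1e-12)
        assert moon_brightness(0.0) == 0.0

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_monotone_increasing(self, a, b):
        lo, hi = sorted((a, b))
        assert moon_brightness(lo) <= moon_brightness(hi)

    def test_out_of_range_rejected(self):
        with pytest.raises(SimConfigError):
            moon_brightness(1.5)


class TestTrueSpectrum:
    def test_city_floor_hundredfold_brighter(self):
        cfg = SkySimConfig()
        rural = true_spectrum(-30.0, -10.0, 0.2, "rural", cfg)
        city = true_spectrum(-30.0, -10.0, 0.2, "city", cfg)
        ratio = band_irradiance(city, VIS_BAND) / band_irradiance(rural, VIS_BAND)
        assert ratio == pytest.approx(100.0, rel=1e-3)

    def test_high_sun_is_daylight_model_shaped(self):
        from skyillum.fitting import fit_spectrum, load_cie_basis
        s = true_spectrum(60.0, -10.0, 0.2, "rural")
        assert fit_spectrum(load_cie_basis(), s).r_squared > 0.99

    def test_log_intensity_monotone_in_elevation(self):
        cfg = SkySimConfig()
        thetas = np.arange(-18.0, 20.5, 1.0)
        vis = [band_irradiance(true_spectrum(t, -10.0, 0.2, "rural", cfg),
                               VIS_BAND) for t in thetas]
        assert np.all(np.diff(np.log10(vis)) > 0)

    def test_moon_below_horizon_contributes_nothing(self):
        dark = true_spectrum(-30.0, -5.0, 1.0, "rural")
        no_moon = true_spectrum(-30.0, -5.0, 0.0, "rural")
        assert np.array_equal(dark.values, no_moon.values)

    def test_full_moon_dominates_rural_night(self):
        moonlit = true_spectrum(-30.0, 30.0, 1.0, "rural")
        dark = true_spectrum(-30.0, 30.0, 0.0, "rural")
        ratio = band_irradiance(moonlit, VIS_BAND) / band_irradiance(dark,
                                                                     VIS_BAND)
        assert ratio > 50.0

    def test_blue_dip_tracks_chappuis_peak(self):
        cfg = SkySimConfig()
        off = SkySimConfig(chappuis_tau_max=0.0)
        thetas = np.arange(-17.0, 0.0, 1.0)

        def x_of(theta, c):
            s = resample_1nm(true_spectrum(theta, -10.0, 0.2, "rural", c),
                             360.0, 830.0)
            return xy_from_xyz(*xyz_from_spectrum(s)).x

        with_dip = np.asarray([x_of(t, cfg) for t in thetas])
        without = np.asarray([x_of(t, off) for t in thetas])
        t_min = thetas[int(np.argmin(with_dip))]
        assert abs(t_min - cfg.chappuis_peak_elev_deg) <= 1.0
        # the absorption is what deepens and pins the dip: at its peak
        # elevation the sky is substantially bluer than without it
        at_peak = thetas == cfg.chappuis_peak_elev_deg
        assert with_dip[at_peak][0] < without[at_peak][0] - 0.02

    def test_invalid_location_rejected(self):
        with pytest.raises(SimConfigError):
            true_spectrum(10.0, 0.0, 0.1, "suburb")


class TestInstrumentModel:
    def test_noise_free_forward_inverts_through_process_raw(self):
        """Affine truth sampled on the instrument's own grid round-trips
        exactly through the full counts -> irradiance chain."""
        from skyillum.synthetic import _dark_library
        cfg = SkySimConfig()
        inst = cfg.instrument_a
        true_wl = inst.true_grid()
        ramp = 2.0e-6 + 1.0e-9 * true_wl
        truth = Spectrum(true_wl,
                         inst.correction_factors_at(true_wl) * np.pi * ramp,
                         Units.IRRADIANCE)
        frame = instrument_forward(truth, inst, 8.0, 28.7, noise=False)
        lib = _dark_library(inst)
        grid = np.arange(*inst.output_range_nm)
        cf = CorrectionFactors(Spectrum(
            np.arange(inst.output_range_nm[0], inst.output_range_nm[1] + 0.5),
            inst.correction_factors_at(
                np.arange(inst.output_range_nm[0],
                          inst.output_range_nm[1] + 0.5)), Units.RELATIVE))
        out = process_raw(frame, lib, inst.wavelength_shift_nm, cf,
                          inst.output_range_nm)
        expected = cf.factors.values * np.pi * (2.0e-6 + 1.0e-9 *
                                                out.wavelengths_nm)
        assert np.allclose(out.values, expected, rtol=1e-9)

    def test_signal_linear_in_truth(self):
        cfg = SkySimConfig()
        inst = cfg.instrument_a
        base = true_spectrum(-25.0, -10.0, 0.2, "rural", cfg)
        bright = base.with_values(base.values * 10.0)
        f1 = instrument_forward(base, inst, 1.2, 25.0, noise=False)
        f2 = instrument_forward(bright, inst, 1.2, 25.0, noise=False)
        dark = inst.mean_dark(1.2, 25.0)
        assert np.allclose(f2.counts.values - dark,
                           10.0 * (f1.counts.values - dark), rtol=1e-9)

    def test_overexposure_saturates_and_qc_rejects(self):
        from skyillum.synthetic import _dark_library
        cfg = SkySimConfig()
        inst = cfg.instrument_a
        blinding = true_spectrum(60.0, -10.0, 0.2, "rural", cfg)
        frame = instrument_forward(blinding, inst, 60.0, 25.0, noise=False)
        assert frame.is_saturated
        grid = np.arange(inst.output_range_nm[0],
                         inst.output_range_nm[1] + 0.5)
        cf = CorrectionFactors(Spectrum(
            grid, inst.correction_factors_at(grid), Units.RELATIVE))
        kept, rejected = qc_filter([frame], _dark_library(inst), 0.0, cf,
                                   inst.output_range_nm)
        assert not kept and rejected[0][1] == "saturated"

    def test_noise_shrinks_with_integration_time(self):
        cfg = SkySimConfig()
        inst = cfg.instrument_a
        truth = true_spectrum(-25.0, -10.0, 0.2, "rural", cfg)
        rng = np.random.default_rng(4)
        errs = []
        for t_int in (1.2, 60.0):
            rel = []
            for _ in range(5):
                f = instrument_forward(truth, inst, t_int, 25.0, rng=rng)
                net = f.counts.values - inst.mean_dark(t_int, 25.0)
                signal = (instrument_forward(truth, inst, t_int, 25.0,
                                             noise=False).counts.values
                          - inst.mean_dark(t_int, 25.0))
                ok = signal > 0
                rel.append(np.mean(np.abs(net[ok] - signal[ok]) / signal[ok]))
            errs.append(np.mean(rel))
        assert errs[1] < errs[0]


class TestCampaign:
    def test_fixed_seed_is_deterministic(self):
        a = generate_campaign(SkySimConfig(seed=5, cadence_s=1800.0))
        b = generate_campaign(SkySimConfig(seed=5, cadence_s=1800.0))
        for loc in ("rural", "city"):
            for fa, fb in zip(a.raw_frames[loc], b.raw_frames[loc]):
                assert np.array_equal(fa.counts.values, fb.counts.values)
        assert a.frame_meta.equals(b.frame_meta)

    def test_every_regime_is_sampled(self, small_campaign):
        regimes = {classify_regime(t)
                   for t in small_campaign.frame_meta["solar_elevation_deg"]}
        assert regimes == set(Regime.ALL)

    def test_elevation_span_covers_study_range(self, small_campaign):
        theta = small_campaign.frame_meta["solar_elevation_deg"]
        assert theta.min() < -25.0 and theta.max() > 15.0

    def test_both_instruments_used(self, small_campaign):
        assert set(small_campaign.frame_meta["instrument"]) == {"A", "B"}

    def test_ledger_reproduces_truth(self, small_campaign):
        cfg = small_campaign.config
        m = small_campaign.frame_meta.iloc[100]
        rebuilt = true_spectrum(m["solar_elevation_deg"],
                                m["lunar_elevation_deg"],
                                m["fraction_illuminated"], m["location"], cfg)
        stored = small_campaign.truth_spectra[m["frame_id"]]
        assert np.array_equal(rebuilt.values, stored.values)
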