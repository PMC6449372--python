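"""Sonar-equation backscatter, velocity correction, sections, wake metrics."""

import warnings

import numpy as np
import pytest

from wakewatch.adcp import (ADCPEnsemble, InstrumentConfig, VelocitySection,
                            compute_sv, correct_velocity, grid_section,
                            slant_range, vertical_velocity_fluctuation,
                            wake_deficit_extent, water_absorption)
from wakewatch.synthetic_data import ADCPSimConfig, generate_adcp_transect


def _cfg(**kw):
    return InstrumentConfig(**kw)


class TestSlantRange:
    def test_hand_arithmetic_first_bin(self):
        cfg = _cfg(blank=1.6, pulse_length=1.0, bin_size=1.0,
                   beam_angle_deg=20.0)
        expect = (1.6 + 1.0 + 0.25) / np.cos(np.deg2rad(20.0))
        assert np.isclose(slant_range(1, cfg), expect)
        assert np.isclose(slant_range(1, cfg), 3.033, atol=5e-4)

    def test_strictly_increasing_with_constant_slope(self):
        cfg = _cfg()
        n = np.arange(1, 41)
        R = slant_range(n, cfg)
        assert np.allclose(np.diff(R),
                           cfg.bin_size / np.cos(np.deg2rad(cfg.beam_angle_deg)))

    def test_vertical_beam_limit(self):
        cfg = _cfg(beam_angle_deg=1e-9, blank=2.0, pulse_length=0.5,
                   bin_size=1.0)
        assert np.isclose(slant_range(3, cfg),
                          2.0 + 0.75 + 2.0 + 0.25, atol=1e-6)

    def test_zero_based_index_rejected(self):
        with pytest.raises(ValueError):
            slant_range(0, _cfg())


def _fg_absorption_reference(T, S, depth, f_khz, pH=8.0):
    """Independent transcription of the Francois & Garrison (1982) model."""
    c = 1412.0 + 3.21 * T + 1.19 * S + 0.0167 * depth
    f = f_khz
    A1 = (8.86 / c) * 10 ** (0.78 * pH - 5.0)
    f1 = 2.8 * (S / 35.0) ** 0.5 * 10 ** (4.0 - 1245.0 / (273.0 + T))
    boric = A1 * f1 * f * f / (f1 * f1 + f * f)
    A2 = 21.44 * S / c * (1 + 0.025 * T)
    P2 = 1 - 1.37e-4 * depth + 6.2e-9 * depth * depth
    f2 = 8.17 * 10 ** (8.0 - 1990.0 / (273.0 + T)) / (1 + 0.0018 * (S - 35.0))
    mgso4 = A2 * P2 * f2 * f * f / (f2 * f2 + f * f)
    if T <= 20:
        A3 = 4.937e-4 - 2.59e-5 * T + 9.11e-7 * T ** 2 - 1.50e-8 * T ** 3
    else:
        A3 = 3.964e-4 - 1.146e-5 * T + 1.45e-7 * T ** 2 - 6.5e-10 * T ** 3
    P3 = 1 - 3.83e-5 * depth + 4.9e-10 * depth * depth
    water = A3 * P3 * f * f
    return (boric + mgso4 + water) / 1000.0


class TestWaterAbsorption:
    def test_matches_independent_transcription(self):
        for (T, S, d, f) in [(10, 35, 10, 600), (5, 34, 25, 600),
                             (15, 30, 5, 300), (12, 34, 15, 1000)]:
            assert np.isclose(water_absorption(T, S, d, f),
                              _fg_absorption_reference(T, S, d, f),
                              atol=1e-6)

    def test_freshwater_absorbs_less_than_seawater(self):
        assert (water_absorption(10, 0.0, 10, 600)
                < water_absorption(10, 35.0, 10, 600))

    def test_positive_for_valid_inputs(self):
        for T in (0, 10, 20):
            for S in (0, 20, 35):
                assert water_absorption(T, S, 10, 600) > 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            water_absorption(50.0, 35, 10, 600)
        with pytest.raises(ValueError):
            water_absorption(10, 35, 10, 0.01)


def _flat_ensemble(counts_value=80.0, n_bins=10, n_beams=4):
    return ADCPEnsemble(
        ping_time=0.0, position_along_transect=0.0,
        echo_counts=np.full((n_beams, n_bins), counts_value),
        measured_velocity=np.zeros((n_bins, 3)),
        bottom_track_velocity=np.zeros(2),
        temperature=10.0, salinity=35.0,
    )


class TestComputeSv:
    def test_noise_floor_counts_give_fixed_terms_only(self):
        cfg = _cfg(noise_floor=(80.0,) * 4)
        ens = _flat_ensemble(80.0)
        prof = compute_sv(ens, cfg)
        R = slant_range(np.arange(1, 11), cfg)
        depth = cfg.transducer_depth + R * np.cos(np.deg2rad(cfg.beam_angle_deg))
        alpha = np.array([water_absorption(10.0, 35.0, d, cfg.frequency_khz)
                          for d in depth])
        expect = (cfg.instrument_constant
                  + 10 * np.log10((10.0 + 273.16) * R ** 2)
                  - 10 * np.log10(cfg.pulse_length)
                  - cfg.transmit_power_dbw + 2 * alpha * R)
        assert np.allclose(prof.sv, expect[None, :], atol=1e-10)

    def test_sv_linear_in_counts_with_slope_kc(self):
        cfg = _cfg()
        e1, e2 = _flat_ensemble(80.0), _flat_ensemble(90.0)
        s1 = compute_sv(e1, cfg).sv
        s2 = compute_sv(e2, cfg).sv
        kc = np.asarray(cfg.rssi_scale)[:, None]
        assert np.allclose(s2 - s1, 10.0 * kc, atol=1e-12)

    def test_sv_max_is_beamwise_maximum(self):
        cfg = _cfg()
        ens = _flat_ensemble(80.0, n_bins=6)
        ens.echo_counts += np.array([[5.0], [17.0], [0.0], [9.0]])
        prof = compute_sv(ens, cfg)
        assert np.all(prof.sv_max >= prof.sv)
        assert np.allclose(prof.sv_max, prof.sv[1])  # beam with +17 counts
        # per-bin values (-80, -75, -90, -85) -> max -75
        assert np.max(np.array([-80.0, -75.0, -90.0, -85.0])) == -75.0

    def test_below_noise_floor_flagged_not_dropped(self):
        cfg = _cfg(noise_floor=(60.0,) * 4)
        prof = compute_sv(_flat_ensemble(50.0), cfg)
        assert prof.below_noise.all()
        assert np.isfinite(prof.sv).all()

    def test_bins_beyond_forty_excluded(self):
        prof = compute_sv(_flat_ensemble(80.0, n_bins=55), _cfg())
        assert prof.sv.shape[1] == 40


class TestCorrectVelocity:
    def test_moving_boat_over_still_water(self):
        ens = _flat_ensemble()
        ens.measured_velocity[:, 0] = -2.0  # water relative to moving boat
        ens.bottom_track_velocity = np.array([-2.0, 0.0])  # bt reading
        water = correct_velocity(ens)
        assert np.allclose(water[:, :2], 0.0)

    def test_stationary_boat_identity(self):
        ens = _flat_ensemble()
        ens.measured_velocity[:, 0] = 1.3
        water = correct_velocity(ens)
        assert np.allclose(water, ens.measured_velocity)

    def test_invalid_bottom_track_gives_nan(self):
        ens = _flat_ensemble()
        ens.bottom_track_velocity = np.array([np.nan, 0.0])
        assert np.isnan(correct_velocity(ens)).all()

    def test_recovers_generator_truth_to_noise_level(self):
        cfg = ADCPSimConfig(noise_sd_velocity=0.05, noise_sd_counts=0.0,
                            seed=2)
        ens, truth = generate_adcp_transect(cfg)
        errs = []
        for e in ens:
            w = correct_velocity(e)
            errs.append(np.hypot(w[:, 0], w[:, 1]).mean()
                        - truth.true_speed(e.position_along_transect))
        assert np.abs(np.mean(errs)) < 0.02
        assert np.std(errs) < 3 * 0.05


class TestGridSection:
    def test_single_ensemble_occupies_one_column(self):
        cfg = _cfg()
        sec = grid_section([_flat_ensemble()], cfg, y_bin=5.0)
        occupied = np.isfinite(sec.speed).any(axis=0)
        assert occupied.sum() == 1

    def test_two_ensembles_in_one_cell_average(self):
        cfg = _cfg()
        e1, e2 = _flat_ensemble(), _flat_ensemble()
        e1.measured_velocity[:, 0] = 1.0
        e2.measured_velocity[:, 0] = 3.0
        sec = grid_section([e1, e2], cfg, y_bin=5.0)
        vals = sec.speed[np.isfinite(sec.speed)]
        assert np.allclose(vals, 2.0)
        # every occupied cell holds samples from both pings
        occupied = sec.n_samples[sec.n_samples > 0]
        assert np.all(occupied % 2 == 0) and occupied.max() >= 2

    def test_section_reproduces_deficit_shape(self):
        cfg = ADCPSimConfig(seed=4)
        ens, truth = generate_adcp_transect(cfg)
        sec = grid_section(ens, cfg.instrument, y_bin=5.0)
        prof = sec.depth_averaged_speed()
        expect = truth.true_speed(sec.y)
        ok = np.isfinite(prof)
        assert np.max(np.abs(prof[ok] - expect[ok])) < 2 * cfg.noise_sd_velocity


class TestWakeDeficitExtent:
    def _section_from_profile(self, y, speed):
        nz = 3
        sp = np.tile(speed, (nz, 1))
        return VelocitySection(y=y, z=np.arange(nz, dtype=float), speed=sp,
                               sv_max=np.full_like(sp, -80.0),
                               w=np.zeros_like(sp),
                               n_samples=np.ones_like(sp, dtype=int))

    def test_flat_profile_returns_zero_with_warning(self):
        sec = self._section_from_profile(np.linspace(-50, 50, 21),
                                         np.full(21, 3.0))
        with pytest.warns(UserWarning, match="no velocity deficit"):
            assert wake_deficit_extent(sec, reference_speed=3.0) == 0.0

    def test_triangular_deficit_half_width_by_similar_triangles(self):
        y = np.linspace(-40, 40, 161)  # 0.5 m resolution
        deficit = np.clip(1.0 - np.abs(y) / 20.0, 0.0, None)  # base 40 m
        sec = self._section_from_profile(y, 3.0 - deficit)
        extent = wake_deficit_extent(sec, reference_speed=3.0, fraction=0.5)
        assert np.isclose(extent, 20.0, atol=0.1)

    def test_recovers_generator_default_width(self):
        cfg = ADCPSimConfig(seed=11)
        ens, truth = generate_adcp_transect(cfg)
        sec = grid_section(ens, cfg.instrument, y_bin=5.0)
        extent = wake_deficit_extent(sec, fraction=0.5)
        assert abs(extent - truth.width_fwhm) <= 3.0


class TestVerticalVelocityFluctuation:
    def test_constant_series_gives_zero(self):
        assert vertical_velocity_fluctuation(np.full(100, 0.4), 21) <= 1e-12

    def test_quantile_matches_brute_force(self):
        t = np.linspace(0, 20 * np.pi, 2000)
        w = 0.8 * np.sin(t)
        window = 501
        half = window // 2
        # brute-force centred moving mean, clipped at the edges
        wp = np.empty_like(w)
        for i in range(w.size):
            lo, hi = max(0, i - half), min(w.size, i + half + 1)
            wp[i] = abs(w[i] - w[lo:hi].mean())
        expect = np.quantile(wp, 0.95)
        got = vertical_velocity_fluctuation(w, window)
        assert np.isclose(got, expect, atol=1e-12)

    def test_mask_restricts_region(self):
        w = np.vstack([np.zeros(50), np.sin(np.linspace(0, 8 * np.pi, 50))])
        full = vertical_velocity_fluctuation(w, 11)
        masked = vertical_velocity_fluctuation(
            w, 11, mask=np.array([[True], [False]]))
        assert masked < full

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError):
            vertical_velocity_fluctuation(np.zeros(10), 11)
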