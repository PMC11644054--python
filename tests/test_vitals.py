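"""Range FFT, bin selection, phase extraction, rate estimation, agreement."""

import numpy as np
import pytest

from mmvital.radar import RadarConfig, SlowTimeCube, VitalScenario, _synthesize, beat_signal
from mmvital.vitals import (
    GateError,
    agreement,
    assign_modes,
    estimate_rates,
    extract_phase,
    predictive_unwrap,
    process_cube,
    range_fft,
    select_bin,
    spectral_peak,
    windowed_rates,
)
from mmvital.vmd import VMDResult, vmd


def make_cube(distances, amplitudes=None, noise=0.0, n_rx=1, seed=0):
    config = RadarConfig()
    distances = np.asarray(distances, float)
    if amplitudes is None:
        amplitudes = np.ones(distances.size)
    rng = np.random.default_rng(seed)
    iq = _synthesize(config, distances, np.asarray(amplitudes, float), noise, rng, n_rx)
    t = np.arange(distances.size) * config.frame_time
    return SlowTimeCube(iq=iq, config=config, timestamps=t, truth_displacement=distances)


class TestRangeFft:
    def test_target_at_0_6_m_peaks_in_bin_20(self):
        profile = range_fft(make_cube(np.full(4, 0.6)))
        power = np.abs(profile.data[0]).mean(axis=0)
        assert np.argmax(power) == 20
        assert profile.bin_spacing == pytest.approx(0.0299792458)

    def test_zero_input_all_zero(self):
        cube = make_cube(np.full(3, 0.6), amplitudes=np.zeros(3))
        profile = range_fft(cube)
        assert np.all(profile.data == 0)

    def test_two_targets_two_bins_apart_resolved(self):
        # superpose two cubes: targets at 0.6 m (bin 20) and 0.72 m (bin 24)
        a = make_cube(np.full(4, 0.6))
        b = make_cube(np.full(4, 0.72))
        a.iq = a.iq + b.iq
        power = np.abs(range_fft(a).data[0]).mean(axis=0)
        import scipy.signal as sps

        peaks, _ = sps.find_peaks(power, prominence=0.2 * power.max())
        assert {20, 24}.issubset(set(peaks.tolist()))


class TestSelectBin:
    def test_single_target_selected(self):
        sel = select_bin(range_fft(make_cube(np.full(4, 0.6))))
        assert sel.index == 20 and not sel.no_target

    def test_target_outside_gate_flagged(self):
        sel = select_bin(range_fft(make_cube(np.full(16, 0.3), noise=1e-3)))
        assert sel.no_target

    def test_tie_breaks_to_lowest_bin(self):
        profile = range_fft(make_cube(np.full(4, 0.6)))
        profile.data = np.ones_like(profile.data)  # perfect tie everywhere
        sel = select_bin(profile)
        assert sel.index == int(np.ceil(0.5 / profile.bin_spacing))

    def test_empty_gate_raises(self):
        profile = range_fft(make_cube(np.full(4, 0.6)))
        with pytest.raises(GateError):
            select_bin(profile, gate=(5.0, 6.0))


class TestExtractPhase:
    def test_sinusoidal_displacement_round_trip_below_1_micron(self):
        config = RadarConfig()
        t = np.arange(800) * config.frame_time
        disp = 1e-3 * np.sin(2 * np.pi * 0.3 * t)
        cube = make_cube(0.6 + disp)
        profile = range_fft(cube)
        ph = extract_phase(profile, select_bin(profile).index)
        # oracle: forward map with the full sensitivity (carrier + beat-tone
        # window-centroid term); the carrier part alone is 4 pi R / lambda
        amp = (ph.phase.max() - ph.phase.min()) / 2
        assert amp == pytest.approx(ph.phase_sensitivity * 1e-3, rel=2e-3)
        assert ph.phase_sensitivity == pytest.approx(4 * np.pi / config.wavelength, rel=0.05)
        recovered = ph.displacement
        truth = disp - disp.mean()
        assert np.sqrt(np.mean((recovered - truth) ** 2)) < 1e-6

    def test_constant_distance_constant_phase(self):
        profile = range_fft(make_cube(np.full(32, 0.63)))
        ph = extract_phase(profile, select_bin(profile).index)
        np.testing.assert_allclose(ph.phase, ph.phase[0], atol=1e-9)

    def test_unwrap_continuity_across_quarter_wavelength(self):
        config = RadarConfig()
        t = np.arange(400) * config.frame_time
        disp = 3e-3 * np.sin(2 * np.pi * 0.2 * t)  # crosses lambda/4 repeatedly
        profile = range_fft(make_cube(0.6 + disp))
        ph = extract_phase(profile, select_bin(profile).index)
        assert np.abs(np.diff(ph.phase)).max() < np.pi

    def test_predictive_unwrap_follows_fast_smooth_ramps(self):
        # increments approach pi: plain unwrap of the wrapped signal slips,
        # the predictor tracks the smooth acceleration
        t = np.arange(600) * 0.0755
        true = 2.9 * t * np.sin(2 * np.pi * 0.05 * t)
        wrapped = np.angle(np.exp(1j * true))
        out = predictive_unwrap(wrapped)
        assert np.abs(out - true).max() < np.pi

    def test_invalid_bin_rejected(self):
        profile = range_fft(make_cube(np.full(4, 0.6)))
        with pytest.raises(ValueError):
            extract_phase(profile, 99)


class TestModeAssignment:
    @staticmethod
    def result_with(freqs, powers):
        n = 256
        modes = np.stack([np.sqrt(2 * p) * np.cos(2 * np.pi * f * np.arange(n) / 13.249)
                          for f, p in zip(freqs, powers)])
        return VMDResult(modes=modes, center_frequencies=np.asarray(freqs, float),
                         fs=13.249, alpha=2000.0, residual=0.0, n_iterations=1,
                         converged=True)

    def test_simple_two_mode_assignment(self):
        asn = assign_modes(self.result_with([0.3, 1.2], [1.0, 0.5]))
        assert (asn.resp_index, asn.heart_index) == (0, 1)

    def test_out_of_band_modes_flagged(self):
        asn = assign_modes(self.result_with([0.05, 3.4], [1.0, 1.0]))
        assert asn.missing_resp and asn.missing_heart

    def test_higher_power_mode_wins_within_band(self):
        asn = assign_modes(self.result_with([0.3, 0.9, 1.8], [1.0, 0.2, 0.6]))
        assert asn.heart_index == 2


class TestRates:
    def test_pure_tone_60_bpm(self):
        fs = 1 / 0.075476
        t = np.arange(int(120 * fs)) / fs
        tone = np.sin(2 * np.pi * 1.0 * t)
        assert spectral_peak(tone, fs) * 60 == pytest.approx(60.0, abs=0.05)

    def test_standby_rates_within_0_02_hz(self):
        scn = VitalScenario(resp_freq=0.25, heart_freq=1.1, duration=120.0,
                            motion_rms_acc=0.030, seed=5)
        est = process_cube(beat_signal(scn, seed=5))
        assert est.resp_hz == pytest.approx(0.25, abs=0.02)
        assert est.heart_hz == pytest.approx(1.1, abs=0.02)
        assert est.ibi_ms.size >= 3 and np.all(est.ibi_ms > 300)
        assert est.ibi_ms.mean() == pytest.approx(1000 / 1.1, rel=0.02)

    def test_constant_mode_flagged(self):
        result = VMDResult(modes=np.vstack([np.zeros(256), np.zeros(256)]),
                           center_frequencies=np.array([0.3, 1.2]), fs=13.249,
                           alpha=2000.0, residual=0.0, n_iterations=1, converged=True)
        est = estimate_rates(result, assign_modes(result), 13.249)
        assert "bbi-series-short" in est.flags and "ibi-series-short" in est.flags

    def test_windowed_rates_shapes(self):
        scn = VitalScenario(resp_freq=0.3, heart_freq=1.2, duration=90.0,
                            motion_rms_acc=0.03, seed=2)
        cube = beat_signal(scn, seed=2)
        profile = range_fft(cube)
        ph = extract_phase(profile, select_bin(profile).index)
        resp, heart = windowed_rates(ph, window_s=30.0)
        assert resp.size == heart.size >= 3
        assert np.all(np.abs(heart - 1.2) < 0.1)


class TestAgreement:
    def test_symmetric_differences(self):
        report = agreement([1.0, 0.0, 1.0], [0.0, 1.0, 1.0])
        assert report.mean_difference == pytest.approx(0.0)
        assert report.loa_high == pytest.approx(1.96)
        assert report.loa_low == pytest.approx(-1.96)

    def test_identical_series(self):
        report = agreement([5.0, 6.0, 7.0], [5.0, 6.0, 7.0])
        assert report.mean_difference == 0.0
        assert report.loa_low == report.loa_high == 0.0
        assert report.error_percent == 0.0

    def test_printed_heart_rate_pair_error_percent(self):
        # oracle: direct computation from the two mean heart rates
        report = agreement(np.full(3, 72.0661), np.full(3, 72.6271))
        assert report.error_percent == pytest.approx(0.772, abs=5e-4)

    def test_zero_mean_reference_flagged(self):
        report = agreement([1.0, -1.0, 0.5], [1.0, -1.0, 0.0])
        assert report.error_percent is None
        assert "zero-mean-reference" in report.flags

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            agreement([1.0, 2.0], [1.0, 2.0, 3.0])
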