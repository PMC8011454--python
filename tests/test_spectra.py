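"""Spectral pipeline: resampling, filtering, segmentation, power scaling."""

import numpy as np
import pytest

import hnslab as H
from hnslab.beats import BeatSeries
from hnslab.spectra import (
    BANDS,
    EvenSeries,
    averaged_spectrum,
    band_power,
    bpv_pipeline,
    detrend_linear,
    hanning_filter9,
    resample_even,
    segment_series,
)


def _constant_beats(sbp=120.0, duration=410.0, pi_s=0.2):
    t = np.arange(0.0, duration + pi_s / 2, pi_s)
    return BeatSeries(t, np.full(t.size, sbp), np.full(t.size, sbp - 40.0))


class TestResample:
    def test_constant_sbp_410s_gives_8200_samples(self):
        series = resample_even(_constant_beats(), "SBP")
        assert len(series) == 8200
        np.testing.assert_allclose(series.values, 120.0)

    def test_linear_interpolation_between_beats(self):
        beats = BeatSeries([0.0, 1.0, 2.0], [100.0, 120.0, 100.0], [60.0, 80.0, 60.0])
        series = resample_even(beats, "SBP", fs_hz=2.0)
        assert series.values[1] == pytest.approx(110.0)  # midpoint of the rise

    def test_planted_frequency_preserved(self):
        p = H.WaveformSimParams(duration_s=420, mean_hr=300,
                                band_oscillations=((0.25, 2.0),), seed=31)
        beats, _ = H.simulate_beat_series(p)
        series = resample_even(beats, "SBP")
        spec = averaged_spectrum(segment_series(series, 30, 2048), series.fs_hz)
        away_from_dc = spec.freq_hz >= 0.05  # skip mean-level leakage
        peak = spec.freq_hz[away_from_dc][np.argmax(spec.power[away_from_dc])]
        assert peak == pytest.approx(0.25, abs=0.02)

    def test_too_short_rejected(self):
        beats = BeatSeries([0.0, 0.3], [120.0, 121.0], [80.0, 81.0])
        with pytest.raises(ValueError):
            resample_even(beats, "SBP")


class TestHanningFilter:
    def test_constant_unchanged(self):
        s = EvenSeries(np.full(100, 7.0))
        np.testing.assert_allclose(hanning_filter9(s).values, 7.0, atol=1e-12)

    def test_impulse_response_is_normalised_kernel(self):
        x = np.zeros(41)
        x[20] = 1.0
        out = hanning_filter9(EvenSeries(x)).values
        w = np.hanning(9) / np.hanning(9).sum()
        np.testing.assert_allclose(out[16:25], w, atol=1e-12)
        assert out.sum() == pytest.approx(1.0)

    def test_white_noise_variance_reduction(self):
        rng = np.random.default_rng(32)
        x = rng.normal(0, 1, 200_000)
        out = hanning_filter9(EvenSeries(x)).values
        w = np.hanning(9) / np.hanning(9).sum()
        assert out.var() == pytest.approx(np.sum(w**2), rel=0.02)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            hanning_filter9(EvenSeries(np.zeros(8)))


class TestDetrend:
    def test_exact_line_zeroed(self):
        t = np.arange(100.0)
        out = detrend_linear(EvenSeries(3.0 + 0.5 * t)).values
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_sinusoid_survives_trend_removal(self):
        # an integer-cycle cosine centred on the grid midpoint is exactly
        # orthogonal to the constant and linear regressors, so it passes
        # through trend removal unchanged
        n = np.arange(2048)
        t = n / 20.0
        tone = 2.0 * np.cos(2 * np.pi * 50 * (n - (n.size - 1) / 2) / n.size)
        out = detrend_linear(EvenSeries(5.0 + 0.1 * t + tone)).values
        assert np.sqrt(np.mean((out - tone) ** 2)) < 1e-8
        assert abs(out.mean()) < 1e-10


class TestSegmentation:
    def test_canonical_410s_layout(self):
        segs = segment_series(EvenSeries(np.arange(8200.0)), 30, 2048)
        assert len(segs) == 30
        starts = [int(s[0]) for s in segs]
        assert starts == [i * 212 for i in range(30)]
        assert starts[-1] == 6148

    def test_exact_length_gives_single_segment(self):
        segs = segment_series(EvenSeries(np.zeros(2048)), 30, 2048)
        assert len(segs) == 1

    def test_segments_within_bounds(self):
        segs = segment_series(EvenSeries(np.arange(5000.0)), 30, 2048)
        for s in segs:
            assert s.size == 2048
            assert 0 <= s[0] and s[-1] <= 4999

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            segment_series(EvenSeries(np.zeros(100)), 30, 2048)


class TestAveragedSpectrum:
    def test_sinusoid_integrates_to_half_amplitude_squared(self):
        t = np.arange(8200) / 20.0
        x = 2.0 * np.sin(2 * np.pi * 0.1 * t)
        spec = averaged_spectrum(segment_series(EvenSeries(x), 30, 2048), 20.0)
        p = band_power(spec, (0.05, 0.15))
        assert p == pytest.approx(2.0, rel=0.05)

    def test_zero_signal_zero_spectrum(self):
        spec = averaged_spectrum([np.zeros(2048)], 20.0)
        assert spec.power.sum() == 0.0

    def test_white_noise_parseval(self):
        rng = np.random.default_rng(33)
        x = rng.normal(0, 2.0, 8200)
        spec = averaged_spectrum(segment_series(EvenSeries(x), 30, 2048), 20.0)
        assert spec.power.sum() == pytest.approx(4.0, rel=0.10)


class TestBandPower:
    def test_planted_vlf_tone_lands_in_vlf(self, vlf_tone_beats):
        series, _ = vlf_tone_beats
        bp = bpv_pipeline(series, "SBP")
        assert bp.vlf >= 0.95 * bp.total

    def test_planted_lf_tone_lands_in_lf(self):
        p = H.WaveformSimParams(duration_s=420, mean_hr=300,
                                band_oscillations=((0.4, 2.0),), seed=34)
        beats, _ = H.simulate_beat_series(p)
        bp = bpv_pipeline(beats, "SBP")
        assert bp.lf >= 0.95 * bp.total
        assert bp.vlf <= 0.05 * bp.total

    def test_band_additivity_any_input(self):
        rng = np.random.default_rng(35)
        x = rng.normal(0, 1, 4096)
        spec = averaged_spectrum(segment_series(EvenSeries(x), 30, 2048), 20.0)
        total = band_power(spec, BANDS["total"])
        parts = sum(band_power(spec, BANDS[b]) for b in ("vlf", "lf", "hf"))
        assert total == pytest.approx(parts, rel=1e-12)

    def test_inverted_band_rejected(self):
        spec = averaged_spectrum([np.zeros(2048)], 20.0)
        with pytest.raises(ValueError):
            band_power(spec, (1.0, 0.5))


class TestPipeline:
    def test_two_tone_powers(self):
        p = H.WaveformSimParams(
            duration_s=420, mean_hr=300,
            band_oscillations=((0.1, 2.0), (0.4, 1.0)), seed=36)
        beats, _ = H.simulate_beat_series(p)
        bp = bpv_pipeline(beats, "SBP")
        assert bp.vlf == pytest.approx(2.0, rel=0.10)
        assert bp.lf == pytest.approx(0.5, rel=0.10)

    def test_constant_series_zero_power(self, quiet_beats):
        series, _ = quiet_beats
        bp = bpv_pipeline(series, "SBP")
        assert bp.total < 1e-12

    def test_amplitude_doubling_quadruples_power(self):
        powers = []
        for amp in (1.0, 2.0):
            p = H.WaveformSimParams(duration_s=420, mean_hr=300,
                                    band_oscillations=((0.1, amp),), seed=37)
            beats, _ = H.simulate_beat_series(p)
            powers.append(bpv_pipeline(beats, "SBP").vlf)
        assert powers[1] / powers[0] == pytest.approx(4.0, rel=0.05)

    def test_time_shift_stability(self):
        # circularly shifting the even series moves band powers by <5%
        p = H.WaveformSimParams(duration_s=420, mean_hr=300,
                                band_oscillations=((0.1, 2.0),), seed=38)
        beats, _ = H.simulate_beat_series(p)
        series = detrend_linear(hanning_filter9(resample_even(beats, "SBP")))
        ref = averaged_spectrum(segment_series(series, 30, 2048), 20.0)
        shifted = series.replace(np.roll(series.values, 911))
        alt = averaged_spectrum(segment_series(shifted, 30, 2048), 20.0)
        for key in ("vlf", "lf"):
            a, b = band_power(ref, BANDS[key]), band_power(alt, BANDS[key])
            if max(a, b) > 1e-6:
                assert abs(a - b) / max(a, b) < 0.05

    def test_hr_variant_units(self, quiet_beats):
        series, _ = quiet_beats
        assert bpv_pipeline(series, "HR").units == "bpm^2"

    def test_short_recording_warns(self):
        beats = _constant_beats(duration=150.0)
        with pytest.warns(UserWarning, match="410"):
            bpv_pipeline(beats, "SBP")
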