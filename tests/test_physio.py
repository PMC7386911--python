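"""Physiological signal processing: filtering, beats, cleaning, spectra,
paired statistics and motion QC."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as spstats

from micacardio import physio
from micacardio.synthgen import make_physio, make_realign
from micacardio.types import BeatSeries, DesignBlocks, FrequencyBand, PhysioTrace, RealignmentTrack


def _sine_trace(freq, fs=100.0, duration=120.0, kind="pulse"):
    t = np.arange(int(duration * fs)) / fs
    return PhysioTrace(samples=np.sin(2 * np.pi * freq * t), fs=fs, kind=kind)


class TestBandpass:
    def test_in_band_tone_passes_nearly_unattenuated(self):
        out = physio.bandpass(_sine_trace(1.2), 0.64, 2.5)
        mid = out.samples[2000:-2000]
        assert np.abs(mid).max() > 0.99

    def test_out_of_band_tone_is_suppressed(self):
        out = physio.bandpass(_sine_trace(0.1), 0.64, 2.5)
        mid = out.samples[4000:-4000]
        assert np.abs(mid).max() < 0.05  # > 95 % attenuation

    def test_band_outside_nyquist_raises(self):
        with pytest.raises(ValueError):
            physio.bandpass(_sine_trace(1.0, fs=10), 6.0, 8.0)


class TestDetectBeats:
    def test_recovers_metronomic_beats(self):
        pulse, *_ , truth = make_physio(120, 50, hr_bpm=60, rsa_depth=0.0, seed=2)
        beats = physio.detect_beats(physio.bandpass(pulse, *physio.PULSE_BAND))
        assert len(beats) == len(truth.beat_times)
        err = np.abs(beats.times - truth.beat_times)
        assert err.max() <= 1.0 / 50 + 1e-9  # within one sample

    def test_flat_trace_warns_and_returns_empty(self):
        trace = PhysioTrace(samples=np.zeros(500), fs=50.0, kind="pulse")
        with pytest.warns(UserWarning):
            beats = physio.detect_beats(trace)
        assert len(beats) == 0

    def test_refractory_interval_keeps_larger_peak(self):
        fs = 100.0
        t = np.arange(int(2 * fs)) / fs
        x = np.exp(-0.5 * ((t - 0.9) / 0.03) ** 2) + 0.7 * np.exp(-0.5 * ((t - 1.1) / 0.03) ** 2)
        beats = physio.detect_beats(PhysioTrace(samples=x, fs=fs, kind="pulse"), min_rr=0.4)
        assert len(beats) == 1
        assert abs(beats.times[0] - 0.9) < 0.02

    def test_manual_edit_hook(self):
        beats = BeatSeries(times=np.array([1.0, 2.0, 3.0]), values=np.ones(3))
        edited = beats.insert_beat(2.5, 1.0).delete_beat(0)
        assert np.allclose(edited.times, [2.0, 2.5, 3.0])


class TestCleanBp:
    def _trace(self, n=5000, fs=50.0, seed=0):
        rng = np.random.default_rng(seed)
        x = 110 + 10 * np.sin(2 * np.pi * 0.1 * np.arange(n) / fs) + rng.normal(0, 1, n)
        return x

    def test_spikes_are_replaced_and_range_restored(self):
        x = self._trace()
        spikes = [100, 900, 2500, 3300, 4400]
        x[spikes] += 100.0
        out = physio.clean_bp(PhysioTrace(samples=x, fs=50.0, kind="bp"))
        clean = np.delete(self._trace(), spikes)
        p1, p99 = np.percentile(clean, [1, 99])
        assert out.samples[spikes].max() <= p99 + 1e-9
        assert not out.valid[spikes].any()

    def test_constant_clean_trace_unchanged(self):
        x = np.full(1000, 120.0)
        out = physio.clean_bp(PhysioTrace(samples=x, fs=50.0, kind="bp"))
        assert np.array_equal(out.samples, x)

    def test_all_invalid_raises_quality_error(self):
        trace = PhysioTrace(samples=np.zeros(100), fs=50.0, kind="bp", valid=np.zeros(100, bool))
        with pytest.raises(physio.QualityError):
            physio.clean_bp(trace)

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=20, deadline=None)
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        x = 100 + rng.standard_normal(2000) * 5
        valid = rng.random(2000) > 0.05
        out1 = physio.clean_bp(PhysioTrace(samples=x, fs=50.0, kind="bp", valid=valid))
        out2 = physio.clean_bp(out1)
        assert np.array_equal(out1.samples, out2.samples)
        assert np.array_equal(out1.valid, out2.valid)


class TestBeatToBeat:
    def test_unit_intervals(self):
        beats = BeatSeries(times=np.arange(4.0), values=np.ones(4))
        ibi, sbp = physio.beat_to_beat(beats, None)
        assert np.allclose(ibi.values, [1, 1, 1])
        assert sbp is None

    def test_rate_step_changes_mean_interval(self):
        times = np.concatenate([np.arange(0, 30, 1.0), 30 + np.arange(0, 30, 60 / 70)])
        ibi, _ = physio.beat_to_beat(BeatSeries(times=times, values=np.ones(len(times))), None)
        assert np.mean(ibi.values[:29]) == pytest.approx(1.0, abs=1e-9)
        assert np.mean(ibi.values[31:]) == pytest.approx(60 / 70, abs=1e-9)

    def test_too_few_beats_raises(self):
        with pytest.raises(physio.InsufficientDataError):
            physio.beat_to_beat(BeatSeries(times=np.array([0.0, 1.0]), values=np.zeros(2)), None)

    def test_systolic_is_max_within_beat(self):
        fs = 100.0
        t = np.arange(int(4 * fs)) / fs
        bp = PhysioTrace(samples=100 + 20 * np.sin(2 * np.pi * 1.0 * t), fs=fs, kind="bp")
        beats = BeatSeries(times=np.array([0.0, 1.0, 2.0, 3.0]), values=np.ones(4))
        _, sbp = physio.beat_to_beat(beats, bp)
        assert np.allclose(sbp.values, 120.0, atol=0.1)


class TestBandFractions:
    def test_pure_lf_oscillation_dominates_lf_band(self):
        times = np.arange(0, 300, 1.0)
        values = 1.0 + 0.1 * np.sin(2 * np.pi * 0.1 * times)
        frac = physio.band_fraction_series(
            BeatSeries(times=times, values=values), FrequencyBand(0.1, 0.03)
        )
        assert frac >= 0.9

    def test_white_noise_fraction_matches_flat_spectrum_expectation(self):
        # series sampled directly on the 4 Hz grid -> flat PSD to 2 Hz
        band = FrequencyBand(0.1, 0.03)
        expected = 0.06 / (2.0 - physio.HP_FLOOR)
        fracs = []
        for seed in range(60):
            rngl = np.random.default_rng(seed)
            times = np.arange(0, 240, 0.25)
            series = BeatSeries(times=times, values=rngl.standard_normal(len(times)))
            fracs.append(physio.band_fraction_series(series, band))
        assert np.mean(fracs) == pytest.approx(expected, abs=0.004)

    def test_disjoint_partition_sums_to_one(self):
        rngl = np.random.default_rng(11)
        times = np.arange(0, 300, 0.5)
        series = BeatSeries(times=times, values=rngl.standard_normal(len(times)))
        edges = [physio.HP_FLOOR, 0.1, 0.5, 1.0, 2.6]
        total = 0.0
        for lo, hi in zip(edges[:-1], edges[1:]):
            band = FrequencyBand((lo + hi) / 2, (hi - lo) / 2)
            total += physio.band_fraction_series(series, band)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_short_series_raises(self):
        series = BeatSeries(times=np.arange(0, 20, 1.0), values=np.ones(20))
        with pytest.raises(physio.InsufficientDataError):
            physio.band_fraction_series(series, FrequencyBand(0.1, 0.03))


class TestDefineBands:
    @staticmethod
    def _spectrum(peak):
        f = np.linspace(0.01, 0.6, 400)
        return f, np.exp(-0.5 * ((f - peak) / 0.01) ** 2) + 0.01

    def test_identical_peaks_give_zero_width(self):
        band = physio.define_bands([self._spectrum(0.1)] * 3, "LF")
        assert band.centre == pytest.approx(0.1, abs=2e-3)
        assert band.half_width == pytest.approx(0.0, abs=1e-9)

    def test_spread_peaks_give_sample_sd_width(self):
        band = physio.define_bands([self._spectrum(p) for p in (0.07, 0.10, 0.13)], "LF")
        assert band.centre == pytest.approx(0.10, abs=2e-3)
        assert band.half_width == pytest.approx(0.03, abs=2e-3)  # sd({.07,.10,.13}), ddof=1

    def test_empty_input_raises(self):
        with pytest.raises(physio.InsufficientDataError):
            physio.define_bands([], "LF")

    def test_peakless_subject_skipped_with_warning(self):
        f = np.linspace(0.01, 0.6, 400)
        flat = (f, np.full_like(f, 0.01))
        with pytest.warns(UserWarning):
            band = physio.define_bands([flat, self._spectrum(0.28), self._spectrum(0.28)], "HF")
        assert band.centre == pytest.approx(0.28, abs=2e-3)


class TestPairedTest:
    def test_identical_conditions_are_null(self):
        res = physio.paired_test([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.t == 0 and res.p == 1 and res.d == 0

    def test_printed_blood_pressure_summary_reproduces_effect_size(self):
        # systolic BP under orthostatic stress: 132.6 +/- 20.2 vs 113.4 +/- 20.2 mmHg
        d = physio.cohens_d_from_summary(132.6, 113.4, 20.2, 20.2)
        assert round(d, 2) == -0.95

    def test_constant_nonzero_differences_are_degenerate(self):
        with pytest.raises(physio.DegenerateDataError):
            physio.paired_test([1, 2, 3, 4], [2, 3, 4, 5])

    def test_matches_reference_t_distribution_on_random_inputs(self):
        rngl = np.random.default_rng(99)
        for _ in range(200):
            n = int(rngl.integers(3, 30))
            rest = rngl.standard_normal(n) * rngl.uniform(0.5, 3)
            lbnp = rest + rngl.standard_normal(n) + rngl.uniform(-1, 1)
            res = physio.paired_test(rest, lbnp)
            ref_t, ref_p = spstats.ttest_rel(lbnp, rest)
            assert abs(res.t - ref_t) < 1e-10
            assert abs(res.p - ref_p) < 1e-8


class TestMotion:
    def test_identity_track_has_zero_displacement(self):
        track = RealignmentTrack(matrices=np.tile(np.eye(4), (5, 1, 1)))
        assert np.all(physio.motion_rms(track) == 0)

    def test_translation_step_measures_one_mm(self):
        mats = np.tile(np.eye(4), (10, 1, 1))
        mats[6:, 0, 3] = 1.0  # 1 mm x-shift between volumes 5 and 6
        disp = physio.motion_rms(RealignmentTrack(matrices=mats))
        assert disp[6] == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.delete(disp, 6) == 0)

    def test_single_volume_raises(self):
        with pytest.raises(physio.InsufficientDataError):
            physio.motion_rms(RealignmentTrack(matrices=np.eye(4)[None]))

    def test_random_walk_matches_closed_form_expectation(self):
        # pure translations: displacement = |delta|, E|delta| = sd * E[chi_3]
        import scipy.special as sps

        expected = 0.2 * np.sqrt(2) * sps.gamma(2.0) / sps.gamma(1.5)
        vals = [physio.motion_rms(make_realign(50, 0.2, seed=s))[1:].mean() for s in range(200)]
        mc_sd = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - expected) < 3 * mc_sd + 1e-3

    def test_compare_motion_pairs_blocks(self, design):
        series = [np.concatenate([np.full(240, 0.3), np.full(240, 0.1),
                                  np.full(240, 0.31), np.full(240, 0.12)]) for _ in range(3)]
        res = physio.compare_motion(series, design, tr=1.25)
        assert res.n == 6
        assert res.mean_lbnp > res.mean_rest
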