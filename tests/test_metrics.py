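import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgsuperpose import (
    BeatAnnotations,
    ChannelSpec,
    cmrr_db,
    detect_r_peaks,
    frequency_response,
    generate_clean_recording,
    heart_rate_series,
    hr_correlation,
    input_referred_noise_vpp,
    make_multichannel,
    snr_eq_pp,
    snr_multibeat,
)
from ecgsuperpose.experiments import expected_range_factor, noise_sigma_for_snr_db

FS = 250.0


class TestSNR:
    def _piecewise_beat(self):
        # flat signal with a known QRS excursion and a known noise ripple
        x = np.zeros(400)
        x[195] = 60.0
        x[205] = -40.0  # QRS vpp = 100 inside the 120 ms window around r=200
        x[300] = 5.0
        x[302] = -5.0  # noise vpp = 10 inside the 40 ms window at mid(280, 320)
        return x

    def test_constructed_20db_beat(self):
        rep = snr_eq_pp(self._piecewise_beat(), FS, r_index=200, t_end_index=280, next_p_index=320)
        assert rep.qrs_vpp == 100.0
        assert rep.noise_vpp == 10.0
        assert rep.snr_db == pytest.approx(20.0)

    def test_zero_noise_flags_infinite(self, template):
        clean = generate_clean_recording(template, 2)
        r = clean.r_indices[0]
        rep = snr_eq_pp(clean.values, FS, r, r + 70, r + 130)
        assert rep.is_infinite and np.isinf(rep.snr_db)

    def test_vpp_matches_bruteforce_scan(self, rng, template):
        clean = generate_clean_recording(template, 3)
        rec = make_multichannel(clean, [ChannelSpec(noise_sigma=50.0)], seed=13)
        x = rec.data[0]
        r = int(clean.r_indices[1])
        rep = snr_eq_pp(x, FS, r, r + 60, r + 138)
        # independent oracle: exhaustive scan over the reported windows
        q0, q1 = rep.qrs_window
        n0, n1 = rep.noise_window
        assert rep.qrs_vpp == max(x[q0:q1]) - min(x[q0:q1])
        assert rep.noise_vpp == max(x[n0:n1]) - min(x[n0:n1])
        assert q1 - q0 == pytest.approx(0.120 * FS, abs=1)
        assert n1 - n0 == pytest.approx(0.040 * FS, abs=1)

    @given(scale=st.floats(1e-3, 1e3))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, scale):
        x = self._piecewise_beat()
        a = snr_eq_pp(x, FS, 200, 280, 320)
        b = snr_eq_pp(scale * x, FS, 200, 280, 320)
        assert b.snr_db == pytest.approx(a.snr_db)

    def test_window_out_of_range(self):
        with pytest.raises(ValueError):
            snr_eq_pp(np.zeros(100), FS, 5, 50, 80)
        with pytest.raises(ValueError):
            snr_eq_pp(np.zeros(400), FS, 200, 320, 280)  # T end after next P

    def test_multibeat_median(self, template):
        clean = generate_clean_recording(template, 6)
        rec = make_multichannel(clean, [ChannelSpec(noise_sigma=80.0)], seed=3)
        med, reports = snr_multibeat(
            rec.data[0], FS, clean.r_indices, template.t_end_offset, template.p_onset_offset
        )
        assert med == pytest.approx(np.median([r.snr_db for r in reports]))
        assert len(reports) == 5


class TestDetector:
    def test_noiseless_exact_recovery(self, template):
        clean = generate_clean_recording(template, 10)
        ann = detect_r_peaks(clean.values, FS)
        np.testing.assert_array_equal(ann.r_indices, clean.r_indices)

    def test_noisy_recovery_within_20ms(self, template):
        clean = generate_clean_recording(template, 10)
        sigma = noise_sigma_for_snr_db(template, 15.0)
        rec = make_multichannel(clean, [ChannelSpec(noise_sigma=sigma)], seed=21)
        ann = detect_r_peaks(rec.data[0], FS)
        assert ann.n_beats == 10  # no spurious, no missed beats
        assert np.all(np.abs(ann.r_indices - clean.r_indices) <= 0.020 * FS)

    def test_all_zero_signal(self):
        with pytest.warns(UserWarning):
            ann = detect_r_peaks(np.zeros(1000), FS)
        assert ann.n_beats == 0

    def test_too_short_signal(self):
        with pytest.raises(ValueError):
            detect_r_peaks(np.ones(100), FS)
        with pytest.raises(ValueError):
            detect_r_peaks(np.ones(1000), 50.0)


class TestHeartRate:
    def test_constant_rr_180_samples(self):
        ann = BeatAnnotations(np.arange(10) * 180, FS)
        bpm = heart_rate_series(ann)
        assert bpm.size == 9
        np.testing.assert_allclose(bpm, 60.0 / (180 / 250))

    def test_constant_rr_one_second(self):
        ann = BeatAnnotations(np.arange(5) * 250, FS)
        np.testing.assert_allclose(heart_rate_series(ann), 60.0)

    def test_non_monotonic_rejected(self):
        with pytest.raises(ValueError):
            BeatAnnotations(np.array([0, 300, 200]), FS)
        with pytest.raises(ValueError):
            BeatAnnotations(np.array([0, 10]), FS)  # violates refractory

    def test_too_few_beats(self):
        with pytest.raises(ValueError):
            heart_rate_series(BeatAnnotations(np.array([100]), FS))


class TestHRCorrelation:
    def test_identical_annotations(self):
        idx = np.cumsum([0, 180, 190, 170, 185, 175])
        ann = BeatAnnotations(idx, FS)
        res = hr_correlation(ann, ann)
        assert res.r == pytest.approx(1.0)
        assert res.n_pairs == idx.size

    def test_shared_rr_process_high_correlation(self, template):
        from ecgsuperpose.experiments import run_hr_correlation

        res = run_hr_correlation(seed=99, n_beats=60, rr_jitter=0.05)
        assert res.pearson_r >= 0.99

    def test_disjoint_annotations_rejected(self):
        a = BeatAnnotations(np.arange(5) * 200, FS)
        b = BeatAnnotations(10_000 + np.arange(5) * 200, FS)
        with pytest.raises(ValueError):
            hr_correlation(a, b)


class TestCMRR:
    def test_bench_worked_example(self):
        assert cmrr_db(100.0, 926.5, 1000.0, 0.086) == pytest.approx(100.6, abs=0.1)

    def test_equal_gains_zero_db(self):
        assert cmrr_db(10.0, 50.0, 10.0, 50.0) == pytest.approx(0.0)

    def test_closed_form_60db(self):
        assert cmrr_db(1.0, 10.0, 1.0, 0.01) == pytest.approx(60.0)

    @given(c=st.floats(1e-3, 1e3))
    @settings(max_examples=25, deadline=None)
    def test_common_rescale_invariance(self, c):
        base = cmrr_db(100.0, 926.5, 1000.0, 0.086)
        assert cmrr_db(100.0 * c, 926.5 * c, 1000.0 * c, 0.086 * c) == pytest.approx(base)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            cmrr_db(0.0, 1.0, 1.0, 1.0)


class TestInputNoise:
    def test_constant_recording_zero(self):
        assert np.all(input_referred_noise_vpp(np.full((3, 100), 2.5), 12.0) == 0)

    def test_gain_linearity(self, rng):
        data = rng.normal(size=(4, 500))
        v1 = input_referred_noise_vpp(data, 1.0)
        v2 = input_referred_noise_vpp(data, 2.0)
        np.testing.assert_allclose(v2, v1 / 2)

    def test_calibrated_gaussian_vpp(self):
        # sigma chosen so the expected 10 s Vpp is 1.4 uV; every seeded
        # replicate must land within 25% of that value
        n = 2500
        sigma = 1.4 / expected_range_factor(n)
        rng = np.random.default_rng(8)
        for _ in range(100):
            vpp = input_referred_noise_vpp(rng.normal(0, sigma, size=(1, n)), 1.0)[0]
            assert abs(vpp - 1.4) / 1.4 < 0.25

    def test_invalid(self):
        with pytest.raises(ValueError):
            input_referred_noise_vpp(np.empty((0, 0)), 1.0)
        with pytest.raises(ValueError):
            input_referred_noise_vpp(np.ones((2, 10)), 0.0)


class TestFrequencyResponse:
    @staticmethod
    def _bandpass_gain(f, fl=0.15, fh=70.0, g0=12.0):
        hp = (f / fl) / np.sqrt(1 + (f / fl) ** 2)
        lp = 1 / np.sqrt(1 + (f / fh) ** 2)
        return g0 * hp * lp

    def test_recovers_first_order_corners(self):
        freqs = np.logspace(-2, 3, 60)
        sweep = [(f, 100.0, 100.0 * self._bandpass_gain(f)) for f in freqs]
        res = frequency_response(sweep)
        # analytic -3 dB points of the synthetic band-pass (well-separated
        # corners: the -3 dB points sit at the corner frequencies)
        from scipy.optimize import brentq

        peak_gain = max(self._bandpass_gain(f) for f in freqs)

        def crossing(f):
            return 20 * np.log10(self._bandpass_gain(f) / peak_gain) + 3.0

        f_lo = brentq(crossing, 1e-3, 1.0)
        f_hi = brentq(crossing, 10.0, 1e3)
        assert res.f_low_3db == pytest.approx(f_lo, rel=0.05)
        assert res.f_high_3db == pytest.approx(f_hi, rel=0.05)
        assert res.gain_db == pytest.approx(20 * np.log10(peak_gain), abs=0.2)

    def test_flat_response_open_ended(self):
        sweep = [(f, 10.0, 20.0) for f in (0.1, 1.0, 10.0, 100.0, 1000.0)]
        res = frequency_response(sweep)
        assert res.low_side_open and res.high_side_open
        assert res.gain_db == pytest.approx(20 * np.log10(2.0))

    def test_unity_everywhere(self):
        sweep = [(f, 5.0, 5.0) for f in (1, 2, 4, 8, 16)]
        assert frequency_response(sweep).gain_db == pytest.approx(0.0)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            frequency_response([(1.0, 1.0, 1.0)] * 3)
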