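"""Heart-rate extraction, respiratory flow, and SLFO construction."""

import numpy as np
import pytest

from gsdecomp.datatypes import PhysioTrace
from gsdecomp.errors import (
    DegenerateSignalError,
    InputError,
    SignalQualityError,
)
from gsdecomp.physio import (
    PRFPair,
    PRF_GRID_FS,
    beats_to_heart_rate,
    build_slfo,
    compute_respiratory_flow,
    convolve_at_volumes,
    detect_beats,
    estimate_prfs,
    gamma_kernel,
)


def pulse_train(beat_times, fs=200.0, duration=None, width=0.04, noise=0.0, rng=None):
    """Gaussian pulses at the given beat times."""
    duration = duration or (beat_times[-1] + 1.0)
    t = np.arange(int(duration * fs)) / fs
    x = np.zeros_like(t)
    for bt in beat_times:
        x += np.exp(-0.5 * ((t - bt) / width) ** 2)
    if noise:
        x += noise * (rng or np.random.default_rng(0)).standard_normal(t.size)
    return PhysioTrace(samples=x, fs=fs, modality="cardiac")


class TestDetectBeats:
    def test_60_bpm_train_gives_unit_intervals(self):
        beats_in = np.arange(0.5, 59.5, 1.0)
        trace = pulse_train(beats_in)
        beats = detect_beats(trace)
        ibi = np.diff(beats)
        assert np.all(np.abs(ibi - 1.0) < 0.01)

    def test_missing_beat_is_repaired_in_heart_rate(self):
        beats_in = np.arange(0.5, 59.5, 1.0)
        beats_in = np.delete(beats_in, 30)  # drop one beat -> 2 s gap
        trace = pulse_train(beats_in)
        hr = beats_to_heart_rate(detect_beats(trace))
        # Hampel replacement caps the deviation at the gap below 5 %
        assert np.abs(hr.values - 60.0).max() / 60.0 <= 0.05

    def test_flat_line_raises(self):
        trace = PhysioTrace(samples=np.zeros(2000), fs=200.0, modality="cardiac")
        with pytest.raises(SignalQualityError):
            detect_beats(trace)

    def test_wrong_modality_rejected(self):
        trace = PhysioTrace(samples=np.sin(np.arange(2000) / 10), fs=200.0,
                            modality="respiratory")
        with pytest.raises(InputError):
            detect_beats(trace)

    def test_noise_between_beats_does_not_create_beats(self):
        rng = np.random.default_rng(3)
        beats_in = np.arange(0.5, 59.5, 0.857)  # ~70 bpm
        trace = pulse_train(beats_in, noise=0.03, rng=rng)
        beats = detect_beats(trace)
        assert abs(beats.size - beats_in.size) <= 1


class TestBeatsToHeartRate:
    def test_constant_ibi_gives_constant_bpm(self):
        beats = np.arange(0, 40, 0.8)
        hr = beats_to_heart_rate(beats)
        np.testing.assert_allclose(hr.values, 75.0, atol=1e-6)

    def test_grid_spacing_is_exactly_100_ms(self):
        beats = np.arange(0, 40, 0.8)
        hr = beats_to_heart_rate(beats)
        assert hr.fs == PRF_GRID_FS

    def test_long_gap_replaced_by_local_median(self):
        # IBIs of 0.8 s with one 2.4 s dropout: the Hampel rule restores 75 bpm
        beats = np.concatenate([np.arange(0, 16.1, 0.8),
                                np.arange(18.4, 40, 0.8)])
        hr = beats_to_heart_rate(beats)
        np.testing.assert_allclose(hr.values, 75.0, atol=1e-6)

    def test_too_few_beats(self):
        with pytest.raises(InputError):
            beats_to_heart_rate(np.array([1.0]))


class TestRespiratoryFlow:
    def _trace(self, x, fs=100.0):
        return PhysioTrace(samples=x, fs=fs, modality="respiratory")

    def test_frequency_doubling_of_sinusoid(self):
        # d/dt sin(wt) squared = cos^2 -> component at 2 * 0.3 Hz
        fs = 100.0
        t = np.arange(int(120 * fs)) / fs
        flow = compute_respiratory_flow(self._trace(np.sin(2 * np.pi * 0.3 * t)))
        v = flow.values - flow.values.mean()
        freqs = np.fft.rfftfreq(v.size, d=1 / PRF_GRID_FS)
        spectrum = np.abs(np.fft.rfft(v))
        peak = freqs[np.argmax(spectrum)]
        assert abs(peak - 0.6) < 0.05

    def test_constant_trace_is_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            compute_respiratory_flow(self._trace(np.ones(5000)))

    def test_square_law_for_deeper_breathing(self):
        fs = 100.0
        t = np.arange(int(240 * fs)) / fs
        amp = np.where(t < 120, 1.0, 2.0)
        flow = compute_respiratory_flow(
            self._trace(amp * np.sin(2 * np.pi * 0.3 * t))
        )
        half = flow.values.size // 2
        margin = int(5 * PRF_GRID_FS)  # skip the amplitude step itself
        ratio = flow.values[half + margin:].mean() / flow.values[:half - margin].mean()
        assert 3.0 < ratio < 5.0

    def test_sign_invariance(self):
        rng = np.random.default_rng(1)
        x = np.cumsum(rng.standard_normal(4000)) / 10
        a = compute_respiratory_flow(self._trace(x))
        b = compute_respiratory_flow(self._trace(-x))
        np.testing.assert_allclose(a.values, b.values, atol=1e-10)


class TestConvolution:
    def test_matches_brute_force_discrete_convolution(self, rng):
        x = rng.standard_normal(100)
        kernel = rng.standard_normal(17)
        npad = kernel.size - 1
        xp = np.concatenate([np.full(npad, x[0]), x])
        expected_full = np.zeros(xp.size)
        for i in range(xp.size):
            for j in range(kernel.size):
                if i - j >= 0:
                    expected_full[i] += xp[i - j] * kernel[j]
        expected = expected_full[npad:]
        tr, n_vol = 0.5, 15
        got = convolve_at_volumes(x, kernel, tr, n_vol)
        idx = np.round(np.arange(n_vol) * tr * PRF_GRID_FS).astype(int)
        assert np.abs(got - expected[idx]).max() < 1e-10

    def test_linearity(self, rng):
        x = rng.standard_normal(200)
        kernel = gamma_kernel(4.0, 1.5)
        a = convolve_at_volumes(3.0 * x, kernel, 1.0, 15)
        b = 3.0 * convolve_at_volumes(x, kernel, 1.0, 15)
        # hold-first padding is linear as well, so exact scaling holds
        np.testing.assert_allclose(a, b, rtol=1e-12)


class TestBuildSlfo:
    def _hr_rf(self, rng, n10=1200):
        from gsdecomp.physio import HeartRateSeries, RespiratoryFlowSeries

        hr = HeartRateSeries(values=70 + 3 * np.sin(np.arange(n10) / 80)
                             + 0.3 * rng.standard_normal(n10))
        rf = RespiratoryFlowSeries(values=np.abs(rng.standard_normal(n10)))
        return hr, rf

    def _delta_prfs(self):
        grid = np.arange(0, 60.0 + 1e-9, 1 / PRF_GRID_FS)
        delta = np.zeros(grid.size)
        delta[0] = 1.0
        return PRFPair(
            cardiac_params=np.zeros(6), respiratory_params=np.zeros(6),
            cardiac_curve=delta, respiratory_curve=np.zeros(grid.size),
            fit_r=1.0,
        )

    def test_delta_cardiac_prf_returns_resampled_hr(self, rng):
        hr, rf = self._hr_rf(rng)
        tr, n_vol = 2.0, 55
        slfo = build_slfo(hr, rf, self._delta_prfs(), tr, n_vol)
        idx = np.round(np.arange(n_vol) * tr * PRF_GRID_FS).astype(int)
        hr_z = (hr.values - hr.values.mean()) / hr.values.std()
        expected = hr_z[idx]
        expected = (expected - expected.mean()) / expected.std()
        np.testing.assert_allclose(slfo.values, expected, atol=1e-10)

    def test_zero_prfs_degenerate(self, rng):
        hr, rf = self._hr_rf(rng)
        prfs = self._delta_prfs()
        prfs.cardiac_curve = np.zeros_like(prfs.cardiac_curve)
        with pytest.raises(DegenerateSignalError):
            build_slfo(hr, rf, prfs, 2.0, 55)

    def test_censoring_shortens_output(self, rng):
        hr, rf = self._hr_rf(rng)
        mask = np.ones(55, dtype=bool)
        mask[10:13] = False
        slfo = build_slfo(hr, rf, self._delta_prfs(), 2.0, 55, censor_mask=mask)
        assert slfo.values.size == 52


class TestEstimatePrfs:
    def test_constant_inputs_rejected(self):
        from gsdecomp.physio import HeartRateSeries, RespiratoryFlowSeries

        hr = HeartRateSeries(values=np.full(1200, 70.0))
        rf = RespiratoryFlowSeries(values=np.abs(np.random.default_rng(0)
                                                 .standard_normal(1200)))
        gs = np.random.default_rng(1).standard_normal(55)
        with pytest.raises(InputError):
            estimate_prfs(hr, rf, gs, 2.0)
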