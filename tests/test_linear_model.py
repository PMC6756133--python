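"""Backward decoder, forward TRF, bootstrap tracking, peak extraction."""

import numpy as np
import pytest
from scipy import stats as sstats

from envtrack.containers import EEGRecording, EnvelopeSignal
from envtrack.linear_model import (BackwardDecoder, ForwardTRF, LagSpec,
                                   bootstrap_spearman, lag_matrix,
                                   reconstruct, train_backward,
                                   train_forward, trf_peaks)
from envtrack.preprocess import bandpass
from envtrack.synthetic import (ArtifactConfig, NoiseConfig, gen_envelope,
                                gen_eeg, gen_matrix_timeline,
                                make_reference_kernel)

NO_ARTIFACTS = ArtifactConfig(blink_rate_per_min=0, glitch_rate_per_min=0)
NOISELESS = NoiseConfig(amplitude_uv=0.0)


def _eeg(data, fs=128.0):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    return EEGRecording(data, fs=fs,
                        labels=[f"ch{i}" for i in range(data.shape[0])])


class TestLagSpec:
    def test_full_window_lag_count(self):
        assert LagSpec(0, 500, 128.0).n_lags == 65

    def test_early_window_stays_inside_bounds(self):
        spec = LagSpec(0, 75, 128.0)
        assert spec.lag_ms[0] == 0
        assert spec.lag_ms[-1] <= 75

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            LagSpec(100, 50, 128.0)


class TestLagMatrix:
    def test_stated_convention(self):
        x = lag_matrix(_eeg([1.0, 2.0, 3.0]), LagSpec(0, 1000 / 128, 128.0))
        assert np.array_equal(x, [[1, 2], [2, 3], [3, 0]])

    def test_zero_lag_is_identity(self):
        data = np.arange(12.0).reshape(2, 6)
        x = lag_matrix(_eeg(data), LagSpec(0, 1.0, 128.0))
        assert np.array_equal(x, data.T)

    def test_column_count_64_channels_full_window(self, rng):
        eeg = EEGRecording(rng.standard_normal((64, 200)), fs=128.0,
                           labels=[f"c{i}" for i in range(64)])
        assert lag_matrix(eeg, LagSpec(0, 500, 128.0)).shape == (200, 4160)

    def test_window_longer_than_recording_rejected(self):
        with pytest.raises(ValueError):
            lag_matrix(_eeg(np.zeros(10)), LagSpec(0, 500, 128.0))


def brute_force_ridge(x, s, lam):
    """Independent normal-equations oracle: explicit Gram accumulation and
    numpy inverse, no shared code path with the implementation."""
    x = np.asarray(x, float)
    gram = np.zeros((x.shape[1], x.shape[1]))
    rhs = np.zeros(x.shape[1])
    for t in range(x.shape[0]):  # explicit accumulation over time
        gram += np.outer(x[t], x[t])
        rhs += x[t] * s[t]
    return np.linalg.inv(gram + lam * np.eye(x.shape[1])) @ rhs


class TestBackwardDecoder:
    def test_identity_system(self):
        rng = np.random.default_rng(0)
        s = rng.standard_normal(500)
        eeg = _eeg(s)
        env = EnvelopeSignal(s, fs=128.0)
        dec = train_backward(eeg, env, LagSpec(0, 1.0, 128.0), lam=1e-10)
        s_hat = reconstruct(dec, eeg)
        assert sstats.spearmanr(s, s_hat.samples).statistic >= 0.999

    def test_matches_normal_equations_oracle(self, rng):
        n_ch, n = 6, 800
        data = rng.standard_normal((n_ch, n))
        s = rng.standard_normal(n)
        eeg = _eeg(data)
        env = EnvelopeSignal(s, fs=128.0)
        spec = LagSpec(0, 40, 128.0)
        dec = train_backward(eeg, env, spec, normalize=False)
        x = lag_matrix(eeg, spec)
        w_ref = brute_force_ridge(x, s, dec.lam)
        w = dec.weights.ravel()
        assert np.max(np.abs(w - w_ref)) / np.max(np.abs(w_ref)) < 1e-6

    def test_lambda_rule_is_max_autocorrelation_entry(self, rng):
        eeg = _eeg(rng.standard_normal((3, 400)))
        env = EnvelopeSignal(rng.standard_normal(400), fs=128.0)
        spec = LagSpec(0, 30, 128.0)
        dec = train_backward(eeg, env, spec)
        from envtrack.linear_model import _zscore_cols
        x = _zscore_cols(lag_matrix(eeg, spec))
        assert dec.lam == pytest.approx(np.abs(x.T @ x).max())

    def test_noiseless_synthetic_reconstruction(self):
        """Delta-band reconstruction of noiseless kernel-generated EEG."""
        tl = gen_matrix_timeline(2, 20, seed=3)
        env = gen_envelope(tl, fs=128.0, seed=3)
        k = make_reference_kernel("attention", fs=128.0)
        eeg = gen_eeg(env, k, gain=1.0, noise_cfg=NOISELESS,
                      artifact_cfg=NO_ARTIFACTS, seed=1)
        envd = bandpass(env, "delta")
        eegd = bandpass(eeg, "delta")
        dec = train_backward(eegd, envd, LagSpec(0, 75, 128.0), lam=1e-6)
        s_hat = reconstruct(dec, eegd)
        assert sstats.spearmanr(envd.samples, s_hat.samples).statistic >= 0.99

    def test_training_rho_non_increasing_in_lambda(self, rng):
        eeg = _eeg(rng.standard_normal((4, 2000)))
        w_true = rng.standard_normal(4)
        env = EnvelopeSignal(w_true @ eeg.data + 0.5 *
                             rng.standard_normal(2000), fs=128.0)
        spec = LagSpec(0, 30, 128.0)
        rhos = []
        for lam in (0.0, 1e2, 1e4, 1e6, 1e8):
            dec = train_backward(eeg, env, spec, lam=lam)
            s_hat = reconstruct(dec, eeg)
            rhos.append(np.corrcoef(env.samples, s_hat.samples)[0, 1])
        assert np.all(np.diff(rhos) <= 1e-9)

    def test_reconstruction_linear_in_weights(self, rng):
        eeg = _eeg(rng.standard_normal((3, 300)))
        env = EnvelopeSignal(rng.standard_normal(300), fs=128.0)
        dec = train_backward(eeg, env, LagSpec(0, 30, 128.0))
        doubled = BackwardDecoder(weights=2 * dec.weights, lam=dec.lam,
                                  lagspec=dec.lagspec, labels=dec.labels,
                                  normalize=dec.normalize)
        zero = BackwardDecoder(weights=0 * dec.weights, lam=dec.lam,
                               lagspec=dec.lagspec, labels=dec.labels,
                               normalize=dec.normalize)
        a = reconstruct(dec, eeg).samples
        assert np.allclose(reconstruct(doubled, eeg).samples, 2 * a)
        assert np.all(reconstruct(zero, eeg).samples == 0)

    def test_time_reversal_preserves_correlation_single_lag(self, rng):
        eeg = _eeg(rng.standard_normal((4, 600)))
        env = EnvelopeSignal(rng.standard_normal(600), fs=128.0)
        spec = LagSpec(0, 1.0, 128.0)  # single (zero) lag: time-symmetric
        dec = train_backward(eeg, env, spec)
        rho = sstats.spearmanr(env.samples,
                               reconstruct(dec, eeg).samples).statistic
        eeg_r = _eeg(eeg.data[:, ::-1])
        env_r = EnvelopeSignal(env.samples[::-1], fs=128.0)
        dec_r = train_backward(eeg_r, env_r, spec)
        rho_r = sstats.spearmanr(env_r.samples,
                                 reconstruct(dec_r, eeg_r).samples).statistic
        assert abs(abs(rho) - abs(rho_r)) < 1e-9

    def test_duration_mismatch_rejected(self, rng):
        eeg = _eeg(rng.standard_normal((2, 100)))
        env = EnvelopeSignal(rng.standard_normal(90), fs=128.0)
        with pytest.raises(ValueError):
            train_backward(eeg, env, LagSpec(0, 30, 128.0))

    def test_json_roundtrip(self, rng):
        eeg = _eeg(rng.standard_normal((3, 200)))
        env = EnvelopeSignal(rng.standard_normal(200), fs=128.0)
        dec = train_backward(eeg, env, LagSpec(0, 30, 128.0))
        back = BackwardDecoder.from_json(dec.to_json())
        assert np.allclose(back.weights, dec.weights)
        assert back.lam == dec.lam
        assert back.lagspec == dec.lagspec


class TestBootstrapSpearman:
    def test_monotone_transform_gives_unity(self, rng):
        a = rng.standard_normal(4000)
        score = bootstrap_spearman(a, np.exp(a), n_boot=100, seed=0,
                                   fs=128.0)
        assert score.rho_median == pytest.approx(1.0)
        assert score.ci_low <= score.rho_median <= score.ci_high

    def test_independent_noise_covers_zero(self, rng):
        a = rng.standard_normal(10000)
        b = rng.standard_normal(10000)
        score = bootstrap_spearman(a, b, n_boot=200, seed=1, fs=128.0)
        assert abs(score.rho_median) < 0.05
        assert score.ci_low < 0 < score.ci_high

    def test_ci_roughly_symmetric_for_exchangeable_data(self, rng):
        a = rng.standard_normal(8000)
        b = rng.standard_normal(8000)
        score = bootstrap_spearman(a, b, n_boot=400, seed=2, fs=128.0)
        asym = (score.ci_high - score.rho_median) - \
            (score.rho_median - score.ci_low)
        assert abs(asym) < 0.02

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_spearman(np.ones(100), np.arange(100.0), fs=10.0)

    def test_deterministic_under_seed(self, rng):
        a = rng.standard_normal(3000)
        b = a + rng.standard_normal(3000)
        s1 = bootstrap_spearman(a, b, n_boot=50, seed=9, fs=128.0)
        s2 = bootstrap_spearman(a, b, n_boot=50, seed=9, fs=128.0)
        assert s1 == s2


class TestForwardTRF:
    def test_noiseless_kernel_recovery_per_channel(self):
        tl = gen_matrix_timeline(3, 20, seed=5)  # ~180 s
        env = gen_envelope(tl, fs=128.0, seed=5)
        k = make_reference_kernel("attention", fs=128.0)
        eeg = gen_eeg(env, k, gain=1.0, noise_cfg=NOISELESS,
                      artifact_cfg=NO_ARTIFACTS, seed=2)
        trf = train_forward(env, eeg, LagSpec(0, 500, 128.0))
        n = k.kernel.shape[1]
        for ch in range(64):
            rho = np.corrcoef(trf.kernel[ch, :n], k.kernel[ch])[0, 1]
            assert rho >= 0.95

    def test_matches_normal_equations_oracle(self, rng):
        n_ch, n = 5, 1500
        eeg = _eeg(rng.standard_normal((n_ch, n)))
        env = EnvelopeSignal(rng.standard_normal(n), fs=128.0)
        spec = LagSpec(0, 100, 128.0)
        trf = train_forward(env, eeg, spec, normalize=False)
        from envtrack.linear_model import _delay_embed
        d = _delay_embed(env.samples, -spec.lags)
        for ch in range(n_ch):
            w_ref = brute_force_ridge(d, eeg.data[ch], trf.lam)
            err = np.max(np.abs(trf.kernel[ch] - w_ref))
            assert err / np.max(np.abs(w_ref)) < 1e-6

    def test_zero_eeg_gives_zero_trf(self):
        env = EnvelopeSignal(np.random.default_rng(0).standard_normal(500),
                             fs=128.0)
        eeg = _eeg(np.zeros((3, 500)))
        trf = train_forward(env, eeg, LagSpec(0, 100, 128.0))
        assert np.allclose(trf.kernel, 0.0)

    def test_synthetic_attention_trf_has_p1_n1_p2_morphology(self):
        tl = gen_matrix_timeline(2, 20, seed=6)
        env = gen_envelope(tl, fs=128.0, seed=6)
        k = make_reference_kernel("attention", fs=128.0)
        eeg = gen_eeg(env, k, gain=1.0, artifact_cfg=NO_ARTIFACTS, seed=3)
        trf = train_forward(env, eeg, LagSpec(0, 500, 128.0))
        peaks = {p.label: p for p in trf_peaks(trf)}
        assert peaks["P1"].amplitude > 0
        assert peaks["N1"].amplitude < 0
        assert peaks["P2"].amplitude > 0


class TestTRFPeaks:
    def _as_trf(self, kernel):
        return ForwardTRF(kernel=kernel.kernel, lag_ms=kernel.lag_ms,
                          fs=kernel.fs, labels=kernel.labels)

    def test_reference_attention_latencies(self):
        peaks = {p.label: p for p in
                 trf_peaks(self._as_trf(make_reference_kernel(fs=128.0)))}
        one_sample = 1000 / 128
        assert abs(peaks["P1"].latency_ms - 50) <= one_sample
        assert abs(peaks["N1"].latency_ms - 80) <= one_sample
        assert abs(peaks["P2"].latency_ms - 160) <= one_sample

    def test_movie_p2_smaller_than_attention(self):
        pa = {p.label: p for p in
              trf_peaks(self._as_trf(make_reference_kernel("attention",
                                                           fs=128.0)))}
        pm = {p.label: p for p in
              trf_peaks(self._as_trf(make_reference_kernel("movie",
                                                           fs=128.0)))}
        assert pm["P2"].amplitude < pa["P2"].amplitude

    def test_single_bump_degenerate_n1_is_flank_minimum(self):
        lag_ms = np.arange(65) * 1000 / 128
        bump = np.exp(-(lag_ms - 100) ** 2 / (2 * 12.0 ** 2))
        trf = ForwardTRF(kernel=bump[None, :], lag_ms=lag_ms, fs=128.0,
                         labels=["Cz"])
        peaks = {p.label: p for p in trf_peaks(trf)}
        window = (lag_ms >= 60) & (lag_ms <= 120)
        assert peaks["N1"].amplitude == pytest.approx(bump[window].min())

    def test_empty_window_rejected(self):
        trf = ForwardTRF(kernel=np.zeros((1, 10)),
                         lag_ms=np.arange(10) * 1000 / 128, fs=128.0,
                         labels=["Cz"])
        with pytest.raises(ValueError):
            trf_peaks(trf, windows={"P2": (120.0, 250.0)})
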