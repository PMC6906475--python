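import numpy as np
import pytest

from spikespeech import metrics as mx
from spikespeech.synth import TokenSpec, synth_token_audio

FS = 30000.0


def _orthonormal_pair(n, rng):
    u = rng.standard_normal(n)
    v = rng.standard_normal(n)
    u = (u - u.mean()) / np.linalg.norm(u - u.mean())
    v = v - v.mean() - (v - v.mean()) @ u * u
    return u, v / np.linalg.norm(v)


class TestFisherMeanCorrelation:
    def test_identity_is_one(self, rng):
        Y = rng.standard_normal((8, 40))
        assert mx.fisher_mean_correlation(Y, Y) > 0.9999

    def test_closed_form_two_bands(self, rng):
        """Bands with r = 0 and r = 0.8 combine to tanh(atanh(0.8)/2) = 0.5."""
        u, v = _orthonormal_pair(200, rng)
        Y = np.vstack([u, u])
        Yh = np.vstack([v, 0.8 * u + 0.6 * v])  # r = 0 and r = 0.8 exactly
        got = mx.fisher_mean_correlation(Y, Yh)
        assert got == pytest.approx(np.tanh(np.arctanh(0.8) / 2), abs=1e-9)
        assert got == pytest.approx(0.5, abs=1e-9)

    def test_equal_band_correlations_pass_through(self, rng):
        u, v = _orthonormal_pair(100, rng)
        Y = np.vstack([u] * 4)
        Yh = np.vstack([0.5 * u + np.sqrt(0.75) * v] * 4)
        assert mx.fisher_mean_correlation(Y, Yh) == pytest.approx(0.5, abs=1e-9)

    def test_symmetric_and_band_permutation_invariant(self, rng):
        Y = rng.standard_normal((6, 50))
        Yh = Y + 0.5 * rng.standard_normal((6, 50))
        r1 = mx.fisher_mean_correlation(Y, Yh)
        assert mx.fisher_mean_correlation(Yh, Y) == pytest.approx(r1, abs=1e-12)
        p = rng.permutation(6)
        assert mx.fisher_mean_correlation(Y[p], Yh[p]) == pytest.approx(r1, abs=1e-12)

    def test_zero_variance_bands_excluded(self, rng):
        Y = rng.standard_normal((3, 30))
        Y[0] = 5.0  # flat band
        r = mx.fisher_mean_correlation(Y, Y + 0.01 * rng.standard_normal((3, 30)))
        assert np.isfinite(r)
        with pytest.raises(ValueError, match="zero variance"):
            mx.fisher_mean_correlation(np.ones((2, 10)), np.ones((2, 10)))


class TestEnvelope:
    def test_self_and_scale_invariance(self, rng):
        x = rng.standard_normal(30000)
        assert mx.envelope_correlation(x, x, FS) == pytest.approx(1.0, abs=1e-9)
        assert mx.envelope_correlation(x, 0.5 * x, FS) == pytest.approx(1.0, abs=1e-9)

    def test_am_tone_recovers_modulator(self):
        t = np.arange(int(2 * FS)) / FS
        modulator = 1.0 + 0.8 * np.sin(2 * np.pi * 4 * t)
        x = modulator * np.sin(2 * np.pi * 1000 * t)
        env = mx.envelope(x, FS)
        sl = slice(3000, -3000)  # ignore filter edges
        r = np.corrcoef(env[sl], modulator[sl])[0, 1]
        assert r >= 0.99

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mx.envelope_correlation(np.zeros(100), np.zeros(99), FS)


class TestPitch:
    def test_pure_tone_tracked_within_2hz(self):
        t = np.arange(int(FS)) / FS
        track = mx.ncf_pitch(np.sin(2 * np.pi * 200 * t), FS)
        assert track.voiced.any()
        assert np.all(np.abs(track.f0[track.voiced] - 200) <= 2)

    def test_noise_is_unvoiced(self, rng):
        track = mx.ncf_pitch(rng.standard_normal(int(FS)), FS)
        assert track.voiced.mean() < 0.2

    def test_silence_is_unvoiced(self):
        track = mx.ncf_pitch(np.zeros(int(FS)), FS)
        assert not track.voiced.any()


class TestGrossPitchError:
    def test_identical_tracks_zero(self):
        f = np.full(10, 150.0)
        assert mx.gross_pitch_error(f, f) == 0.0

    def test_one_bad_frame_in_four(self):
        f0 = np.array([100.0, 100.0, 100.0, 100.0])
        f0h = np.array([100.0, 130.0, 100.0, 100.0])
        assert mx.gross_pitch_error(f0, f0h) == pytest.approx(25.0)

    def test_exactly_20_percent_not_an_error(self):
        f0 = np.array([100.0])
        assert mx.gross_pitch_error(f0, np.array([120.0])) == 0.0
        assert mx.gross_pitch_error(f0, np.array([120.0001])) == 100.0

    def test_missing_reconstruction_pitch_counts_as_error(self):
        f0 = np.array([100.0, 100.0])
        assert mx.gross_pitch_error(f0, np.array([100.0, 0.0])) == 50.0

    def test_voicing_mask_restricts_frames(self):
        f0 = np.array([100.0, 100.0, 100.0])
        f0h = np.array([500.0, 100.0, 100.0])
        voiced = np.array([False, True, True])
        assert mx.gross_pitch_error(f0, f0h, voiced=voiced) == 0.0


class TestLoudness:
    def test_full_scale_997hz_reference(self):
        t = np.arange(int(5 * FS)) / FS
        l = mx.momentary_loudness(np.sin(2 * np.pi * 997 * t), FS)
        assert np.mean(l) == pytest.approx(-3.01, abs=0.1)

    def test_half_amplitude_drops_6db(self):
        t = np.arange(int(2 * FS)) / FS
        x = np.sin(2 * np.pi * 500 * t)
        d = mx.momentary_loudness(x, FS) - mx.momentary_loudness(0.5 * x, FS)
        np.testing.assert_allclose(d, 20 * np.log10(2), atol=1e-6)

    def test_silence_floored(self):
        l = mx.momentary_loudness(np.zeros(int(FS)), FS)
        assert np.all(l == mx.SILENCE_FLOOR_LUFS)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            mx.momentary_loudness(np.zeros(100), FS)


class TestLoudnessFactor:
    def test_identity_is_one(self):
        l = np.array([-20.0, -25.0])
        assert mx.mean_loudness_factor(l, l) == 1.0

    def test_10db_doubles(self):
        l = np.full(5, -20.0)
        assert mx.mean_loudness_factor(l, l - 10.0) == pytest.approx(2.0)
        assert mx.mean_loudness_factor(l, l + 10.0) == pytest.approx(2.0)

    def test_20db_quadruples(self):
        l = np.full(5, -20.0)
        assert mx.mean_loudness_factor(l, l - 20.0) == pytest.approx(4.0)


def _speech_like(seed=2, dur=2.0):
    return synth_token_audio(
        TokenSpec("s", dur, 140.0, [(600.0, 800.0), (1800.0, 2200.0)]), FS, seed=seed
    )


class TestEstoi:
    def test_self_is_one(self):
        x = _speech_like()
        assert mx.estoi(x, x, FS) == pytest.approx(1.0, abs=1e-6)

    def test_monotone_in_snr(self, rng):
        clean = _speech_like()
        scores = []
        for snr_db in (20, 10, 0, -10):
            noise = rng.standard_normal(clean.size)
            noise *= np.sqrt(np.mean(clean**2) / np.mean(noise**2)) * 10 ** (-snr_db / 20)
            scores.append(mx.estoi(clean, clean + noise, FS))
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_independent_noise_near_zero(self, rng):
        clean = _speech_like()
        assert abs(mx.estoi(clean, 0.1 * rng.standard_normal(clean.size), FS)) < 0.1


class TestStmi:
    def test_index_identities(self, rng):
        T = np.abs(rng.standard_normal((5, 6, 8)))
        assert mx.stmi_index(T, T) == pytest.approx(1.0)
        assert mx.stmi_index(T, np.zeros_like(T)) == pytest.approx(0.0)
        assert mx.stmi_index(T, 2 * T) == pytest.approx(0.0)

    def test_silent_target_rejected(self):
        with pytest.raises(ValueError, match="silent"):
            mx.stmi_index(np.zeros((2, 2)), np.ones((2, 2)))

    def test_full_pipeline_self_and_homogeneity(self):
        x = _speech_like()
        assert mx.stmi(x, x, FS) == pytest.approx(1.0, abs=1e-9)
        # the analysis path is 1-homogeneous, so doubling mirrors N = 2T
        assert mx.stmi(x, 2 * x, FS) == pytest.approx(0.0, abs=1e-6)

    def test_silence_reconstruction_scores_zero(self):
        x = _speech_like()
        assert mx.stmi(x, np.zeros_like(x), FS) == pytest.approx(0.0, abs=1e-9)


class TestJointBehaviour:
    def test_identity_suite(self):
        """Every metric attains its ideal when reconstruction equals target."""
        x = _speech_like(seed=5, dur=3.0)
        rep = mx.evaluate_all(x, x.copy(), FS)
        assert rep.fisher_mean_r == pytest.approx(1.0, abs=1e-4)
        assert rep.envelope_r == pytest.approx(1.0, abs=1e-9)
        assert rep.gpe_percent == 0.0
        assert rep.mean_loudness_factor == pytest.approx(1.0)
        assert rep.estoi == pytest.approx(1.0, abs=1e-6)
        assert rep.stmi == pytest.approx(1.0, abs=1e-9)

    def test_metrics_degrade_with_noise(self, rng):
        """Additive-noise corruption never improves any metric (tolerated ties)."""
        x = _speech_like(seed=6, dur=3.0)
        levels = (0.0, 0.5, 2.0)
        reps = []
        for lv in levels:
            noise = lv * np.sqrt(np.mean(x**2)) * rng.standard_normal(x.size)
            reps.append(mx.evaluate_all(x, x + noise, FS))
        tol = 0.02
        for a, b in zip(reps, reps[1:]):
            assert b.fisher_mean_r <= a.fisher_mean_r + tol
            assert b.envelope_r <= a.envelope_r + tol
            assert b.gpe_percent >= a.gpe_percent - 2.0
            assert b.mean_loudness_factor >= a.mean_loudness_factor - tol
            assert b.estoi <= a.estoi + tol
            assert b.stmi <= a.stmi + tol
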