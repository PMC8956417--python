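"""Envelope extraction, DFA scaling anchors, surrogates, and the
nonlinearity test."""

import numpy as np
import pytest

from neuromark import (
    DFAConfig,
    alpha_profile,
    dfa,
    generate_fgn,
    hilbert_envelope,
    lognormal_envelope,
    phase_randomized_surrogate,
    surrogate_nonlinearity_test,
)
from neuromark.protocol import STANDARD_BANDS, ProtocolSpec, default_effects_group_a
from neuromark.recordings import Recording, band_filter
from neuromark.synth import _oscillator_carrier

ALPHA = STANDARD_BANDS["alpha"]
FS = 256.0


def reference_dfa(x, sizes, overlap=0.5):
    """Brute-force DFA written straight from the procedure: integrate,
    per-window linear detrend, RMS of residuals, log-log slope. Kept
    independent of the production implementation."""
    y = np.cumsum(np.asarray(x, float) - np.mean(x))
    F = []
    for t in sizes:
        step = max(1, int(round(t * (1 - overlap))))
        residuals = []
        for start in range(0, len(y) - t + 1, step):
            w = y[start:start + t]
            k = np.arange(t)
            b, a = np.polyfit(k, w, 1)
            residuals.extend(w - (a + b * k))
        F.append(np.sqrt(np.mean(np.square(residuals))))
    slope = np.polyfit(np.log(sizes), np.log(F), 1)[0]
    return slope, np.array(F)


def _lrtc_signal(hurst, dur_s, seed):
    """Alpha-band oscillation with an fGn envelope of known exponent."""
    n = int(dur_s * FS)
    rng = np.random.default_rng(seed)
    env = lognormal_envelope(hurst, n, rng, fs=FS)
    return env * _oscillator_carrier(n, FS, rng, f0=10.0)


class TestHilbertEnvelope:
    def test_constant_tone_envelope_equals_amplitude(self):
        t = np.arange(int(FS * 10)) / FS
        env = hilbert_envelope(3.0 * np.sin(2 * np.pi * 10 * t))
        assert np.abs(env - 3.0).max() < 0.06  # within 2%

    def test_recovers_known_modulator(self):
        t = np.arange(int(FS * 20)) / FS
        m = 1.0 + 0.5 * np.sin(2 * np.pi * 0.3 * t)
        x = m * np.sin(2 * np.pi * 10 * t)
        env = hilbert_envelope(x)
        cut = (len(t) - len(env)) // 2
        r = np.corrcoef(env, m[cut:cut + len(env)])[0, 1]
        assert r > 0.95

    def test_zeros_stay_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            env = hilbert_envelope(np.zeros(1024))
        assert np.all(env == 0)


class TestDfa:
    def test_matches_brute_force_reference(self, rng):
        x = rng.standard_normal(4096)
        cfg = DFAConfig(fit_range=(16, 1024), n_windows=12)
        res = dfa(x, cfg)
        sizes = (res.window_sizes).astype(int)
        ref_alpha, ref_F = reference_dfa(x, list(sizes))
        np.testing.assert_allclose(res.fluctuations, ref_F, rtol=1e-10)
        assert res.alpha == pytest.approx(ref_alpha, abs=1e-10)

    def test_white_noise_alpha_half(self):
        alphas = [dfa(np.random.default_rng(s).standard_normal(65536)).alpha
                  for s in range(4)]
        assert np.mean(alphas) == pytest.approx(0.5, abs=0.03)

    def test_brownian_alpha_three_halves(self):
        alphas = [dfa(np.cumsum(np.random.default_rng(s).standard_normal(65536))).alpha
                  for s in range(4)]
        assert np.mean(alphas) == pytest.approx(1.5, abs=0.05)

    def test_one_over_f_alpha_one(self):
        alphas = []
        for s in range(4):
            freqs = np.fft.rfftfreq(65536)
            amp = np.zeros_like(freqs)
            amp[1:] = freqs[1:] ** -0.5  # power ~ 1/f
            phases = np.random.default_rng(s).uniform(0, 2 * np.pi, len(freqs))
            alphas.append(dfa(np.fft.irfft(amp * np.exp(1j * phases))).alpha)
        assert np.mean(alphas) == pytest.approx(1.0, abs=0.05)

    def test_fluctuations_grow_with_window(self, rng):
        res = dfa(rng.standard_normal(16384))
        assert res.fluctuations[-1] > res.fluctuations[0]
        assert np.all(np.diff(np.log(res.fluctuations)) > -0.05)

    def test_integration_raises_alpha_by_one(self):
        # alpha(cumsum X) = alpha(X) + 1 for fractional noise
        for hurst in (0.5, 0.7):
            x = generate_fgn(hurst, 65536, seed=42)
            a = dfa(x).alpha
            b = dfa(np.cumsum(x), DFAConfig(fit_range=(16, 65536 // 4))).alpha
            assert b == pytest.approx(a + 1.0, abs=0.07)

    def test_too_short_series_names_minimum(self):
        with pytest.raises(ValueError, match="at least"):
            dfa(np.zeros(100), DFAConfig(fit_range=(16, 256)))


class TestSurrogates:
    def test_amplitude_spectrum_preserved_exactly(self, rng):
        x = rng.standard_normal(4096) + np.sin(np.arange(4096) * 0.3)
        s = phase_randomized_surrogate(x, seed=1)
        np.testing.assert_allclose(np.abs(np.fft.rfft(s)), np.abs(np.fft.rfft(x)),
                                   rtol=1e-9)
        assert phase_randomized_surrogate(x, seed=1)[0] == s[0]  # seeded

    def test_white_noise_stays_white(self, rng):
        x = rng.standard_normal(65536)
        assert dfa(phase_randomized_surrogate(x, seed=2)).alpha == pytest.approx(0.5, abs=0.05)

    def test_envelope_lrtc_destroyed(self):
        # phase randomization keeps the spectrum but scrambles the envelope:
        # the surrogate's envelope exponent collapses toward uncorrelated
        cfg = DFAConfig(fit_range=(2.0, 13.0), fs=FS)
        drops = []
        for s in range(3):
            x = band_filter(_lrtc_signal(0.8, 60.0, 300 + s), ALPHA, fs=FS)
            orig = dfa(hilbert_envelope(x), cfg).alpha
            surr = dfa(hilbert_envelope(phase_randomized_surrogate(x, seed=s)), cfg).alpha
            drops.append(orig - surr)
        assert np.mean(drops) >= 0.15

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            phase_randomized_surrogate(np.zeros(32), seed=0)


class TestSurrogateNonlinearityTest:
    def test_identical_alphas_give_p_one(self, monkeypatch):
        # if every surrogate equals its original, all paired differences are
        # zero and the test must report no evidence of nonlinearity
        import neuromark.lrtc as lrtc_mod
        monkeypatch.setattr(lrtc_mod, "phase_randomized_surrogate",
                            lambda x, seed: np.asarray(x, float))
        sigs = [band_filter(np.random.default_rng(s).standard_normal(int(FS * 10)),
                            ALPHA, fs=FS) for s in range(6)]
        res = lrtc_mod.surrogate_nonlinearity_test(sigs, FS, n_surrogates=2, seed=0)
        assert res.p_value == 1.0

    def test_detects_envelope_lrtc_across_channels(self):
        sigs = [band_filter(_lrtc_signal(0.8, 30.0, 700 + s), ALPHA, fs=FS)
                for s in range(10)]
        res = surrogate_nonlinearity_test(sigs, FS, n_surrogates=10,
                                          cfg=DFAConfig(fit_range=(1.0, 6.0), fs=FS),
                                          seed=5)
        assert res.p_value < 0.05
        assert res.alpha_original.mean() > res.alpha_surrogate_mean.mean()

    def test_needs_six_units(self):
        sigs = [np.random.default_rng(s).standard_normal(2048) for s in range(4)]
        with pytest.raises(ValueError, match="6"):
            surrogate_nonlinearity_test(sigs, FS)


class TestAlphaProfile:
    @staticmethod
    def _recording(samples):
        return Recording(samples, [f"ch{i}" for i in range(samples.shape[0])], FS)

    def test_white_noise_profile_flat_near_half(self, rng):
        # wide-band envelope of white noise fluctuates fast: uncorrelated at
        # the chunk scales, so the exponent sits near 0.5
        rec = self._recording(rng.standard_normal((4, int(FS * 40))))
        _, alphas = alpha_profile(rec, STANDARD_BANDS["whole"])
        assert abs(alphas.mean() - 0.5) < 0.1
        assert alphas.std(axis=1).mean() < 0.25

    def test_profile_tracks_hurst_switch(self):
        low = np.stack([band_filter(_lrtc_signal(0.6, 20.0, 40 + i), ALPHA, fs=FS)
                        for i in range(4)])
        high = np.stack([band_filter(_lrtc_signal(0.9, 20.0, 80 + i), ALPHA, fs=FS)
                         for i in range(4)])
        rec = self._recording(np.concatenate([low, high], axis=1))
        _, alphas = alpha_profile(rec, ALPHA)
        n = alphas.shape[1] // 2
        assert alphas[:, n:].mean() > alphas[:, :n].mean()

    def test_group_a_session_rises_in_decision_stage(self, session_a):
        _, alphas = alpha_profile(session_a, ALPHA)
        # chunks: 0 baseline, 1-5 S1, 6 D1, 7-16 S2, 17+ D2 (4 s chunks, 75 s)
        scalp = alphas[:19]
        s1 = scalp[:, 2:6].mean()
        d2 = scalp[:, 17:].mean()
        assert d2 > s1

    def test_chunk_too_short_for_fit_errors(self, rng):
        rec = self._recording(rng.standard_normal((1, int(FS * 16))))
        with pytest.raises(ValueError, match="chunk"):
            alpha_profile(rec, ALPHA, chunk_s=4.0,
                          cfg=DFAConfig(fit_range=(0.25, 2.0), fs=FS))
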