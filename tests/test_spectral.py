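"""Welch PSD scaling, band power, coherence bounds/symmetry, and
biharmonic topographic interpolation."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuromark import (
    SpectralConfig,
    band_power,
    coherence_matrix,
    load_standard_montage,
    msc_coherence,
    topographic_interpolate,
    welch_psd,
)
from neuromark.protocol import COHERENCE_13, STANDARD_BANDS
from neuromark.recordings import StageSegment, stage_segment
from neuromark.spectral import PSDEstimate

ALPHA = STANDARD_BANDS["alpha"]
WHOLE = STANDARD_BANDS["whole"]


class TestWelchPsd:
    def test_one_hz_resolution_at_256(self, rng):
        psd = welch_psd(rng.standard_normal(256 * 4), 256.0)
        assert psd.resolution == 1.0
        assert np.allclose(np.diff(psd.frequencies), 1.0)

    def test_parseval_on_white_noise(self, rng):
        x = rng.standard_normal(256 * 20)
        psd = welch_psd(x, 256.0)
        total = np.trapezoid(psd.density, psd.frequencies)
        assert total == pytest.approx(x.var(), rel=0.10)

    def test_sine_peak_at_its_frequency(self):
        t = np.arange(256 * 8) / 256.0
        psd = welch_psd(np.sin(2 * np.pi * 10.0 * t), 256.0)
        assert psd.frequencies[np.argmax(psd.density)] == 10.0

    def test_too_short_segment_errors(self, rng):
        with pytest.raises(ValueError, match="shorter"):
            welch_psd(rng.standard_normal(100), 256.0)

    def test_variance_shrinks_with_averaging(self, rng):
        # Welch variance reduction ~ 1/M on white noise
        fs = 256.0
        variances = {}
        for m in (4, 16, 64):
            n = int(m * fs * 0.5 + fs * 0.5)  # m windows of 1 s at 50% overlap
            reps = [welch_psd(rng.standard_normal(n), fs).density[10:40]
                    for _ in range(30)]
            variances[m] = np.var(np.stack(reps), axis=0).mean()
        assert variances[4] / variances[16] == pytest.approx(4.0, rel=0.6)
        assert variances[16] / variances[64] == pytest.approx(4.0, rel=0.6)


class TestBandPower:
    def test_flat_density_integrates_to_width(self):
        freqs = np.arange(0.0, 129.0)
        psd = PSDEstimate(freqs, np.full_like(freqs, 3.0), 1.0)
        assert band_power(psd, ALPHA) == pytest.approx(12.0)  # 3 * (12-8)

    def test_zero_density(self):
        freqs = np.arange(0.0, 129.0)
        psd = PSDEstimate(freqs, np.zeros_like(freqs), 1.0)
        assert band_power(psd, ALPHA) == 0.0

    def test_white_noise_band_ratio_matches_bandwidths(self, rng):
        x = rng.standard_normal(256 * 120)
        psd = welch_psd(x, 256.0)
        ratio = band_power(psd, ALPHA) / band_power(psd, WHOLE)
        assert ratio == pytest.approx(4.0 / 39.0, rel=0.10)

    def test_band_outside_grid_errors(self):
        psd = PSDEstimate(np.arange(0.0, 10.0), np.ones(10), 1.0)
        with pytest.raises(ValueError, match="outside"):
            band_power(psd, STANDARD_BANDS["beta"])


class TestMscCoherence:
    def test_self_coherence_is_one(self, rng):
        x = rng.standard_normal(256 * 60)
        spec = msc_coherence(x, x.copy(), 256.0)
        assert spec.band_mean(WHOLE) == pytest.approx(1.0, abs=1e-9)

    def test_independent_noise_has_low_coherence(self, rng):
        x = rng.standard_normal(256 * 60)
        y = rng.standard_normal(256 * 60)
        assert msc_coherence(x, y, 256.0).band_mean(WHOLE) < 0.2

    def test_symmetry_and_bounds(self, rng):
        x = rng.standard_normal(256 * 30)
        y = 0.5 * x + rng.standard_normal(256 * 30)
        ab = msc_coherence(x, y, 256.0)
        ba = msc_coherence(y, x, 256.0)
        np.testing.assert_allclose(ab.msc, ba.msc, rtol=1e-12, atol=1e-15)
        assert np.all((ab.msc >= 0.0) & (ab.msc <= 1.0))

    def test_matches_scipy_reference(self, rng):
        from scipy import signal as sps
        x = rng.standard_normal(256 * 60)
        y = 0.6 * x + rng.standard_normal(256 * 60)
        ours = msc_coherence(x, y, 256.0)
        f_ref, c_ref = sps.coherence(
            x, y, fs=256.0, window=sps.get_window("hamming", 2560),
            noverlap=768, nfft=2560)
        np.testing.assert_allclose(ours.msc, c_ref, atol=1e-8)

    def test_short_segment_falls_back_with_warning(self, rng):
        x = rng.standard_normal(256 * 5)  # 5 s < one 10 s epoch
        with pytest.warns(UserWarning, match="falling back"):
            spec = msc_coherence(x, rng.standard_normal(len(x)), 256.0)
        assert spec.degenerate
        assert spec.n_epochs > 1

    def test_single_epoch_warns_and_degenerates_to_one(self, rng):
        x = rng.standard_normal(300)
        y = rng.standard_normal(300)
        cfg = SpectralConfig(window_s=1.0, overlap_s=0.5,
                             epoch_len_s=1.1, epoch_overlap_s=0.1)
        with pytest.warns(UserWarning):
            spec = msc_coherence(x[:290], y[:290], 256.0, cfg)
        assert spec.n_epochs == 1


class TestCoherenceMatrix:
    def test_symmetric_unit_diagonal_pair_count(self, session_a):
        seg = stage_segment(session_a, "S2")
        m = coherence_matrix(seg, list(COHERENCE_13), ALPHA)
        assert m.shape == (13, 13)
        np.testing.assert_array_equal(m, m.T)
        np.testing.assert_allclose(np.diag(m), 1.0)
        iu = np.triu_indices(13, 1)
        assert len(iu[0]) == 78
        assert np.all((m[iu] >= 0) & (m[iu] <= 1))

    def test_targeted_pair_exceeds_untargeted(self, session_a):
        seg = stage_segment(session_a, "S2")
        m = coherence_matrix(seg, ["Cz", "Pz", "T3"], ALPHA)
        assert m[0, 1] > m[0, 2]  # Cz-Pz coherent by construction, Cz-T3 not

    def test_unknown_electrode_errors(self, session_a):
        seg = stage_segment(session_a, "S2")
        with pytest.raises(ValueError, match="XX"):
            coherence_matrix(seg, ["Cz", "XX"], ALPHA)

    def test_agrees_with_pairwise_estimator(self, session_a):
        seg = stage_segment(session_a, "S2")
        m = coherence_matrix(seg, ["Cz", "Pz"], ALPHA)
        pair = msc_coherence(seg.channel("Cz"), seg.channel("Pz"), seg.fs)
        assert m[0, 1] == pytest.approx(pair.band_mean(ALPHA), abs=1e-9)


class TestTopographicInterpolation:
    def test_constant_input_gives_constant_field(self):
        layout = load_standard_montage()
        vals = {ch: 4.2 for ch in ("Fz", "Cz", "Pz", "C3", "C4")}
        _, _, field = topographic_interpolate(vals, layout, grid=32)
        assert np.nanmax(np.abs(field - 4.2)) < 1e-8

    def test_exact_reproduction_at_electrodes(self, rng):
        layout = load_standard_montage()
        labels = ["Fp1", "Fp2", "Cz", "O1", "O2", "T3", "T4"]
        vals = dict(zip(labels, rng.standard_normal(len(labels))))
        from scipy.interpolate import RBFInterpolator
        pts = layout.positions(labels)
        rbf = RBFInterpolator(pts, [vals[l] for l in labels],
                              kernel="thin_plate_spline", smoothing=0.0)
        np.testing.assert_allclose(rbf(pts), [vals[l] for l in labels], atol=1e-6)

    def test_antisymmetric_input_gives_antisymmetric_field(self):
        # +1/-1 at mirrored electrodes: the Green's function is symmetric, so
        # the field must be antisymmetric about the midline
        layout = load_standard_montage()
        vals = {"C3": 1.0, "C4": -1.0, "Fz": 0.0, "Pz": 0.0}
        _, _, field = topographic_interpolate(vals, layout, grid=41)
        flipped = field[:, ::-1]
        mask = ~np.isnan(field) & ~np.isnan(flipped)
        np.testing.assert_allclose(field[mask], -flipped[mask], atol=1e-6)

    def test_duplicate_coordinates_error(self):
        from neuromark import MontageLayout
        layout = MontageLayout({"A": (0.1, 0.1), "B": (0.1, 0.1),
                                "C": (0.2, 0.3), "D": (-0.4, 0.2)})
        with pytest.raises(ValueError, match="duplicate"):
            topographic_interpolate({"A": 1.0, "B": 2.0, "C": 0.0, "D": 0.0}, layout)

    def test_needs_four_electrodes(self):
        layout = load_standard_montage()
        with pytest.raises(ValueError, match="4"):
            topographic_interpolate({"Cz": 1.0, "Pz": 2.0, "Fz": 0.5}, layout)

    def test_plot_topomap_writes_png(self, tmp_path, rng):
        from neuromark import plot_topomap
        layout = load_standard_montage()
        vals = dict(zip(("Fz", "Cz", "Pz", "C3", "C4"), rng.standard_normal(5)))
        out = tmp_path / "map.png"
        plot_topomap(vals, layout, path=out, title="alpha power")
        assert out.stat().st_size > 1000


@settings(max_examples=20, deadline=None)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1), st.floats(0.0, 1.0))
def test_msc_always_bounded(seed, mix):
    """Property: the MSC estimate lies in [0, 1] for arbitrary mixtures."""
    r = np.random.default_rng(seed)
    x = r.standard_normal(256 * 12)
    y = mix * x + (1 - mix) * r.standard_normal(len(x))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        spec = msc_coherence(x, y, 256.0)
    assert np.all(spec.msc >= 0.0) and np.all(spec.msc <= 1.0)
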