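"""Long-range temporal correlations: Hilbert envelopes, detrended
fluctuation analysis (DFA), phase-randomized surrogates, and the
surrogate-based nonlinearity test.

DFA quantifies how the RMS fluctuation F(t) of the integrated,
per-window linearly detrended signal grows with window size t. A power law
F(t) ~ t^alpha with alpha = 0.5 indicates uncorrelated amplitudes, 0.5 <
alpha <= 1 persistent long-range correlations, alpha = 1 the 1/f regime,
and alpha = 1.5 the smoothness of Brownian motion. For band-specific
analyses the exponent is computed on the Hilbert amplitude envelope of the
band-filtered signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats

from .protocol import BandSpec
from .recordings import Recording, band_filter

__all__ = [
    "DFAConfig",
    "DFAResult",
    "SurrogateTestResult",
    "hilbert_envelope",
    "dfa",
    "envelope_dfa",
    "phase_randomized_surrogate",
    "surrogate_nonlinearity_test",
    "alpha_profile",
]


@dataclass(frozen=True)
class DFAConfig:
    """Fit window range in seconds (with ``fs`` = 1, in samples).

    ``fit_range = None`` adapts to the series: from max(0.25 s, 16 samples)
    up to a quarter of the series length. The long-series default used for
    stage-level envelopes is 2-20 s; 4 s chunks use 0.25-1 s.
    """

    fit_range: tuple[float, float] | None = None
    fs: float = 1.0
    window_overlap: float = 0.5
    n_windows: int = 20
    detrend_order: int = 1

    def resolve_windows(self, n_samples: int) -> np.ndarray:
        if self.fit_range is None:
            lo = max(16, round(0.25 * self.fs))
            hi = n_samples // 4
        else:
            lo = round(self.fit_range[0] * self.fs)
            hi = round(self.fit_range[1] * self.fs)
        lo = max(lo, 4)
        if hi > n_samples // 4:
            raise ValueError(
                f"max DFA window of {hi} samples needs a series of at least "
                f"{4 * hi} samples (got {n_samples})")
        if hi <= lo:
            raise ValueError(f"degenerate DFA fit range [{lo}, {hi}] samples")
        sizes = np.unique(np.geomspace(lo, hi, self.n_windows).round().astype(int))
        return sizes[sizes >= 4]


@dataclass
class DFAResult:
    window_sizes: np.ndarray  # seconds (samples when fs = 1)
    fluctuations: np.ndarray  # F(t)
    alpha: float
    r_squared: float
    fit_range_s: tuple[float, float]


def dfa(series: np.ndarray, cfg: DFAConfig = DFAConfig()) -> DFAResult:
    """Detrended fluctuation analysis with 50%-overlapping windows and
    per-window linear detrending; alpha is the least-squares slope of
    log F(t) against log t."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    sizes = cfg.resolve_windows(len(x))
    y = np.cumsum(x - x.mean())
    F = np.empty(len(sizes))
    for i, t in enumerate(sizes):
        step = max(1, int(round(t * (1.0 - cfg.window_overlap))))
        starts = np.arange(0, len(y) - t + 1, step)
        win = y[starts[:, None] + np.arange(t)[None, :]]
        k = np.arange(t, dtype=float)
        A = np.column_stack([np.ones(t), k])
        coef, *_ = np.linalg.lstsq(A, win.T, rcond=None)
        resid = win.T - A @ coef
        F[i] = np.sqrt(np.mean(resid * resid))
    logt = np.log(sizes / cfg.fs)
    logF = np.log(F)
    slope, intercept = np.polyfit(logt, logF, 1)
    pred = slope * logt + intercept
    ss_res = float(np.sum((logF - pred) ** 2))
    ss_tot = float(np.sum((logF - logF.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return DFAResult(window_sizes=sizes / cfg.fs, fluctuations=F, alpha=float(slope),
                     r_squared=r2, fit_range_s=(sizes[0] / cfg.fs, sizes[-1] / cfg.fs))


def hilbert_envelope(band_filtered: np.ndarray, trim: float = 0.05) -> np.ndarray:
    """Amplitude envelope: magnitude of the analytic signal, with ``trim``
    (default 5%) of samples discarded at each edge to suppress Hilbert
    transform edge effects. Expects a narrowband (band-filtered) input."""
    x = np.asarray(band_filtered, dtype=float)
    n = x.shape[-1]
    if n < 8:
        raise ValueError("series too short for envelope extraction")
    if np.ptp(x, axis=-1).max() == 0:
        warnings.warn("constant input has no oscillatory envelope; returning zeros",
                      stacklevel=2)
        shape = list(x.shape)
        shape[-1] = n - 2 * int(n * trim)
        return np.zeros(shape)
    env = np.abs(sps.hilbert(x, axis=-1))
    cut = int(n * trim)
    return env[..., cut: n - cut] if cut else env


def envelope_dfa(series: np.ndarray, band: BandSpec, fs: float,
                 cfg: DFAConfig | None = None) -> DFAResult:
    """Band-filter -> Hilbert envelope -> DFA, the standard LRTC pipeline."""
    filtered = band_filter(series, band, fs=fs)
    env = hilbert_envelope(filtered)
    if cfg is None:
        cfg = DFAConfig(fs=fs)
    elif cfg.fs != fs:
        cfg = DFAConfig(fit_range=cfg.fit_range, fs=fs,
                        window_overlap=cfg.window_overlap, n_windows=cfg.n_windows)
    return dfa(env, cfg)


def phase_randomized_surrogate(series: np.ndarray, seed) -> np.ndarray:
    """Surrogate with the exact Fourier amplitudes of the input but random
    phases (DC and Nyquist kept real); destroys any structure beyond the
    linear autocorrelation, including envelope LRTC."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 64:
        raise ValueError("series must be 1-D with at least 64 samples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spec = np.fft.rfft(x)
    phases = rng.uniform(0, 2 * np.pi, len(spec))
    phases[0] = 0.0
    if len(x) % 2 == 0:
        phases[-1] = 0.0
    return np.fft.irfft(np.abs(spec) * np.exp(1j * phases), n=len(x))


@dataclass
class SurrogateTestResult:
    alpha_original: np.ndarray          # per unit
    alpha_surrogates: np.ndarray        # units x n_surrogates
    p_value: float
    n_surrogates: int

    @property
    def alpha_surrogate_mean(self) -> np.ndarray:
        return self.alpha_surrogates.mean(axis=1)


def surrogate_nonlinearity_test(series_set, fs: float, n_surrogates: int = 10,
                                cfg: DFAConfig | None = None, seed=0) -> SurrogateTestResult:
    """Wilcoxon signed-rank test of envelope DFA exponents against
    phase-randomized surrogates.

    Each unit (channel or subject) contributes a band-filtered signal; its
    envelope exponent is paired with the mean exponent of ``n_surrogates``
    surrogates of the same signal (envelope recomputed per surrogate). A
    small two-sided p indicates nonlinear structure — here, long-range
    correlated amplitude envelopes, which phase randomization destroys.
    """
    series_set = [np.asarray(s, dtype=float) for s in series_set]
    if len(series_set) < 6:
        raise ValueError(
            f"signed-rank test needs at least 6 units, got {len(series_set)}; "
            "pool more channels or subjects")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if cfg is None:
        cfg = DFAConfig(fs=fs)
    orig = np.empty(len(series_set))
    surr = np.empty((len(series_set), n_surrogates))
    for i, x in enumerate(series_set):
        orig[i] = dfa(hilbert_envelope(x), cfg).alpha
        for j in range(n_surrogates):
            s = phase_randomized_surrogate(x, rng)
            surr[i, j] = dfa(hilbert_envelope(s), cfg).alpha
    diffs = orig - surr.mean(axis=1)
    if np.allclose(diffs, 0.0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(diffs, alternative="two-sided").pvalue)
    return SurrogateTestResult(alpha_original=orig, alpha_surrogates=surr,
                               p_value=p, n_surrogates=n_surrogates)


def alpha_profile(rec: Recording, band: BandSpec, chunk_s: float = 4.0,
                  cfg: DFAConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """DFA exponent time course: one exponent per consecutive ``chunk_s``
    chunk of the band envelope, per channel.

    Returns ``(chunk_onsets_s, alphas)`` with ``alphas`` of shape
    (n_channels, n_chunks). Uses a short-scale fit range (0.25 s up to a
    quarter chunk) since long windows cannot fit in a 4 s chunk.
    """
    fs = rec.fs
    chunk = round(chunk_s * fs)
    if rec.n_samples < 2 * chunk:
        raise ValueError("recording must contain at least two chunks")
    if cfg is None:
        cfg = DFAConfig(fit_range=(0.25, chunk_s / 4.0), fs=fs)
    if round(cfg.fit_range[1] * fs) * 4 > chunk:
        raise ValueError("chunk shorter than 4x the max DFA window")
    filtered = band_filter(rec.samples, band, fs=fs)
    env = np.abs(sps.hilbert(filtered, axis=-1))
    n_chunks = rec.n_samples // chunk
    alphas = np.empty((rec.n_channels, n_chunks))
    for c in range(n_chunks):
        seg = env[:, c * chunk: (c + 1) * chunk]
        for ch in range(rec.n_channels):
            alphas[ch, c] = dfa(seg[ch], cfg).alpha
    onsets = np.arange(n_chunks) * chunk_s
    return onsets, alphas
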