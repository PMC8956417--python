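"""Welch power spectra, band powers, magnitude-squared coherence, and
topographic interpolation.

PSDs are one-sided densities normalized so the integral over frequency
equals the signal variance; with the default configuration (1 s Hamming
window, 0.5 s overlap, nfft = 256 at fs = 256 Hz) the frequency resolution
is exactly 1 Hz. Coherence is the standard magnitude-squared estimate
|G_XY|^2 / (G_XX G_YY) averaged over 10 s epochs with 3 s overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, signal

from .protocol import BandSpec
from .recordings import MontageLayout, StageSegment

__all__ = [
    "SpectralConfig",
    "PSDEstimate",
    "CoherenceSpectrum",
    "welch_psd",
    "band_power",
    "msc_coherence",
    "coherence_matrix",
    "topographic_interpolate",
    "plot_topomap",
]


@dataclass(frozen=True)
class SpectralConfig:
    """Welch PSD settings (1 s Hamming windows, 50% overlap, 1 Hz bins at
    256 Hz) and coherence epoching (10 s epochs, 3 s overlap)."""

    window_s: float = 1.0
    overlap_s: float = 0.5
    nfft: int = 256
    epoch_len_s: float = 10.0
    epoch_overlap_s: float = 3.0

    def __post_init__(self) -> None:
        if self.overlap_s >= self.window_s:
            raise ValueError("overlap_s must be < window_s")
        if self.epoch_overlap_s >= self.epoch_len_s:
            raise ValueError("epoch_overlap_s must be < epoch_len_s")


@dataclass
class PSDEstimate:
    frequencies: np.ndarray
    density: np.ndarray  # power per Hz; last axis = frequency
    resolution: float

    @property
    def n_segments(self) -> int | None:
        return getattr(self, "_n_segments", None)


@dataclass
class CoherenceSpectrum:
    pair: tuple[str, str]
    frequencies: np.ndarray
    msc: np.ndarray
    n_epochs: int
    epoch_len_s: float
    epoch_overlap_s: float
    degenerate: bool = False  # True when the epoching had to be shortened

    def band_mean(self, band: BandSpec) -> float:
        mask = (self.frequencies >= band.low) & (self.frequencies <= band.high)
        if not mask.any():
            raise ValueError(f"band {band.name} outside coherence grid")
        return float(self.msc[mask].mean())

    def band_peak(self, band: BandSpec) -> float:
        """Maximum MSC inside the band (alternative summary to the mean)."""
        mask = (self.frequencies >= band.low) & (self.frequencies <= band.high)
        if not mask.any():
            raise ValueError(f"band {band.name} outside coherence grid")
        return float(self.msc[mask].max())


def welch_psd(segment: np.ndarray, fs: float,
              cfg: SpectralConfig = SpectralConfig()) -> PSDEstimate:
    """Welch's averaged modified periodogram of one (or several) channels.

    ``segment`` may be 1-D or channels x time; the estimate is one-sided and
    density-scaled (integral over frequency ~ variance). Frequency spacing is
    ``fs / nfft``.
    """
    x = np.asarray(segment, dtype=float)
    nper = round(cfg.window_s * fs)
    if x.shape[-1] < nper:
        raise ValueError(
            f"segment of {x.shape[-1]} samples is shorter than one "
            f"{cfg.window_s} s window ({nper} samples)")
    if cfg.nfft < nper:
        raise ValueError("nfft must be >= window length")
    freqs, dens = signal.welch(
        x, fs=fs, window=signal.get_window("hamming", nper),
        noverlap=round(cfg.overlap_s * fs), nfft=cfg.nfft,
        detrend="constant", scaling="density", axis=-1)
    est = PSDEstimate(frequencies=freqs, density=dens, resolution=fs / cfg.nfft)
    step = nper - round(cfg.overlap_s * fs)
    est._n_segments = 1 + (x.shape[-1] - nper) // step
    return est


def band_power(psd: PSDEstimate, band: BandSpec) -> float | np.ndarray:
    """Integrated power in [low, high]: trapezoid rule on the PSD bin grid.

    Returned as an integral (not a mean) so Parseval interpretability is
    kept: summing band powers of adjacent bands approximates total variance.
    """
    f = psd.frequencies
    if band.low < f[0] - 1e-9 or band.high > f[-1] + 1e-9:
        raise ValueError(
            f"band {band.name} [{band.low}, {band.high}] outside PSD grid "
            f"[{f[0]}, {f[-1]}]")
    mask = (f >= band.low - 1e-9) & (f <= band.high + 1e-9)
    return np.trapezoid(psd.density[..., mask], f[mask], axis=-1)


# ---------------------------------------------------------------------------
# coherence

def _epoch_slices(n: int, nper: int, nover: int) -> list[slice]:
    step = nper - nover
    return [slice(s, s + nper) for s in range(0, n - nper + 1, step)]


def _epoch_ffts(x: np.ndarray, fs: float, nper: int, nover: int):
    """Hamming-windowed, mean-detrended epoch FFTs: (..., n_epochs, n_freqs)."""
    sl = _epoch_slices(x.shape[-1], nper, nover)
    win = signal.get_window("hamming", nper)
    segs = np.stack([x[..., s] for s in sl], axis=-2)
    segs = segs - segs.mean(axis=-1, keepdims=True)
    F = np.fft.rfft(segs * win, axis=-1)
    freqs = np.fft.rfftfreq(nper, d=1.0 / fs)
    return freqs, F


def _resolve_epoching(n: int, fs: float, cfg: SpectralConfig) -> tuple[int, int, bool]:
    nper = round(cfg.epoch_len_s * fs)
    nover = round(cfg.epoch_overlap_s * fs)
    degenerate = False
    if n < nper:
        # segment shorter than one epoch (e.g. the 5 s decision intervals):
        # fall back to Welch-style 1 s subwindows over the whole segment
        nper, nover = round(cfg.window_s * fs), round(cfg.overlap_s * fs)
        degenerate = True
        warnings.warn(
            "segment shorter than one coherence epoch; falling back to "
            f"{cfg.window_s} s subwindows (estimate flagged degenerate)",
            stacklevel=3)
        if n < nper:
            raise ValueError("segment shorter than one coherence subwindow")
    n_epochs = 1 + (n - nper) // (nper - nover)
    if n_epochs == 1:
        warnings.warn(
            "single-epoch coherence estimate degenerates to 1 at every "
            "frequency; interpret with caution", stacklevel=3)
        degenerate = True
    return nper, nover, degenerate


def msc_coherence(x: np.ndarray, y: np.ndarray, fs: float,
                  cfg: SpectralConfig = SpectralConfig(),
                  pair: tuple[str, str] = ("x", "y")) -> CoherenceSpectrum:
    """Magnitude-squared coherence of two equal-length signals.

    Cross- and auto-spectra are averaged over N Hamming-windowed epochs
    (default 10 s, 3 s overlap); msc(f) = |G_XY|^2 / (G_XX G_YY) in [0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    nper, nover, degenerate = _resolve_epoching(len(x), fs, cfg)
    freqs, Fx = _epoch_ffts(x, fs, nper, nover)
    _, Fy = _epoch_ffts(y, fs, nper, nover)
    gxy = (Fx * Fy.conj()).mean(axis=0)
    gxx = (np.abs(Fx) ** 2).mean(axis=0)
    gyy = (np.abs(Fy) ** 2).mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        msc = np.abs(gxy) ** 2 / (gxx * gyy)
    msc = np.clip(np.nan_to_num(msc, nan=0.0), 0.0, 1.0)
    return CoherenceSpectrum(pair=pair, frequencies=freqs, msc=msc,
                             n_epochs=Fx.shape[0], epoch_len_s=nper / fs,
                             epoch_overlap_s=nover / fs, degenerate=degenerate)


def coherence_matrix(segment: StageSegment, electrodes: list[str], band: BandSpec,
                     cfg: SpectralConfig = SpectralConfig()) -> np.ndarray:
    """Pairwise band-averaged MSC matrix over the given electrodes.

    Symmetric with unit diagonal. One windowed FFT per channel is shared by
    all pairs, so the 13-electrode matrix costs 13 FFT sets, not 78.
    """
    unknown = [e for e in electrodes if e not in segment.channel_labels]
    if unknown:
        raise ValueError(f"electrodes not in segment: {unknown}")
    idx = [segment.channel_labels.index(e) for e in electrodes]
    data = segment.samples[idx]
    nper, nover, _ = _resolve_epoching(data.shape[-1], segment.fs, cfg)
    freqs, F = _epoch_ffts(data, segment.fs, nper, nover)  # (ch, ep, f)
    mask = (freqs >= band.low) & (freqs <= band.high)
    F = F[..., mask]
    G = np.einsum("aef,bef->abf", F, F.conj()) / F.shape[1]
    auto = np.einsum("aaf->af", G).real
    with np.errstate(divide="ignore", invalid="ignore"):
        msc = np.abs(G) ** 2 / (auto[:, None, :] * auto[None, :, :])
    msc = np.clip(np.nan_to_num(msc, nan=0.0), 0.0, 1.0).mean(axis=-1)
    np.fill_diagonal(msc, 1.0)
    return msc


# ---------------------------------------------------------------------------
# topographic interpolation

def topographic_interpolate(values: dict[str, float] | np.ndarray,
                            layout: MontageLayout,
                            labels: list[str] | None = None,
                            grid: int = 64):
    """Biharmonic (thin-plate / Green's-function) spline interpolation of
    per-electrode scalars over the unit head disc.

    Returns ``(xx, yy, field)`` where points outside the head circle are NaN.
    The spline passes through the electrode values exactly.
    """
    if isinstance(values, dict):
        labels = list(values)
        vals = np.array([values[k] for k in labels], dtype=float)
    else:
        vals = np.asarray(values, dtype=float)
        if labels is None:
            raise ValueError("labels are required when values is an array")
    if len(vals) < 4:
        raise ValueError("need at least 4 electrodes to interpolate")
    pts = layout.positions(list(labels))
    # duplicate coordinates make the spline system singular
    uniq = {tuple(np.round(p, 12)) for p in pts}
    if len(uniq) != len(pts):
        raise ValueError("duplicate electrode coordinates in layout")
    rbf = interpolate.RBFInterpolator(pts, vals, kernel="thin_plate_spline",
                                      smoothing=0.0)
    g = np.linspace(-1.0, 1.0, grid)
    xx, yy = np.meshgrid(g, g)
    flat = np.column_stack([xx.ravel(), yy.ravel()])
    field = rbf(flat).reshape(grid, grid)
    field[xx ** 2 + yy ** 2 > 1.0] = np.nan
    return xx, yy, field


def plot_topomap(values: dict[str, float], layout: MontageLayout, path=None,
                 title: str = "", grid: int = 64, cmap: str = "RdBu_r"):
    """Render a scalp map of per-electrode values to a matplotlib figure.

    Interpolates with :func:`topographic_interpolate`, draws the head circle
    and electrode positions, and saves to ``path`` if given. Returns the
    figure.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    xx, yy, field = topographic_interpolate(values, layout, grid=grid)
    fig, ax = plt.subplots(figsize=(4, 4))
    vmax = np.nanmax(np.abs(field))
    im = ax.pcolormesh(xx, yy, field, cmap=cmap, vmin=-vmax, vmax=vmax,
                       shading="auto")
    theta = np.linspace(0, 2 * np.pi, 200)
    ax.plot(np.cos(theta), np.sin(theta), color="k", lw=1.5)
    pts = layout.positions(list(values))
    ax.scatter(pts[:, 0], pts[:, 1], s=12, c="k", zorder=3)
    for lab, (x, y) in zip(values, pts):
        ax.annotate(lab, (x, y), fontsize=6, ha="center", va="bottom")
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.7)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
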