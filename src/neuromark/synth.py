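"""Synthetic EEG cohort generator.

Builds multichannel sessions whose band powers, interelectrode coherences,
and alpha-envelope long-range temporal correlations are set to known values,
following the study protocol (baseline + S1 + D1 + S2 + D2 at 256 Hz, 21
channels) and its two-group structure (16 electric-car selectors vs 29
others). Every quantity the analysis pipeline estimates is therefore
recoverable against ground truth.

Construction of one channel in one stage:

    x(t) = sum_bands  sqrt(P_band) * e_band(t) * c_band(t)  +  pink(t) + sensor(t)

with unit-variance narrowband carriers ``c``, unit-RMS nonnegative
envelopes ``e``, a 1/f background and white sensor noise. Constant-envelope
bands use band-filtered white noise as the carrier; enveloped bands (alpha)
use a randomly frequency-modulated oscillator at the band centre, whose own analytic
amplitude is nearly constant — so the Hilbert envelope of the band-filtered
output recovers the imposed envelope. Alpha envelopes are log-transformed
fractional Gaussian noise (carrying a chosen Hurst exponent), band-limited
by a Gaussian smoother so the amplitude-modulation sidebands stay inside
the band. Coherence between targeted electrode pairs is imposed by mixing a
shared alpha carrier into each member: with weight ``w`` per channel the
theoretical magnitude-squared coherence of the pair is ``w**4``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .protocol import (
    CHANNELS_21,
    STANDARD_BANDS,
    BandSpec,
    CohortSpec,
    GroupEffectSpec,
    ProtocolSpec,
)
from .recordings import Event, Recording, write_recording

__all__ = [
    "generate_fgn",
    "lognormal_envelope",
    "synthesize_channel",
    "impose_coherence",
    "generate_session",
    "generate_cohort",
    "write_cohort",
    "BASE_BAND_POWER",
]

#: Baseline band powers in uV^2 (before group gains); ballpark resting-EEG
#: proportions with a dominant posterior-alpha / slow-activity mix.
BASE_BAND_POWER: dict[str, float] = {"delta": 30.0, "theta": 20.0, "alpha": 15.0, "beta": 8.0}
PINK_POWER = 10.0   # 1/f background variance, uV^2
SENSOR_POWER = 2.0  # white sensor-noise variance, uV^2
#: Between-subject lognormal spread of band power (sigma of log), per band.
SUBJECT_POWER_SIGMA: dict[str, float] = {"delta": 0.2, "theta": 0.2, "alpha": 0.25, "beta": 0.2}
#: Envelope coefficient of variation (lognormal transform of the fGn).
ENVELOPE_CV = 0.5

_REFERENCE_CHANNELS = ("A1", "A2")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# fractional Gaussian noise

def generate_fgn(hurst: float, n_samples: int, seed) -> np.ndarray:
    """Exact unit-variance fractional Gaussian noise by circulant embedding.

    Embeds the fGn autocovariance ``g(k) = (|k+1|^2H - 2|k|^2H + |k-1|^2H)/2``
    in a circulant matrix whose eigenvalues are obtained by FFT (Davies-Harte
    construction); any length is handled by padding to the next power of two.
    Falls back to spectral synthesis in the (rare, extreme-H) case of a
    negative eigenvalue.

    H = 0.5 gives white noise; H > 0.5 persistent correlations.
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError(f"hurst must be in (0, 1), got {hurst}")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = _rng(seed)
    m = 1 << max(6, int(np.ceil(np.log2(n_samples))))
    k = np.arange(m + 1, dtype=float)
    g = 0.5 * ((k + 1) ** (2 * hurst) - 2 * k ** (2 * hurst) + np.abs(k - 1) ** (2 * hurst))
    row = np.concatenate([g[: m + 1], g[m - 1:0:-1]])  # length 2m
    lam = np.fft.fft(row).real
    if lam.min() < -1e-9 * lam.max():
        return _fgn_spectral(hurst, n_samples, rng)
    lam = np.clip(lam, 0.0, None)
    two_m = 2 * m
    # Hermitian-symmetric spectral weights make the FFT output real with the
    # exact circulant covariance (ensemble variance gamma(0) = 1)
    w = np.empty(two_m, dtype=complex)
    w[0] = np.sqrt(lam[0] / two_m) * rng.standard_normal()
    w[m] = np.sqrt(lam[m] / two_m) * rng.standard_normal()
    z = rng.standard_normal(m - 1) + 1j * rng.standard_normal(m - 1)
    w[1:m] = np.sqrt(lam[1:m] / (2 * two_m)) * z
    w[m + 1:] = np.conj(w[1:m][::-1])
    x = np.fft.fft(w).real
    return x[:n_samples]


def _fgn_spectral(hurst: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Approximate fGn via its power-law spectrum S(f) ~ f^(1-2H)."""
    m = 1 << max(6, int(np.ceil(np.log2(n))))
    freqs = np.fft.rfftfreq(m, d=1.0)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** ((1.0 - 2.0 * hurst) / 2.0)
    phases = rng.uniform(0, 2 * np.pi, len(freqs))
    spec = amp * np.exp(1j * phases)
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=m)[:n]
    sd = x.std()
    return x / sd if sd > 0 else x


def lognormal_envelope(hurst: float, n_samples: int, seed,
                       cv: float = ENVELOPE_CV, fs: float = 256.0,
                       smooth_s: float = 0.05) -> np.ndarray:
    """Nonnegative, unit-RMS amplitude envelope with fGn temporal structure.

    ``exp(sigma * fGn(H))`` with sigma set so the coefficient of variation is
    ``cv``; the log-transform preserves the fGn scaling exponent to good
    approximation while guaranteeing positivity. A Gaussian smoother of width
    ``smooth_s`` (pass 0 to disable) band-limits the envelope so that
    amplitude modulation does not spill power outside the carrier band; it
    leaves the scaling at time scales beyond ~2*smooth_s untouched.
    """
    from scipy.ndimage import gaussian_filter1d

    g = generate_fgn(hurst, n_samples, seed)
    if smooth_s > 0:
        # smooth the Gaussian process and re-standardize before the exp
        # transform: a constant rescale leaves the scaling exponent at
        # window sizes beyond the smoothing width unchanged
        g = gaussian_filter1d(g, smooth_s * fs, mode="nearest")
        sd = g.std()
        if sd > 0:
            g = g / sd
    sigma = np.sqrt(np.log1p(cv * cv))
    env = np.exp(sigma * g)
    return env / np.sqrt(np.mean(env * env))


# ---------------------------------------------------------------------------
# channel synthesis

def _inband_fraction(taps: np.ndarray, band: BandSpec, fs: float) -> float:
    """Fraction of a filtered-white-noise carrier's power inside the band."""
    freqs, h = sps.freqz(taps, worN=4096, fs=fs)
    p = np.abs(h) ** 2
    inside = (freqs >= band.low) & (freqs <= band.high)
    return float(p[inside].sum() / p.sum())


def _unit_carrier(band: BandSpec, n: int, fs: float, rng: np.random.Generator,
                  noise: np.ndarray | None = None) -> np.ndarray:
    """Narrowband noise carrier with unit in-band power.

    Filtered white noise leaks a little power into the transition skirts, so
    the carrier is normalized by the analytic in-band fraction of the filter:
    its Welch band power is 1, its total variance slightly above 1.
    """
    if noise is None:
        noise = rng.standard_normal(n)
    numtaps = min(int(3 * fs / band.low) | 1, max(3, (n // 2) * 2 - 1))
    taps = sps.firwin(numtaps, [band.low, band.high], pass_zero=False,
                      window="hamming", fs=fs)
    x = sps.fftconvolve(noise, taps, mode="same")
    sd = x.std()
    if sd == 0:
        return x
    return x / (sd * np.sqrt(_inband_fraction(taps, band, fs)))


def _oscillator_carrier(n: int, fs: float, rng: np.random.Generator,
                        f0: float, dev_hz: float = 1.0,
                        mod_smooth_s: float = 0.1) -> np.ndarray:
    """Unit-variance oscillator with band-limited random frequency modulation.

    ``sqrt(2) * cos(2*pi * integral(f0 + df(t)))`` where the instantaneous
    frequency deviation ``df`` is Gaussian noise smoothed to ~1.6 Hz
    bandwidth with standard deviation ``dev_hz``. The spectrum is a compact
    ~2-3 Hz-wide line at f0 with steep (non-Lorentzian) tails — wide enough
    that a phase-randomized surrogate's envelope decorrelates within a
    second, yet the carrier's own analytic amplitude stays essentially
    constant, so an imposed envelope is what an envelope analysis recovers.
    """
    from scipy.ndimage import gaussian_filter1d

    df = gaussian_filter1d(rng.standard_normal(n), mod_smooth_s * fs, mode="nearest")
    sd = df.std()
    if sd > 0:
        df *= dev_hz / sd
    return np.sqrt(2.0) * np.cos(2 * np.pi * np.cumsum(f0 + df) / fs)


def _scale_to_band_power(x: np.ndarray, band: BandSpec, fs: float,
                         power: float) -> np.ndarray:
    """Scale a narrowband component so its Welch band power equals ``power``.

    Amplitude modulation pushes some power into sidebands just outside the
    band; normalizing against the measured in-band power keeps the generated
    band power on target regardless of the envelope's bandwidth.
    """
    nper = min(len(x), round(fs))
    freqs, dens = sps.welch(x, fs=fs, window=sps.get_window("hamming", nper),
                            noverlap=nper // 2, scaling="density")
    mask = (freqs >= band.low) & (freqs <= band.high)
    measured = np.trapezoid(dens[mask], freqs[mask])
    if measured <= 0:
        return x
    return x * np.sqrt(power / measured)


def _pink_noise(n: int, fs: float, rng: np.random.Generator,
                f_low: float = 0.5, f_high: float = 45.0) -> np.ndarray:
    """Unit-variance 1/f-spectrum background between f_low and f_high."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    band = (freqs >= f_low) & (freqs <= f_high)
    amp[band] = freqs[band] ** -0.5
    spec = amp * np.exp(1j * rng.uniform(0, 2 * np.pi, len(freqs)))
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def synthesize_channel(bands, background_pink_power: float, sensor_noise_power: float,
                       duration: float, fs: float, seed) -> np.ndarray:
    """Synthesize one EEG channel as enveloped narrowband oscillations plus
    1/f background and white sensor noise.

    ``bands`` is a list of ``(BandSpec, power, envelope)`` triples; the
    envelope may be ``None`` (constant amplitude) or a nonnegative series of
    length ``duration * fs``. Each band contributes ``power`` (uV^2) of
    variance, so its Welch band power matches the request up to spectral
    leakage (within 10% on >= 20 s of signal). Constant-envelope bands ride
    on band-filtered noise; enveloped bands on a band-centre oscillator (see
    module docstring), keeping the modulation inside the band.
    """
    rng = _rng(seed)
    n = round(duration * fs)
    out = np.zeros(n)
    for band, power, envelope in bands:
        if power < 0:
            raise ValueError(f"band {band.name}: power must be >= 0")
        if envelope is None:
            env = np.ones(n)
        else:
            env = np.asarray(envelope, dtype=float)
            if env.shape != (n,):
                raise ValueError(
                    f"band {band.name}: envelope length {env.shape} != {n}")
            if np.any(env < 0):
                raise ValueError(f"band {band.name}: envelope must be nonnegative")
        if power == 0:
            continue
        if envelope is None:
            # carrier already has unit in-band power: scale directly
            x = np.sqrt(power) * _unit_carrier(band, n, fs, rng)
        else:
            carrier = _oscillator_carrier(n, fs, rng, f0=0.5 * (band.low + band.high))
            x = _scale_to_band_power(env * carrier, band, fs, power)
        out += x
    if background_pink_power < 0 or sensor_noise_power < 0:
        raise ValueError("noise powers must be >= 0")
    if background_pink_power > 0:
        out += np.sqrt(background_pink_power) * _pink_noise(n, fs, rng)
    if sensor_noise_power > 0:
        out += np.sqrt(sensor_noise_power) * rng.standard_normal(n)
    return out


def impose_coherence(shared_source: np.ndarray, private_a: np.ndarray,
                     private_b: np.ndarray, c: float) -> tuple[np.ndarray, np.ndarray]:
    """Mix a shared source into two private signals with weight ``c``.

    For independent, unit-variance, spectrally matched inputs the outputs
    ``x = c*s + sqrt(1-c^2)*n1`` and ``y = c*s + sqrt(1-c^2)*n2`` have unit
    variance and theoretical magnitude-squared coherence ``c**4`` at every
    frequency (cross-spectrum c^2*S over auto-spectra S each).
    """
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"mixing weight c must be in [0, 1], got {c}")
    root = np.sqrt(1.0 - c * c)
    return c * shared_source + root * private_a, c * shared_source + root * private_b


# ---------------------------------------------------------------------------
# sessions and cohorts

def _stage_plan(protocol: ProtocolSpec) -> list[Event]:
    events: list[Event] = []
    t = 0.0
    events.append(Event("baseline", None, t, protocol.baseline_s))
    t += protocol.baseline_s
    events.append(Event("S1", None, t, protocol.s1_s))
    for i in range(protocol.s1_trials):
        events.append(Event("S1", i + 1, t + i * protocol.s1_trial_s, protocol.s1_trial_s))
    t += protocol.s1_s
    events.append(Event("D1", None, t, protocol.d1_s))
    t += protocol.d1_s
    events.append(Event("S2", None, t, protocol.s2_s))
    for i in range(protocol.s2_trials):
        events.append(Event("S2", i + 1, t + i * protocol.s2_trial_s, protocol.s2_trial_s))
    t += protocol.s2_s
    events.append(Event("D2", None, t, protocol.d2_s))
    return events


@dataclass
class _SubjectTraits:
    """Per-subject multiplicative band-power factors (between-subject
    variability), drawn once per subject: a global factor per band times a
    small per-channel jitter."""
    band_factor: dict[str, float]
    channel_jitter: dict[tuple[str, str], float]  # (band, channel) -> factor

    @classmethod
    def draw(cls, rng: np.random.Generator, channels) -> "_SubjectTraits":
        band_factor = {
            b: float(np.exp(rng.normal(0.0, SUBJECT_POWER_SIGMA[b])))
            for b in BASE_BAND_POWER
        }
        jitter = {
            (b, ch): float(np.exp(rng.normal(0.0, 0.1)))
            for b in BASE_BAND_POWER for ch in channels
        }
        return cls(band_factor, jitter)

    def power(self, band: str, channel: str) -> float:
        return BASE_BAND_POWER[band] * self.band_factor[band] * self.channel_jitter[(band, channel)]


def generate_session(subject_effects: GroupEffectSpec, protocol: ProtocolSpec,
                     montage: list[str] | tuple[str, ...] = CHANNELS_21,
                     seed=0, traits: _SubjectTraits | None = None,
                     subject_id: str = "") -> Recording:
    """Generate one recording session with stage/trial events.

    Stage durations match the protocol exactly; the configured group effects
    (alpha power gain per channel/stage, alpha coherence per electrode pair,
    alpha-envelope Hurst exponent per stage) are applied within each stage.
    Ear electrodes A1/A2 carry low-amplitude sensor noise only.
    """
    montage = list(montage)
    fs = protocol.sampling_rate
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    stage_seeds = ss.spawn(5)
    if traits is None:
        traits = _SubjectTraits.draw(np.random.default_rng(ss.spawn(1)[0]),
                                     [c for c in montage if c not in _REFERENCE_CHANNELS])

    alpha = STANDARD_BANDS["alpha"]
    other_bands = [STANDARD_BANDS[b] for b in ("delta", "theta", "beta")]
    # individual alpha peak frequency, one per subject
    f0 = float(np.random.default_rng(ss.spawn(1)[0]).uniform(9.5, 10.5))

    blocks: list[np.ndarray] = []
    for stage, stage_ss in zip(("baseline", "S1", "D1", "S2", "D2"), stage_seeds):
        n = round(protocol.stage_durations()[stage] * fs)
        rng = np.random.default_rng(stage_ss)
        block = np.zeros((len(montage), n))

        # coherent alpha set for this stage: a common oscillator source mixed
        # into each member with weight w = msc_target**(1/4)
        targets = subject_effects.msc_targets(stage) if stage != "baseline" else {}
        coherent: dict[str, float] = {}
        for pair, msc in targets.items():
            w = msc ** 0.25
            for ch in pair:
                coherent[ch] = max(coherent.get(ch, 0.0), w)
        shared_carrier = _oscillator_carrier(n, fs, rng, f0) if coherent else None
        hurst = subject_effects.hurst(stage)

        for ci, ch in enumerate(montage):
            if ch in _REFERENCE_CHANNELS:
                block[ci] = np.sqrt(SENSOR_POWER) * rng.standard_normal(n)
                continue
            # alpha component: enveloped oscillator, possibly coherence-mixed
            own = _oscillator_carrier(n, fs, rng, f0)
            if ch in coherent:
                w = coherent[ch]
                carrier = w * shared_carrier + np.sqrt(1 - w * w) * own
            else:
                carrier = own
            env = lognormal_envelope(hurst, n, rng, fs=fs)
            p_alpha = traits.power("alpha", ch) * subject_effects.gain(ch, stage)
            block[ci] = _scale_to_band_power(env * carrier, alpha, fs, p_alpha)
            # remaining bands: constant-envelope narrowband noise
            for band in other_bands:
                c = _unit_carrier(band, n, fs, rng)
                block[ci] += np.sqrt(traits.power(band.name, ch)) * c
            block[ci] += np.sqrt(PINK_POWER) * _pink_noise(n, fs, rng)
            block[ci] += np.sqrt(SENSOR_POWER) * rng.standard_normal(n)
        blocks.append(block)

    samples = np.concatenate(blocks, axis=1)
    return Recording(samples=samples, channel_labels=montage, fs=fs,
                     events=_stage_plan(protocol), subject_id=subject_id)


def _allocate(n: int, count_16_or_29: int, total: int) -> int:
    """Scale a default questionnaire count to a group of size n."""
    return round(n * count_16_or_29 / total)


def generate_cohort(spec: CohortSpec):
    """Generate all sessions of a cohort plus its self-report table.

    Returns ``(recordings, self_report)`` where the self-report is a
    DataFrame with columns subject_id, group, age, sex, emotional_selection,
    attentional_selection, info_useful, changed_choice. Fully reproducible
    from ``spec.master_seed``; per-subject random streams are spawned from
    the master seed by subject index, so any single subject can be
    regenerated in isolation.
    """
    import pandas as pd

    ss = np.random.SeedSequence(spec.master_seed)
    subject_seeds = ss.spawn(spec.n_subjects + 1)
    table_rng = np.random.default_rng(subject_seeds[-1])

    rows = []
    recordings = []
    groups = ["A"] * spec.n_group_a + ["B"] * spec.n_group_b
    # questionnaire patterns scaled from the default 16/29 cohort
    q = {
        "A": dict(emo=_allocate(spec.n_group_a, 5, 16), att=_allocate(spec.n_group_a, 11, 16),
                  useful=_allocate(spec.n_group_a, 13, 16), changed=0),
        "B": dict(emo=_allocate(spec.n_group_b, 18, 29), att=_allocate(spec.n_group_b, 11, 29),
                  useful=_allocate(spec.n_group_b, 16, 29), changed=_allocate(spec.n_group_b, 5, 29)),
    }
    flags: dict[str, dict[str, np.ndarray]] = {}
    for g, n in (("A", spec.n_group_a), ("B", spec.n_group_b)):
        def pick(k: int) -> np.ndarray:
            v = np.zeros(n, dtype=bool)
            if n:
                v[table_rng.permutation(n)[:k]] = True
            return v
        flags[g] = {
            "emotional_selection": pick(q[g]["emo"]),
            "attentional_selection": pick(q[g]["att"]),
            "info_useful": pick(q[g]["useful"]),
            "changed_choice": pick(q[g]["changed"]),
        }

    idx_in_group = {"A": 0, "B": 0}
    for i, group in enumerate(groups):
        effects = spec.effects_a if group == "A" else spec.effects_b
        mean, sd = spec.age_mean_sd_a if group == "A" else spec.age_mean_sd_b
        subject_id = f"sub-{i + 1:02d}"
        rec = generate_session(effects, spec.protocol, CHANNELS_21,
                               seed=subject_seeds[i], subject_id=subject_id)
        recordings.append(rec)
        j = idx_in_group[group]
        idx_in_group[group] += 1
        rows.append({
            "subject_id": subject_id,
            "group": group,
            "age": float(np.clip(table_rng.normal(mean, sd), 20, 43)),
            "sex": "M" if table_rng.random() < 28 / 45 else "F",
            **{k: bool(v[j]) for k, v in flags[group].items()},
        })
    return recordings, pd.DataFrame(rows)


def write_cohort(recordings, self_report, out_dir) -> None:
    """Write a cohort to disk: one EDF + events TSV per subject plus the
    self-report CSV (layout consumed by the pipeline's files mode)."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        write_recording(rec, out / f"{rec.subject_id}.edf", out / f"{rec.subject_id}_events.tsv")
    self_report.to_csv(out / "self_report.csv", index=False)
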