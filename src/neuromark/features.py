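"""Per-subject EEG feature extraction: band powers, pairwise coherences,
and envelope DFA exponents per protocol stage, emitted as a long-format
table (subject_id, stage, band, measure, location, value)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .lrtc import DFAConfig, dfa, hilbert_envelope
from .protocol import (
    COHERENCE_13,
    FRONTAL_CENTRAL,
    PROCESSING_STAGES,
    SCALP_19,
    STANDARD_BANDS,
    BandSpec,
)
from .recordings import Recording, StageSegment, band_filter, segment_stages
from .spectral import SpectralConfig, band_power, coherence_matrix, welch_psd

__all__ = ["extract_features", "pair_key"]


def pair_key(a: str, b: str) -> str:
    """Canonical electrode-pair name, order-free: pair_key('Pz','Cz') == 'Cz-Pz'."""
    return "-".join(sorted((a, b)))


def _stage_segments(rec: Recording) -> dict[str, StageSegment]:
    return {s.stage: s for s in segment_stages(rec, include_trials=False)
            if s.for_processing}


def extract_features(
    rec: Recording,
    psd_bands: tuple[str, ...] = ("alpha", "theta", "whole"),
    psd_channels: tuple[str, ...] = SCALP_19,
    coherence_bands: tuple[str, ...] = ("alpha",),
    coherence_electrodes: tuple[str, ...] = COHERENCE_13,
    dfa_bands: tuple[str, ...] = ("alpha",),
    dfa_channels: tuple[str, ...] = FRONTAL_CENTRAL,
    stages: tuple[str, ...] = PROCESSING_STAGES,
    spectral_cfg: SpectralConfig = SpectralConfig(),
) -> pd.DataFrame:
    """Compute the feature table for one (already broadband-filtered)
    recording.

    PSD band powers come from Welch spectra of whole-stage segments;
    coherence values are band-averaged MSC for every pair of
    ``coherence_electrodes``; DFA exponents are computed on the Hilbert
    envelope of the band-filtered stage segment, with the fit window range
    adapted to the stage length (0.25 s up to a quarter of the segment).
    """
    rows: list[dict] = []
    segs = _stage_segments(rec)
    for stage in stages:
        if stage not in segs:
            raise ValueError(f"recording {rec.subject_id} lacks stage {stage}")
        seg = segs[stage]
        ch_idx = [seg.channel_labels.index(c) for c in psd_channels]
        psd = welch_psd(seg.samples[ch_idx], seg.fs, spectral_cfg)
        for band_name in psd_bands:
            bp = band_power(psd, STANDARD_BANDS[band_name])
            for ch, v in zip(psd_channels, np.atleast_1d(bp)):
                rows.append(dict(subject_id=rec.subject_id, stage=stage,
                                 band=band_name, measure="psd", location=ch,
                                 value=float(v)))
        for band_name in coherence_bands:
            msc = coherence_matrix(seg, list(coherence_electrodes),
                                   STANDARD_BANDS[band_name], spectral_cfg)
            for i in range(len(coherence_electrodes)):
                for j in range(i + 1, len(coherence_electrodes)):
                    rows.append(dict(
                        subject_id=rec.subject_id, stage=stage, band=band_name,
                        measure="coherence",
                        location=pair_key(coherence_electrodes[i], coherence_electrodes[j]),
                        value=float(msc[i, j])))
        for band_name in dfa_bands:
            band = STANDARD_BANDS[band_name]
            filtered = band_filter(seg, band)
            cfg = DFAConfig(fs=seg.fs)  # adaptive fit range per stage length
            for ch in dfa_channels:
                env = hilbert_envelope(filtered.channel(ch))
                res = dfa(env, cfg)
                rows.append(dict(subject_id=rec.subject_id, stage=stage,
                                 band=band_name, measure="dfa", location=ch,
                                 value=float(res.alpha)))
    return pd.DataFrame(rows)
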