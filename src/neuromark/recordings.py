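"""Recording containers, EDF/TSV I/O, filtering, and stage segmentation.

A :class:`Recording` is a channels-by-time matrix in microvolts with an
event table mapping the session's protocol stages (baseline, S1, D1, S2, D2)
onto time. Preprocessing applies a zero-phase Butterworth broadband filter
(0.5-45 Hz, order 4) before analysis; band-specific work uses zero-phase
windowed-sinc FIR filters. Times are 0-based seconds and stage intervals are
half-open, ``[onset, onset + duration)``.
"""

from __future__ import annotations

import importlib.resources
import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .edf import read_edf, write_edf
from .protocol import STAGES, BandSpec

__all__ = [
    "Event",
    "Recording",
    "StageSegment",
    "MontageLayout",
    "load_standard_montage",
    "write_recording",
    "read_recording",
    "broadband_filter",
    "band_filter",
    "segment_stages",
]


@dataclass(frozen=True)
class Event:
    stage: str
    trial: int | None  # 1-based trial index within S1/S2, None for stage rows
    onset_s: float
    duration_s: float


@dataclass
class Recording:
    """Multichannel EEG in microvolts with stage/trial events."""

    samples: np.ndarray  # channels x time, uV
    channel_labels: list[str]
    fs: float
    events: list[Event] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be channels x time")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.samples.shape[0]} channels but {len(self.channel_labels)} labels"
            )
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        dur = self.duration_s
        for ev in self.events:
            if ev.stage not in STAGES:
                raise ValueError(f"unknown stage {ev.stage!r}")
            if ev.onset_s < 0 or ev.onset_s + ev.duration_s > dur + 1e-9:
                raise ValueError(
                    f"event {ev.stage} [{ev.onset_s}, {ev.onset_s + ev.duration_s})"
                    f" outside recording of {dur} s"
                )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not in recording (has {self.channel_labels})"
            ) from None
        return self.samples[idx]

    def copy_with(self, samples: np.ndarray) -> "Recording":
        return Recording(
            samples=samples,
            channel_labels=list(self.channel_labels),
            fs=self.fs,
            events=list(self.events),
            subject_id=self.subject_id,
        )


@dataclass
class StageSegment:
    """A labeled slice of a recording (one stage, or one trial within S1/S2)."""

    stage: str
    trial: int | None
    samples: np.ndarray  # channels x time
    channel_labels: list[str]
    fs: float
    subject_id: str = ""
    #: True for the pre-stimulus baseline, which is recorded but not part of
    #: the primary processing.
    for_processing: bool = True

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in segment") from None
        return self.samples[idx]


class MontageLayout:
    """Electrode label -> (x, y) planar coordinates inside the unit head disc."""

    def __init__(self, coords: dict[str, tuple[float, float]]):
        for lab, (x, y) in coords.items():
            if x * x + y * y > 1.0 + 1e-9:
                raise ValueError(f"electrode {lab} at ({x}, {y}) outside unit disc")
        self.coords = {lab: (float(x), float(y)) for lab, (x, y) in coords.items()}

    def __contains__(self, label: str) -> bool:
        return label in self.coords

    def positions(self, labels: list[str]) -> np.ndarray:
        missing = [lab for lab in labels if lab not in self.coords]
        if missing:
            raise KeyError(f"montage has no coordinates for {missing}")
        return np.array([self.coords[lab] for lab in labels])


def load_standard_montage() -> MontageLayout:
    """The packaged 10-20 planar projection (21 electrodes, unit head circle)."""
    ref = importlib.resources.files("neuromark.data").joinpath("montage_1020.csv")
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path)
    return MontageLayout({r.label: (r.x, r.y) for r in df.itertuples()})


# ---------------------------------------------------------------------------
# I/O

def events_to_frame(rec: Recording) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": rec.subject_id,
                "stage": ev.stage,
                "trial": "" if ev.trial is None else ev.trial,
                "onset_s": ev.onset_s,
                "duration_s": ev.duration_s,
            }
            for ev in rec.events
        ]
    )


def write_recording(rec: Recording, edf_path: str | os.PathLike,
                    events_path: str | os.PathLike | None = None) -> None:
    """Write a recording as EDF plus a TSV event table."""
    write_edf(edf_path, rec.samples, rec.channel_labels, rec.fs,
              recording_id=rec.subject_id)
    if events_path is not None:
        events_to_frame(rec).to_csv(events_path, sep="\t", index=False)


def read_recording(edf_path: str | os.PathLike,
                   events_path: str | os.PathLike | None = None) -> Recording:
    """Read an EDF recording and, optionally, its TSV event table.

    Round-trips through :func:`write_recording` preserve channel labels
    exactly and samples to EDF 16-bit quantization.
    """
    sig = read_edf(edf_path)
    events: list[Event] = []
    subject_id = sig.recording_id
    if events_path is not None:
        df = pd.read_csv(events_path, sep="\t")
        required = {"stage", "trial", "onset_s", "duration_s"}
        if not required.issubset(df.columns):
            raise ValueError(f"event table {events_path} missing columns "
                             f"{sorted(required - set(df.columns))}")
        for row in df.itertuples():
            trial = None if pd.isna(row.trial) or row.trial == "" else int(row.trial)
            events.append(Event(str(row.stage), trial,
                                float(row.onset_s), float(row.duration_s)))
        if "subject_id" in df.columns and len(df):
            subject_id = str(df["subject_id"].iloc[0])
    return Recording(samples=sig.samples, channel_labels=sig.labels, fs=sig.fs,
                     events=events, subject_id=subject_id)


# ---------------------------------------------------------------------------
# Filtering

def broadband_filter(rec: Recording, low: float = 0.5, high: float = 45.0,
                     order: int = 4) -> Recording:
    """Zero-phase Butterworth bandpass (default 0.5-45 Hz, order 4).

    Applied forward-backward, so the effective magnitude order is doubled
    and the phase response is zero; removes DC.
    """
    if high >= rec.fs / 2:
        raise ValueError(f"high cutoff {high} Hz >= Nyquist {rec.fs / 2} Hz")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    out = signal.sosfiltfilt(sos, rec.samples, axis=-1)
    return rec.copy_with(out)


def _fir_taps(band: BandSpec, fs: float) -> np.ndarray:
    # windowed-sinc (Hamming); length scales with the low cutoff so the
    # transition stays <= ~1 Hz, forced odd for a symmetric (type I) filter
    numtaps = int(3 * fs / band.low) | 1
    return signal.firwin(numtaps, [band.low, band.high], pass_zero=False,
                         window="hamming", fs=fs)


def band_filter(data: Recording | StageSegment | np.ndarray, band: BandSpec,
                fs: float | None = None):
    """Zero-phase FIR bandpass to one frequency band.

    Accepts a :class:`Recording`, a :class:`StageSegment`, or a raw array
    (then ``fs`` is required); returns the same shape/kind.
    """
    if isinstance(data, Recording):
        arr, fs_ = data.samples, data.fs
    elif isinstance(data, StageSegment):
        arr, fs_ = data.samples, data.fs
    else:
        if fs is None:
            raise ValueError("fs is required when filtering a raw array")
        arr, fs_ = np.asarray(data, dtype=float), float(fs)
    if band.high >= fs_ / 2:
        raise ValueError(f"band {band.name} high edge {band.high} Hz >= Nyquist")
    taps = _fir_taps(band, fs_)
    padlen = min(arr.shape[-1] - 1, 3 * len(taps))
    out = signal.filtfilt(taps, [1.0], arr, axis=-1, padlen=padlen)
    if isinstance(data, Recording):
        return data.copy_with(out)
    if isinstance(data, StageSegment):
        return replace(data, samples=out)
    return out


# ---------------------------------------------------------------------------
# Segmentation

def segment_stages(rec: Recording, include_trials: bool = True) -> list[StageSegment]:
    """Cut a recording into stage segments (plus S1/S2 trial subsegments).

    The baseline segment is returned with ``for_processing=False``: it is
    recorded as a reference interval only.
    """
    if not rec.events:
        raise ValueError("recording has no events; cannot segment")
    present = {ev.stage for ev in rec.events}
    missing = [s for s in STAGES if s not in present]
    if missing:
        raise ValueError(f"event table lacks stages: {missing}")
    segments: list[StageSegment] = []
    for ev in rec.events:
        if ev.trial is not None and not include_trials:
            continue
        i0 = round(ev.onset_s * rec.fs)
        i1 = round((ev.onset_s + ev.duration_s) * rec.fs)
        segments.append(
            StageSegment(
                stage=ev.stage,
                trial=ev.trial,
                samples=rec.samples[:, i0:i1],
                channel_labels=list(rec.channel_labels),
                fs=rec.fs,
                subject_id=rec.subject_id,
                for_processing=ev.stage != "baseline",
            )
        )
    return segments


def stage_segment(rec: Recording, stage: str) -> StageSegment:
    """Convenience accessor: the (whole-stage) segment for one stage."""
    for seg in segment_stages(rec):
        if seg.stage == stage and seg.trial is None:
            return seg
    raise ValueError(f"stage {stage!r} not found")
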