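"""Study protocol, frequency bands, and cohort/effect specifications.

The default protocol reproduces a block-design neuromarketing session:
a 5 s pre-stimulus baseline, an emotional-stimulation stage S1 (five 4 s
trials of product images), a first decision interval D1 (5 s), an
attentional-stimulation stage S2 (five 8 s trials of images plus written
specifications), and a second decision interval D2 (5 s), recorded from a
21-channel 10-20 montage at 256 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

__all__ = [
    "CHANNELS_21",
    "SCALP_19",
    "COHERENCE_13",
    "FRONTAL_CENTRAL",
    "STAGES",
    "PROCESSING_STAGES",
    "BandSpec",
    "STANDARD_BANDS",
    "ProtocolSpec",
    "GroupEffectSpec",
    "CohortSpec",
    "default_effects_group_a",
    "default_effects_group_b",
    "default_cohort_spec",
]

#: Full 21-channel clinical montage (10-20 placement, ear references included).
CHANNELS_21: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "Fz", "C3", "C4", "Cz", "P3", "P4", "Pz",
    "O1", "O2", "F7", "F8", "T3", "T4", "T5", "T6", "A1", "A2",
)

#: The 19 scalp derivations used for analysis (ear electrodes excluded).
SCALP_19: tuple[str, ...] = tuple(c for c in CHANNELS_21 if c not in ("A1", "A2"))

#: The 13 electrodes retained for coherence analysis (frontal, central,
#: parietal and occipital rows).
COHERENCE_13: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "Fz", "F4", "C3", "Cz", "C4", "P3", "Pz", "P4", "O1", "O2",
)

#: Frontal-central electrode set used by the group power effect and the
#: clustering feature presets.
FRONTAL_CENTRAL: tuple[str, ...] = ("Fp1", "Fp2", "F3", "F4", "Fz", "C3", "Cz", "C4")

STAGES: tuple[str, ...] = ("baseline", "S1", "D1", "S2", "D2")
#: Stages entering the analysis (the baseline is recorded but not processed).
PROCESSING_STAGES: tuple[str, ...] = ("S1", "D1", "S2", "D2")


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band [low, high] in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(
                f"band {self.name!r}: need 0 < low < high, got ({self.low}, {self.high})"
            )


#: Conventional EEG bands; "whole" spans the full spectrum of interest.
STANDARD_BANDS: dict[str, BandSpec] = {
    "delta": BandSpec("delta", 1.0, 4.0),
    "theta": BandSpec("theta", 4.0, 8.0),
    "alpha": BandSpec("alpha", 8.0, 12.0),
    "beta": BandSpec("beta", 12.0, 30.0),
    "whole": BandSpec("whole", 1.0, 40.0),
}


@dataclass(frozen=True)
class ProtocolSpec:
    """Timing of one recording session.

    Defaults give baseline 5 s, S1 = 5 x 4 s = 20 s, D1 = 5 s,
    S2 = 5 x 8 s = 40 s, D2 = 5 s: a 75 s session at 256 Hz.
    """

    sampling_rate: float = 256.0
    baseline_s: float = 5.0
    s1_trials: int = 5
    s1_trial_s: float = 4.0
    d1_s: float = 5.0
    s2_trials: int = 5
    s2_trial_s: float = 8.0
    d2_s: float = 5.0

    def __post_init__(self) -> None:
        for name in ("sampling_rate", "baseline_s", "s1_trial_s", "d1_s", "s2_trial_s", "d2_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.s1_trials < 1 or self.s2_trials < 1:
            raise ValueError("trial counts must be >= 1")

    @property
    def s1_s(self) -> float:
        return self.s1_trials * self.s1_trial_s

    @property
    def s2_s(self) -> float:
        return self.s2_trials * self.s2_trial_s

    def stage_durations(self) -> dict[str, float]:
        return {
            "baseline": self.baseline_s,
            "S1": self.s1_s,
            "D1": self.d1_s,
            "S2": self.s2_s,
            "D2": self.d2_s,
        }

    @property
    def total_s(self) -> float:
        return sum(self.stage_durations().values())

    def n_samples(self) -> int:
        return round(self.total_s * self.sampling_rate)


@dataclass(frozen=True)
class GroupEffectSpec:
    """Generator-side controls for one group's EEG phenotype.

    alpha_power_gain
        Multiplier on alpha-band power, keyed by ``(channel, stage)``.
        Channels/stages not listed have gain 1.
    coherence_target
        Target magnitude-squared coherence of the alpha band, keyed by
        ``(electrode_a, electrode_b, stage)``; stage ``"*"`` applies to all
        processing stages.
    envelope_hurst
        Hurst exponent of the alpha amplitude envelope, keyed by stage.
        Stages not listed use 0.5 (uncorrelated amplitude fluctuations).
    """

    alpha_power_gain: Mapping[tuple[str, str], float] = field(default_factory=dict)
    coherence_target: Mapping[tuple[str, str, str], float] = field(default_factory=dict)
    envelope_hurst: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, g in self.alpha_power_gain.items():
            if g <= 0:
                raise ValueError(f"alpha_power_gain{key} must be > 0, got {g}")
        for key, c in self.coherence_target.items():
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"coherence_target{key} must be in [0, 1], got {c}")
        for stage, h in self.envelope_hurst.items():
            if not 0.0 < h < 1.0:
                raise ValueError(f"envelope_hurst[{stage!r}] must be in (0, 1), got {h}")

    def gain(self, channel: str, stage: str) -> float:
        return float(self.alpha_power_gain.get((channel, stage), 1.0))

    def hurst(self, stage: str) -> float:
        return float(self.envelope_hurst.get(stage, 0.5))

    def msc_targets(self, stage: str) -> dict[frozenset, float]:
        out: dict[frozenset, float] = {}
        for (a, b, st), c in self.coherence_target.items():
            if st == "*" or st == stage:
                out[frozenset((a, b))] = float(c)
        return out


def default_effects_group_a() -> GroupEffectSpec:
    """Phenotype of the electric-car group: elevated frontal-central alpha
    power in every stage, elevated Cz-Pz and Cz-Fp2 alpha coherence, and
    persistent alpha-envelope fluctuations peaking in the second decision
    interval. An attention-driven S2 alpha increase at Cz/C4 is shared with
    group B. Magnitudes are synthetic choices (the effects are only known to
    be significant at n = 16 vs 29, not how large they are)."""
    gains: dict[tuple[str, str], float] = {}
    for ch in FRONTAL_CENTRAL:
        for stage in PROCESSING_STAGES:
            gains[(ch, stage)] = 1.8
    for ch in ("Cz", "C4"):  # shared attentional S2 boost, on top of the group gain
        gains[(ch, "S2")] = gains.get((ch, "S2"), 1.0) * 1.6
    return GroupEffectSpec(
        alpha_power_gain=gains,
        coherence_target={("Cz", "Pz", "*"): 0.5, ("Cz", "Fp2", "*"): 0.5},
        envelope_hurst={"S1": 0.6, "D1": 0.7, "S2": 0.6, "D2": 0.9},
    )


def default_effects_group_b() -> GroupEffectSpec:
    """Phenotype of the non-electric group: baseline alpha power apart from
    the shared attentional S2 boost, near-zero targeted coherence, and
    weakly persistent alpha envelopes in all stages."""
    return GroupEffectSpec(
        alpha_power_gain={("Cz", "S2"): 1.6, ("C4", "S2"): 1.6},
        coherence_target={("Cz", "Pz", "*"): 0.05, ("Cz", "Fp2", "*"): 0.05},
        envelope_hurst={"S1": 0.6, "D1": 0.6, "S2": 0.6, "D2": 0.6},
    )


@dataclass(frozen=True)
class CohortSpec:
    """A synthetic cohort: 16 electric-car selectors (A) vs 29 others (B)
    by default, with group A drawn younger (the real cohort showed a
    significant age difference between groups)."""

    n_group_a: int = 16
    n_group_b: int = 29
    protocol: ProtocolSpec = field(default_factory=ProtocolSpec)
    effects_a: GroupEffectSpec = field(default_factory=default_effects_group_a)
    effects_b: GroupEffectSpec = field(default_factory=default_effects_group_b)
    age_mean_sd_a: tuple[float, float] = (27.0, 4.0)
    age_mean_sd_b: tuple[float, float] = (34.0, 5.0)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group_a < 0 or self.n_group_b < 0:
            raise ValueError("group sizes must be >= 0")
        if self.n_group_a + self.n_group_b == 0:
            raise ValueError("cohort must contain at least one subject")

    @property
    def n_subjects(self) -> int:
        return self.n_group_a + self.n_group_b

    def with_seed(self, seed: int) -> "CohortSpec":
        return replace(self, master_seed=seed)
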