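"""Generate a small synthetic EEG cohort and write it to disk as EDF.

Each subject gets a 75 s, 21-channel session at 256 Hz following the
block design: 5 s baseline, S1 (5 x 4 s car images), D1 (5 s decision),
S2 (5 x 8 s images with specifications), D2 (5 s decision). Group A
subjects (electric-car selectors) carry elevated frontal-central alpha
power, elevated Cz-Pz / Cz-Fp2 alpha coherence, and persistent D2
alpha-envelope fluctuations.
"""

from neuromark import CohortSpec, generate_cohort
from neuromark.synth import write_cohort

spec = CohortSpec(n_group_a=3, n_group_b=4, master_seed=42)
recordings, self_report = generate_cohort(spec)
write_cohort(recordings, self_report, "cohort_out")

print(self_report.to_string(index=False))
rec = recordings[0]
print(f"\n{rec.subject_id}: {rec.n_channels} channels x {rec.duration_s:.0f} s "
      f"at {rec.fs:.0f} Hz, sample SD {rec.samples.std():.1f} uV")
print("Stage events:")
for ev in rec.events:
    if ev.trial is None:
        print(f"  {ev.stage:>8s}: {ev.onset_s:5.1f} s + {ev.duration_s:4.1f} s")
# The table lists one row per subject with group label, age, sex, and the
# questionnaire fields; EDF + events TSV files land in cohort_out/.
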