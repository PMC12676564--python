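"""Generate a small synthetic eyes-open EEG cohort and inspect it.

The generator plants group-specific rhythms (posterior alpha for controls,
generalized theta for the AD-like group, anterior theta for the FTD-like
group) on top of 1/f background noise, with one photic-stimulation interval
per recording.
"""

from dmdeeg import CohortSpec, generate_cohort

spec = CohortSpec(n_subjects_per_group=2, duration=40.0, seed=0)
cohort = generate_cohort(spec)

for rec, interval in cohort:
    print(f"{rec.subject_id}  group={rec.group:3s}  "
          f"{rec.n_channels} ch @ {rec.fs:.0f} Hz, {rec.duration:.0f} s, "
          f"stimulus [{interval.onset:.1f}, {interval.offset:.1f}] s, "
          f"RMS {rec.data.std():.2f} uV")

# Each line is one subject: channel count, sampling rate, the stimulus-on
# interval the epoching step will use, and the overall signal scale in
# microvolts.  Same seed -> bit-identical cohort.
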