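"""Generate a small synthetic cohort and look at its latent mood structure.

A latent per-subject mood trajectory (higher = more depressed) declines
during week 1, rebounds in week 2 for a fraction of subjects, and scores
higher in the morning.  It drives both the diary answers and the EEG
alpha-band amplitude.
"""

import numpy as np

from moodquant import CohortConfig, generate_cohort

config = CohortConfig(
    n_subjects=3, n_days=14, eeg_duration_s=10.0,
    coupling_strength=3.0, diary_noise_sd=2.0, seed=42,
)
cohort = generate_cohort(config)

print(f"subjects: {cohort.subject_ids}")
sid = cohort.subject_ids[0]
traj = cohort.truths[sid]
print(f"{sid}: {len(traj.values)} sessions "
      f"({len(cohort.recordings)} recordings in total)")
print("first 3 days of latent mood (morning, evening pairs):")
for day in range(3):
    m, e = traj.values[2 * day], traj.values[2 * day + 1]
    print(f"  day {day + 1}: morning {m:5.2f}   evening {e:5.2f}")
week1 = traj.values[:14].mean()
week2 = traj.values[14:].mean()
print(f"week-1 mean {week1:.2f} vs week-2 mean {week2:.2f} "
      "(declining = improving mood)")
entry = cohort.qlog_entries[sid][0]
print(f"first diary entry: {entry.period}, scores "
      f"{entry.scores.min()}..{entry.scores.max()} on the 1-100 scale")
rec = cohort.recordings[(sid, traj.session_times[0])]
print(f"first recording: {rec.samples.shape[0]} channels x "
      f"{rec.samples.shape[1]} samples at {rec.sample_rate_hz:.0f} Hz, "
      f"range [{rec.samples.min():.1f}, {rec.samples.max():.1f}] uV")
# Morning values exceed evening values because low mood is worse after waking.
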