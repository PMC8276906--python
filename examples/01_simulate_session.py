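"""Simulate one stress/breathing EEG session and inspect its structure.

Builds a participant profile, generates the full session (120 s baseline +
4 blocks of 90 s mental-arithmetic stressor and 200 s breathing), and
prints the schedule, per-condition band power, and the self-report series.
"""

import numpy as np
from scipy import signal

import stressbci as sb

profile = sb.session.sample_profile("L1", group="ASD", seed=42)
schedule = sb.make_schedule(rest_duration=30.0)
rec = sb.generate_recording(profile, schedule)
reports = sb.generate_self_reports(profile)

print(f"participant {profile.id}: STAI-C {profile.trait_anxiety}, "
      f"seed {profile.seed}")
print(f"session: {rec.duration:.0f} s, {rec.data.shape[0]} channels at "
      f"{rec.rate:.0f} Hz")
print("labeled seconds per condition:", schedule.labeled_seconds())

# Beta power rises under stress, alpha rises under guided breathing.
for band, (lo, hi) in sb.BANDS.items():
    row = []
    for cond in sb.CONDITIONS:
        pows = []
        for seg in rec.annotations:
            if seg.label != cond:
                continue
            i0, i1 = int(seg.onset * rec.rate), int(seg.end * rec.rate)
            f, p = signal.welch(rec.data[:, i0:i1], fs=rec.rate, nperseg=512)
            m = (f >= lo) & (f <= hi)
            pows.append(p[:, m].sum())
        row.append(f"{cond}={np.mean(pows):8.1f}")
    print(f"{band:6s} power (uV^2, summed over channels): " + "  ".join(row))

print("post-stressor self-reports (1=very relaxed .. 5=very stressed):",
      reports.post_stressor)
print("post-breathing self-reports:", reports.post_breathing)
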