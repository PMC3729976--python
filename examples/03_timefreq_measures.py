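"""Complex-demodulation time-frequency measures for a small group.

Computes, for matched standard and deviant trials, the three measures —
overall spectral power change, non-phase-locked ("induced") power
change, and inter-trial phase locking (ITPL), all relative to the
-300..0 ms baseline — and prints occipital-ROI group means.  Single-
subject induced-power estimates are noisy (chi-square sampling error of
residual power across 40 trials), so a group average is the readable
summary.
"""

import numpy as np

from oscmmn import OCCIPITAL_ROI, SimConfig, generate_epochs, generate_schedule
from oscmmn.preprocess import PreprocConfig, preprocess
from oscmmn.timefreq import (
    complex_demodulate,
    itpl,
    itpl_change,
    match_standard_trials,
    non_phase_locked_power_change,
    overall_power_change,
)

n_subjects = 8
acc = {("std", m): [] for m in ("overall", "induced", "itpl")}
acc.update({("dev", m): [] for m in ("overall", "induced", "itpl")})
for s in range(n_subjects):
    schedule = generate_schedule(40, (16, 1, 1), seed=s)
    epochs = generate_epochs(
        schedule, SimConfig.default(seed=300 + s),
        event_subset=schedule.deviant_and_preceding_standard_indices(),
        dtype=np.float32,
    )
    clean, _ = preprocess(epochs, PreprocConfig())
    deviants = clean.pick_condition("deviant")
    standards, _ = match_standard_trials(clean, schedule)
    for cond, ep in (("std", standards), ("dev", deviants)):
        tfr = complex_demodulate(ep)  # 4-50 Hz in 2 Hz steps, every 25 ms
        acc[(cond, "overall")].append(overall_power_change(tfr).values)
        acc[(cond, "induced")].append(non_phase_locked_power_change(tfr).values)
        acc[(cond, "itpl")].append(itpl_change(itpl(tfr)).values)

freqs = tfr.frequencies_hz
lats = tfr.latencies_ms
roi = [clean.channel_names.index(c) for c in OCCIPITAL_ROI]
theta, alpha = (freqs >= 4) & (freqs <= 8), (freqs >= 8) & (freqs <= 14)
early, late = (lats >= 50) & (lats <= 250), (lats >= 300) & (lats <= 600)

def roi_mean(cond, measure, fsel, lsel):
    maps = np.mean(acc[(cond, measure)], axis=0)
    return maps[np.ix_(roi, np.flatnonzero(fsel), np.flatnonzero(lsel))].mean()

print(f"group of {n_subjects} subjects, occipital ROI ({', '.join(OCCIPITAL_ROI)}):")
for cond, label in (("std", "standard"), ("dev", "deviant ")):
    print(f"  {label}:"
          f"  theta power 50-250 ms {roi_mean(cond, 'overall', theta, early):+.3f} uV^2"
          f" | theta ITPL 50-250 ms {roi_mean(cond, 'itpl', theta, early):+.3f}"
          f" | induced alpha 300-600 ms {roi_mean(cond, 'induced', alpha, late):+.3f} uV^2")
# Expected pattern: theta power rises equally in both conditions (the
# burst amplitude is condition-matched); deviants show clearly higher
# theta phase locking; deviants show a deeper induced alpha decrease.
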