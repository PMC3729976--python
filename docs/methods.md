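# Methods

This note documents the models, numerical choices, and known limits of
`oscmmn`.  It is the design record; empirical claims below are all
quantities the test suite or `scripts/acceptance.py` computes.

## The synthetic oddball study

The generator is a forward model of the *statistical structure* an
oscillatory mismatch analysis must resolve, not a biophysical
simulation.  Each epoch (−300..600 ms at 1000 Hz, 64 channels on an
idealized 10-10 layout) is a sum of four parts:

**1/f background noise.**  Gaussian noise spectrally shaped to
PSD ∝ 1/f^β (β = 1 by default), normalized to an exact RMS of 5 μV per
channel, independent across channels and epochs.  Real EEG noise is
spatially correlated and continuous across epochs; independence makes
trial-level sampling behavior exactly as assumed by the statistics and
is the main idealization to keep in mind when transferring conclusions
to real data.

**Evoked components.**  Deterministic Gaussian bumps (latency, FWHM,
amplitude, spatial topography): a P1 (+3 μV at 120 ms, FWHM 60 ms) and
N1 (−4 μV at 180 ms, FWHM 70 ms) identical in every condition, plus a
sustained deviant-only late negativity (−1.2 μV at 450 ms, FWHM
200 ms).  The late component exists because a purely oscillatory
difference wave produces below-alpha intervals of only about half a
theta cycle, which can never satisfy a calibrated consecutive-sample
criterion of ~100 samples; empirical mismatch responses likewise
contain sustained late segments distinct from the theta-driven early
phase.  Its spectrum is concentrated below ~3 Hz, so it leaves the
theta-band power contrast intact (verified by the dissociation recovery
test).

**Theta phase reset.**  One 6 Hz burst per epoch, amplitude 4 μV,
multiplied by a raised-cosine (Hann) envelope over 50–250 ms so it is
time-limited without spectral splatter.  The per-trial phase at the
window center is von Mises with mean 0; the concentration κ is the only
condition-dependent knob (κ = 0.4 standards, κ = 8 deviants; resultant
lengths ≈ 0.20 vs 0.94).  Amplitude is condition-identical by
construction, so single-trial theta-band power is matched across
conditions to within 2% — phase realignment without power change.  The
κ and amplitude defaults were fixed during generator design so that the
deviant−standard ITPL difference (≈ 0.17 at occipital channels with 40
matched trials) is of the clearly-significant magnitude such studies
report, rather than a marginal one: the phase-locked P1–N1 complex and
the in-band noise both dilute the measured phase-locking contrast, and
weaker settings under-represent the phenomenon.

**Alpha desynchronization.**  An ongoing 12 Hz process (3 μV, random
uniform phase per trial, present throughout the epoch) multiplied by
√(1 − d·w(t)), where w ramps up over 50 ms just before 300 ms, is 1
inside 300–600 ms, and d is the fractional *power* drop (0.35 standards,
0.6 deviants).  Random phase makes the process invisible to evoked
measures; the multiplicative envelope makes band power inside the
window exactly (1 − d) times baseline.

**Randomness.**  Every epoch draws from its own substream of the
configured seed (noise first, then alpha phase, then the von Mises
phase — last, because its rejection sampler's consumption depends
on κ).  Hence generation is bit-reproducible, an event's voltages do not
depend on which other events are rendered, and changing only κ changes
only the theta phases — which is what makes the power-matching property
exactly testable.

**Schedules.**  Counts are ratio-exact (640/40/40 for 40 deviants at
16:1:1).  Rare events (deviants and targets) are shuffled and dropped
into the standard stream with a guaranteed minimum of two standards
before each (exposed as `min_standards_before`, since the constraint
between rare events themselves is underdetermined); the remaining
standards are multinomially distributed over the gaps.  ISIs are uniform
on the integer-millisecond grid in 612–642 ms; onsets step by stimulus
duration (200 ms) plus ISI.  Targets are task events and generate no
analyzed epoch unless requested.

## Preprocessing

Amplitude rejection drops any trial with |x| strictly greater than
100 μV on any channel/sample (a sample at exactly the bound is kept);
rejection applies to raw amplitudes, before re-referencing.  The common
average reference subtracts the instantaneous cross-channel mean;
baseline correction subtracts the −300..0 ms mean per trial and
channel.  No ocular regression or channel interpolation is performed.
Note that common-average referencing shrinks a spatially broad effect:
the alpha process here loses roughly a third of its amplitude at the
occipital peak, which is why single-subject induced-power numbers look
small while the group statistics remain clearly significant.

## ERP analysis

Per subject, condition averages over the occipital ROI (O1, Oz, O2,
PO9, PO10, PO7, PO8); deviant − standard per subject; zero-phase
4th-order Butterworth low-pass at 40 Hz (forward–backward; the contract
is < 1% passband deviation below 30 Hz and > 90% attenuation above
60 Hz, not a specific kernel).  Sample-wise one-sample t-tests across
subjects; zero-variance samples are flagged degenerate (p = 0 when the
common value is nonzero, else 1).

The minimum run length L is calibrated by simulation: Gaussian AR(1)
subject waves at the lag-1 autocorrelation estimated from the observed
difference waves (the minimal model consistent with a lag-1 estimate;
variance is irrelevant because t is scale-free), n_sim ≥ 1000 null
experiments, and L is the smallest length for which the *family-wise*
probability of any run of ≥ L sub-alpha samples anywhere in the window
is ≤ α.  Calibration is family-wise rather than per-run because the
analyst scans the whole epoch.  With heavily low-passed 1 kHz waves the
estimated lag-1 autocorrelation is ≈ 0.996 and L comes out near
100–125 samples; L scales with the smoothness of the input and is not a
fixed constant of the method.

## Time-frequency analysis

Frequencies 4–50 Hz in 2 Hz steps; latencies every 25 ms across the
epoch; envelope FIR bandwidth 4 Hz by default (two-sided, equal to twice
the frequency step, so neighboring bins do not leak into each other);
kernel length chosen so the Hamming transition spans about three
bandwidths (275 taps at 1 kHz / 4 Hz).  Epochs are mirror-padded by the
kernel half-length; latencies whose filter support extends past real
data are flagged in `edge_mask`.  The qualitative condition contrasts
are verified to be stable at 2, 4 and 8 Hz bandwidths.

Implementation: analysis frequencies land on DFT bins of the padded
length, so demodulation is an exact spectral rotation; the zero-phase
kernel response is applied in the frequency domain and the output is
evaluated only at the 25 ms latency grid through a truncated-bin inverse
transform.  Bins beyond the passband-plus-transition (where the kernel
sits at its ~10⁻³ stopband floor) are dropped; the discrepancy against
the literal time-domain path is bounded by the filter's own stopband
leakage (measured ≈ 0.7% of peak on noise epochs) and a general
time-domain fallback handles frequency grids off the DFT bins.  Trial
data may be processed in single precision (the pipeline default, as is
common in EEG toolboxes); group-level maps and statistics are always
double.

Induced power subtracts the *complex* trial-average grid from each
trial before squaring; by linearity of demodulation this equals
demodulating (trial − time-domain average), which the tests assert.
ITPL uses unit-normalized phasors (amplitude-invariant by
construction); zero-magnitude cells carry no phase and are excluded
from that cell's mean and counted.  Statistics run on
baseline-subtracted ITPL maps; raw ITPL is also available.  Standard
trials are matched to deviants by selecting the standard immediately
preceding each deviant (equating trial counts and SNR); matching is
mandatory for ITPL and optional-but-default for power in the pipeline.

One model consequence worth flagging: with power-matched phase reset,
the deviants' theta is *more* phase-locked, so their non-phase-locked
residual in the theta/low-alpha range is necessarily smaller — the
induced-power contrast can therefore show an early negative cluster in
addition to the late alpha effect.  This is arithmetic, not an artifact.

## Cluster statistics

Channel adjacency: pairs closer than 1.3 × the median nearest-neighbor
distance of the layout, with isolated channels linked to their nearest
neighbor so every channel has at least one.  Frequency and latency
adjacency are consecutive bins.  Cluster-forming threshold: the
two-tailed t critical value at α = 0.01 (lowered from 0.05 to avoid
near-global clusters); positive and negative cells cluster separately.

The null records, per relabeling, the maximum positive and maximum
|negative| cluster sums.  Default decision ("two_tailed"): each cluster's
Monte-Carlo p against its own tail's distribution, significant at
final α/2 = 0.025 per tail.  A "literal" mode refers |summed t| to the
pooled max-|sum| distribution at 0.05.  Sampled p-values carry the +1
correction, (count + 1)/(n + 1), so they are never exactly zero; when
the number of distinct relabelings is ≤ n_permutations the test
enumerates exactly (paired: all 2ⁿ sign flips; independent: all group
assignments) and reports plain proportions.  Paired (within-subject)
relabeling is the default since standard/deviant is a within-subject
contrast; the independent-samples mode exists for genuinely separate
groups or literal replication of analyses that applied it to
within-subject data.

Band tests average map cells over theta (4–8), alpha (8–14), beta
(14–30) and gamma (30–50 Hz) — band-edge bins belong to both adjacent
bands, exactly as those ranges are conventionally printed — and then
run the channel × time permutation within each band.

## Problem sizes

The study-scale property checks run at 30 synthetic subjects × 40
matched trial pairs with 1000 permutations and 20 replicate experiments
(dissociation recovery), 500 replicate null experiments at 20 subjects
(family-wise error), and 10×-replicate oracle simulations for the
run-length calibration; the acceptance script uses one 30-subject
study.  These sizes give Monte-Carlo standard errors comfortably inside
the asserted tolerances while keeping a full run in minutes on one CPU.

## What passing tests do and do not show

The generator realizes exactly the assumptions the measures are built
on (independent trials, stationary 1/f noise, a single reset burst, a
single multiplicative ERD).  Tests passing on it demonstrate the
*pipeline's* correctness and statistical validity — calibration of
family-wise error, exact identities, recovery of effects of known
location and size.  They do not certify sensitivity on real recordings,
where noise is colored across space, oscillations are non-sinusoidal
and bursty, artifacts are structured, and effect topographies are
subject-specific.  Known limitations: no ocular-artifact model or
correction, no channel interpolation, no source-space statistics, no
wavelet/multitaper alternatives, no between-channel phase coherence.
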