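# Methods

This note documents the models, rules and numerical choices implemented in
`swrpipe`, and what its synthetic benchmark does and does not establish.

## Signal model and preprocessing

Recordings are multi-channel sampled signals with per-channel roles (LFP or
EMG). Down-sampling is polyphase rational-ratio resampling with a
Kaiser-windowed anti-alias filter (`scipy.signal.resample_poly`); 32 kHz →
1250 Hz is the ratio 5/128, and output length is ⌈n·5/128⌉. DC is preserved
and a 200 Hz sine survives within 1% amplitude (tested).

Both band-pass filters are Chebyshev Type II of order 4, applied
forward–backward (`sosfiltfilt`) so that filtering is zero-phase and event
timestamps are not biased. A Chebyshev II design is specified by its
stopband, not its passband, so the band alone does not pin down a filter.
We use 40 dB stopband attenuation with stopband edges at 50/400 Hz for the
100–250 Hz ripple band and 130/570 Hz for the 250–350 Hz EMG band — the
widest edges for which the declared passbands stay within ~0.5 dB of unity
at order 4. Narrower edges (e.g. 80/275 Hz) would attenuate the passband
boundaries themselves by tens of dB at this order and were rejected.

Band power uses 1-s Hann-tapered periodogram windows advancing in 0.5-s
steps (1 s is the shortest window resolving the 1 Hz delta edge); delta is
the PSD integral over 1–5 Hz, theta over 5–10 Hz, and EMG tone is the
per-window RMS of the 250–350 Hz filtered EMG. Windows never extend past
the end of the signal.

## Sleep-state scoring

States are assigned per window with the standard criteria, in strict
precedence order:

1. **AWAKE** if EMG tone is at or above the movement cutoff;
2. otherwise **REM** if theta/delta exceeds 2.0 *and* EMG is below the
   atonia cutoff;
3. otherwise **SWS** if delta power exceeds the high-delta cutoff;
4. otherwise AWAKE. Ties at any cutoff resolve to the non-sleep side, so
   sleep calls are conservative.

Cutoffs are per-recording quantiles, making the scorer self-calibrating to
amplitude scale: movement = 75th EMG percentile, atonia = 20th EMG
percentile, high delta = 25th percentile of delta power among immobile
windows. The movement and delta quantiles were chosen from the geometry of
the feature distributions: in home-cage mouse recordings SWS occupies the
majority of time, so the EMG distribution has a large low-tone mass with an
awake tail (the 75th percentile falls in the gap between the two for awake
fractions of roughly 15–40%), and among immobile windows most have elevated
delta (the 25th percentile falls below the SWS delta cluster). Quantiles
placed mid-cluster (e.g. a 50th-percentile delta cutoff) would split the SWS
windows roughly in half and are unusable with a strict threshold rule. All
cutoffs are config-overridable for recordings with different state budgets.

Window labels become bouts on the window grid; bouts shorter than 10 s are
absorbed into their longer neighbor (suppressing single-window flicker);
finally SWS bouts separated by **less than 3 s** are merged (strict
comparison; the gap is relabeled SWS, and any short intervening bout is
consumed). The merge is idempotent and the post-merge hypnogram never
contains an inter-SWS gap under 3 s (both property-tested).

## Ripple detection (NSS)

Detection operates on the 100–250 Hz filtered LFP, restricted to SWS. The
normalized squared signal is `z((x²) * MA(8 ms))`: square, smooth with an
8-ms moving average (edge-replicating), then standardize using the mean and
SD computed **over SWS samples only**, so SD units are state-consistent.
The 8-ms window spans roughly one period of a 125–250 Hz oscillation —
short enough to track the envelope, long enough to average out the 2f
component of the squared sine. Whole-recording normalization is available
by passing a different support. The statistic is invariant to positive
rescaling of the input; a constant signal raises a degenerate-signal error.

Episode rules, in order: (1) candidates are maximal runs with NSS > 2 SD
inside the support; (2) candidates separated by less than 30 ms are merged
(merging first prevents one physiological event split by a brief dip from
being dropped as two short fragments); (3) episodes longer than 100 ms or
shorter than 20 ms are discarded; (4) survivors must have a peak NSS > 5 SD.
All comparisons are strict: an episode of exactly 100 ms is kept, a gap of
exactly 30 ms is not merged. The 20-ms floor is our addition — a
supra-threshold blip shorter than ~3 ripple cycles is noise by period
count. Onset/offset are the 2 SD crossing times, normalized power is the
maximum NSS within the event, and the intra-ripple frequency is the
zero-crossing count of the filtered trace over twice the duration (NaN with
fewer than two crossings). The detector is equivalent to an exhaustive
brute-force scanner on randomized inputs and monotone in the peak
threshold (both tested).

## Rate dynamics

The occurrence rate is events per second of SWS. Two binning schemes:

* **Wall-clock bins** tile each home-cage epoch (default 40 min bins; the
  default session is 2 pre-encoding + 6 post-encoding + 2 post-test bins
  with 10-min encoding and 5-min test maze visits between blocks). Maze
  periods are excised: bins tile home-cage time only. A bin's SWS seconds
  are the overlap of SWS bouts with the bin; an event belongs to the bin
  containing its peak time (the detector's most robust timestamp).
* **Cumulative-SWS bins** concatenate the SWS bouts of an epoch into one
  sleep timeline and cut it into 15-min spans, controlling for how much
  each subject slept per bin. The wall-clock ↔ cumulative mapping is a
  bijection on SWS time (round-trip tested). A final partial span is kept
  only if it holds at least 300 s.

In both schemes a bin with under 300 s (5 min) of SWS is flagged
`excluded` — kept in the table, masked from statistics, never silently
dropped. Early post-maze bins are legitimately often excluded because
animals take tens of minutes to re-enter SWS after exploration.

## Group statistics

`rm_anova` implements the balanced cell-means sums-of-squares
decomposition: one-way repeated measures (bins) or two-way mixed (bins ×
group) with subjects nested in groups. It is written in-package rather than
delegated so that (a) agreement with the brute-force oracle holds to 1e-10
and (b) a table with zero effect variance returns F = 0, p = 1 rather than
NaN; it is cross-checked against pingouin in the test suite. Excluded bins
are dropped column-wise before fitting, with a warning — the same pairwise
deletion the unequal-n problem forces in practice; per-bin Bonferroni
t-tests are provided as the fallback path. Within-subject effects carry a
Greenhouse–Geisser-corrected p next to the uncorrected one (ε from the
covariance of the repeated measures); choosing between them is left to the
user. Assumption checks (Shapiro–Wilk, Levene, Mauchly via pingouin) are
advisory only. Bonferroni adjustment is p·m capped at 1. All tests are
two-sided at α = 0.05.

## Behavior

Recognition performance is `100 × novel / (novel + fam1 + fam2)` over arm
times only (central-platform time never enters); chance is 33%. Arm-entry
segmentation from video is out of scope — arm times arrive pre-tabulated.
Exploration metrics from a position track: distance is the summed Euclidean
step length, speed is distance over elapsed time, and immobility is the
fraction of steps slower than 2 cm/s (the tracking vendor's cutoff is
proprietary; ours is declared and overridable).

## Synthetic data: what it emulates, and what it does not

The generator is the benchmark's ground truth, so its defaults are the
study conditions, not tuning knobs:

* **Hypnogram** — awake is the background state; SWS bouts arrive as a
  renewal process and REM is only permitted immediately after SWS
  (physiological ordering). Bout durations are shifted-exponential
  (maximum-entropy choice given only reported means) with a 10-s floor;
  defaults are the vehicle-group statistics (SWS 8.01 bouts/h, 4.68 min;
  REM 3.75 bouts/h, 1.23 min), and the awake mean duration is derived so
  the requested bout rates are matched in expectation. Empirical rates
  converge to the requested ones within 5% over 100 h (tested).
* **LFP** — unit-variance 1/f background (flattened below 0.5 Hz), plus a
  delta-band oscillator gated on during SWS and a theta oscillator during
  REM (amplitude 2, with 0.25-s on/off ramps), giving the scorer the same
  cues an experimenter uses. Default fs is 1250 Hz, the analysis rate; a
  32 kHz mode exists to exercise the down-sampler.
* **Ripples** — Hann-windowed sinusoids at 120–200 Hz, 40–90 ms, placed by
  a Poisson process during SWS only at 0.7 events/s (mid-range of the
  typical 0.4–1 Hz recurrence), with epoch multipliers for learning-induced
  surges. A 150-ms minimum peak separation emulates the refractoriness of
  real SWRs; without it ~9% of Poisson pairs would fall close enough that
  the merge-then-exclude rules discard both, making ground truth
  self-contradictory. Burst amplitude is expressed as envelope peak over
  the ripple-band background SD (default 10). The default was set from the
  detection geometry: the NSS of a Hann burst exceeds 2 SD only over a
  central fraction of the burst, and below snr ≈ 6 a 40-ms burst clears
  2 SD for under 20 ms — i.e. it would not count as a ripple under the
  detection convention this package implements. At snr 10, injected events
  peak near 10 SD, which is where clear SWR detections sit.
* **EMG** — white noise with per-state SD 3.0 (awake), 1.0 (SWS), 0.4
  (REM): tone, tonic, atonic.
* **Behavior** — arm times are Dirichlet-distributed with mean
  (p, (1−p)/2, (1−p)/2) and concentration 50, summing exactly to the total;
  `concentration=None` gives the noiseless expectation.
* **Cohorts** — two independent groups share a session design; the control
  profile carries 1.5× post-encoding/post-test multipliers, the treated
  profile is flat. For group-level rate statistics the generator skips
  signal rendering (`signals=False`): hypnogram plus event stream is
  sufficient and replicates become cheap.

What passing tests on this benchmark show: the implementation applies the
stated rules exactly, recovers known ground truth, and has the claimed
power/error behavior under the simulated noise model. What they do not
show: performance on real recordings — the simulator has stationary
backgrounds, no movement or electrical artifacts, no spindles or dentate
spikes masquerading as ripples, sharply separable state features, and
burst-shaped ripples without the sharp-wave deflection. Real data will
degrade state-scoring agreement and detection precision relative to these
figures.

## Problem sizes used in validation

Scoring agreement is assessed on a 2-h recording, detector recovery on
20 min at 1250 Hz, bout-statistic convergence on a 100-h hypnogram, and
the group-level emulation on 100 replicates of two n = 7 cohorts with a
shortened session (ten 20-min home-cage bins) — sizes at which the checked
quantities have comfortably converged while the whole suite stays quick on
a laptop.
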