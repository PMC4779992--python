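# swrpipe

Detection and rate-dynamics analysis of hippocampal **sharp wave-ripples
(SWRs)** — transient 100–250 Hz oscillations of the CA1 local field potential
that occur mainly during slow-wave sleep (SWS) and are a core substrate of
memory consolidation. The package is aimed at electrophysiologists who record
LFP + neck EMG around a learning task and want a reproducible, scriptable
version of the classic home-cage analysis chain:

1. **Preprocess** — polyphase down-sampling (e.g. 32 kHz → 1250 Hz), zero-phase
   Chebyshev II band-pass filters (ripple band 100–250 Hz, EMG 250–350 Hz),
   and sliding delta (1–5 Hz) / theta (5–10 Hz) band power with EMG tone.
2. **Score sleep states** — an automated awake/SWS/REM classifier using the
   standard criteria (movement EMG → awake; immobile + high delta → SWS;
   atonia + high theta/delta → REM), with SWS bouts separated by < 3 s merged.
3. **Detect ripples** with the normalized squared signal (NSS): the
   ripple-band LFP is squared, smoothed, and standardized to SD units over
   the SWS samples. Candidate events are runs with NSS > 2 SD; events closer
   than 30 ms are merged, episodes longer than 100 ms are discarded, and the
   peak must exceed 5 SD. Per event: onset/offset, peak time, normalized
   power (max NSS), intra-ripple frequency (zero crossings / 2·duration).
4. **Bin occurrence rates** around behavioral epochs, as events per second
   of SWS (SWS-Rs/sec), in wall-clock bins or in bins of cumulated SWS time;
   bins holding under 5 min of SWS are flagged excluded.
5. **Group statistics** — repeated-measures / mixed ANOVA from the balanced
   sums-of-squares decomposition, Bonferroni-corrected post-hoc t-tests, and
   Shapiro–Wilk / Levene / Mauchly assumption checks.
6. **Behavior** — Y-maze recognition performance,
   `100 × time_novel / (time in all three arms)` with 33% chance level, plus
   exploration metrics (distance, speed, % immobility).

A first-class synthetic-data module generates ground-truthed recordings
(semi-Markov hypnograms, 1/f LFP with state-gated oscillators and injected
ripple bursts, state-dependent EMG, behavioral sessions, and two-group
cohorts with a learning-induced rate surge), so every stage can be validated
against known answers.

## Worked example

```python
import numpy as np
from swrpipe import *
from swrpipe.synthetic import HypnogramParams, RippleProfile

# 20 minutes of simulated sleep with ripples injected at 0.7 events/s of SWS
hyp = generate_hypnogram(HypnogramParams(total_dur=1200.0, seed=11))
rec, truth = generate_recording(hyp, RippleProfile(base_rate=0.7), seed=11)

filt = filter_ripple_band(rec.channel("LFP"), rec.fs)
events = detect_and_characterize(filt, rec.fs, truth.hypnogram)
print(f"injected {len(truth.events)}, detected {len(events)}")

stats = baseline_characterization(events, truth.hypnogram)
print(f"rate {stats['rate_per_s_sws']:.3f} SWS-Rs/sec, "
      f"freq {stats['mean_freq_hz']:.0f} Hz, "
      f"duration {stats['mean_duration_ms']:.0f} ms, "
      f"power {stats['mean_norm_power']:.1f} SD")
```

Output:

```
injected 470, detected 466
rate 0.626 SWS-Rs/sec, freq 154 Hz, duration 33 ms, power 10.1 SD
```

The detected rate sits in the 0.4–1 Hz range typical of SWR recurrence; 463
of the 470 injected bursts are matched by a detection within ±10 ms, at a
mean normalized power of ~10 SD — comfortably above the 5 SD peak criterion.
(The reported duration is the supra-2-SD span of the NSS, which is shorter
than the underlying burst.) The same stages are available from the shell:

```bash
swrpipe --seed 11 simulate --duration 1200 --out sim.dat
swrpipe score-states sim.dat --out hyp.csv
swrpipe detect sim.dat --hypnogram hyp.csv --out events.csv
swrpipe dynamics events.csv --hypnogram hyp.csv --scheme sws --out bins.csv
```

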