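"""Ground-truthed synthetic recordings: hypnograms, LFP/EMG, ripples, behavior.

The generator emulates home-cage mouse recordings around a Y-maze recognition
session: a semi-Markov awake/SWS/REM hypnogram with configurable bout
statistics, a local field potential made of 1/f background plus state-gated
delta (SWS) and theta (REM) oscillations with ripple bursts injected during
SWS only, and an EMG whose tone is high awake, low in SWS and minimal in REM.
Every injected event is returned as ground truth, so detectors and state
scorers can be benchmarked with known answers.

Default bout statistics follow the vehicle-group values reported for this
preparation (SWS 8.01 bouts/h, 4.68 min mean; REM 3.75 bouts/h, 1.23 min);
the default ripple rate of 0.7 events per second of SWS sits mid-range of the
0.4-1 Hz recurrence typical of hippocampal sharp wave-ripples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    AWAKE,
    REM,
    SWS,
    Bout,
    Hypnogram,
    ParameterError,
    SessionDesign,
    SignalRecording,
    intersect_intervals,
)
from .preprocess import filter_ripple_band

MIN_BOUT_S = 10.0  # floor under every simulated bout duration


@dataclass
class HypnogramParams:
    """Bout statistics of the simulated sleep architecture.

    Rates are bouts per hour of recording; mean durations in minutes.
    """

    sws_rate: float = 8.01
    sws_mean_dur: float = 4.68
    rem_rate: float = 3.75
    rem_mean_dur: float = 1.23
    total_dur: float = 3600.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("sws_rate", "sws_mean_dur", "rem_rate", "rem_mean_dur"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.total_dur < 0:
            raise ParameterError("total_dur must be non-negative")
        occupied = (
            self.sws_rate * self.sws_mean_dur + self.rem_rate * self.rem_mean_dur
        ) / 60.0
        if occupied > 1.0:
            raise ParameterError(
                f"requested SWS+REM occupancy {occupied:.2f} exceeds the recording"
            )
        if self.rem_rate > self.sws_rate:
            raise ParameterError("rem_rate cannot exceed sws_rate (REM follows SWS)")


@dataclass
class RippleProfile:
    """Rate, shape and amplitude of injected ripple bursts.

    ``amplitude_snr`` is the burst envelope peak over the background SD in the
    100-250 Hz band; ``epoch_multipliers`` scale the base rate inside labeled
    behavioral epochs (e.g. a post-encoding surge).
    """

    base_rate: float = 0.7
    epoch_multipliers: dict[str, float] = field(default_factory=dict)
    dur_range: tuple[float, float] = (40.0, 90.0)  # ms
    freq_range: tuple[float, float] = (120.0, 200.0)  # Hz
    amplitude_snr: float = 10.0
    min_separation: float = 0.150  # s, refractory gap between burst peaks

    def validate(self) -> None:
        if self.base_rate < 0:
            raise ParameterError("base_rate must be non-negative")
        lo, hi = self.dur_range
        if not (0 < lo <= hi <= 100):
            raise ParameterError("dur_range must lie within (0, 100] ms")
        flo, fhi = self.freq_range
        if not (100 < flo <= fhi < 250):
            raise ParameterError("freq_range must lie within (100, 250) Hz")
        if self.amplitude_snr <= 0:
            raise ParameterError("amplitude_snr must be positive")


@dataclass
class NoiseParams:
    """Amplitudes of the background processes (arbitrary units)."""

    pink_sd: float = 1.0
    delta_amp: float = 2.0  # SWS-gated 1-5 Hz oscillation amplitude
    theta_amp: float = 2.0  # REM-gated 5-10 Hz oscillation amplitude
    emg_sd: dict[str, float] = field(
        default_factory=lambda: {AWAKE: 3.0, SWS: 1.0, REM: 0.4}
    )


@dataclass
class GroundTruth:
    """What the generator actually injected."""

    hypnogram: Hypnogram
    events: list[tuple[float, float, float]]  # (peak time s, duration ms, freq Hz)
    behavioral_times: dict[str, float] | None = None


def generate_hypnogram(params: HypnogramParams) -> Hypnogram:
    """Simulate an awake/SWS/REM bout sequence covering [0, total_dur).

    Awake is the background state; SWS bouts arrive as a renewal process and
    REM may only follow SWS (with probability rem_rate/sws_rate so the REM
    bout rate comes out right). Bout durations are shifted-exponential with
    the stated means and a 10 s floor, so empirical rates converge to the
    requested ones. Deterministic for a fixed seed.
    """
    params.validate()
    if params.total_dur == 0:
        return Hypnogram([])
    rng = np.random.default_rng(params.seed)
    sws_mean_s = params.sws_mean_dur * 60.0
    rem_mean_s = params.rem_mean_dur * 60.0
    p_rem = params.rem_rate / params.sws_rate
    cycle_s = 3600.0 / params.sws_rate
    awake_mean_s = cycle_s - sws_mean_s - p_rem * rem_mean_s
    if awake_mean_s <= MIN_BOUT_S:
        raise ParameterError(
            "requested rates leave no room for awake periods between sleep bouts"
        )

    def draw(mean: float) -> float:
        return MIN_BOUT_S + rng.exponential(mean - MIN_BOUT_S)

    bouts: list[Bout] = []
    t = 0.0
    while t < params.total_dur:
        for state, mean in [(AWAKE, awake_mean_s), (SWS, sws_mean_s)]:
            dur = draw(mean)
            end = min(t + dur, params.total_dur)
            if end > t:
                bouts.append(Bout(state, t, end))
            t = end
            if t >= params.total_dur:
                break
        else:
            if rng.random() < p_rem:
                dur = draw(rem_mean_s)
                end = min(t + dur, params.total_dur)
                if end > t:
                    bouts.append(Bout(REM, t, end))
                t = end
    return Hypnogram(bouts)


def _pink_noise(n: int, rng: np.random.Generator, f_min: float, fs: float) -> np.ndarray:
    """Unit-variance 1/f noise, flattened below f_min to keep variance finite."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = 1.0 / np.sqrt(np.maximum(freqs, f_min))
    amp[0] = 0.0
    phases = rng.uniform(0, 2 * np.pi, len(freqs))
    spec = amp * np.exp(1j * phases)
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def place_events(
    hyp: Hypnogram,
    prof: RippleProfile,
    rng: np.random.Generator,
    design: SessionDesign | None = None,
) -> list[tuple[float, float, float]]:
    """Poisson placement of ripple events inside SWS bouts.

    The local rate is ``base_rate`` times the epoch multiplier at that time
    (1.0 outside labeled epochs). Bursts are kept wholly inside their SWS bout
    and thinned to a minimum peak-to-peak separation. Returns sorted
    (peak_time, duration_ms, freq_hz) tuples.
    """
    prof.validate()
    events: list[tuple[float, float, float]] = []
    for lo, hi in hyp.intervals(SWS):
        # split the bout at epoch boundaries so the rate is piecewise constant
        cuts = [lo, hi]
        if design is not None:
            for _, s, e in design.epochs:
                for c in (s, e):
                    if lo < c < hi:
                        cuts.append(c)
        cuts = sorted(set(cuts))
        for a, b in zip(cuts[:-1], cuts[1:]):
            mult = 1.0
            if design is not None:
                label = design.epoch_at((a + b) / 2.0)
                if label is not None:
                    mult = prof.epoch_multipliers.get(label, 1.0)
            lam = prof.base_rate * mult * (b - a)
            n = rng.poisson(lam)
            peaks = np.sort(rng.uniform(a, b, n))
            for pk in peaks:
                dur_ms = rng.uniform(*prof.dur_range)
                if pk - dur_ms / 2000.0 < lo or pk + dur_ms / 2000.0 > hi:
                    continue  # burst would spill outside its SWS bout
                if events and pk - events[-1][0] < prof.min_separation:
                    continue  # refractory thinning
                freq = rng.uniform(*prof.freq_range)
                events.append((float(pk), float(dur_ms), float(freq)))
    return events


def generate_recording(
    hyp: Hypnogram,
    prof: RippleProfile | None = None,
    noise: NoiseParams | None = None,
    fs: float = 1250.0,
    seed: int = 0,
    design: SessionDesign | None = None,
) -> tuple[SignalRecording, GroundTruth]:
    """Render LFP + EMG channels for a hypnogram, injecting ripple bursts.

    LFP = 1/f background + state-gated delta/theta oscillators + Hann-windowed
    sine bursts during SWS; EMG = white noise whose SD follows the state.
    """
    if fs < 625.0:
        raise ParameterError("fs must be at least 625 Hz (twice the ripple band top)")
    prof = prof or RippleProfile()
    noise = noise or NoiseParams()
    prof.validate()
    rng = np.random.default_rng(seed)
    total = hyp.span
    n = int(round(total * fs))
    if n == 0:
        rec = SignalRecording(np.zeros((2, 0)), fs, ["LFP", "EMG"])
        return rec, GroundTruth(hypnogram=hyp, events=[])

    lfp = noise.pink_sd * _pink_noise(n, rng, f_min=0.5, fs=fs)
    t = np.arange(n) / fs

    # state-gated oscillators, ramped over 0.25 s to avoid spectral clicks
    ramp_n = int(0.25 * fs)

    def _gated(intervals: np.ndarray, f_lo: float, f_hi: float, amp: float) -> np.ndarray:
        out = np.zeros(n)
        for lo, hi in intervals:
            i0, i1 = int(round(lo * fs)), min(int(round(hi * fs)), n)
            if i1 <= i0:
                continue
            f = rng.uniform(f_lo, f_hi)
            phase = rng.uniform(0, 2 * np.pi)
            seg = amp * np.sin(2 * np.pi * f * t[i0:i1] + phase)
            m = i1 - i0
            env = np.ones(m)
            r = min(ramp_n, m // 2)
            if r > 0:
                env[:r] = np.linspace(0, 1, r)
                env[m - r :] = np.linspace(1, 0, r)
            out[i0:i1] = seg * env
        return out

    lfp = lfp + _gated(hyp.intervals(SWS), 1.5, 4.0, noise.delta_amp)
    lfp = lfp + _gated(hyp.intervals(REM), 6.0, 9.0, noise.theta_amp)

    # measure the background ripple-band SD before injecting bursts
    ripple_bg_sd = float(np.std(filter_ripple_band(lfp, fs)))

    events = place_events(hyp, prof, rng, design=design)
    amp = prof.amplitude_snr * ripple_bg_sd
    for pk, dur_ms, freq in events:
        half = dur_ms / 2000.0
        i0 = int(round((pk - half) * fs))
        i1 = int(round((pk + half) * fs))
        i0, i1 = max(i0, 0), min(i1, n)
        m = i1 - i0
        if m <= 1:
            continue
        env = np.hanning(m)
        lfp[i0:i1] += amp * env * np.sin(2 * np.pi * freq * (t[i0:i1] - pk))

    emg = rng.standard_normal(n)
    level = np.full(n, noise.emg_sd[AWAKE])
    for state in (AWAKE, SWS, REM):
        for lo, hi in hyp.intervals(state):
            i0, i1 = int(round(lo * fs)), min(int(round(hi * fs)), n)
            level[i0:i1] = noise.emg_sd[state]
    emg *= level

    rec = SignalRecording(np.vstack([lfp, emg]), fs, ["LFP", "EMG"])
    return rec, GroundTruth(hypnogram=hyp, events=events)


@dataclass
class ArmTimes:
    """Seconds spent in each Y-maze arm during one phase."""

    time_novel: float
    time_fam1: float
    time_fam2: float
    phase: str = "test"

    @property
    def total(self) -> float:
        return self.time_novel + self.time_fam1 + self.time_fam2


def generate_behavioral_session(
    novel_preference: float,
    total_arm_time: float,
    seed: int = 0,
    concentration: float | None = 50.0,
) -> ArmTimes:
    """Draw per-arm exploration times with a given expected novel-arm share.

    Times are Dirichlet-distributed with mean (p, (1-p)/2, (1-p)/2) and sum
    exactly to ``total_arm_time``; ``concentration=None`` gives the noiseless
    expectation.
    """
    if not 0.0 <= novel_preference <= 1.0:
        raise ParameterError("novel_preference must lie in [0, 1]")
    if total_arm_time <= 0:
        raise ParameterError("total_arm_time must be positive")
    p = novel_preference
    mean = np.array([p, (1 - p) / 2.0, (1 - p) / 2.0])
    if concentration is None:
        shares = mean
    else:
        rng = np.random.default_rng(seed)
        alpha = np.maximum(mean * concentration, 1e-9)
        shares = rng.dirichlet(alpha)
    times = shares * total_arm_time
    # re-normalize the last entry so the three times sum exactly
    times[2] = total_arm_time - times[0] - times[1]
    return ArmTimes(
        time_novel=float(times[0]),
        time_fam1=float(times[1]),
        time_fam2=float(times[2]),
    )


@dataclass
class Subject:
    recording: SignalRecording | None
    truth: GroundTruth


def generate_cohort(
    n_subjects: int,
    design: SessionDesign,
    control_profile: RippleProfile,
    treated_profile: RippleProfile,
    seed: int = 0,
    hyp_params: HypnogramParams | None = None,
    signals: bool = False,
    fs: float = 1250.0,
) -> dict[str, list[Subject]]:
    """Two independent groups of simulated subjects sharing one session design.

    The control profile typically carries epoch multipliers > 1 for the
    post-encoding / post-test epochs (a learning-induced ripple surge); the
    treated profile is flat. With ``signals=False`` only hypnograms and
    ground-truth event streams are produced (``recording`` is None), which is
    what group-level rate statistics need.
    """
    if n_subjects < 2:
        raise ParameterError("need at least 2 subjects per group")
    base = hyp_params or HypnogramParams()
    root = np.random.default_rng(seed)
    out: dict[str, list[Subject]] = {"control": [], "treated": []}
    for group, prof in (("control", control_profile), ("treated", treated_profile)):
        prof.validate()
        for _ in range(n_subjects):
            sub_seed = int(root.integers(0, 2**31 - 1))
            hp = HypnogramParams(
                sws_rate=base.sws_rate,
                sws_mean_dur=base.sws_mean_dur,
                rem_rate=base.rem_rate,
                rem_mean_dur=base.rem_mean_dur,
                total_dur=design.total_end,
                seed=sub_seed,
            )
            hyp = generate_hypnogram(hp)
            if signals:
                rec, truth = generate_recording(
                    hyp, prof, fs=fs, seed=sub_seed + 1, design=design
                )
            else:
                rng = np.random.default_rng(sub_seed + 1)
                rec = None
                truth = GroundTruth(
                    hypnogram=hyp, events=place_events(hyp, prof, rng, design=design)
                )
            out[group].append(Subject(recording=rec, truth=truth))
    return out
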