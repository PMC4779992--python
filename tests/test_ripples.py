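import numpy as np
import pytest

from swrpipe.core import Bout, DegenerateSignalError, Hypnogram, ParameterError, RippleEvent
from swrpipe.ripples import (
    DetectorParams,
    NSSeries,
    baseline_characterization,
    compute_nss,
    detect_ripples,
    ripple_features,
)

FS = 1000.0  # convenient grid: 1 sample = 1 ms


def nss_from(values, fs=FS):
    return NSSeries(values=np.asarray(values, float), fs=fs)


def put_run(values, start_ms, dur_ms, level, peak=None):
    """Raise values above threshold on [start, start+dur) ms; optional peak spike."""
    values[start_ms : start_ms + dur_ms] = level
    if peak is not None:
        values[start_ms + dur_ms // 2] = peak
    return values


def brute_force_detect(values, mask, fs, p: DetectorParams):
    """Independent scanner implementing the candidate/merge/duration/peak rules."""
    above = [(v > p.low_sd) and m for v, m in zip(values, mask)]
    runs = []
    i = 0
    n = len(values)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            runs.append([i, j])
            i = j
        else:
            i += 1
    # merge gaps strictly shorter than merge_gap
    merged = []
    for r in runs:
        if merged and (r[0] - merged[-1][1]) / fs * 1000.0 < p.merge_gap:
            merged[-1][1] = r[1]
        else:
            merged.append(list(r))
    out = []
    for s, e in merged:
        dur_ms = (e - s) / fs * 1000.0
        if dur_ms > p.max_dur or dur_ms < p.min_dur:
            continue
        peak = max(values[s:e])
        if not peak > p.high_sd:
            continue
        ipk = s + int(np.argmax(values[s:e]))
        out.append((s, e, ipk, peak))
    return out


class TestComputeNss:
    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(5000)
        support = np.array([[0.0, 5.0]])
        a = compute_nss(x, FS, support)
        b = compute_nss(3.5 * x, FS, support)
        assert np.allclose(a.values, b.values, atol=1e-9)

    def test_constant_signal_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            compute_nss(np.ones(2000), FS, np.array([[0.0, 2.0]]))

    def test_empty_support_rejected(self):
        with pytest.raises(ParameterError):
            compute_nss(np.random.default_rng(0).standard_normal(100), FS, np.empty((0, 2)))

    def test_hand_oracle_20_samples(self):
        """Exact square -> moving-average -> standardize on a tiny input."""
        x = np.arange(20, dtype=float) - 10.0
        fs = 1000.0
        smooth_win = 3.0  # ms -> 3 samples
        nss = compute_nss(x, fs, np.array([[0.0, 0.020]]), smooth_win=smooth_win)
        # independent oracle, straight from the definition
        sq = x**2
        sm = np.empty(20)
        for i in range(20):  # centered 3-point moving average, edges replicated
            window = [sq[min(max(j, 0), 19)] for j in range(i - 1, i + 2)]
            sm[i] = np.mean(window)
        mu, sd = sm.mean(), sm.std()
        assert np.allclose(nss.values, (sm - mu) / sd, atol=1e-12)

    def test_mask_limits_detection_support(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(4000)
        nss = compute_nss(x, FS, np.array([[1.0, 3.0]]))
        assert not nss.mask[:999].any()
        assert nss.mask[1000:2999].all()


class TestDetectRules:
    def test_no_crossing_no_events(self):
        assert detect_ripples(nss_from(np.zeros(2000))) == []

    def test_single_event_onset_offset(self):
        """A 50-ms supra-2 run from 1.000 to 1.050 s with a 7 SD peak."""
        v = put_run(np.zeros(3000), 1000, 50, 3.0, peak=7.0)
        events = detect_ripples(nss_from(v))
        assert len(events) == 1
        e = events[0]
        assert e.onset == pytest.approx(1.000)
        assert e.offset == pytest.approx(1.050)
        assert e.norm_power == pytest.approx(7.0)
        assert e.duration_ms == pytest.approx(50.0)

    def test_short_gap_merges(self):
        """Two 30-ms runs separated by 20 ms merge into one 80-ms event."""
        v = np.zeros(3000)
        put_run(v, 1000, 30, 3.0, peak=6.0)
        put_run(v, 1050, 30, 3.0)
        events = detect_ripples(nss_from(v))
        assert len(events) == 1
        assert events[0].duration_ms == pytest.approx(80.0)

    def test_gap_of_exactly_merge_gap_not_merged(self):
        """A 30-ms gap is NOT merged (strict 'less than 30 ms')."""
        v = np.zeros(3000)
        put_run(v, 1000, 40, 3.0, peak=6.0)
        put_run(v, 1070, 40, 3.0, peak=6.0)
        events = detect_ripples(nss_from(v))
        assert len(events) == 2

    def test_long_episode_excluded(self):
        """A 120-ms run is dropped even with a 9 SD peak."""
        v = put_run(np.zeros(3000), 1000, 120, 3.0, peak=9.0)
        assert detect_ripples(nss_from(v)) == []

    def test_duration_of_exactly_max_kept(self):
        """Exactly 100 ms is kept (exclusion is strict 'longer than')."""
        v = put_run(np.zeros(3000), 1000, 100, 3.0, peak=6.0)
        events = detect_ripples(nss_from(v))
        assert len(events) == 1
        assert events[0].duration_ms == pytest.approx(100.0)

    def test_weak_peak_rejected(self):
        """A 50-ms run peaking at 4 SD fails the 5 SD peak test."""
        v = put_run(np.zeros(3000), 1000, 50, 3.0, peak=4.0)
        assert detect_ripples(nss_from(v)) == []

    def test_sub_minimum_duration_rejected(self):
        v = put_run(np.zeros(3000), 1000, 10, 3.0, peak=8.0)
        assert detect_ripples(nss_from(v)) == []

    def test_peak_time_is_argmax(self):
        v = np.zeros(3000)
        put_run(v, 1000, 60, 3.0)
        v[1042] = 9.0
        events = detect_ripples(nss_from(v))
        assert events[0].peak_time == pytest.approx(1.042)

    def test_invalid_params(self):
        with pytest.raises(ParameterError):
            detect_ripples(nss_from(np.zeros(10)), DetectorParams(low_sd=6.0))


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_arrays(self):
        """Vectorized detector == exhaustive scanner on 300 random series."""
        rng = np.random.default_rng(42)
        p = DetectorParams()
        for _ in range(300):
            n = int(rng.integers(50, 2000))
            v = rng.gamma(1.0, 1.5, n) - 1.0
            # sprinkle bursts so events actually occur
            for _ in range(int(rng.integers(0, 4))):
                s = int(rng.integers(0, max(1, n - 60)))
                put_run(v, s, int(rng.integers(10, 60)), 3.0, peak=rng.uniform(4, 9))
            mask = np.ones(n, dtype=bool)
            if rng.random() < 0.3:
                mask[: int(rng.integers(0, n // 2))] = False
            nss = NSSeries(values=v, fs=FS, mask=mask)
            got = detect_ripples(nss, p)
            expect = brute_force_detect(v, mask, FS, p)
            assert len(got) == len(expect)
            for e, (s, t, ipk, peak) in zip(got, expect):
                assert e.onset == pytest.approx(s / FS)
                assert e.offset == pytest.approx(t / FS)
                assert e.peak_time == pytest.approx(ipk / FS)
                assert e.norm_power == pytest.approx(peak)

    def test_threshold_monotonicity(self):
        """Raising high_sd never adds events."""
        rng = np.random.default_rng(7)
        v = rng.gamma(1.0, 1.5, 5000) - 1.0
        for _ in range(6):
            s = int(rng.integers(0, 4900))
            put_run(v, s, 50, 3.0, peak=rng.uniform(4, 12))
        nss = nss_from(v)
        prev = None
        for high in (4.0, 5.0, 6.0, 8.0, 11.0):
            events = detect_ripples(nss, DetectorParams(high_sd=high))
            onsets = {e.onset for e in events}
            if prev is not None:
                assert onsets <= prev
            prev = onsets


class TestRippleFeatures:
    def test_pure_burst_frequency(self):
        """A 150 Hz burst of 40 ms reads back as 150 +- 5 Hz."""
        fs = 1250.0
        t = np.arange(int(0.2 * fs)) / fs
        x = np.sin(2 * np.pi * 150.0 * (t - 0.1))
        e = RippleEvent(onset=0.080, offset=0.120, peak_time=0.1, norm_power=7.0,
                        duration_ms=40.0)
        e = ripple_features(e, x, fs)
        assert e.freq_hz == pytest.approx(150.0, abs=5.0)

    def test_too_few_crossings_flagged(self):
        fs = 1250.0
        x = np.ones(int(0.2 * fs))  # no zero crossings
        e = RippleEvent(onset=0.080, offset=0.120, peak_time=0.1, norm_power=7.0,
                        duration_ms=40.0)
        assert np.isnan(ripple_features(e, x, fs).freq_hz)

    def test_frequency_recovery_on_generator(self, short_recording):
        """Median |estimated - injected| frequency error < 10 Hz."""
        from swrpipe.preprocess import filter_ripple_band
        from swrpipe.ripples import detect_and_characterize

        rec, truth = short_recording
        filt = filter_ripple_band(rec.channel("LFP"), rec.fs)
        events = detect_and_characterize(filt, rec.fs, truth.hypnogram)
        peaks = np.array([e[0] for e in truth.events])
        errs = []
        for e in events:
            d = np.abs(peaks - e.peak_time)
            i = int(np.argmin(d))
            if d[i] <= 0.010:
                errs.append(abs(e.freq_hz - truth.events[i][2]))
        assert np.median(errs) < 10.0


class TestBaselineCharacterization:
    def _hyp(self, sws_seconds):
        return Hypnogram([Bout("SWS", 0.0, sws_seconds)])

    def test_rate_definition(self):
        """12 events over 30 s of SWS -> 0.4 events per second of SWS."""
        events = [
            RippleEvent(i, i + 0.05, i + 0.02, 6.0, 50.0, 150.0) for i in range(12)
        ]
        out = baseline_characterization(events, self._hyp(30.0))
        assert out["rate_per_s_sws"] == pytest.approx(0.4)

    def test_no_events_flagged(self):
        out = baseline_characterization([], self._hyp(30.0))
        assert out["rate_per_s_sws"] == 0.0
        assert np.isnan(out["mean_freq_hz"])

    def test_no_sws_errors(self):
        with pytest.raises(ParameterError):
            baseline_characterization([], Hypnogram([Bout("AWAKE", 0, 10)]))

    def test_poisson_rate_recovery(self, short_recording):
        """Detected rate within +-10% of the injected rate on 20 min."""
        from swrpipe.preprocess import filter_ripple_band
        from swrpipe.ripples import detect_and_characterize

        rec, truth = short_recording
        filt = filter_ripple_band(rec.channel("LFP"), rec.fs)
        events = detect_and_characterize(filt, rec.fs, truth.hypnogram)
        est = baseline_characterization(events, truth.hypnogram)["rate_per_s_sws"]
        true_rate = len(truth.events) / truth.hypnogram.duration("SWS")
        assert est == pytest.approx(true_rate, rel=0.10)
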