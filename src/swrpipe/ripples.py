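"""Sharp wave-ripple detection via the normalized squared signal (NSS).

The 100-250 Hz band-filtered LFP is squared, smoothed with a short moving
average, and standardized to SD units using the mean and SD computed over the
slow-wave-sleep samples only (detection is restricted to SWS). Candidate
events are maximal runs where the NSS exceeds 2 SD; candidates separated by
less than 30 ms are merged, episodes longer than 100 ms (or shorter than a
20 ms floor) are discarded, and survivors must reach a 5 SD peak. The
normalized power of a ripple is the maximum NSS within it, and its
intra-ripple frequency is estimated from zero crossings of the filtered
trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    SWS,
    DegenerateSignalError,
    Hypnogram,
    ParameterError,
    RippleEvent,
)


@dataclass
class DetectorParams:
    """Thresholds and episode rules of the NSS detector.

    ``low_sd``/``high_sd`` are the envelope and peak thresholds in SD units;
    ``max_dur``/``min_dur``/``merge_gap`` are in ms. Comparisons are strict:
    an episode lasting exactly ``max_dur`` is kept, a gap of exactly
    ``merge_gap`` is not merged.
    """

    low_sd: float = 2.0
    high_sd: float = 5.0
    max_dur: float = 100.0
    merge_gap: float = 30.0
    min_dur: float = 20.0
    smooth_win: float = 8.0

    def validate(self) -> None:
        if not self.low_sd < self.high_sd:
            raise ParameterError("low_sd must be below high_sd")
        if not 0 < self.min_dur < self.max_dur:
            raise ParameterError("need 0 < min_dur < max_dur")
        if self.merge_gap < 0 or self.smooth_win <= 0:
            raise ParameterError("merge_gap must be >= 0 and smooth_win > 0")


@dataclass
class NSSeries:
    """Standardized squared ripple-band signal, with its detection support.

    ``values`` are in SD units of the squared-and-smoothed signal over the
    support; ``mask`` marks samples inside the support (detection never fires
    outside it). ``normalization`` records the (mean, sd) used.
    """

    values: np.ndarray
    fs: float
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    normalization: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.ones(len(self.values), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if len(self.mask) != len(self.values):
            raise ParameterError("mask and values must share one length")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("NSS values must be finite")


def _support_mask(n: int, fs: float, intervals: np.ndarray) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for lo, hi in np.asarray(intervals, dtype=float).reshape(-1, 2):
        i0 = max(int(np.ceil(lo * fs)), 0)
        i1 = min(int(np.ceil(hi * fs)), n)
        mask[i0:i1] = True
    return mask


def compute_nss(
    filtered_lfp: np.ndarray,
    fs: float,
    support: np.ndarray | Hypnogram,
    smooth_win: float = 8.0,
) -> NSSeries:
    """Square, smooth and standardize the ripple-band signal over a support.

    ``support`` is either a (n, 2) array of SWS intervals (seconds) or a
    hypnogram, whose SWS bouts are used. Mean and SD are computed over
    support samples only, making the SD units state-consistent; the statistic
    is invariant to positive rescaling of the input.
    """
    x = np.asarray(filtered_lfp, dtype=float)
    if isinstance(support, Hypnogram):
        support = support.intervals(SWS)
    support = np.asarray(support, dtype=float).reshape(-1, 2)
    if len(support) == 0:
        raise ParameterError("empty detection support")
    mask = _support_mask(len(x), fs, support)
    if not mask.any():
        raise ParameterError("support covers no samples of the signal")

    from scipy.ndimage import uniform_filter1d

    k = max(1, int(round(smooth_win * fs / 1000.0)))
    sq = x * x
    sm = uniform_filter1d(sq, k, mode="nearest")

    mu = float(np.mean(sm[mask]))
    sd = float(np.std(sm[mask]))
    if sd == 0.0:
        raise DegenerateSignalError("filtered signal has zero variance on support")
    values = (sm - mu) / sd
    return NSSeries(values=values, fs=fs, mask=mask, normalization=(mu, sd))


def detect_ripples(nss: NSSeries, p: DetectorParams | None = None) -> list[RippleEvent]:
    """Threshold the NSS into ripple events.

    Pipeline: (1) candidate intervals are maximal in-support runs with
    NSS > low_sd; (2) candidates separated by less than merge_gap are merged;
    (3) candidates longer than max_dur or shorter than min_dur are dropped;
    (4) survivors must have peak NSS > high_sd. Onset/offset are the
    threshold-crossing times; peak_time is the NSS argmax within the event.
    """
    p = p or DetectorParams()
    p.validate()
    v = nss.values
    above = (v > p.low_sd) & nss.mask
    if not above.any():
        return []
    d = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [len(v)]])
    runs = list(zip(starts.tolist(), ends.tolist()))

    gap_samples = p.merge_gap * nss.fs / 1000.0
    merged: list[list[int]] = [list(runs[0])]
    for s, e in runs[1:]:
        if s - merged[-1][1] < gap_samples:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    min_samples = p.min_dur * nss.fs / 1000.0
    max_samples = p.max_dur * nss.fs / 1000.0
    events: list[RippleEvent] = []
    for s, e in merged:
        dur = e - s
        if dur > max_samples or dur < min_samples:
            continue
        seg = v[s:e]
        peak = float(seg.max())
        if not peak > p.high_sd:
            continue
        ipk = s + int(np.argmax(seg))
        events.append(
            RippleEvent(
                onset=s / nss.fs,
                offset=e / nss.fs,
                peak_time=ipk / nss.fs,
                norm_power=peak,
                duration_ms=dur / nss.fs * 1000.0,
            )
        )
    return events


def ripple_features(
    event: RippleEvent, filtered_lfp: np.ndarray, fs: float
) -> RippleEvent:
    """Fill in the intra-ripple frequency of a detected event.

    freq = zero-crossing count of the filtered trace within [onset, offset)
    divided by twice the duration. With fewer than 2 crossings the frequency
    is undefined and left NaN.
    """
    i0 = int(round(event.onset * fs))
    i1 = int(round(event.offset * fs))
    seg = np.asarray(filtered_lfp, dtype=float)[i0:i1]
    if len(seg) < 2:
        raise ParameterError("event lies outside the signal span")
    signs = np.sign(seg)
    signs[signs == 0] = 1
    crossings = int(np.count_nonzero(np.diff(signs)))
    dur_s = event.offset - event.onset
    freq = crossings / (2.0 * dur_s) if crossings >= 2 else float("nan")
    event.freq_hz = float(freq)
    return event


def detect_and_characterize(
    filtered_lfp: np.ndarray,
    fs: float,
    hyp: Hypnogram,
    p: DetectorParams | None = None,
) -> list[RippleEvent]:
    """Convenience: NSS over the hypnogram's SWS support, detect, add features."""
    p = p or DetectorParams()
    nss = compute_nss(filtered_lfp, fs, hyp, smooth_win=p.smooth_win)
    events = detect_ripples(nss, p)
    return [ripple_features(e, filtered_lfp, fs) for e in events]


def baseline_characterization(
    events: list[RippleEvent], hyp: Hypnogram
) -> dict[str, float]:
    """Occurrence rate (events per second of SWS) and mean event properties.

    Means are NaN-flagged when no events (or no defined frequencies) exist;
    zero SWS time is an error since the rate is then undefined.
    """
    sws_seconds = hyp.duration(SWS)
    if sws_seconds <= 0:
        raise ParameterError("hypnogram contains no SWS; occurrence rate undefined")
    if not events:
        return {
            "rate_per_s_sws": 0.0,
            "mean_freq_hz": float("nan"),
            "mean_duration_ms": float("nan"),
            "mean_norm_power": float("nan"),
            "n_events": 0.0,
        }
    freqs = np.array([e.freq_hz for e in events], dtype=float)
    return {
        "rate_per_s_sws": len(events) / sws_seconds,
        "mean_freq_hz": float(np.nanmean(freqs)) if np.any(np.isfinite(freqs)) else float("nan"),
        "mean_duration_ms": float(np.mean([e.duration_ms for e in events])),
        "mean_norm_power": float(np.mean([e.norm_power for e in events])),
        "n_events": float(len(events)),
    }
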