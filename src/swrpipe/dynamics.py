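"""Occurrence-rate time courses of ripple events around behavioral epochs.

Two binning schemes are provided. Wall-clock binning tiles each home-cage
epoch (pre-encoding, post-encoding, post-test) with fixed-length bins and
expresses the rate as events per second of the SWS contained in each bin.
Cumulative-SWS binning first concatenates the SWS bouts of an epoch into a
single sleep timeline and cuts *that* into bins, controlling for how much
each subject slept per bin. In both schemes a bin with under 5 min (300 s)
of SWS is flagged excluded — kept in the table, masked from statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import (
    SWS,
    DesignError,
    Hypnogram,
    RateBin,
    RippleEvent,
    SessionDesign,
    intersect_intervals,
    interval_overlap,
)

MIN_SWS_SECONDS = 300.0  # "less than 5 min of SWS" exclusion rule


def _peak_times(events: list[RippleEvent] | np.ndarray) -> np.ndarray:
    """Peak times from RippleEvents, (peak, dur, freq) ground-truth tuples,
    or a plain array of times."""
    if len(events) and isinstance(events[0], RippleEvent):
        return np.array([e.peak_time for e in events], dtype=float)
    arr = np.asarray(events, dtype=float)
    if arr.ndim == 2:
        return arr[:, 0]
    return arr.reshape(-1)


def wallclock_bins(
    events: list[RippleEvent],
    hyp: Hypnogram,
    design: SessionDesign,
    bin_len: float = 2400.0,
) -> list[RateBin]:
    """Fixed wall-clock bins tiling each epoch (default 40 min).

    ``bin_len`` must divide every epoch length. An event belongs to the bin
    containing its peak time; the rate is events per second of SWS in the
    bin, NaN when the bin holds no SWS.
    """
    peaks = _peak_times(events)
    sws = hyp.intervals(SWS)
    bins: list[RateBin] = []
    for label, start, end in design.epochs:
        n_bins = (end - start) / bin_len
        if abs(n_bins - round(n_bins)) > 1e-9 or round(n_bins) < 1:
            raise DesignError(
                f"bin_len {bin_len} does not divide epoch {label} of length {end - start}"
            )
        for k in range(int(round(n_bins))):
            lo = start + k * bin_len
            hi = lo + bin_len
            sws_sec = interval_overlap(sws, lo, hi)
            count = int(np.count_nonzero((peaks >= lo) & (peaks < hi)))
            rate = count / sws_sec if sws_sec > 0 else float("nan")
            bins.append(
                RateBin(
                    label=label,
                    start=lo,
                    end=hi,
                    sws_seconds=sws_sec,
                    count=count,
                    rate=rate,
                    excluded=sws_sec < MIN_SWS_SECONDS,
                )
            )
    return bins


def cumulative_sws_position(t: float, segments: np.ndarray) -> float:
    """Map a wall-clock time inside an SWS segment onto the cumulative-SWS axis."""
    segments = np.asarray(segments, dtype=float).reshape(-1, 2)
    cum = 0.0
    for lo, hi in segments:
        if lo <= t < hi:
            return cum + (t - lo)
        cum += hi - lo
    raise ValueError(f"time {t} lies outside the SWS segments")


def wallclock_from_cumulative(c: float, segments: np.ndarray) -> float:
    """Inverse of :func:`cumulative_sws_position`."""
    segments = np.asarray(segments, dtype=float).reshape(-1, 2)
    cum = 0.0
    for lo, hi in segments:
        if c < cum + (hi - lo):
            return lo + (c - cum)
        cum += hi - lo
    raise ValueError(f"cumulative position {c} exceeds total SWS {cum}")


def sws_time_bins(
    events: list[RippleEvent],
    hyp: Hypnogram,
    design: SessionDesign,
    bin_len: float = 900.0,
) -> list[RateBin]:
    """Bins of cumulated SWS time within each epoch (default 15 min).

    SWS bouts intersecting the epoch are concatenated into one timeline which
    is cut into consecutive ``bin_len`` spans; a final partial span is kept
    only if it holds at least 300 s of SWS, otherwise it is flagged excluded.
    Bin start/end are positions on the cumulative-SWS axis.
    """
    peaks = _peak_times(events)
    sws = hyp.intervals(SWS)
    bins: list[RateBin] = []
    for label, start, end in design.epochs:
        segs = intersect_intervals(sws, start, end)
        total = float(np.sum(segs[:, 1] - segs[:, 0])) if len(segs) else 0.0
        if total == 0.0:
            bins.append(
                RateBin(label=label, start=0.0, end=0.0, sws_seconds=0.0,
                        count=0, rate=float("nan"), excluded=True)
            )
            continue
        in_epoch = peaks[(peaks >= start) & (peaks < end)]
        cum_pos = []
        for t in in_epoch:
            try:
                cum_pos.append(cumulative_sws_position(t, segs))
            except ValueError:
                continue  # event outside SWS (cannot happen for SWS-gated detections)
        cum_pos = np.asarray(cum_pos)
        edges = list(np.arange(0.0, total, bin_len)) + [total]
        for lo, hi in zip(edges[:-1], edges[1:]):
            span = hi - lo
            count = int(np.count_nonzero((cum_pos >= lo) & (cum_pos < hi)))
            bins.append(
                RateBin(
                    label=label,
                    start=lo,
                    end=hi,
                    sws_seconds=span,
                    count=count,
                    rate=count / span if span > 0 else float("nan"),
                    excluded=span < MIN_SWS_SECONDS,
                )
            )
    return bins


def rate_table(
    cohort_bins: dict[str, list[RateBin]]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align per-subject bin lists into a subjects x bins rate matrix.

    Returns (rates, excluded): two DataFrames indexed by subject with one
    column per bin (labelled ``<epoch>[k]``). Excluded bins keep their rate
    value in ``rates`` but are flagged True in ``excluded`` — masking, not
    zeroing, is the caller's contract. All subjects must share one design.
    """
    ref_cols: list[str] | None = None
    rows, masks = {}, {}
    for subject, bins in cohort_bins.items():
        counts: dict[str, int] = {}
        cols = []
        for b in bins:
            k = counts.get(b.label, 0)
            counts[b.label] = k + 1
            cols.append(f"{b.label}[{k}]")
        if ref_cols is None:
            ref_cols = cols
        elif cols != ref_cols:
            raise DesignError(f"subject {subject!r} has a misaligned bin layout")
        rows[subject] = [b.rate for b in bins]
        masks[subject] = [b.excluded for b in bins]
    rates = pd.DataFrame.from_dict(rows, orient="index", columns=ref_cols)
    excluded = pd.DataFrame.from_dict(masks, orient="index", columns=ref_cols)
    return rates, excluded
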