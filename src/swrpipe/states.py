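"""Automated sleep-state scoring from band power and EMG tone.

The classifier applies the classic polysomnographic criteria: movement-level
EMG means awake; among immobile windows, a high theta/delta ratio with muscle
atonia means REM; high delta power means slow-wave sleep; everything else is
awake. Thresholds are per-recording quantiles so the scorer self-calibrates
to a recording's amplitude scale, and are all config-overridable.

After window labeling, bouts shorter than ``min_bout`` are absorbed into
their longer neighbor (suppressing single-window flicker) and SWS bouts
separated by less than 3 s are merged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AWAKE, REM, SWS, Bout, Hypnogram, ParameterError
from .preprocess import BandPowerSeries


@dataclass
class ScoringThresholds:
    """Quantile cutoffs of the scorer.

    ``emg_quantile``: EMG-tone quantile above which a window is movement
    (awake). ``delta_quantile``: delta-power quantile *of the immobile
    windows* above which delta counts as high. ``theta_delta_ratio``: ratio
    above which an atonic window is REM. ``atonia_quantile``: EMG quantile
    below which muscle tone counts as atonic. ``min_bout``: shortest bout
    kept, seconds.

    The movement and delta quantiles default to 0.75 and 0.25: for typical
    mouse sleep architecture (SWS occupying most of a home-cage recording)
    these fall in the gaps between the awake/SWS EMG clusters and the
    background/SWS delta clusters rather than splitting a cluster.
    """

    emg_quantile: float = 0.75
    delta_quantile: float = 0.25
    theta_delta_ratio: float = 2.0
    atonia_quantile: float = 0.20
    min_bout: float = 10.0

    def validate(self) -> None:
        for name in ("emg_quantile", "delta_quantile", "atonia_quantile"):
            q = getattr(self, name)
            if not 0.0 < q < 1.0:
                raise ParameterError(f"{name} must lie in (0, 1)")
        if self.theta_delta_ratio <= 0:
            raise ParameterError("theta_delta_ratio must be positive")
        if self.min_bout < 0:
            raise ParameterError("min_bout must be non-negative")


def label_windows(bp: BandPowerSeries, th: ScoringThresholds) -> np.ndarray:
    """Per-window state labels before any bout-level smoothing.

    Ties at a cutoff resolve to the non-sleep side (conservative sleep calls).
    """
    th.validate()
    if len(bp) == 0:
        raise ParameterError("empty band-power series")
    emg = np.asarray(bp.emg_tone, dtype=float)
    delta = np.asarray(bp.delta_power, dtype=float)
    theta = np.asarray(bp.theta_power, dtype=float)

    emg_cut = np.quantile(emg, th.emg_quantile)
    atonia_cut = np.quantile(emg, th.atonia_quantile)
    immobile = emg < emg_cut
    if immobile.any():
        delta_cut = np.quantile(delta[immobile], th.delta_quantile)
    else:
        delta_cut = np.inf

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(delta > 0, theta / np.where(delta > 0, delta, 1.0), np.inf)
        ratio = np.where((delta == 0) & (theta == 0), 0.0, ratio)

    labels = np.full(len(bp), AWAKE, dtype=object)
    rem = immobile & (ratio > th.theta_delta_ratio) & (emg < atonia_cut)
    sws = immobile & ~rem & (delta > delta_cut)
    labels[rem] = REM
    labels[sws] = SWS
    return labels


def _windows_to_bouts(labels: np.ndarray, bp: BandPowerSeries) -> list[Bout]:
    """Turn the window label sequence into bouts on the window-center grid.

    Window i owns the half-open segment centered on its time, of width
    ``step`` (the tiling resolution of the series).
    """
    half = bp.step / 2.0
    edges = np.concatenate([bp.times - half, [bp.times[-1] + half]])
    bouts: list[Bout] = []
    start = edges[0]
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[i - 1]:
            bouts.append(Bout(str(labels[i - 1]), start, edges[i]))
            start = edges[i]
    return bouts


def _absorb_short_bouts(bouts: list[Bout], min_bout: float) -> list[Bout]:
    """Merge bouts shorter than min_bout into the longer adjacent neighbor."""
    bouts = list(bouts)
    while len(bouts) > 1:
        durs = [b.end - b.start for b in bouts]
        short = [i for i, d in enumerate(durs) if d < min_bout]
        if not short:
            break
        i = min(short, key=lambda k: durs[k])
        if i == 0:
            j = 1
        elif i == len(bouts) - 1:
            j = i - 1
        else:
            j = i - 1 if durs[i - 1] >= durs[i + 1] else i + 1
        lo = min(bouts[i].start, bouts[j].start)
        hi = max(bouts[i].end, bouts[j].end)
        merged = Bout(bouts[j].state, lo, hi)
        bouts[min(i, j) : max(i, j) + 1] = [merged]
        # coalesce same-state neighbors created by the relabeling
        k = 0
        while k < len(bouts) - 1:
            if bouts[k].state == bouts[k + 1].state:
                bouts[k : k + 2] = [Bout(bouts[k].state, bouts[k].start, bouts[k + 1].end)]
            else:
                k += 1
    return bouts


def merge_sws(hyp: Hypnogram, gap: float = 3.0) -> Hypnogram:
    """Merge SWS bouts separated by less than ``gap`` seconds (strict).

    The intervening gap is relabeled SWS; non-SWS bouts inside it are consumed
    or clipped. Idempotent.
    """
    sws = hyp.intervals(SWS)
    if len(sws) == 0:
        return Hypnogram(list(hyp.bouts))
    merged = [list(sws[0])]
    for lo, hi in sws[1:]:
        if lo - merged[-1][1] < gap:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])

    out: list[Bout] = []
    for b in hyp.bouts:
        if b.state == SWS:
            continue
        pieces = [(b.start, b.end)]
        clipped: list[tuple[float, float]] = []
        for lo, hi in pieces:
            cur = lo
            for ms, me in merged:
                if me <= cur or ms >= hi:
                    continue
                if ms > cur:
                    clipped.append((cur, ms))
                cur = max(cur, me)
            if cur < hi:
                clipped.append((cur, hi))
        for lo, hi in clipped:
            out.append(Bout(b.state, lo, hi))
    for lo, hi in merged:
        out.append(Bout(SWS, lo, hi))
    out.sort(key=lambda b: b.start)
    # coalesce adjacent same-state bouts
    final: list[Bout] = []
    for b in out:
        if final and final[-1].state == b.state and np.isclose(final[-1].end, b.start):
            final[-1] = Bout(b.state, final[-1].start, b.end)
        else:
            final.append(b)
    return Hypnogram(final)


def score_states(
    bp: BandPowerSeries, th: ScoringThresholds | None = None
) -> Hypnogram:
    """Classify a recording into an awake/SWS/REM hypnogram.

    Applies the window rules of :func:`label_windows`, absorbs bouts shorter
    than ``min_bout`` into their longer neighbor, then merges SWS bouts
    separated by less than 3 s.
    """
    th = th or ScoringThresholds()
    labels = label_windows(bp, th)
    bouts = _windows_to_bouts(labels, bp)
    bouts = _absorb_short_bouts(bouts, th.min_bout)
    return merge_sws(Hypnogram(bouts))


def state_durations(hyp: Hypnogram) -> dict[str, dict[str, float]]:
    """Per-state bout rate (per hour) and mean bout duration (minutes).

    Rates are counts over the hypnogram's total span; an empty hypnogram
    yields zero rates and NaN mean durations.
    """
    span_h = hyp.span / 3600.0
    out: dict[str, dict[str, float]] = {}
    for state in (AWAKE, SWS, REM):
        iv = hyp.intervals(state)
        n = len(iv)
        durs_min = (iv[:, 1] - iv[:, 0]) / 60.0 if n else np.array([])
        out[state] = {
            "count": float(n),
            "rate_per_hour": n / span_h if span_h > 0 else 0.0,
            "mean_duration_min": float(np.mean(durs_min)) if n else float("nan"),
        }
    return out
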