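"""Shared containers for the ripple-analysis pipeline.

Conventions used throughout the package:

* time is in seconds from the start of the recording (0-based);
* intervals are half-open ``[start, end)``;
* an event lies "inside" an interval when its *peak time* does.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

AWAKE = "AWAKE"
SWS = "SWS"
REM = "REM"
STATES = (AWAKE, SWS, REM)


class ParameterError(ValueError):
    """An argument violates a documented precondition."""


class FormatError(ValueError):
    """A file does not conform to the expected on-disk layout."""


class ValidationError(ValueError):
    """In-memory data violates a structural invariant."""


class DesignError(ValueError):
    """A session design is inconsistent with the requested analysis."""


class DegenerateSignalError(ValueError):
    """A signal has no usable variance on the requested support."""


@dataclass
class SignalRecording:
    """Multi-channel sampled signal with per-channel roles.

    ``samples`` is a (channels, time) array; ``channel_roles`` assigns each
    channel either ``"LFP"`` or ``"EMG"``.
    """

    samples: np.ndarray
    fs: float
    channel_roles: list[str]
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples))
        if self.fs <= 0:
            raise ParameterError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_roles) != self.samples.shape[0]:
            raise ValidationError(
                f"{len(self.channel_roles)} roles for {self.samples.shape[0]} channels"
            )
        for role in self.channel_roles:
            if role not in ("LFP", "EMG"):
                raise ValidationError(f"unknown channel role {role!r}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel(self, role: str, index: int = 0) -> np.ndarray:
        """Return the ``index``-th channel with the given role (1-D view)."""
        matches = [i for i, r in enumerate(self.channel_roles) if r == role]
        if index >= len(matches):
            raise KeyError(f"no channel #{index} with role {role!r}")
        return self.samples[matches[index]]


@dataclass(frozen=True)
class Bout:
    state: str
    start: float
    end: float


class Hypnogram:
    """Ordered, non-overlapping sleep/wake bouts on a seconds timeline."""

    def __init__(self, bouts: Iterable[Bout | tuple], validate: bool = True):
        norm = []
        for b in bouts:
            if not isinstance(b, Bout):
                b = Bout(*b)
            norm.append(b)
        self.bouts: list[Bout] = norm
        if validate:
            self.validate()

    def validate(self) -> None:
        prev_end = -np.inf
        for b in self.bouts:
            if b.state not in STATES:
                raise ValidationError(f"unknown state {b.state!r}")
            if not b.start < b.end:
                raise ValidationError(f"bout {b} has start >= end")
            if b.start < prev_end:
                raise ValidationError(f"bout {b} overlaps its predecessor")
            prev_end = b.end

    def __len__(self) -> int:
        return len(self.bouts)

    def __iter__(self):
        return iter(self.bouts)

    def __eq__(self, other) -> bool:
        return isinstance(other, Hypnogram) and self.bouts == other.bouts

    @property
    def span(self) -> float:
        """Total span (last end minus first start); 0 for an empty hypnogram."""
        if not self.bouts:
            return 0.0
        return self.bouts[-1].end - self.bouts[0].start

    def intervals(self, state: str) -> np.ndarray:
        """(n, 2) array of [start, end) intervals for one state."""
        rows = [(b.start, b.end) for b in self.bouts if b.state == state]
        return np.asarray(rows, dtype=float).reshape(-1, 2)

    def duration(self, state: str) -> float:
        iv = self.intervals(state)
        return float(np.sum(iv[:, 1] - iv[:, 0])) if len(iv) else 0.0

    def states_at(self, times: Sequence[float]) -> np.ndarray:
        """State label at each time; empty string where no bout covers it."""
        times = np.asarray(times, dtype=float)
        starts = np.array([b.start for b in self.bouts])
        ends = np.array([b.end for b in self.bouts])
        labels = np.array([b.state for b in self.bouts], dtype=object)
        out = np.full(times.shape, "", dtype=object)
        if len(self.bouts):
            idx = np.searchsorted(starts, times, side="right") - 1
            ok = (idx >= 0) & (times < ends[np.clip(idx, 0, len(ends) - 1)])
            out[ok] = labels[idx[ok]]
        return out.astype(str)


def intersect_intervals(intervals: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Clip a (n, 2) interval array to [lo, hi), dropping empty pieces."""
    iv = np.asarray(intervals, dtype=float).reshape(-1, 2)
    if len(iv) == 0:
        return iv
    clipped = np.column_stack([np.maximum(iv[:, 0], lo), np.minimum(iv[:, 1], hi)])
    return clipped[clipped[:, 1] > clipped[:, 0]]


def interval_overlap(intervals: np.ndarray, lo: float, hi: float) -> float:
    """Total seconds of overlap between intervals and [lo, hi)."""
    iv = intersect_intervals(intervals, lo, hi)
    return float(np.sum(iv[:, 1] - iv[:, 0])) if len(iv) else 0.0


@dataclass
class RippleEvent:
    """One detected sharp wave-ripple."""

    onset: float
    offset: float
    peak_time: float
    norm_power: float
    duration_ms: float
    freq_hz: float = float("nan")

    def __post_init__(self) -> None:
        if not self.onset < self.offset:
            raise ValidationError("event onset must precede offset")


@dataclass
class SessionDesign:
    """Behavioral epoch boundaries and maze periods on the recording clock.

    ``epochs`` are the home-cage analysis blocks (pre_encoding, post_encoding,
    post_test); ``maze_intervals`` are the encoding / test maze visits that
    separate them and are excised from rate binning.
    """

    epochs: list[tuple[str, float, float]]
    maze_intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for label, start, end in self.epochs:
            if not start < end:
                raise DesignError(f"epoch {label} has start >= end")
            if start < prev_end:
                raise DesignError(f"epoch {label} overlaps its predecessor")
            prev_end = end
        for lo, hi in self.maze_intervals:
            for label, start, end in self.epochs:
                if lo < end and hi > start:
                    raise DesignError(
                        f"maze interval [{lo}, {hi}) overlaps epoch {label}"
                    )

    @property
    def total_end(self) -> float:
        ends = [e for _, _, e in self.epochs] + [e for _, e in self.maze_intervals]
        return max(ends) if ends else 0.0

    def epoch_at(self, t: float) -> str | None:
        for label, start, end in self.epochs:
            if start <= t < end:
                return label
        return None


def default_design(
    bin_len: float = 2400.0,
    n_pre: int = 2,
    n_post_encoding: int = 6,
    n_post_test: int = 2,
    encoding_maze: float = 600.0,
    test_maze: float = 300.0,
) -> SessionDesign:
    """Recognition-memory session layout: baseline, encoding, consolidation, test.

    Defaults give ten 40-min home-cage blocks (2 pre-encoding, 6 post-encoding,
    2 post-test) separated by a 10-min encoding and a 5-min test maze visit.
    """
    t = 0.0
    epochs = []
    epochs.append(("pre_encoding", t, t + n_pre * bin_len))
    t += n_pre * bin_len
    maze = [(t, t + encoding_maze)]
    t += encoding_maze
    epochs.append(("post_encoding", t, t + n_post_encoding * bin_len))
    t += n_post_encoding * bin_len
    maze.append((t, t + test_maze))
    t += test_maze
    epochs.append(("post_test", t, t + n_post_test * bin_len))
    return SessionDesign(epochs=epochs, maze_intervals=maze)


@dataclass
class RateBin:
    """One occurrence-rate analysis bin.

    ``start``/``end`` are wall-clock seconds for wall-clock bins, or positions
    on the per-epoch cumulative-SWS timeline for SWS-time bins. A bin holding
    under 300 s of SWS is flagged ``excluded`` (rate unreliable), never dropped.
    """

    label: str
    start: float
    end: float
    sws_seconds: float
    count: int
    rate: float
    excluded: bool
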