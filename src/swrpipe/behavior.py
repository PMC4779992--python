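"""Y-maze spatial recognition scoring and exploration metrics.

Recognition performance is the percentage of arm-exploration time spent in
the novel (previously blocked) arm: time_novel / (time in all three arms) x
100, with 33% as the chance level. Time on the central platform is excluded
by construction (it is not an arm time). Exploration metrics (distance,
speed, immobility) come from the position track.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ParameterError
from .synthetic import ArmTimes

CHANCE_LEVEL_PERCENT = 100.0 / 3.0


def recognition_performance(rec: ArmTimes | tuple[float, float, float]) -> float:
    """Percent of total arm time spent in the novel arm."""
    if isinstance(rec, ArmTimes):
        novel, fam1, fam2 = rec.time_novel, rec.time_fam1, rec.time_fam2
    else:
        novel, fam1, fam2 = rec
    for t in (novel, fam1, fam2):
        if t < 0:
            raise ParameterError("arm times must be non-negative")
    total = novel + fam1 + fam2
    if total <= 0:
        raise ParameterError("zero total arm time; performance undefined")
    # clamp: novel/total can exceed 1 by one ulp when both familiar times are 0
    return min(100.0, max(0.0, 100.0 * novel / total))


@dataclass
class Track:
    """Position samples (cm) at a fixed sampling step (s)."""

    positions: np.ndarray  # (n, 2)
    step: float

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        if self.step <= 0:
            raise ParameterError("track step must be positive")
        if not np.all(np.isfinite(self.positions)):
            raise ParameterError("track coordinates must be finite")


def exploration_metrics(
    track: Track, immobility_speed: float = 2.0
) -> dict[str, float]:
    """Distance traveled (cm), mean speed (cm/s) and % immobility.

    Immobility is the fraction of steps whose instantaneous speed falls below
    ``immobility_speed`` (default 2 cm/s, config-overridable).
    """
    pos = track.positions
    if len(pos) < 2:
        raise ParameterError("need at least 2 track positions")
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    distance = float(steps.sum())
    elapsed = (len(pos) - 1) * track.step
    speeds = steps / track.step
    return {
        "distance_cm": distance,
        "mean_speed_cm_s": distance / elapsed,
        "immobility_percent": 100.0 * float(np.mean(speeds < immobility_speed)),
    }
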