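import tempfile

import numpy as np
import pytest
from hypothesis import configuration, settings

# deterministic property tests; keep hypothesis state out of the repo tree
configuration.set_hypothesis_home_dir(tempfile.mkdtemp(prefix="hypothesis-"))
settings.register_profile("deterministic", database=None, derandomize=True)
settings.load_profile("deterministic")

from swrpipe.synthetic import (
    HypnogramParams,
    RippleProfile,
    generate_hypnogram,
    generate_recording,
)


@pytest.fixture(scope="session")
def short_recording():
    """20-min default-parameter recording with ground truth (shared, read-only)."""
    hyp = generate_hypnogram(HypnogramParams(total_dur=1200.0, seed=11))
    rec, truth = generate_recording(hyp, RippleProfile(), fs=1250.0, seed=11)
    return rec, truth


def random_hypnogram(rng: np.random.Generator, total: float = 600.0):
    """Small random (but valid) hypnogram for property tests."""
    from swrpipe.core import Bout, Hypnogram

    states = ["AWAKE", "SWS", "REM"]
    bouts = []
    t = 0.0
    while t < total:
        dur = rng.uniform(1.0, 60.0)
        end = min(t + dur, total)
        bouts.append(Bout(rng.choice(states), t, end))
        t = end
    return Hypnogram(bouts)
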