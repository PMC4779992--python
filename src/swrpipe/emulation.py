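"""Group-level emulation of the learning-induced ripple-rate surge.

Builds two simulated cohorts sharing one session design — a control group
whose ripple rate rises after encoding and after the recognition test, and a
treated group with a flat profile — bins each subject's ground-truth events,
and asks the mixed repeated-measures ANOVA whether the bins x treatment
interaction is detected. Repeating this over many replicates measures the
pipeline's power (and, with the surge switched off, its type-I error).

Signals are not rendered here: rate statistics only need the hypnogram and
the injected event stream, so replicates are cheap and the emulation can use
shortened epochs.
"""

from __future__ import annotations

import numpy as np

from .core import SessionDesign, default_design
from .dynamics import rate_table, wallclock_bins
from .stats import rm_anova
from .synthetic import HypnogramParams, RippleProfile, generate_cohort


def emulate_cohort_rates(
    seed: int,
    n_subjects: int = 7,
    surge_multiplier: float = 1.5,
    design: SessionDesign | None = None,
    bin_len: float = 1200.0,
    base_rate: float = 0.7,
):
    """One replicate: simulate both groups and return (rates, groups, excluded)."""
    design = design or default_design(bin_len=bin_len)
    control = RippleProfile(
        base_rate=base_rate,
        epoch_multipliers={
            "post_encoding": surge_multiplier,
            "post_test": surge_multiplier,
        },
    )
    treated = RippleProfile(base_rate=base_rate)
    cohort = generate_cohort(n_subjects, design, control, treated, seed=seed)
    per_subject = {}
    groups = {}
    for group, subjects in cohort.items():
        for i, sub in enumerate(subjects):
            name = f"{group}_{i}"
            per_subject[name] = wallclock_bins(
                sub.truth.events, sub.truth.hypnogram, design, bin_len
            )
            groups[name] = group
    rates, excluded = rate_table(per_subject)
    import pandas as pd

    return rates, pd.Series(groups).reindex(rates.index), excluded


def interaction_detection_rate(
    n_replicates: int = 100,
    seed: int = 0,
    n_subjects: int = 7,
    surge_multiplier: float = 1.5,
    bin_len: float = 1200.0,
    alpha: float = 0.05,
) -> float:
    """Fraction of replicates in which the bins x treatment interaction is
    significant at ``alpha``. ``surge_multiplier=1.0`` gives the type-I rate."""
    import warnings

    root = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_replicates):
        rep_seed = int(root.integers(0, 2**31 - 1))
        rates, groups, excluded = emulate_cohort_rates(
            rep_seed,
            n_subjects=n_subjects,
            surge_multiplier=surge_multiplier,
            bin_len=bin_len,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = rm_anova(rates, between=groups, excluded=excluded)
        inter = next(r for r in results if r.effect == "bins * group")
        if inter.p < alpha:
            hits += 1
    return hits / n_replicates
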