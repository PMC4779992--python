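"""Group statistics over rate tables: repeated-measures ANOVA, Bonferroni
post-hoc t-tests, and assumption checks.

The ANOVA is the classical balanced cell-means sums-of-squares decomposition:
a one-way repeated-measures F when only the within factor (time bins) is
present, and main effects plus interaction in the two-way mixed design with
treatment group as the between-subjects factor. Excluded (masked) bins are
dropped pairwise with a warning before fitting. Sphericity violations are
reported alongside a Greenhouse-Geisser-corrected p; selection between the
uncorrected and corrected p is left to the user. All tests are two-sided at
alpha = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import DesignError


@dataclass
class AnovaResult:
    effect: str
    F: float
    df: tuple[int, int]
    p: float
    p_gg: float | None = None  # Greenhouse-Geisser-corrected p (within effects)
    eps: float | None = None


def _drop_masked(
    rates: pd.DataFrame, excluded: pd.DataFrame | None
) -> pd.DataFrame:
    if excluded is None:
        bad = rates.columns[rates.isna().any(axis=0)]
    else:
        bad = rates.columns[excluded.any(axis=0) | rates.isna().any(axis=0)]
    if len(bad):
        warnings.warn(
            f"dropping {len(bad)} bin(s) with excluded/missing cells: {list(bad)}",
            stacklevel=3,
        )
        rates = rates.drop(columns=bad)
    return rates


def _gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the within-subject covariance matrix."""
    k = data.shape[1]
    S = np.cov(data, rowvar=False)
    mean_diag = np.trace(S) / k
    mean_all = S.mean()
    row_means = S.mean(axis=1)
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * (np.sum(S**2) - 2 * k * np.sum(row_means**2) + k**2 * mean_all**2)
    if den <= 0:
        return 1.0
    return float(min(1.0, max(num / den, 1.0 / (k - 1))))


def _f_p(ss_num: float, df_num: int, ss_den: float, df_den: int) -> tuple[float, float]:
    if ss_num <= 1e-300:  # no effect at all: F defined as 0
        return 0.0, 1.0
    if ss_den <= 0 or df_den <= 0:
        return float("inf"), 0.0
    F = (ss_num / df_num) / (ss_den / df_den)
    return float(F), float(sps.f.sf(F, df_num, df_den))


def rm_anova(
    rates: pd.DataFrame,
    between: pd.Series | list | None = None,
    excluded: pd.DataFrame | None = None,
) -> list[AnovaResult]:
    """Repeated-measures ANOVA over a subjects x bins rate table.

    With ``between`` absent: one-way RM ANOVA with "bins" as the repeated
    factor. With ``between`` (one group label per subject): two-way mixed
    ANOVA — group and bin main effects plus their interaction. Balanced cell
    sizes are assumed for the mixed design. Within-subject effects carry a
    Greenhouse-Geisser-corrected p alongside the uncorrected one.
    """
    rates = _drop_masked(rates, excluded)
    n, j = rates.shape
    if n < 2 or j < 2:
        raise DesignError("need at least 2 subjects and 2 bins")
    y = rates.to_numpy(dtype=float)
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    subj_means = y.mean(axis=1)
    bin_means = y.mean(axis=0)
    ss_subject = float(j * ((subj_means - grand) ** 2).sum())
    ss_bin = float(n * ((bin_means - grand) ** 2).sum())
    eps = _gg_epsilon(y) if j > 2 else 1.0

    if between is None:
        ss_err = ss_total - ss_subject - ss_bin
        df1, df2 = j - 1, (n - 1) * (j - 1)
        F, p = _f_p(ss_bin, df1, ss_err, df2)
        p_gg = float(sps.f.sf(F, df1 * eps, df2 * eps)) if F > 0 else 1.0
        return [AnovaResult("bins", F, (df1, df2), p, p_gg=p_gg, eps=eps)]

    groups = pd.Series(list(between), index=rates.index)
    labels = groups.unique()
    g = len(labels)
    if g < 2:
        raise DesignError("between factor needs at least 2 groups")
    counts = groups.value_counts()
    if counts.nunique() != 1:
        raise DesignError("mixed ANOVA requires balanced group sizes")
    ss_group = 0.0
    ss_cells = 0.0
    for lab in labels:
        sub = y[(groups == lab).to_numpy()]
        ss_group += j * len(sub) * (sub.mean() - grand) ** 2
        ss_cells += len(sub) * ((sub.mean(axis=0) - grand) ** 2).sum()
    ss_group = float(ss_group)
    ss_inter = float(ss_cells) - ss_group - ss_bin
    ss_subj_within = ss_subject - ss_group
    ss_err = ss_total - ss_subject - ss_bin - ss_inter
    df_group, df_sw = g - 1, n - g
    df_bin, df_err = j - 1, (n - g) * (j - 1)
    df_inter = (g - 1) * (j - 1)

    F_g, p_g = _f_p(ss_group, df_group, ss_subj_within, df_sw)
    F_b, p_b = _f_p(ss_bin, df_bin, ss_err, df_err)
    F_i, p_i = _f_p(ss_inter, df_inter, ss_err, df_err)
    gg_b = float(sps.f.sf(F_b, df_bin * eps, df_err * eps)) if F_b > 0 else 1.0
    gg_i = float(sps.f.sf(F_i, df_inter * eps, df_err * eps)) if F_i > 0 else 1.0
    return [
        AnovaResult("group", F_g, (df_group, df_sw), p_g),
        AnovaResult("bins", F_b, (df_bin, df_err), p_b, p_gg=gg_b, eps=eps),
        AnovaResult("bins * group", F_i, (df_inter, df_err), p_i, p_gg=gg_i, eps=eps),
    ]


def bonferroni(pvals: np.ndarray | list[float]) -> np.ndarray:
    """Bonferroni adjustment: p times the number of comparisons, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    return np.minimum(p * p.size, 1.0)


def bonferroni_pairs(
    rates: pd.DataFrame,
    comparisons: list,
    between: pd.Series | list | None = None,
    welch: bool = False,
) -> pd.DataFrame:
    """Post-hoc t-tests with Bonferroni correction.

    Without ``between``, each comparison is a pair of bin labels compared by
    a paired t-test within subjects. With ``between``, each comparison is a
    single bin label compared between the two groups (pooled-variance t by
    default, Welch with ``welch=True``). Returns a table with raw and
    adjusted p values.
    """
    if not comparisons:
        raise DesignError("no comparisons requested")
    rows = []
    if between is None:
        for a, b in comparisons:
            res = sps.ttest_rel(rates[a], rates[b])
            rows.append((f"{a} vs {b}", float(res.statistic), float(res.df), float(res.pvalue)))
    else:
        groups = pd.Series(list(between), index=rates.index)
        labels = groups.unique()
        if len(labels) != 2:
            raise DesignError("group comparisons require exactly 2 groups")
        for col in comparisons:
            x = rates.loc[(groups == labels[0]).to_numpy(), col]
            y = rates.loc[(groups == labels[1]).to_numpy(), col]
            res = sps.ttest_ind(x, y, equal_var=not welch)
            rows.append((f"{col}: {labels[0]} vs {labels[1]}",
                         float(res.statistic), float(res.df), float(res.pvalue)))
    df = pd.DataFrame(rows, columns=["comparison", "t", "df", "p_raw"])
    df["p_bonferroni"] = bonferroni(df["p_raw"].to_numpy())
    df["significant"] = df["p_bonferroni"] < 0.05
    return df


def assumption_checks(
    rates: pd.DataFrame, between: pd.Series | list | None = None
) -> dict[str, dict]:
    """Shapiro-Wilk normality, Levene variance homogeneity, Mauchly sphericity.

    Advisory only: the pipeline reports the checks but does not switch tests
    automatically. Checks whose sample-size minima are not met are skipped
    with a notice.
    """
    report: dict[str, dict] = {"normality": {}, "levene": {}, "sphericity": {}}
    for col in rates.columns:
        x = rates[col].dropna().to_numpy()
        if len(x) < 3:
            report["normality"][col] = {"skipped": "needs n >= 3"}
            continue
        if np.ptp(x) == 0:
            report["normality"][col] = {"skipped": "constant sample"}
            continue
        w, p = sps.shapiro(x)
        report["normality"][col] = {"W": float(w), "p": float(p)}

    if between is not None:
        groups = pd.Series(list(between), index=rates.index)
        for col in rates.columns:
            samples = [
                rates.loc[(groups == lab).to_numpy(), col].dropna().to_numpy()
                for lab in groups.unique()
            ]
            if any(len(s) < 2 for s in samples):
                report["levene"][col] = {"skipped": "needs n >= 2 per group"}
                continue
            w, p = sps.levene(*samples)
            report["levene"][col] = {"W": float(w), "p": float(p)}
    else:
        report["levene"]["all"] = {"skipped": "no between-subjects factor"}

    k = rates.shape[1]
    if k < 3:
        report["sphericity"] = {
            "satisfied": True,
            "note": "with 2 repeated levels sphericity holds trivially",
        }
    else:
        import pingouin as pg

        long = rates.reset_index(names="subject").melt(
            id_vars="subject", var_name="bin", value_name="rate"
        )
        spher = pg.sphericity(long, dv="rate", within="bin", subject="subject")
        report["sphericity"] = {
            "satisfied": bool(spher.spher),
            "W": float(spher.W),
            "chi2": float(spher.chi2),
            "dof": float(spher.dof),
            "p": float(spher.pval),
        }
    return report
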