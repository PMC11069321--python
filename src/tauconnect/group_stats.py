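"""Cohort-level descriptive statistics and network-specific uptake tests.

Covers the usual clinical table (pooled two-sample t for continuous
variables, chi-square for categorical, Mann-Whitney U for ordinal) plus
per-network mean SUVR comparisons between the NC and AD groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import AtlasSpec, SubjectTable

logger = logging.getLogger(__name__)


class GroupStatsError(ValueError):
    pass


@dataclass
class GroupComparison:
    variable: str
    test: str  # pooled_t | welch_t | chi_square | mann_whitney
    statistic: float
    df: float | None
    p_two_sided: float
    group_summaries: dict[str, str]
    n1: int
    n2: int


def pooled_t_from_summary(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    variable: str = "",
) -> GroupComparison:
    """Pooled-variance (Student) two-sample t-test from summary statistics.

    df = n1 + n2 - 2; two-sided p from the t distribution. Degenerate case
    (both SDs zero, equal means) reports t=0, p=1 by convention.
    """
    if min(n1, n2) < 2:
        raise GroupStatsError("need n >= 2 per group")
    if min(sd1, sd2) < 0:
        raise GroupStatsError("SDs must be >= 0")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if sp2 == 0:
        if mean1 == mean2:
            logger.warning("degenerate t-test (zero pooled variance, equal means)")
            t = 0.0
        else:
            raise GroupStatsError("zero pooled variance with unequal means")
    else:
        t = (mean1 - mean2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), df) if sp2 > 0 else 1.0
    return GroupComparison(
        variable=variable,
        test="pooled_t",
        statistic=float(t),
        df=float(df),
        p_two_sided=float(p),
        group_summaries={
            "group1": f"{mean1} +/- {sd1}",
            "group2": f"{mean2} +/- {sd2}",
        },
        n1=int(n1),
        n2=int(n2),
    )


def two_sample_t(
    x: np.ndarray, y: np.ndarray, variable: str = "", welch: bool = False
) -> GroupComparison:
    """Two-sample t from raw samples (pooled by default, Welch by flag)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if min(x.size, y.size) < 2:
        raise GroupStatsError("need n >= 2 per group")
    t, p = stats.ttest_ind(x, y, equal_var=not welch)
    df = (
        stats.ttest_ind(x, y, equal_var=False).df
        if welch
        else x.size + y.size - 2
    )
    return GroupComparison(
        variable=variable,
        test="welch_t" if welch else "pooled_t",
        statistic=float(t),
        df=float(df),
        p_two_sided=float(p),
        group_summaries={
            "group1": f"{x.mean():.3g} +/- {x.std(ddof=1):.3g}",
            "group2": f"{y.mean():.3g} +/- {y.std(ddof=1):.3g}",
        },
        n1=int(x.size),
        n2=int(y.size),
    )


def chi_square_2x2(a: int, b: int, c: int, d: int, variable: str = "") -> GroupComparison:
    """2x2 chi-square without continuity correction.

    chi2 = N*(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)), df=1. Symmetric under
    simultaneous row and column swaps. Empty margins are rejected.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise GroupStatsError("cell counts must be >= 0")
    margins = [a + b, c + d, a + c, b + d]
    if 0 in margins:
        raise GroupStatsError("empty margin in 2x2 table")
    N = table.sum()
    chi2 = N * (a * d - b * c) ** 2 / np.prod([float(m) for m in margins])
    p = stats.chi2.sf(chi2, df=1)
    return GroupComparison(
        variable=variable,
        test="chi_square",
        statistic=float(chi2),
        df=1.0,
        p_two_sided=float(p),
        group_summaries={"group1": f"{a}/{b}", "group2": f"{c}/{d}"},
        n1=int(a + b),
        n2=int(c + d),
    )


def mann_whitney(x: np.ndarray, y: np.ndarray, variable: str = "") -> GroupComparison:
    """Mann-Whitney U, normal approximation with tie correction, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if min(x.size, y.size) < 1:
        raise GroupStatsError("need non-empty samples")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return GroupComparison(
        variable=variable,
        test="mann_whitney",
        statistic=float(res.statistic),
        df=None,
        p_two_sided=float(res.pvalue),
        group_summaries={
            "group1": f"median {np.median(x):.3g}",
            "group2": f"median {np.median(y):.3g}",
        },
        n1=int(x.size),
        n2=int(y.size),
    )


def network_uptake(
    table: SubjectTable, atlas: AtlasSpec, modality: str, welch: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject network-mean SUVR plus per-network NC-vs-AD t-tests.

    Returns ``(subject_means, tests)``: subject_means has one row per
    subject and one column per network; tests has per-network t, df, raw p
    and a Bonferroni-corrected column (times the number of networks, capped
    at 1).
    """
    if table.P != atlas.P:
        raise GroupStatsError("subject table and atlas disagree on ROI count")
    suvr = table.tau if modality == "tau" else table.fdg
    if modality not in ("tau", "fdg"):
        raise GroupStatsError(f"modality must be 'tau' or 'fdg', got {modality!r}")
    nets = atlas.networks_present
    means = pd.DataFrame(
        {net: suvr[:, atlas.network_mask(net)].mean(axis=1) for net in nets},
        index=table.subjects["subject_id"],
    )
    nc = table.group_index("NC")
    ad = table.group_index("AD")
    rows = []
    k = len(nets)
    for net in nets:
        cmp = two_sample_t(
            means.loc[nc.tolist(), net].to_numpy(),
            means.loc[ad.tolist(), net].to_numpy(),
            variable=f"{modality}:{net}",
            welch=welch,
        )
        rows.append(
            {
                "network": net,
                "t": cmp.statistic,
                "df": cmp.df,
                "p": cmp.p_two_sided,
                "p_bonferroni": min(1.0, cmp.p_two_sided * k),
                "mean_nc": means.loc[nc.tolist(), net].mean(),
                "mean_ad": means.loc[ad.tolist(), net].mean(),
            }
        )
    return means, pd.DataFrame(rows).set_index("network")
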