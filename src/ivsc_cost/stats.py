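"""Scenario comparison statistics: one-way ANOVA with Bonferroni post hoc.

The three scenarios' per-patient cost (or time) vectors are compared with
a classical independent-groups one-way ANOVA; pairwise two-sample t-tests
are run only when the omnibus F-test is significant, with Bonferroni
adjustment (p multiplied by the number of comparisons, capped at 1).

Note the scenarios are counterfactual treatments of the *same* patients,
i.e. correlated samples; the independent-groups analysis mirrors the
original study design.  A repeated-measures variant is available behind
the ``repeated`` flag for the statistically stricter reading.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["AnovaResult", "PosthocResult", "one_way_anova", "bonferroni_pairwise"]


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    group_means: tuple[float, ...]
    group_sds: tuple[float, ...]
    repeated: bool = False


@dataclass(frozen=True)
class PosthocResult:
    pairs: tuple[tuple[int, int], ...]
    p_raw: tuple[float, ...]
    p_adjusted: tuple[float, ...]
    significant: tuple[bool, ...]
    ran: bool
    alpha: float = 0.05


def _as_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    if len(groups) < 2:
        raise ValueError("at least two groups required")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 observations")
    return arrays


def one_way_anova(
    groups: Sequence[Sequence[float]], repeated: bool = False
) -> AnovaResult:
    """Classical between/within decomposition; F = MSB / MSW.

    With both between- and within-group variance zero (all observations
    identical) F is defined as 0 with p = 1.  ``repeated=True`` runs the
    within-subject variant (equal group sizes required; observations
    matched by position).
    """
    arrays = _as_groups(groups)
    k = len(arrays)
    n_total = sum(g.size for g in arrays)
    grand = sum(g.sum() for g in arrays) / n_total
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in arrays)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    means = tuple(float(g.mean()) for g in arrays)
    sds = tuple(float(g.std(ddof=1)) for g in arrays)

    if repeated:
        sizes = {g.size for g in arrays}
        if len(sizes) != 1:
            raise ValueError("repeated-measures ANOVA requires equal group sizes")
        n = arrays[0].size
        mat = np.vstack(arrays)  # k x n, columns are subjects
        subj_means = mat.mean(axis=0)
        ss_subject = k * ((subj_means - grand) ** 2).sum()
        ss_error = ss_within - ss_subject
        df_b, df_w = k - 1, (k - 1) * (n - 1)
        ms_b = ss_between / df_b
        ms_e = ss_error / df_w if df_w else math.nan
    else:
        df_b, df_w = k - 1, n_total - k
        ms_b = ss_between / df_b
        ms_e = ss_within / df_w

    if ms_e == 0.0:
        if ms_b == 0.0:
            f, p = 0.0, 1.0
        else:
            f, p = math.inf, 0.0
    else:
        f = ms_b / ms_e
        p = float(sps.f.sf(f, df_b, df_w))
    return AnovaResult(
        f_statistic=float(f),
        df_between=df_b,
        df_within=df_w,
        p_value=p,
        group_means=means,
        group_sds=sds,
        repeated=repeated,
    )


def bonferroni_pairwise(
    groups: Sequence[Sequence[float]],
    omnibus: AnovaResult | None = None,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> PosthocResult:
    """All pairwise two-sided t-tests with Bonferroni adjustment.

    Adjusted p = min(1, m * p) for m comparisons.  Mirroring the gated
    protocol, the result carries ``ran=False`` when the omnibus p-value is
    >= alpha — the pairwise tables are still computed, but a gated report
    should not present them.
    """
    arrays = _as_groups(groups)
    if omnibus is None:
        omnibus = one_way_anova(groups)
    gate_open = omnibus.p_value < alpha

    pairs = list(itertools.combinations(range(len(arrays)), 2))
    m = len(pairs)
    p_raw: list[float] = []
    for i, j in pairs:
        a, b = arrays[i], arrays[j]
        if np.all(a == a[0]) and np.all(b == b[0]):
            # degenerate: no within-pair variance; identical groups tie
            p = 1.0 if a[0] == b[0] else 0.0
        else:
            p = float(sps.ttest_ind(a, b, equal_var=equal_var).pvalue)
        p_raw.append(p)
    p_adj = [min(1.0, m * p) for p in p_raw]
    return PosthocResult(
        pairs=tuple(pairs),
        p_raw=tuple(p_raw),
        p_adjusted=tuple(p_adj),
        significant=tuple(p < alpha for p in p_adj),
        ran=gate_open,
        alpha=alpha,
    )
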