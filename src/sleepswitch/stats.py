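"""Group-level statistics: sleep/responsiveness correlations and the
condition-comparison families used throughout the study.

Conventions: all tests are two-tailed at alpha = 0.05.  Designs that allow
a parametric test are screened with Shapiro-Wilk (p < 0.05 forces the
nonparametric alternative).  Post hoc comparisons after a Friedman test use
Dunn's rank-sum z statistics with a Bonferroni-style family adjustment;
many-to-one comparisons after ANOVA use Dunnett's test against the declared
control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sst

from .errors import ContractError, InsufficientDataError

ALPHA = 0.05


@dataclass
class CorrelationResult:
    R: float
    p: float
    n: int
    window: Literal["day", "night"]
    method: str = "pearson"


def correlate_sleep_vs_responsiveness(
    sleep_min_per_hr: Sequence[float],
    peak_responsiveness: Sequence[float],
    window: Literal["day", "night"],
) -> CorrelationResult:
    """Pearson correlation (two-tailed) between per-fly sleep duration and
    per-fly peak responsiveness; flies missing either value are excluded
    listwise."""
    x = np.asarray(sleep_min_per_hr, dtype=float)
    y = np.asarray(peak_responsiveness, dtype=float)
    if x.shape != y.shape:
        raise ContractError("paired per-fly vectors must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise InsufficientDataError(f"need >= 3 complete pairs, have {len(x)}")
    r, p = sst.pearsonr(x, y)
    return CorrelationResult(R=float(r), p=float(p), n=int(len(x)), window=window)


@dataclass
class Contrast:
    label: str
    statistic: float
    p_unadjusted: float
    p: float                     # adjusted where applicable
    adjustment: str = "none"


@dataclass
class GroupComparison:
    test: str
    statistic: float
    p: float                     # omnibus (or single-test) p
    group_labels: list[str]
    group_n: list[int]
    contrasts: list[Contrast] = field(default_factory=list)
    normality_p: float | None = None
    fell_back_to: str | None = None


@dataclass
class Design:
    """Comparison family declaration.

    family:
      friedman_dunn           repeated measures, contrasts vs ``reference``
      wilcoxon_signed_rank_vs_zero   one sample vs 0
      mann_whitney            two independent groups
      paired_t                two paired groups (Shapiro screen on differences)
      unpaired_t              two independent groups (Shapiro screen per group)
      two_way_anova_dunnett   factors (group, factor2), Dunnett vs control group
    """

    family: str
    reference: str | None = None
    alpha: float = ALPHA


def _shapiro_ok(values: np.ndarray) -> tuple[bool, float]:
    if len(values) < 3 or np.allclose(values, values[0]):
        return False, float("nan")
    p = float(sst.shapiro(values).pvalue)
    return p >= ALPHA, p


def _friedman_dunn(data: dict[str, np.ndarray], reference: str) -> GroupComparison:
    labels = list(data)
    if reference not in labels:
        raise ContractError(f"reference {reference!r} not among conditions")
    mat = np.column_stack([data[k] for k in labels])
    if np.any(~np.isfinite(mat)):
        raise ContractError("friedman_dunn requires complete blocks")
    n, k = mat.shape
    if n < 2 or k < 3:
        raise InsufficientDataError("Friedman needs >= 2 subjects and >= 3 conditions")
    with np.errstate(invalid="ignore"):
        stat, p = sst.friedmanchisquare(*[mat[:, j] for j in range(k)])
    if not np.isfinite(stat):
        # fully tied blocks: no evidence of any difference
        stat, p = 0.0, 1.0
    # Dunn post hoc on within-block ranks, all conditions vs the reference
    ranks = sst.rankdata(mat, axis=1)
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    ref_j = labels.index(reference)
    others = [j for j in range(k) if j != ref_j]
    m = len(others)
    contrasts = []
    for j in others:
        z = (mean_ranks[j] - mean_ranks[ref_j]) / se
        p_un = 2.0 * sst.norm.sf(abs(z))
        contrasts.append(Contrast(
            label=f"{labels[j]} vs {reference}", statistic=float(z),
            p_unadjusted=float(p_un), p=float(min(1.0, p_un * m)),
            adjustment="dunn_bonferroni"))
    return GroupComparison(
        test="friedman_dunn", statistic=float(stat), p=float(p),
        group_labels=labels, group_n=[n] * k, contrasts=contrasts)


def _two_way_anova_dunnett(df: pd.DataFrame, reference: str) -> GroupComparison:
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    for col in ("value", "group", "factor2"):
        if col not in df.columns:
            raise ContractError("two-way ANOVA needs columns value, group, factor2")
    model = ols("value ~ C(group) * C(factor2)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    stat = float(table.loc["C(group)", "F"])
    p = float(table.loc["C(group)", "PR(>F)"])
    groups = sorted(df["group"].unique())
    if reference not in groups:
        raise ContractError(f"control group {reference!r} absent")
    treat = [g for g in groups if g != reference]
    samples = [df.loc[df["group"] == g, "value"].to_numpy() for g in treat]
    control = df.loc[df["group"] == reference, "value"].to_numpy()
    res = sst.dunnett(*samples, control=control)
    contrasts = [
        Contrast(label=f"{g} vs {reference}", statistic=float(res.statistic[i]),
                 p_unadjusted=float("nan"), p=float(res.pvalue[i]),
                 adjustment="dunnett")
        for i, g in enumerate(treat)
    ]
    return GroupComparison(
        test="two_way_anova_dunnett", statistic=stat, p=p,
        group_labels=groups,
        group_n=[int((df["group"] == g).sum()) for g in groups],
        contrasts=contrasts)


def compare_conditions(data, design: Design) -> GroupComparison:
    """Run the declared comparison family.

    ``data`` is a dict {condition: 1-D values} for most families, or a tidy
    DataFrame (value, group, factor2) for the two-way ANOVA.  Parametric
    designs fall back to the nonparametric analogue when the Shapiro-Wilk
    screen fails (p < 0.05); the fallback is recorded.
    """
    fam = design.family
    if fam == "friedman_dunn":
        if design.reference is None:
            raise ContractError("friedman_dunn needs a reference condition")
        return _friedman_dunn({k: np.asarray(v, float) for k, v in data.items()},
                              design.reference)

    if fam == "wilcoxon_signed_rank_vs_zero":
        (label, values), = data.items()
        values = np.asarray(values, float)
        if len(values) < 2 or np.allclose(values, 0):
            raise InsufficientDataError("degenerate sample for Wilcoxon")
        stat, p = sst.wilcoxon(values, alternative="two-sided")
        return GroupComparison(test=fam, statistic=float(stat), p=float(p),
                               group_labels=[label], group_n=[len(values)])

    if fam in ("mann_whitney", "unpaired_t"):
        (la, va), (lb, vb) = data.items()
        va, vb = np.asarray(va, float), np.asarray(vb, float)
        if fam == "unpaired_t":
            ok_a, pa = _shapiro_ok(va)
            ok_b, pb = _shapiro_ok(vb)
            norm_p = float(np.nanmin([pa, pb]))
            if ok_a and ok_b:
                stat, p = sst.ttest_ind(va, vb)
                return GroupComparison(test="unpaired_t", statistic=float(stat),
                                       p=float(p), group_labels=[la, lb],
                                       group_n=[len(va), len(vb)], normality_p=norm_p)
            stat, p = sst.mannwhitneyu(va, vb, alternative="two-sided")
            return GroupComparison(test="unpaired_t", statistic=float(stat),
                                   p=float(p), group_labels=[la, lb],
                                   group_n=[len(va), len(vb)], normality_p=norm_p,
                                   fell_back_to="mann_whitney")
        stat, p = sst.mannwhitneyu(va, vb, alternative="two-sided")
        return GroupComparison(test=fam, statistic=float(stat), p=float(p),
                               group_labels=[la, lb], group_n=[len(va), len(vb)])

    if fam == "paired_t":
        (la, va), (lb, vb) = data.items()
        va, vb = np.asarray(va, float), np.asarray(vb, float)
        if va.shape != vb.shape:
            raise ContractError("paired_t requires equal-length paired samples")
        ok, norm_p = _shapiro_ok(va - vb)
        if ok:
            stat, p = sst.ttest_rel(va, vb)
            return GroupComparison(test=fam, statistic=float(stat), p=float(p),
                                   group_labels=[la, lb],
                                   group_n=[len(va), len(vb)], normality_p=norm_p)
        stat, p = sst.wilcoxon(va, vb, alternative="two-sided")
        return GroupComparison(test=fam, statistic=float(stat), p=float(p),
                               group_labels=[la, lb], group_n=[len(va), len(vb)],
                               normality_p=norm_p, fell_back_to="wilcoxon")

    if fam == "two_way_anova_dunnett":
        if design.reference is None:
            raise ContractError("two_way_anova_dunnett needs a control group")
        return _two_way_anova_dunnett(data, design.reference)

    raise ContractError(f"unknown comparison family {fam!r}")
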