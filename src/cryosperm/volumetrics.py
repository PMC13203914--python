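"""Univariate stage: assumption checks, one-way ANOVA, Bonferroni post hoc.

Each holotomography-derived region volume (and any sperm-quality feature)
is analysed as a one-way layout, grouped either by treatment (does
freezing / an antioxidant change the volume?) or by donor (how large is
inter-individual variability?). Percentage features are arcsine-square-
root transformed before testing. Normality (Shapiro-Wilk, per group) and
variance homogeneity (Levene) are checked at α = 0.05; failures annotate
the result but do not divert to a nonparametric test.

Pairwise comparisons are classical Bonferroni post hoc tests: two-sample
t statistics on the ANOVA's pooled within-group variance (df = N − k),
raw p multiplied by the number of pairs and capped at 1. Significance
tiers follow the box-plot convention: ns, p ≤ 0.05, p ≤ 0.01. Welch
per-pair tests are available behind a flag.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .feature_table import (
    FeatureTable,
    METADATA_COLUMNS,
    PERCENT_FEATURES,
    SchemaError,
    arcsine_transform,
)

ALPHA = 0.05


@dataclass(frozen=True)
class GroupSummary:
    group_label: str
    n: int
    mean: float
    sd: float


@dataclass(frozen=True)
class AssumptionFlags:
    """Shapiro-Wilk per group plus one Levene homogeneity outcome.

    ``None`` p-values mean the test was untestable (group too small or
    degenerate); the corresponding flag is then also ``None``.
    """

    shapiro_p: dict
    normality_ok: dict
    levene_p: Optional[float]
    homogeneity_ok: Optional[bool]

    def to_dict(self) -> dict:
        return {
            "shapiro_p": {str(k): v for k, v in self.shapiro_p.items()},
            "normality_ok": {str(k): v for k, v in self.normality_ok.items()},
            "levene_p": self.levene_p,
            "homogeneity_ok": self.homogeneity_ok,
        }


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    ss_between: float
    ss_within: float
    ms_within: float
    assumptions: Optional[AssumptionFlags] = None

    def to_dict(self) -> dict:
        d = {
            "f_stat": self.f_stat,
            "df_between": self.df_between,
            "df_within": self.df_within,
            "p_value": self.p_value,
            "ss_between": self.ss_between,
            "ss_within": self.ss_within,
        }
        if self.assumptions is not None:
            d["assumptions"] = self.assumptions.to_dict()
        return d


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    raw_p: float
    adjusted_p: float
    tier: str  # "ns" | "p<=0.05" | "p<=0.01"


@dataclass(frozen=True)
class PairwiseTable:
    comparisons: tuple

    def lookup(self, a: str, b: str) -> PairwiseComparison:
        for c in self.comparisons:
            if {c.group_a, c.group_b} == {a, b}:
                return c
        raise KeyError(f"no comparison for pair ({a!r}, {b!r})")

    def to_dict(self) -> dict:
        return {
            "comparisons": [vars(c).copy() for c in self.comparisons]
        }


def _as_groups(groups) -> dict:
    if isinstance(groups, Mapping):
        items = groups.items()
    else:
        items = ((f"group{i}", g) for i, g in enumerate(groups))
    out = {}
    for label, values in items:
        v = np.asarray(values, dtype=float).ravel()
        out[str(label)] = v
    if any(v.size == 0 for v in out.values()):
        raise ValueError("every group must contain at least one value")
    return out


def check_assumptions(groups, alpha: float = ALPHA) -> AssumptionFlags:
    """Shapiro-Wilk normality per group and Levene variance homogeneity.

    Groups with n < 3 or zero variance are flagged untestable (``None``).
    """
    g = _as_groups(groups)
    shapiro_p, ok = {}, {}
    for label, v in g.items():
        if v.size < 3 or np.ptp(v) == 0:
            shapiro_p[label] = None
            ok[label] = None
        else:
            p = float(stats.shapiro(v).pvalue)
            shapiro_p[label] = p
            ok[label] = p >= alpha
    testable = [v for v in g.values() if v.size >= 2]
    if len(testable) >= 2 and any(np.ptp(v) > 0 for v in testable):
        lev_p = float(stats.levene(*testable, center="mean").pvalue)
        hom = lev_p >= alpha
    else:
        lev_p, hom = None, None
    return AssumptionFlags(shapiro_p, ok, lev_p, hom)


def one_way_anova(groups, with_assumptions: bool = False) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA (between/within decomposition)."""
    g = _as_groups(groups)
    k = len(g)
    if k < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    all_v = np.concatenate(list(g.values()))
    n = all_v.size
    if n <= k:
        raise ValueError("total N must exceed the number of groups")
    grand = all_v.mean()
    ss_between = float(sum(v.size * (v.mean() - grand) ** 2 for v in g.values()))
    ss_within = float(sum(((v - v.mean()) ** 2).sum() for v in g.values()))
    df_b, df_w = k - 1, n - k
    ms_w = ss_within / df_w
    if ms_w == 0.0:
        # degenerate: no within-group variance; F defined as 0 when the
        # between variance is also 0, infinite otherwise
        f = 0.0 if ss_between == 0.0 else math.inf
        p = 1.0 if ss_between == 0.0 else 0.0
    else:
        f = (ss_between / df_b) / ms_w
        p = float(stats.f.sf(f, df_b, df_w))
    flags = check_assumptions(g) if with_assumptions else None
    return AnovaResult(f, df_b, df_w, p, ss_between, ss_within, ms_w, flags)


def _tier(adjusted_p: float) -> str:
    if adjusted_p <= 0.01:
        return "p<=0.01"
    if adjusted_p <= 0.05:
        return "p<=0.05"
    return "ns"


def bonferroni_pairwise(groups, welch: bool = False) -> PairwiseTable:
    """All-pairs t tests with Bonferroni adjustment over k(k−1)/2 pairs."""
    g = _as_groups(groups)
    labels = list(g)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    m = len(labels) * (len(labels) - 1) // 2
    if not welch:
        anova = one_way_anova(g)
    comparisons = []
    for a, b in itertools.combinations(labels, 2):
        va, vb = g[a], g[b]
        if welch:
            raw = float(stats.ttest_ind(va, vb, equal_var=False).pvalue)
        else:
            se = math.sqrt(anova.ms_within * (1 / va.size + 1 / vb.size))
            if se == 0.0:
                raw = 1.0 if va.mean() == vb.mean() else 0.0
            else:
                t = (va.mean() - vb.mean()) / se
                raw = 2 * float(stats.t.sf(abs(t), anova.df_within))
        adj = min(1.0, raw * m)
        comparisons.append(PairwiseComparison(a, b, raw, adj, _tier(adj)))
    return PairwiseTable(tuple(comparisons))


@dataclass(frozen=True)
class RegionAnalysis:
    feature: str
    grouping: str
    summaries: tuple
    anova: AnovaResult
    pairwise: PairwiseTable

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "grouping": self.grouping,
            "groups": [vars(s).copy() for s in self.summaries],
            "anova": self.anova.to_dict(),
            "pairwise": self.pairwise.to_dict(),
        }


def region_analysis(table: FeatureTable, feature: str, grouping: str = "treatment") -> RegionAnalysis:
    """Group summaries + ANOVA + Bonferroni table for one feature.

    ``grouping='treatment'`` reproduces the treatment-contrast pathway,
    ``grouping='donor_id'`` the inter-individual-variability pathway.
    Percentage features are arcsine-transformed before testing (summaries
    stay on the raw scale).
    """
    if grouping not in METADATA_COLUMNS:
        raise SchemaError(f"grouping must be one of {METADATA_COLUMNS}")
    values = np.asarray(table.column(feature), dtype=float)
    labels = table.labels(grouping)
    order = list(dict.fromkeys(labels))  # first-appearance order
    raw_groups = {str(g): values[labels == g] for g in order}
    summaries = tuple(
        GroupSummary(g, int(v.size), float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else 0.0)
        for g, v in raw_groups.items()
    )
    if feature in PERCENT_FEATURES:
        test_groups = {g: arcsine_transform(v) for g, v in raw_groups.items()}
    else:
        test_groups = raw_groups
    anova = one_way_anova(test_groups, with_assumptions=True)
    pairwise = bonferroni_pairwise(test_groups)
    return RegionAnalysis(feature, grouping, summaries, anova, pairwise)
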