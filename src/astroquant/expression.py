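"""Expression scores, relative quantification, and the group-statistics ladder.

Three bespoke pieces of arithmetic used throughout the study, plus the
normality-gated statistical decision ladder:

* gene set score — per-sample average of gene-wise mean-centered normalized
  expression over a marker panel: c_ij = e_ij - mean_j(e_ij),
  S_j = mean_i(c_ij).  Scores sum to zero across samples by construction.
* 2^-ddCt relative quantification — target Ct normalized to a housekeeping
  gene (GAPDH role) per sample, then to the mean dCt of a reference group.
* fold-change / percent-change helpers with half-up decimal rounding, used
  to reproduce ratio-of-group-means summaries.
* compare_groups — Shapiro-Wilk normality gate, then t-test / one-way ANOVA
  with Tukey post-hoc (parametric branch) or Mann-Whitney / Kruskal-Wallis
  with Dunn-Bonferroni post-hoc (nonparametric branch); paired designs use
  the paired t-test or the Wilcoxon signed-rank test.  Significance stars
  follow the usual mapping (* p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ExpressionMatrix:
    """Normalized expression values e_ij, genes x samples."""

    e: pd.DataFrame  # index: gene ids, columns: sample ids

    def __post_init__(self):
        if self.e.index.has_duplicates or self.e.columns.has_duplicates:
            raise ValueError("gene and sample ids must be unique")

    @property
    def ng(self) -> int:
        return self.e.shape[0]

    @property
    def ns(self) -> int:
        return self.e.shape[1]

    @property
    def gene_ids(self) -> list:
        return list(self.e.index)

    @property
    def sample_ids(self) -> list:
        return list(self.e.columns)


@dataclass(frozen=True)
class GeneSetScoreResult:
    scores: pd.Series  # S_j per sample
    centered: pd.DataFrame  # c_ij


@dataclass(frozen=True)
class CtTable:
    """Raw qPCR cycle-threshold values with housekeeping and grouping info."""

    ct: pd.DataFrame  # genes x samples
    housekeeping: str
    groups: pd.Series  # sample -> group label

    def __post_init__(self):
        if self.housekeeping not in self.ct.index:
            raise ValueError(
                f"housekeeping gene {self.housekeeping!r} missing from Ct table"
            )
        hk = self.ct.loc[self.housekeeping]
        if hk.isna().any() or not np.isfinite(hk.to_numpy(dtype=float)).all():
            raise ValueError("housekeeping Ct must be finite for every sample")
        missing = [s for s in self.ct.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without group label: {missing}")


def gene_set_score(matrix: ExpressionMatrix | pd.DataFrame) -> GeneSetScoreResult:
    """Per-sample score of a gene panel from mean-centered expression.

    c_ij = e_ij - (1/ns) * sum_j e_ij ;  S_j = (1/ng) * sum_i c_ij
    """
    e = matrix.e if isinstance(matrix, ExpressionMatrix) else matrix
    if e.shape[0] < 1 or e.shape[1] < 1:
        raise ValueError("need at least one gene and one sample")
    if e.isna().any().any():
        bad = [
            (g, s)
            for g in e.index
            for s in e.columns
            if pd.isna(e.loc[g, s])
        ]
        raise ValueError(f"missing expression values at (gene, sample): {bad}")
    centered = e.sub(e.mean(axis=1), axis=0)
    scores = centered.mean(axis=0)
    scores.name = "gene_set_score"
    return GeneSetScoreResult(scores=scores, centered=centered)


def ddct_fold(
    table: CtTable, target_gene: str, reference_group: str
) -> pd.Series:
    """Relative expression per sample by the comparative 2^-ddCt method.

    dCt_j = Ct(target)_j - Ct(housekeeping)_j; ddCt_j = dCt_j minus the
    arithmetic mean dCt of the reference group; fold_j = 2^-ddCt_j.
    """
    if target_gene not in table.ct.index:
        raise ValueError(f"target gene {target_gene!r} missing from Ct table")
    dct = table.ct.loc[target_gene] - table.ct.loc[table.housekeeping]
    if dct.isna().any():
        bad = list(dct.index[dct.isna()])
        raise ValueError(f"missing Ct for samples: {bad}")
    ref_samples = [s for s in table.ct.columns if table.groups[s] == reference_group]
    if not ref_samples:
        raise ValueError(f"reference group {reference_group!r} has no samples")
    ddct = dct - dct[ref_samples].mean()
    fold = np.power(2.0, -ddct)
    fold.name = f"fold_{target_gene}"
    return fold


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def fold_change(mean_a: float, mean_b: float, decimals: int | None = None) -> float:
    """Ratio of group means a/b, optionally rounded half-up to ``decimals``."""
    if mean_b <= 0:
        raise ValueError(f"denominator mean must be > 0, got {mean_b}")
    ratio = mean_a / mean_b
    return ratio if decimals is None else _round_half_up(ratio, decimals)


def percent_change(before: float, after: float, decimals: int | None = None) -> float:
    """Percentage increase from ``before`` to ``after``."""
    if before <= 0:
        raise ValueError(f"baseline must be > 0, got {before}")
    pct = 100.0 * (after - before) / before
    return pct if decimals is None else _round_half_up(pct, decimals)


# ---------------------------------------------------------------------------
# group comparison ladder

STAR_LEVELS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def p_to_stars(p: float) -> str:
    for cut, stars in STAR_LEVELS:
        if p < cut:
            return stars
    return "ns"


@dataclass(frozen=True)
class GroupComparisonResult:
    test_name: str
    statistic: float
    p_value: float
    stars: str
    normality_p: tuple  # Shapiro-Wilk p per group (of the differences when paired)
    branch: str  # "parametric" | "nonparametric" | "paired"
    posthoc: pd.DataFrame | None = None
    warnings: tuple = ()


def _dunn_bonferroni(groups: Sequence[np.ndarray], labels: Sequence[str]) -> pd.DataFrame:
    """Dunn's rank-based multiple comparisons with Bonferroni adjustment."""
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes, idx = [], [], 0
    for g in groups:
        mean_ranks.append(ranks[idx : idx + len(g)].mean())
        sizes.append(len(g))
        idx += len(g)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    m = len(groups) * (len(groups) - 1) // 2
    rows = []
    for i, j in combinations(range(len(groups)), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "statistic": z,
                "p_adj": min(1.0, p * m),
            }
        )
    return pd.DataFrame(rows)


def compare_groups(
    groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
    paired: bool = False,
    alpha: float = 0.05,
    normality_alpha: float = 0.05,
) -> GroupComparisonResult:
    """Normality-gated group comparison with post-hoc tests and stars.

    Each group passes through the Shapiro-Wilk test; if every group is
    compatible with normality (p >= ``normality_alpha``) the parametric
    branch is taken (t-test for two groups, one-way ANOVA with Tukey's HSD
    beyond two), otherwise the nonparametric branch (Mann-Whitney U, or
    Kruskal-Wallis with Dunn-Bonferroni).  Paired two-group designs gate on
    the pairwise differences and use the paired t-test or the Wilcoxon
    signed-rank test.  Groups smaller than 3 force the nonparametric branch
    (Shapiro-Wilk is undefined there) with a warning.
    """
    if isinstance(groups, Mapping):
        labels = list(groups.keys())
        data = [np.asarray(groups[k], dtype=float) for k in labels]
    else:
        data = [np.asarray(g, dtype=float) for g in groups]
        labels = [f"group{i + 1}" for i in range(len(data))]
    if len(data) < 2:
        raise ValueError("need at least two groups")
    notes: list = []

    if paired:
        if len(data) != 2:
            raise ValueError("paired comparison requires exactly two groups")
        a, b = data
        if len(a) != len(b):
            raise ValueError("paired groups must have equal length")
        diffs = a - b
        if len(diffs) < 3:
            normal, norm_p = False, (float("nan"),)
            notes.append("fewer than 3 pairs; Wilcoxon forced")
        else:
            sw = stats.shapiro(diffs)
            norm_p = (float(sw.pvalue),)
            normal = sw.pvalue >= normality_alpha
        if normal:
            res = stats.ttest_rel(a, b)
            name = "paired t-test"
        else:
            res = stats.wilcoxon(a, b)
            name = "Wilcoxon signed-rank"
        p = float(res.pvalue)
        return GroupComparisonResult(
            test_name=name,
            statistic=float(res.statistic),
            p_value=p,
            stars=p_to_stars(p),
            normality_p=norm_p,
            branch="paired",
            warnings=tuple(notes),
        )

    small = [lbl for lbl, g in zip(labels, data) if len(g) < 3]
    if small:
        notes.append(
            f"groups below n=3 ({small}); normality gate skipped, "
            "nonparametric branch forced"
        )
        warnings.warn(notes[-1], RuntimeWarning, stacklevel=2)
        normal = False
        norm_p = tuple(float("nan") for _ in data)
    else:
        shapiro_ps = []
        for g in data:
            if np.ptp(g) == 0:  # constant group: not normal, Shapiro undefined
                shapiro_ps.append(0.0)
            else:
                shapiro_ps.append(float(stats.shapiro(g).pvalue))
        norm_p = tuple(shapiro_ps)
        normal = all(p >= normality_alpha for p in shapiro_ps)

    posthoc = None
    if normal:
        branch = "parametric"
        if len(data) == 2:
            res = stats.ttest_ind(data[0], data[1])
            name = "t-test"
        else:
            res = stats.f_oneway(*data)
            name = "one-way ANOVA"
            tk = stats.tukey_hsd(*data)
            rows = []
            for i, j in combinations(range(len(data)), 2):
                rows.append(
                    {
                        "group_a": labels[i],
                        "group_b": labels[j],
                        "statistic": float(tk.statistic[i, j]),
                        "p_adj": float(tk.pvalue[i, j]),
                    }
                )
            posthoc = pd.DataFrame(rows)
            name += " + Tukey"
    else:
        branch = "nonparametric"
        if len(data) == 2:
            if all(np.ptp(g) == 0 for g in data) and np.ptp(
                np.concatenate(data)
            ) == 0:
                # identical constant groups: no evidence of difference
                return GroupComparisonResult(
                    test_name="Mann-Whitney U",
                    statistic=float(len(data[0]) * len(data[1]) / 2.0),
                    p_value=1.0,
                    stars="ns",
                    normality_p=norm_p,
                    branch=branch,
                    warnings=tuple(notes),
                )
            res = stats.mannwhitneyu(data[0], data[1], alternative="two-sided")
            name = "Mann-Whitney U"
        else:
            res = stats.kruskal(*data)
            name = "Kruskal-Wallis + Dunn"
            posthoc = _dunn_bonferroni(data, labels)

    p = float(res.pvalue)
    return GroupComparisonResult(
        test_name=name,
        statistic=float(res.statistic),
        p_value=p,
        stars=p_to_stars(p),
        normality_p=norm_p,
        branch=branch,
        posthoc=posthoc,
        warnings=tuple(notes),
    )


def rank_list(statistics: pd.Series) -> pd.DataFrame:
    """Gene/statistic table sorted for preranked enrichment (.rnk convention)."""
    df = statistics.sort_values(ascending=False).reset_index()
    df.columns = ["gene", "statistic"]
    return df
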