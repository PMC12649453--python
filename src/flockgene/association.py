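"""Genotype–litter-size association with compact-letter display.

Per locus, animals are grouped by genotype class; groups with fewer
than ``min_group_n`` animals are summarized but never tested. Eligible
groups enter a classical fixed-effects one-way ANOVA, followed by
unadjusted pairwise comparisons using the pooled within-group variance
(Fisher's LSD) by default — Welch, Bonferroni-adjusted LSD and Tukey HSD
are available as options. Significance is rendered as a compact letter
display at two thresholds independently: lowercase letters at the
"significant" alpha (default 0.05) and uppercase at the "highly
significant" alpha (default 0.01); groups sharing no letter differ at
that threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import Cohort

__all__ = [
    "GenotypeGroup",
    "AssociationTable",
    "group_summaries",
    "anova_oneway",
    "pairwise_comparisons",
    "letter_display",
    "associate_locus",
    "associate_all",
    "association_frame",
]


@dataclass(frozen=True)
class GenotypeGroup:
    locus_id: str
    genotype: str
    n: int
    mean: float
    sd: float
    letters_05: str = ""
    letters_01: str = ""
    tested: bool = True


@dataclass(frozen=True)
class AssociationTable:
    locus_id: str
    groups: tuple[GenotypeGroup, ...]
    anova_F: float
    anova_p: float
    excluded_groups: tuple[str, ...] = ()
    testable: bool = True


def _group_vectors(cohort: Cohort, locus_id: str) -> dict[str, np.ndarray]:
    df = cohort.litter_sizes(locus_id)
    if len(df) == 0:
        raise ValueError(f"{locus_id}: no typed animals with phenotypes")
    labels = cohort.locus(locus_id).genotype_labels
    out: dict[str, np.ndarray] = {}
    for label in labels:  # fixed ref_hom/het/alt_hom order
        vals = df.loc[df["genotype"] == label, "litter_size"].to_numpy(dtype=float)
        if len(vals) > 0:
            out[label] = vals
    return out


def group_summaries(cohort: Cohort, locus_id: str) -> list[GenotypeGroup]:
    """n, mean and sample SD (n-1 denominator) of litter size per
    observed genotype class."""
    groups = _group_vectors(cohort, locus_id)
    return [
        GenotypeGroup(
            locus_id=locus_id,
            genotype=label,
            n=len(v),
            mean=float(v.mean()),
            sd=float(v.std(ddof=1)) if len(v) > 1 else 0.0,
        )
        for label, v in groups.items()
    ]


def anova_oneway(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA (F, p) by direct sums of
    squares. With zero within- and between-group variance the F is 0
    and p is 1 (identical groups carry no evidence)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = len(all_vals) - len(groups)
    if df_within < 1:
        raise ValueError("ANOVA needs residual degrees of freedom")
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    F = (ss_between / df_between) / (ss_within / df_within)
    return float(F), float(stats.f.sf(F, df_between, df_within))


def _pooled_mse(groups: Sequence[np.ndarray]) -> tuple[float, int]:
    ss = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df = sum(len(g) - 1 for g in groups)
    return ss / df, df


def pairwise_comparisons(
    groups: Mapping[str, np.ndarray],
    method: str = "lsd",
) -> pd.DataFrame:
    """Symmetric matrix of two-sided pairwise p-values.

    ``lsd`` (default) uses the pooled within-group variance across all
    eligible groups with its full residual degrees of freedom;
    ``welch`` uses per-pair unequal-variance t tests;
    ``bonferroni`` multiplies LSD p-values by the number of pairs;
    ``tukey`` uses the studentized-range (Tukey HSD) distribution.
    """
    labels = list(groups)
    vecs = [np.asarray(groups[k], dtype=float) for k in labels]
    k = len(labels)
    pmat = pd.DataFrame(np.ones((k, k)), index=labels, columns=labels)
    if k < 2:
        return pmat
    n_pairs = k * (k - 1) // 2
    mse, df_w = _pooled_mse(vecs)
    for (i, gi), (j, gj) in combinations(enumerate(vecs), 2):
        diff = gi.mean() - gj.mean()
        if method in ("lsd", "bonferroni"):
            if mse == 0.0:
                p = 1.0 if diff == 0 else 0.0
            else:
                se = np.sqrt(mse * (1 / len(gi) + 1 / len(gj)))
                p = 2 * stats.t.sf(abs(diff) / se, df_w)
            if method == "bonferroni":
                p = min(1.0, p * n_pairs)
        elif method == "welch":
            vi, vj = gi.var(ddof=1) / len(gi), gj.var(ddof=1) / len(gj)
            if vi + vj == 0.0:
                p = 1.0 if diff == 0 else 0.0
            else:
                t = abs(diff) / np.sqrt(vi + vj)
                df = (vi + vj) ** 2 / (
                    vi**2 / (len(gi) - 1) + vj**2 / (len(gj) - 1)
                )
                p = 2 * stats.t.sf(t, df)
        elif method == "tukey":
            if mse == 0.0:
                p = 1.0 if diff == 0 else 0.0
            else:
                se = np.sqrt(mse / 2 * (1 / len(gi) + 1 / len(gj)))
                p = stats.studentized_range.sf(abs(diff) / se, k, df_w)
        else:
            raise ValueError(f"unknown pairwise method {method!r}")
        pmat.iloc[i, j] = pmat.iloc[j, i] = float(min(1.0, p))
    return pmat


def letter_display(
    pvalues: pd.DataFrame,
    alpha: float,
    means: Optional[Mapping[str, float]] = None,
    uppercase: bool = False,
) -> dict[str, str]:
    """Compact letter display by the insert-and-absorb algorithm.

    Groups are processed in descending-mean order (ties broken by group
    label) so the first letter lands on the largest mean. Two groups
    share at least one letter iff their pairwise p-value is >= alpha.
    """
    labels = list(pvalues.index)
    if means is not None:
        labels.sort(key=lambda g: (-means[g], g))
    # letter columns: each a set of group labels sharing that letter
    columns: list[set[str]] = [set(labels)]
    for gi, gj in combinations(labels, 2):
        if pvalues.loc[gi, gj] >= alpha:
            continue
        new_columns: list[set[str]] = []
        for col in columns:
            if gi in col and gj in col:
                a, b = set(col), set(col)
                a.discard(gj)
                b.discard(gi)
                new_columns.extend([a, b])
            else:
                new_columns.append(col)
        # absorb columns that are subsets of others
        new_columns.sort(key=len, reverse=True)
        kept: list[set[str]] = []
        for col in new_columns:
            if not any(col <= other for other in kept):
                kept.append(col)
        columns = kept
    # order columns by the rank of their top group for stable letters
    rank = {g: i for i, g in enumerate(labels)}
    columns.sort(key=lambda col: min(rank[g] for g in col))
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ" if uppercase else "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in labels}
    for letter, col in zip(alphabet, columns):
        for g in col:
            out[g] += letter
    return {g: "".join(sorted(v)) for g, v in out.items()}


def associate_locus(
    cohort: Cohort,
    locus_id: str,
    min_group_n: int = 3,
    alpha_significant: float = 0.05,
    alpha_highly: float = 0.01,
    method: str = "lsd",
) -> AssociationTable:
    """Association analysis for one locus (summaries, ANOVA, letters)."""
    vectors = _group_vectors(cohort, locus_id)
    eligible = {g: v for g, v in vectors.items() if len(v) >= min_group_n}
    excluded = tuple(g for g in vectors if g not in eligible)

    testable = len(eligible) >= 2
    if testable:
        F, p = anova_oneway(list(eligible.values()))
        pmat = pairwise_comparisons(eligible, method=method)
        means = {g: float(v.mean()) for g, v in eligible.items()}
        low = letter_display(pmat, alpha_significant, means, uppercase=False)
        high = letter_display(pmat, alpha_highly, means, uppercase=True)
    else:
        F, p = float("nan"), float("nan")
        low, high = {}, {}

    groups = tuple(
        GenotypeGroup(
            locus_id=locus_id,
            genotype=g,
            n=len(v),
            mean=float(v.mean()),
            sd=float(v.std(ddof=1)) if len(v) > 1 else 0.0,
            letters_05=low.get(g, ""),
            letters_01=high.get(g, ""),
            tested=g in eligible and testable,
        )
        for g, v in vectors.items()
    )
    return AssociationTable(
        locus_id=locus_id,
        groups=groups,
        anova_F=F,
        anova_p=p,
        excluded_groups=excluded,
        testable=testable,
    )


def associate_all(cohort: Cohort, **kwargs) -> list[AssociationTable]:
    """Association tables for every locus of the panel."""
    return [associate_locus(cohort, loc.id, **kwargs) for loc in cohort.loci]


def association_frame(tables: Sequence[AssociationTable]) -> pd.DataFrame:
    """Flatten association tables into one report row per genotype group."""
    rows = []
    for tab in tables:
        for grp in tab.groups:
            rows.append(
                {
                    "locus": tab.locus_id,
                    "genotype": grp.genotype,
                    "n": grp.n,
                    "mean": grp.mean,
                    "sd": grp.sd,
                    "letters05": grp.letters_05,
                    "letters01": grp.letters_01,
                    "tested": grp.tested,
                    "anova_F": tab.anova_F,
                    "anova_p": tab.anova_p,
                }
            )
    return pd.DataFrame(rows)
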