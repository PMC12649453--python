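"""Relative gene expression by the 2^-ddCt method.

Replicate Ct values are averaged arithmetically per sample/gene, then

* dCt  = mean Ct(target) - mean Ct(reference)
* ddCt = dCt(sample) - mean dCt over the calibrator group
* fold = 2^-ddCt

assuming a doubling of template per cycle. Group contrasts reuse the
ANOVA + compact-letter machinery of :mod:`flockgene.association`,
computed on -ddCt (log2 fold) by default since fold ratios are
log-normal; a flag switches to the fold scale. Two-factor panels are
lettered within each level of the conditioning factor (e.g. capitals
across stages within a tissue, lowercase across tissues within a stage).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .association import anova_oneway, letter_display, pairwise_comparisons
from .model import CtRecord

__all__ = [
    "RelativeExpression",
    "relative_expression",
    "expression_frame",
    "expression_contrasts",
]

log = logging.getLogger("flockgene")


@dataclass(frozen=True)
class RelativeExpression:
    sample_id: str
    group: str
    gene: str
    dct: float
    ddct: float
    fold: float


def relative_expression(
    ct_records: Iterable[CtRecord],
    target_gene: str,
    reference_gene: str,
    calibrator_group: str,
) -> list[RelativeExpression]:
    """Per-sample fold change of ``target_gene`` over ``reference_gene``
    relative to the mean dCt of ``calibrator_group``.

    Samples missing the reference gene are dropped with a warning; an
    empty calibrator group is an error.
    """
    by_sample: dict[str, dict[str, CtRecord]] = {}
    groups: dict[str, str] = {}
    for rec in ct_records:
        if rec.gene not in (target_gene, reference_gene):
            continue
        by_sample.setdefault(rec.sample_id, {})[rec.gene] = rec
        groups[rec.sample_id] = rec.group

    dcts: dict[str, float] = {}
    for sample, genes in sorted(by_sample.items()):
        if target_gene not in genes:
            continue
        if reference_gene not in genes:
            log.warning(
                "sample %s lacks reference gene %s — dropped", sample, reference_gene
            )
            continue
        dcts[sample] = genes[target_gene].mean_ct - genes[reference_gene].mean_ct

    calib = [d for s, d in dcts.items() if groups[s] == calibrator_group]
    if not calib:
        raise ValueError(f"calibrator group {calibrator_group!r} has no usable samples")
    calib_mean = float(np.mean(calib))

    out = []
    for sample, dct in dcts.items():
        ddct = dct - calib_mean
        out.append(
            RelativeExpression(
                sample_id=sample,
                group=groups[sample],
                gene=target_gene,
                dct=dct,
                ddct=ddct,
                fold=float(2.0 ** (-ddct)),
            )
        )
    return out


def expression_frame(expr: Sequence[RelativeExpression]) -> pd.DataFrame:
    frame = pd.DataFrame(
        [
            {
                "sample_id": e.sample_id,
                "group": e.group,
                "gene": e.gene,
                "dct": e.dct,
                "ddct": e.ddct,
                "fold": e.fold,
            }
            for e in expr
        ]
    )
    return frame


def expression_contrasts(
    expr: Sequence[RelativeExpression] | pd.DataFrame,
    factor: str = "group",
    within: Optional[str] = None,
    scale: str = "log",
    alpha: float = 0.05,
    method: str = "lsd",
    min_group_n: int = 2,
) -> pd.DataFrame:
    """Grouped expression summaries with significance letters.

    Compares levels of ``factor``; if ``within`` is given (a second
    factor column), letters are computed independently within each of
    its levels. ``scale="log"`` tests -ddCt (log2 fold); ``scale="fold"``
    tests the fold values directly.
    """
    frame = expr if isinstance(expr, pd.DataFrame) else expression_frame(expr)
    if scale == "log":
        frame = frame.assign(_value=-frame["ddct"])
    elif scale == "fold":
        frame = frame.assign(_value=frame["fold"])
    else:
        raise ValueError(f"unknown scale {scale!r}")

    def _one_layout(sub: pd.DataFrame) -> pd.DataFrame:
        groups = {
            str(lvl): g["_value"].to_numpy()
            for lvl, g in sub.groupby(factor, sort=True)
        }
        eligible = {k: v for k, v in groups.items() if len(v) >= min_group_n}
        letters: dict[str, str] = {}
        anova_p = float("nan")
        if len(eligible) >= 2:
            _, anova_p = anova_oneway(list(eligible.values()))
            pmat = pairwise_comparisons(eligible, method=method)
            means = {k: float(v.mean()) for k, v in eligible.items()}
            letters = letter_display(pmat, alpha, means)
        rows = []
        for lvl, vals in groups.items():
            rows.append(
                {
                    factor: lvl,
                    "n": len(vals),
                    "mean_log2_fold" if scale == "log" else "mean_fold": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                    "mean_fold_display": float(2.0 ** vals.mean())
                    if scale == "log"
                    else float(vals.mean()),
                    "letters": letters.get(lvl, ""),
                    "anova_p": anova_p,
                }
            )
        return pd.DataFrame(rows)

    if within is None:
        return _one_layout(frame)
    parts = []
    for lvl, sub in frame.groupby(within, sort=True):
        part = _one_layout(sub)
        part.insert(0, within, lvl)
        parts.append(part)
    return pd.concat(parts, ignore_index=True)
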