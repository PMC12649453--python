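"""Cohort-level reproductive performance metrics.

Definitions (all on mated ewes unless stated):

* fertility    = lambed ewes / mated ewes x 100 (%)
* fecundity    = total live-born lambs / mated ewes x 100 (%)
* lambs per ewe = mean +/- SD of litter size over lambed ewes
* prolificacy  = share of lambed ewes delivering two or more lambs (%)
  (the mean lambs per lambed ewe is also reported, as
  ``lambs_per_ewe_mean``, because the term is used both ways in the
  livestock literature)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .model import PhenotypeRecord

__all__ = ["ReproSummary", "summarize_reproduction"]


@dataclass(frozen=True)
class ReproSummary:
    n_mated: int
    n_lambed: int
    total_lambs: int
    fertility_pct: float
    fecundity_pct: float
    lambs_per_ewe_mean: float
    lambs_per_ewe_sd: float
    prolificacy_pct: float
    litter_distribution: tuple[tuple[int, int], ...]  # (litter size, count)


def summarize_reproduction(
    phenotypes: Sequence[PhenotypeRecord] | Iterable[PhenotypeRecord],
    n_mated: int,
) -> ReproSummary:
    """Reproductive parameters of a cohort of lambing records.

    ``n_mated`` may exceed the number of records (ewes that did not
    lamb carry no record); it must be positive and at least the number
    of lambed ewes.
    """
    records = list(phenotypes)
    if n_mated < 1:
        raise ValueError("n_mated must be >= 1")
    if n_mated < len(records):
        raise ValueError(
            f"n_mated ({n_mated}) smaller than number of lambing records ({len(records)})"
        )
    sizes = np.array([r.litter_size for r in records], dtype=float)
    n_lambed = len(sizes)
    total = int(sizes.sum())
    dist: dict[int, int] = {}
    for s in sizes.astype(int):
        dist[s] = dist.get(s, 0) + 1
    return ReproSummary(
        n_mated=n_mated,
        n_lambed=n_lambed,
        total_lambs=total,
        fertility_pct=100.0 * n_lambed / n_mated,
        fecundity_pct=100.0 * total / n_mated,
        lambs_per_ewe_mean=float(sizes.mean()) if n_lambed else 0.0,
        lambs_per_ewe_sd=float(sizes.std(ddof=1)) if n_lambed > 1 else 0.0,
        prolificacy_pct=100.0 * float((sizes >= 2).sum()) / n_lambed if n_lambed else 0.0,
        litter_distribution=tuple(sorted(dist.items())),
    )
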