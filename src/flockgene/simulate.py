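"""Synthetic cohorts, Ct panels, and the published-table fixture.

Two roles:

1. A seedable generator producing cohorts with the statistical
   structure the analysis assumes — biallelic genotypes sampled under
   Hardy–Weinberg proportions (or from two-locus haplotype frequencies
   for linked pairs), binary litter sizes (1 or 2) with
   genotype-dependent twin probability, and triplicate Ct panels with
   Gaussian technical noise.

2. A deterministic reconstruction of the published 157-ewe cohort, one
   locus at a time: genotype class sizes are taken from the published
   association table and the number of twin-bearing ewes per class is
   recovered by integer inversion of the printed group means under the
   constraints that litter sizes are binary and the cohort totals 79
   twin litters (236 lambs). The eight loci cannot be reconstructed
   jointly — joint genotypes were never published — so fixtures are
   single-locus cohorts; multi-locus behaviour is covered by the
   simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import Cohort, Locus

__all__ = [
    "SimulatedLocus",
    "LDPairSpec",
    "SimulationConfig",
    "simulate_cohort",
    "sample_genotype_counts",
    "simulate_ct_panel",
    "PAPER_PANEL",
    "COHORT_SIZE",
    "COHORT_TWIN_LITTERS",
    "COHORT_TOTAL_LAMBS",
    "twin_composition",
    "reconstruct_paper_cohort",
]

# --------------------------------------------------------------------------
# published fixture inputs: per-locus genotype class sizes and printed
# group means (litter size) from the 157-ewe association table, plus the
# cohort totals (78 single + 79 twin litters = 236 lambs).
# --------------------------------------------------------------------------

COHORT_SIZE = 157
COHORT_TWIN_LITTERS = 79
COHORT_SINGLE_LITTERS = 78
COHORT_TOTAL_LAMBS = 236


@dataclass(frozen=True)
class PaperLocus:
    """Published per-locus inputs: class sizes and printed group means."""

    locus: Locus
    counts: tuple[int, int, int]  # ref_hom, het, alt_hom class sizes
    printed_means: tuple[Optional[float], Optional[float], Optional[float]]


def _pl(label: str, counts: tuple[int, int, int], means) -> PaperLocus:
    return PaperLocus(Locus.from_label(label), counts, tuple(means))


PAPER_PANEL: dict[str, PaperLocus] = {
    pl.locus.id: pl
    for pl in [
        _pl("g.18202368 A>T", (150, 7, 0), (1.52, 1.14, None)),
        _pl("g.18202372 G>A", (92, 59, 6), (1.27, 1.83, 1.83)),
        _pl("g.18202426 C>T", (112, 40, 5), (1.47, 1.56, 1.80)),
        _pl("g.18202431 G>C", (137, 20, 0), (1.47, 1.75, None)),
        _pl("g.18202439 C>T", (146, 11, 0), (1.49, 1.73, None)),
        _pl("g.18202451 C>T", (149, 8, 0), (1.49, 1.75, None)),
        _pl("g.18202467 T>A", (150, 7, 0), (1.51, 1.29, None)),
        _pl("g.18202472 G>C", (92, 59, 6), (1.41, 1.61, 1.83)),
    ]
}


def _round_half_up(x: float, nd: int) -> float:
    scale = 10**nd
    return math.floor(x * scale + 0.5) / scale


def twin_composition(locus_id: str) -> tuple[tuple[int, ...], bool]:
    """Twin-bearing ewes per genotype class by integer inversion.

    For each class of size ``n`` with printed mean ``m``, the candidate
    twin counts are the integers ``t`` with ``1 + t/n`` rounding to
    ``m`` at two decimals; the returned composition is the candidate
    combination whose twin total is 79. If no exact combination exists
    (one published cell admits no exact inversion) the closest
    composition consistent with the cohort twin total is returned and
    the second element of the result is False.
    """
    if locus_id not in PAPER_PANEL:
        raise KeyError(f"unknown fixture locus {locus_id!r}")
    pl = PAPER_PANEL[locus_id]
    sizes = [n for n in pl.counts if n > 0]
    means = [m for n, m in zip(pl.counts, pl.printed_means) if n > 0]
    exact_sets = []
    for n, m in zip(sizes, means):
        cands = [t for t in range(n + 1) if _round_half_up(1 + t / n, 2) == m]
        exact_sets.append(cands)

    def combos(sets):
        for tup in product(*sets):
            if sum(tup) == COHORT_TWIN_LITTERS:
                yield tup

    exact_combos = list(combos(exact_sets))
    if exact_combos:
        # unique in practice; deterministic tie-break just in case
        return min(exact_combos), True
    # relax classes with no exact candidate to their full range and pick
    # the combination minimizing total deviation from the printed means
    relaxed = [c if c else list(range(n + 1)) for c, n in zip(exact_sets, sizes)]
    best = min(
        combos(relaxed),
        key=lambda tup: (
            sum(abs(1 + t / n - m) for t, n, m in zip(tup, sizes, means)),
            tup,
        ),
    )
    return best, False


def reconstruct_paper_cohort(locus_id: str) -> Cohort:
    """Deterministic 157-ewe single-locus cohort matching the published
    class sizes and (where exactly invertible) group means."""
    pl = PAPER_PANEL[locus_id]
    twins, _ = twin_composition(locus_id)
    locus = pl.locus
    labels = locus.genotype_labels
    genos: list[str] = []
    litters: list[int] = []
    k = 0
    for cls, n in enumerate(pl.counts):
        if n == 0:
            continue
        t = twins[k]
        k += 1
        r, a = locus.ref_allele, locus.alt_allele
        geno = (f"{r}/{r}", f"{r}/{a}", f"{a}/{a}")[cls]
        genos.extend([geno] * n)
        litters.extend([2] * t + [1] * (n - t))
    ids = [f"E{i:03d}" for i in range(1, COHORT_SIZE + 1)]
    genotypes = pd.DataFrame({locus.id: genos}, index=pd.Index(ids, name="animal_id"))
    phenotypes = pd.DataFrame(
        {"litter_size": litters}, index=pd.Index(ids, name="animal_id")
    )
    return Cohort(loci=[locus], genotypes=genotypes, phenotypes=phenotypes)


# --------------------------------------------------------------------------
# forward simulation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulatedLocus:
    locus: Locus
    p_ref: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_ref <= 1.0):
            raise ValueError(f"{self.locus.id}: p_ref outside [0, 1]")


@dataclass(frozen=True)
class LDPairSpec:
    """Two loci simulated jointly from haplotype frequencies
    (AB, Ab, aB, ab; uppercase = reference allele)."""

    locus_a: Locus
    locus_b: Locus
    haplotypes: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        h = np.asarray(self.haplotypes, dtype=float)
        if np.any(h < 0) or abs(h.sum() - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must be non-negative and sum to 1")


@dataclass
class SimulationConfig:
    """Study-design parameters for a synthetic cohort.

    ``twin_model`` maps locus id -> {"ref_hom"/"het"/"alt_hom": twin
    probability}; probabilities from several loci combine
    multiplicatively on the relative scale against ``base_twin_prob``
    and are capped to [0, 1]. The default base twin probability of 0.5
    matches a cohort lambing roughly half twins.
    """

    n_animals: int
    loci: list[SimulatedLocus] = field(default_factory=list)
    ld_pairs: list[LDPairSpec] = field(default_factory=list)
    twin_model: dict[str, dict[str, float]] = field(default_factory=dict)
    base_twin_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        solo = {sl.locus.id for sl in self.loci}
        paired = [l.id for p in self.ld_pairs for l in (p.locus_a, p.locus_b)]
        if solo & set(paired):
            raise ValueError(
                f"loci configured both solo and in an LD pair: {sorted(solo & set(paired))}"
            )
        if len(paired) != len(set(paired)):
            raise ValueError("a locus appears in more than one LD pair")
        if not (0.0 <= self.base_twin_prob <= 1.0):
            raise ValueError("base_twin_prob must be in [0, 1]")

    @property
    def all_loci(self) -> list[Locus]:
        out = [sl.locus for sl in self.loci]
        for p in self.ld_pairs:
            out.extend([p.locus_a, p.locus_b])
        return out


_CLASS_NAMES = ("ref_hom", "het", "alt_hom")


def simulate_cohort(config: SimulationConfig, rng: Optional[np.random.Generator] = None) -> Cohort:
    """Draw a cohort under the configured allele/haplotype frequencies
    and genotype-dependent twin probabilities. Fully reproducible from
    ``config.seed`` (or an explicitly passed generator)."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_animals
    dosages: dict[str, np.ndarray] = {}
    for sl in config.loci:
        dosages[sl.locus.id] = rng.binomial(2, 1.0 - sl.p_ref, size=n)
    for pair in config.ld_pairs:
        gametes = rng.choice(4, size=(n, 2), p=np.asarray(pair.haplotypes))
        dosages[pair.locus_a.id] = (gametes >= 2).sum(axis=1)  # aB, ab carry alt at A
        dosages[pair.locus_b.id] = (gametes % 2 == 1).sum(axis=1)  # Ab, ab alt at B

    loci = config.all_loci
    ids = pd.Index([f"S{i:05d}" for i in range(1, n + 1)], name="animal_id")
    geno = {}
    for loc in loci:
        r, a = loc.ref_allele, loc.alt_allele
        strings = np.array([f"{r}/{r}", f"{r}/{a}", f"{a}/{a}"])
        geno[loc.id] = strings[dosages[loc.id]]
    genotypes = pd.DataFrame(geno, index=ids)

    prob = np.full(n, config.base_twin_prob)
    for locus_id, mapping in config.twin_model.items():
        if locus_id not in dosages:
            raise ValueError(f"twin_model references unsimulated locus {locus_id!r}")
        per_class = np.array([mapping.get(c, config.base_twin_prob) for c in _CLASS_NAMES])
        if config.base_twin_prob > 0:
            prob = prob * per_class[dosages[locus_id]] / config.base_twin_prob
        else:
            prob = per_class[dosages[locus_id]]
    prob = np.clip(prob, 0.0, 1.0)
    litter = 1 + (rng.random(n) < prob).astype(int)
    phenotypes = pd.DataFrame({"litter_size": litter}, index=ids)
    return Cohort(loci=loci, genotypes=genotypes, phenotypes=phenotypes)


def sample_genotype_counts(
    p_ref: float,
    n: int,
    rng: np.random.Generator,
    size: int = 1,
) -> np.ndarray:
    """Vectorized genotype class counts under Hardy–Weinberg proportions;
    returns an array of shape (size, 3) (ref_hom, het, alt_hom)."""
    p, q = p_ref, 1.0 - p_ref
    return rng.multinomial(n, [p * p, 2 * p * q, q * q], size=size)


def simulate_ct_panel(
    groups: Mapping[str, int],
    true_folds: Mapping[str, float],
    noise_sd: float = 0.2,
    seed: int | np.random.Generator = 0,
    baseline_dct: float = 6.0,
    reference_ct: float = 15.0,
    n_replicates: int = 3,
    target_gene: str = "TARGET",
    reference_gene: str = "REF",
):
    """Synthetic Ct records for a grouped expression experiment.

    Reference-gene replicate Cts are Normal(``reference_ct``,
    ``noise_sd``); target replicates sit ``baseline_dct - log2(fold)``
    cycles above the reference level plus the same Gaussian technical
    noise, so with ``noise_sd = 0`` the 2^-ddCt pipeline recovers every
    configured fold exactly (against a calibrator group with fold 1).
    """
    from .model import CtRecord

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    records: list[CtRecord] = []
    for group in groups:
        fold = true_folds[group]
        if fold <= 0:
            raise ValueError(f"true fold for {group!r} must be positive")
        for s in range(groups[group]):
            sid = f"{group}_{s + 1:02d}"
            ref = reference_ct + rng.normal(0.0, noise_sd, size=n_replicates)
            tgt = (
                reference_ct
                + baseline_dct
                - math.log2(fold)
                + rng.normal(0.0, noise_sd, size=n_replicates)
            )
            records.append(CtRecord(sid, group, reference_gene, tuple(map(float, ref))))
            records.append(CtRecord(sid, group, target_gene, tuple(map(float, tgt))))
    return records
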