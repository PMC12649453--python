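"""Two-locus haplotype-frequency estimation (EM) and LD statistics.

With unphased genotypes at two biallelic loci, only the double
heterozygote is phase-ambiguous: it is either a coupling pair
(AB/ab) or a repulsion pair (Ab/aB). The EM algorithm splits that class
between the two configurations in proportion to the current
haplotype-frequency products and re-estimates the four haplotype
frequencies until convergence; its log-likelihood is non-decreasing by
construction and every iterate preserves the single-locus allele
frequencies (they are sufficient statistics for the margins).

From the estimated haplotype frequencies:

* ``D  = h_AB - p_A p_B``
* ``D' = |D| / D_max`` with Lewontin's sign-dependent range
  ``D_max = min(p_A q_B, q_A p_B)`` for ``D > 0`` and
  ``min(p_A p_B, q_A q_B)`` for ``D < 0``
* ``r^2 = D^2 / (p_A q_A p_B q_B)``

A pair is flagged "strongly linked" when ``D' > 0.86`` and
``r^2 > 0.30`` (both thresholds configurable).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import Cohort

__all__ = [
    "TwoLocusCounts",
    "HaplotypeFrequencies",
    "LDResult",
    "two_locus_counts",
    "em_haplotype_frequencies",
    "ld_statistics",
    "pairwise_ld",
]

log = logging.getLogger("flockgene")

_CLAMP = 1e-12  # haplotype frequencies below this are reported as 0


@dataclass(frozen=True)
class TwoLocusCounts:
    """3x3 joint genotype counts; rows = alt dosage at locus A (0/1/2),
    columns = alt dosage at locus B."""

    locus_a: str
    locus_b: str
    table: np.ndarray
    n: int = field(init=False)

    def __post_init__(self) -> None:
        tab = np.asarray(self.table, dtype=float)
        if tab.shape != (3, 3) or np.any(tab < 0):
            raise ValueError("joint genotype table must be 3x3 and non-negative")
        object.__setattr__(self, "table", tab)
        object.__setattr__(self, "n", int(round(tab.sum())))
        if self.n < 1:
            raise ValueError("no jointly typed animals")


@dataclass(frozen=True)
class HaplotypeFrequencies:
    """Estimated frequencies of the four haplotypes AB, Ab, aB, ab
    (uppercase = reference allele)."""

    locus_a: str
    locus_b: str
    h_AB: float
    h_Ab: float
    h_aB: float
    h_ab: float
    loglik: float
    iterations: int
    converged: bool
    loglik_trace: tuple[float, ...] = ()

    @property
    def as_array(self) -> np.ndarray:
        return np.array([self.h_AB, self.h_Ab, self.h_aB, self.h_ab])

    @property
    def p_a_ref(self) -> float:
        return self.h_AB + self.h_Ab

    @property
    def p_b_ref(self) -> float:
        return self.h_AB + self.h_aB


@dataclass(frozen=True)
class LDResult:
    locus_a: str
    locus_b: str
    D: float
    D_prime: float
    r2: float
    strong_linkage: bool
    defined: bool = True


def two_locus_counts(cohort: Cohort, locus_a: str, locus_b: str) -> TwoLocusCounts:
    """Joint 3x3 genotype counts over animals typed at both loci."""
    da = cohort.dosage(locus_a)
    db = cohort.dosage(locus_b)
    both = pd.DataFrame({"a": da, "b": db}).dropna().astype(int)
    tab = np.zeros((3, 3))
    for (i, j), cnt in both.value_counts().items():
        tab[i, j] = cnt
    return TwoLocusCounts(locus_a, locus_b, tab)


def _genotype_probs(h: np.ndarray) -> np.ndarray:
    """Cell probabilities of the 3x3 genotype table under haplotype
    frequencies h = (AB, Ab, aB, ab), assuming random union of gametes."""
    hAB, hAb, haB, hab = h
    return np.array(
        [
            [hAB**2, 2 * hAB * hAb, hAb**2],
            [2 * hAB * haB, 2 * (hAB * hab + hAb * haB), 2 * hAb * hab],
            [haB**2, 2 * haB * hab, hab**2],
        ]
    )


def _loglik(table: np.ndarray, h: np.ndarray) -> float:
    probs = _genotype_probs(h)
    mask = table > 0
    with np.errstate(divide="ignore"):
        lp = np.log(probs[mask])
    if np.any(np.isneginf(lp)):
        return -np.inf
    return float((table[mask] * lp).sum())


def em_haplotype_frequencies(
    counts: TwoLocusCounts,
    tol: float = 1e-8,
    max_iter: int = 50_000,
    init: Optional[Sequence[float]] = None,
) -> HaplotypeFrequencies:
    """EM estimate of the four haplotype frequencies from a 3x3 table.

    Initialization is at linkage equilibrium (products of the margin
    allele frequencies) unless ``init`` is given; iteration stops when
    the largest absolute frequency change drops below ``tol``. On data
    with no double heterozygotes the first M-step already lands on the
    closed-form counting estimate.
    """
    tab = counts.table
    n = counts.n
    # Known haplotype counts contributed by the eight unambiguous cells;
    # order (AB, Ab, aB, ab). Cell (i, j) holds i alt alleles at A, j at B.
    base = np.zeros(4)
    for i in range(3):
        for j in range(3):
            if i == 1 and j == 1:
                continue
            c = tab[i, j]
            if c == 0:
                continue
            # with at least one homozygous locus the gamete pairing is
            # forced; alt-dosage i splits over the two gametes as below
            ga = [1, 1] if i == 2 else ([0, 0] if i == 0 else [1, 0])
            gb = [1, 1] if j == 2 else ([0, 0] if j == 0 else [1, 0])
            for k in range(2):
                base[2 * ga[k] + gb[k]] += c  # AB=0, Ab=1, aB=2, ab=3
    n_dh = tab[1, 1]

    pa = 1.0 - (tab[1, :].sum() + 2 * tab[2, :].sum()) / (2 * n)  # ref freq at A
    pb = 1.0 - (tab[:, 1].sum() + 2 * tab[:, 2].sum()) / (2 * n)

    def run(h0: np.ndarray):
        h = h0
        trace = [_loglik(tab, h)]
        converged = False
        iterations = 0
        for iterations in range(1, max_iter + 1):
            denom = h[0] * h[3] + h[1] * h[2]
            coupling = 0.5 if denom == 0 else h[0] * h[3] / denom
            counts_vec = base.copy()
            counts_vec[0] += n_dh * coupling
            counts_vec[3] += n_dh * coupling
            counts_vec[1] += n_dh * (1 - coupling)
            counts_vec[2] += n_dh * (1 - coupling)
            new_h = counts_vec / (2 * n)
            delta = np.max(np.abs(new_h - h))
            h = new_h
            trace.append(_loglik(tab, h))
            if delta < tol or n_dh == 0:
                # without double heterozygotes the M-step is
                # data-determined: the first update is already the
                # closed-form counting MLE
                converged = True
                break
        return h, trace, iterations, converged

    if init is not None:
        starts = [np.asarray(init, dtype=float) / np.sum(init)]
    else:
        # equilibrium start, plus coupling- and repulsion-shifted starts:
        # the equilibrium point can be an unstable EM fixed point (the
        # 50/50 phase split reproduces itself), so explore the whole
        # admissible one-parameter family (margins are EM-invariant)
        starts = [np.array([pa * pb, pa * (1 - pb), (1 - pa) * pb, (1 - pa) * (1 - pb)])]
        if n_dh > 0:
            lo, hi = max(0.0, pa + pb - 1.0), min(pa, pb)
            for x in (lo + 0.05 * (hi - lo), lo + 0.5 * (hi - lo), lo + 0.95 * (hi - lo)):
                starts.append(
                    np.array([x, pa - x, pb - x, 1.0 - pa - pb + x]).clip(min=0.0)
                )

    best = None
    for h0 in starts:
        h, trace, iterations, converged = run(h0)
        ll = trace[-1]
        if best is None or ll > best[1] + 1e-12:
            best = (h, ll, trace, iterations, converged)
    h, _, trace, iterations, converged = best
    if not converged:
        warnings.warn(
            f"EM did not converge in {max_iter} iterations for "
            f"{counts.locus_a} x {counts.locus_b}; returning best estimate",
            RuntimeWarning,
        )
    h = np.where(h < _CLAMP, 0.0, h)
    h = h / h.sum()
    return HaplotypeFrequencies(
        locus_a=counts.locus_a,
        locus_b=counts.locus_b,
        h_AB=float(h[0]),
        h_Ab=float(h[1]),
        h_aB=float(h[2]),
        h_ab=float(h[3]),
        loglik=_loglik(tab, h),
        iterations=iterations,
        converged=converged,
        loglik_trace=tuple(trace),
    )


def ld_statistics(
    h: HaplotypeFrequencies,
    dprime_threshold: float = 0.86,
    r2_threshold: float = 0.30,
) -> LDResult:
    """D, D', r2 and the strong-linkage flag from haplotype frequencies.

    A monomorphic margin leaves D' and r2 undefined; the result is
    returned flagged (``defined=False``) with NaN statistics.
    """
    pA, pB = h.p_a_ref, h.p_b_ref
    qA, qB = 1.0 - pA, 1.0 - pB
    if min(pA, qA, pB, qB) <= 0.0:
        return LDResult(h.locus_a, h.locus_b, np.nan, np.nan, np.nan, False, defined=False)
    D = h.h_AB - pA * pB
    if D > 0:
        d_max = min(pA * qB, qA * pB)
    else:
        d_max = min(pA * pB, qA * qB)
    d_prime = 0.0 if D == 0 else abs(D) / d_max
    r2 = D**2 / (pA * qA * pB * qB)
    strong = (d_prime > dprime_threshold) and (r2 > r2_threshold)
    return LDResult(h.locus_a, h.locus_b, float(D), float(d_prime), float(r2), bool(strong))


def pairwise_ld(
    cohort: Cohort,
    loci: Optional[Sequence[str]] = None,
    dprime_threshold: float = 0.86,
    r2_threshold: float = 0.30,
    tol: float = 1e-8,
    max_iter: int = 50_000,
) -> pd.DataFrame:
    """LD statistics for every unordered locus pair of the panel."""
    ids = list(loci) if loci is not None else cohort.locus_ids
    if len(ids) < 2:
        raise ValueError("pairwise LD needs at least two loci")
    rows = []
    for la, lb in combinations(ids, 2):
        try:
            counts = two_locus_counts(cohort, la, lb)
            haps = em_haplotype_frequencies(counts, tol=tol, max_iter=max_iter)
            res = ld_statistics(haps, dprime_threshold, r2_threshold)
        except ValueError as exc:
            log.warning("LD %s x %s failed: %s", la, lb, exc)
            res = LDResult(la, lb, np.nan, np.nan, np.nan, False, defined=False)
        rows.append(
            {
                "locus_a": res.locus_a,
                "locus_b": res.locus_b,
                "D": res.D,
                "Dprime": res.D_prime,
                "r2": res.r2,
                "strong": res.strong_linkage,
                "defined": res.defined,
            }
        )
    return pd.DataFrame(rows)
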