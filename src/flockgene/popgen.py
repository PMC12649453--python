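"""Per-locus diversity statistics and Hardy–Weinberg testing.

For a locus with allele frequencies :math:`p_i` the indices are

* homozygosity  :math:`H_o = \\sum_i p_i^2`
* heterozygosity (gene diversity)  :math:`H_e = 1 - H_o`
* effective number of alleles  :math:`N_e = 1 / H_o`
* polymorphic information content
  :math:`PIC = 1 - \\sum_i p_i^2 - \\sum_{i<j} 2 p_i^2 p_j^2`

The Hardy–Weinberg test is the classical three-class goodness-of-fit
chi-square :math:`\\chi^2 = \\sum_i (f_i - n p_i)^2 / (n p_i)` with
expected proportions :math:`(p^2, 2pq, q^2)` computed from *unrounded*
allele frequencies, one degree of freedom (three classes, one estimated
allele frequency), no continuity correction, and zero-count homozygote
classes still contributing their expected term.

All formulas are implemented for k alleles even though cohorts here are
biallelic.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import Cohort

__all__ = [
    "GenotypeCounts",
    "AlleleFrequencies",
    "HweResult",
    "DiversityResult",
    "count_genotypes",
    "allele_frequencies",
    "hwe_chi2",
    "hwe_exact",
    "diversity_from_freqs",
    "diversity_indices",
    "classify_pic",
    "diversity_table",
]


@dataclass(frozen=True)
class GenotypeCounts:
    """Observed genotype class counts at one biallelic locus."""

    locus_id: str
    n_ref_hom: int
    n_het: int
    n_alt_hom: int

    def __post_init__(self) -> None:
        if min(self.n_ref_hom, self.n_het, self.n_alt_hom) < 0:
            raise ValueError(f"{self.locus_id}: negative genotype count")
        if self.n < 1:
            raise ValueError(f"{self.locus_id}: no typed animals")

    @property
    def n(self) -> int:
        return self.n_ref_hom + self.n_het + self.n_alt_hom

    @property
    def as_array(self) -> np.ndarray:
        return np.array([self.n_ref_hom, self.n_het, self.n_alt_hom], dtype=float)


@dataclass(frozen=True)
class AlleleFrequencies:
    locus_id: str
    p_ref: float
    p_alt: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_ref <= 1.0 and 0.0 <= self.p_alt <= 1.0):
            raise ValueError(f"{self.locus_id}: frequencies outside [0, 1]")
        if abs(self.p_ref + self.p_alt - 1.0) > 1e-9:
            raise ValueError(f"{self.locus_id}: frequencies must sum to 1")


@dataclass(frozen=True)
class HweResult:
    locus_id: str
    chi2: float
    df: int
    p_value: float
    monomorphic: bool = False


@dataclass(frozen=True)
class DiversityResult:
    locus_id: str
    Ho: float
    He: float
    Ne: float
    PIC: float
    pic_class: str


def count_genotypes(cohort: Cohort, locus_id: str) -> GenotypeCounts:
    """Count genotype classes over non-missing calls at a locus."""
    dosage = cohort.dosage(locus_id).dropna()
    if len(dosage) == 0:
        raise ValueError(f"{locus_id}: zero typed animals")
    vals = dosage.astype(int).value_counts()
    return GenotypeCounts(
        locus_id=locus_id,
        n_ref_hom=int(vals.get(0, 0)),
        n_het=int(vals.get(1, 0)),
        n_alt_hom=int(vals.get(2, 0)),
    )


def allele_frequencies(counts: GenotypeCounts) -> AlleleFrequencies:
    """Allele frequencies by the gene-counting rule on raw counts."""
    p_ref = (2 * counts.n_ref_hom + counts.n_het) / (2 * counts.n)
    return AlleleFrequencies(counts.locus_id, p_ref=p_ref, p_alt=1.0 - p_ref)


def hwe_chi2(counts: GenotypeCounts) -> HweResult:
    """Three-class Hardy–Weinberg chi-square goodness-of-fit test.

    A monomorphic locus is reported as ``chi2 = 0, p = 1`` by convention
    (there is nothing to test).
    """
    freqs = allele_frequencies(counts)
    p, q = freqs.p_ref, freqs.p_alt
    if p == 0.0 or q == 0.0:
        return HweResult(counts.locus_id, chi2=0.0, df=1, p_value=1.0, monomorphic=True)
    expected = counts.n * np.array([p * p, 2 * p * q, q * q])
    chi2 = float(((counts.as_array - expected) ** 2 / expected).sum())
    return HweResult(
        counts.locus_id,
        chi2=chi2,
        df=1,
        p_value=float(stats.chi2.sf(chi2, df=1)),
    )


def hwe_exact(counts: GenotypeCounts) -> HweResult:
    """Exact Hardy–Weinberg test (conditional on allele counts).

    Optional alternative to the chi-square; enumerates all heterozygote
    counts compatible with the observed allele counts and sums the
    probabilities of tables no more likely than the observed one.
    """
    n = counts.n
    n_alt = 2 * counts.n_alt_hom + counts.n_het
    n_alt = min(n_alt, 2 * n - n_alt)  # rare-allele count
    if n_alt == 0:
        return HweResult(counts.locus_id, chi2=0.0, df=1, p_value=1.0, monomorphic=True)
    hets = np.arange(n_alt % 2, n_alt + 1, 2)
    from scipy.special import gammaln

    def logprob(h: np.ndarray) -> np.ndarray:
        ra = (n_alt - h) // 2
        rr = n - ra - h
        return (
            h * np.log(2)
            + gammaln(n + 1)
            - gammaln(rr + 1)
            - gammaln(h + 1)
            - gammaln(ra + 1)
            - gammaln(2 * n + 1)
            + gammaln(n_alt + 1)
            + gammaln(2 * n - n_alt + 1)
        )

    lp = logprob(hets)
    obs = lp[hets == counts.n_het][0]
    p_val = float(np.exp(lp[lp <= obs + 1e-12]).sum())
    chi = hwe_chi2(counts)
    return HweResult(counts.locus_id, chi2=chi.chi2, df=1, p_value=min(1.0, p_val))


def diversity_from_freqs(freqs: Sequence[float]) -> tuple[float, float, float, float]:
    """(Ho, He, Ne, PIC) from a full allele-frequency vector (k alleles)."""
    p = np.asarray(freqs, dtype=float)
    if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("allele frequencies must be non-negative and sum to 1")
    ho = float((p**2).sum())
    he = 1.0 - ho
    ne = 1.0 / ho
    cross = sum(2 * p[i] ** 2 * p[j] ** 2 for i, j in combinations(range(len(p)), 2))
    pic = he - float(cross)
    return ho, he, ne, pic


def classify_pic(pic: float, low: float = 0.25, high: float = 0.5) -> str:
    """Informativeness class: low (< 0.25), moderate, high (>= 0.5).

    The boundary value 0.25 itself is assigned to "low" (the defining
    inequalities are strict, leaving the boundary to convention).
    """
    if not (0.0 <= pic <= 1.0):
        raise ValueError(f"PIC must be in [0, 1], got {pic}")
    if pic <= low:
        return "low"
    if pic < high:
        return "moderate"
    return "high"


def diversity_indices(freqs: AlleleFrequencies) -> DiversityResult:
    ho, he, ne, pic = diversity_from_freqs([freqs.p_ref, freqs.p_alt])
    return DiversityResult(
        locus_id=freqs.locus_id,
        Ho=ho,
        He=he,
        Ne=ne,
        PIC=pic,
        pic_class=classify_pic(pic),
    )


def diversity_table(cohort: Cohort, exact_hwe: bool = False) -> pd.DataFrame:
    """Full per-locus summary: frequencies, diversity indices, HWE test."""
    rows = []
    for locus in cohort.loci:
        counts = count_genotypes(cohort, locus.id)
        freqs = allele_frequencies(counts)
        div = diversity_indices(freqs)
        hwe = (hwe_exact if exact_hwe else hwe_chi2)(counts)
        rows.append(
            {
                "locus": locus.id,
                "n": counts.n,
                "n_ref_hom": counts.n_ref_hom,
                "n_het": counts.n_het,
                "n_alt_hom": counts.n_alt_hom,
                "p_ref": freqs.p_ref,
                "p_alt": freqs.p_alt,
                "Ho": div.Ho,
                "He": div.He,
                "Ne": div.Ne,
                "PIC": div.PIC,
                "pic_class": div.pic_class,
                "chi2": hwe.chi2,
                "df": hwe.df,
                "p_value": hwe.p_value,
            }
        )
    return pd.DataFrame(rows)
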