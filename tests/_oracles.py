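"""Independent reference computations used only by the test suite.

These deliberately avoid the library code paths they check: the
two-locus likelihood is written out directly and maximized by
exhaustive grid search, the letter-display checker verifies the sharing
relation pair by pair, and the diversity oracle sums the defining
series with explicit loops.
"""

from __future__ import annotations

import numpy as np


def two_locus_loglik(table: np.ndarray, h_AB: float, h_Ab: float, h_aB: float, h_ab: float) -> float:
    """Log-likelihood of a 3x3 unphased genotype table under random
    union of gametes with the given haplotype frequencies."""
    probs = np.array(
        [
            [h_AB * h_AB, 2 * h_AB * h_Ab, h_Ab * h_Ab],
            [2 * h_AB * h_aB, 2 * (h_AB * h_ab + h_Ab * h_aB), 2 * h_Ab * h_ab],
            [h_aB * h_aB, 2 * h_aB * h_ab, h_ab * h_ab],
        ]
    )
    total = 0.0
    for i in range(3):
        for j in range(3):
            if table[i, j] > 0:
                if probs[i, j] <= 0:
                    return -np.inf
                total += table[i, j] * np.log(probs[i, j])
    return total


def grid_max_loglik(table: np.ndarray, step: float = 1e-6) -> float:
    """Exhaustive grid maximum of the two-locus likelihood.

    The haplotype margins of any maximum equal the sample allele
    frequencies (allele counts are sufficient statistics for the
    margins), which reduces the search to the coupling frequency h_AB
    inside its Frechet bounds; that interval is scanned exhaustively,
    coarse-to-fine down to ``step``.
    """
    table = np.asarray(table, dtype=float)
    n = table.sum()
    pA = 1.0 - (table[1, :].sum() + 2 * table[2, :].sum()) / (2 * n)
    pB = 1.0 - (table[:, 1].sum() + 2 * table[:, 2].sum()) / (2 * n)
    lo, hi = max(0.0, pA + pB - 1.0), min(pA, pB)

    def scan(lo, hi, k):
        xs = np.linspace(lo, hi, k)
        vals = [
            two_locus_loglik(
                table,
                x,
                max(0.0, pA - x),
                max(0.0, pB - x),
                max(0.0, 1.0 - pA - pB + x),
            )
            for x in xs
        ]
        i = int(np.argmax(vals))
        return xs[i], vals[i], xs[1] - xs[0] if k > 1 else 0.0

    if hi - lo < 1e-15:
        return two_locus_loglik(table, lo, pA - lo, pB - lo, 1.0 - pA - pB + lo)
    width = hi - lo
    x, best, dx = scan(lo, hi, 2001)
    while dx > step:
        lo2, hi2 = max(lo, x - 2 * dx), min(hi, x + 2 * dx)
        x, best, dx = scan(lo2, hi2, 401)
    return best


def letters_consistent(pvalues, letters, alpha) -> bool:
    """Check shares-a-letter <=> p >= alpha for every pair of groups."""
    labels = list(pvalues.index)
    for i, gi in enumerate(labels):
        for gj in labels[i + 1 :]:
            share = bool(set(letters[gi]) & set(letters[gj]))
            if share != (pvalues.loc[gi, gj] >= alpha):
                return False
    return True


def diversity_oracle(freqs) -> tuple[float, float, float, float]:
    """(Ho, He, Ne, PIC) by explicit summation of the defining series."""
    p = list(freqs)
    ho = sum(pi**2 for pi in p)
    he = 1.0 - ho
    ne = 1.0 / ho
    pic = 1.0 - sum(pi**2 for pi in p)
    for i in range(len(p) - 1):
        for j in range(i + 1, len(p)):
            pic -= 2.0 * p[i] ** 2 * p[j] ** 2
    return ho, he, ne, pic


def anova_oracle(groups) -> float:
    """One-way ANOVA F statistic by direct sums of squares."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    return (ssb / (len(groups) - 1)) / (ssw / (len(allv) - len(groups)))
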