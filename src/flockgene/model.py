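"""Core domain types: loci, genotype calls, phenotypes, Ct records, cohorts.

The central container is :class:`Cohort`, which joins an animal x locus
genotype matrix with per-animal reproductive phenotypes. All pipeline
stages (diversity statistics, linkage disequilibrium, association,
reproductive summaries) consume a cohort.

Genotypes are unphased biallelic calls stored canonically as
``"<ref>/<alt>"`` strings (heterozygotes always reference-allele first),
so ``"A/G"`` and ``"G/A"`` are the same call. Missing calls are ``None``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

__all__ = [
    "Locus",
    "GenotypeCall",
    "PhenotypeRecord",
    "CtRecord",
    "Cohort",
    "GENOTYPE_CLASSES",
]

#: Ordered genotype class names: reference homozygote, heterozygote,
#: alternate homozygote (0, 1, 2 copies of the alternate allele).
GENOTYPE_CLASSES = ("ref_hom", "het", "alt_hom")

_LOCUS_LABEL_RE = re.compile(r"^(?P<pos>\S+)\s+(?P<ref>\S)>(?P<alt>\S)$")


@dataclass(frozen=True)
class Locus:
    """A biallelic variant site identified by an opaque positional label.

    Parameters
    ----------
    id
        Free-text label, e.g. ``"g.18202372 G>A"``. No coordinate
        arithmetic is ever performed on it.
    ref_allele, alt_allele
        Single-character allele symbols; must differ.
    """

    id: str
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("locus id must be nonempty")
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError(f"{self.id}: allele symbols must be single characters")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.id}: ref and alt alleles must differ")

    @classmethod
    def from_label(cls, label: str) -> "Locus":
        """Build a locus from a ``"<position> R>A"`` style label."""
        m = _LOCUS_LABEL_RE.match(label.strip())
        if m is None:
            raise ValueError(
                f"cannot infer alleles from locus label {label!r}; "
                "expected a '<position> R>A' form or explicit alleles"
            )
        return cls(id=label.strip(), ref_allele=m.group("ref"), alt_allele=m.group("alt"))

    @property
    def genotype_labels(self) -> tuple[str, str, str]:
        """Genotype class labels, e.g. ``("GG", "GA", "AA")``."""
        r, a = self.ref_allele, self.alt_allele
        return (r + r, r + a, a + a)

    def canonical(self, allele1: str, allele2: str) -> str:
        """Canonical ``ref/alt`` string for an unordered allele pair."""
        pair = {allele1, allele2}
        if not pair <= {self.ref_allele, self.alt_allele}:
            bad = pair - {self.ref_allele, self.alt_allele}
            raise ValueError(
                f"unknown allele symbol(s) {sorted(bad)} for locus {self.id!r}"
            )
        if allele1 == allele2:
            return f"{allele1}/{allele2}"
        return f"{self.ref_allele}/{self.alt_allele}"

    def n_alt(self, genotype: Optional[str]) -> Optional[int]:
        """Alternate-allele dosage (0/1/2) of a canonical genotype string."""
        if genotype is None or genotype != genotype:  # None or NaN
            return None
        a1, a2 = genotype.split("/")
        return (a1 == self.alt_allele) + (a2 == self.alt_allele)


@dataclass(frozen=True)
class GenotypeCall:
    """One animal's unphased call at one locus.

    Both alleles are missing or neither; the pair is unordered.
    """

    animal_id: str
    locus_id: str
    allele1: Optional[str]
    allele2: Optional[str]

    def __post_init__(self) -> None:
        if (self.allele1 is None) != (self.allele2 is None):
            raise ValueError(
                f"{self.animal_id}@{self.locus_id}: both alleles must be "
                "missing or neither"
            )

    @property
    def is_missing(self) -> bool:
        return self.allele1 is None


@dataclass(frozen=True)
class PhenotypeRecord:
    """Reproductive record of one ewe.

    ``litter_size`` counts live-born lambs recorded at lambing and must be
    >= 1: the sampling design excludes non-lambing animals, so a zero is
    a data error, not a phenotype.
    """

    animal_id: str
    litter_size: int
    parity: Optional[int] = None
    age_years: Optional[float] = None

    def __post_init__(self) -> None:
        if int(self.litter_size) != self.litter_size or self.litter_size < 1:
            raise ValueError(
                f"{self.animal_id}: litter_size must be an integer >= 1 "
                f"(got {self.litter_size!r}); non-lambing ewes are excluded "
                "from the cohort by design"
            )
        if self.parity is not None and self.parity < 1:
            raise ValueError(f"{self.animal_id}: parity must be >= 1")
        if self.age_years is not None and self.age_years <= 0:
            raise ValueError(f"{self.animal_id}: age_years must be positive")


@dataclass(frozen=True)
class CtRecord:
    """qPCR cycle-threshold replicates for one sample/gene combination."""

    sample_id: str
    group: str
    gene: str
    ct_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.ct_values) < 1:
            raise ValueError(f"{self.sample_id}/{self.gene}: needs >= 1 Ct value")
        for ct in self.ct_values:
            if not (ct > 0 and ct == ct and ct != float("inf")):
                raise ValueError(
                    f"{self.sample_id}/{self.gene}: Ct values must be finite "
                    f"and positive (got {ct!r})"
                )

    @property
    def n_replicates(self) -> int:
        return len(self.ct_values)

    @property
    def mean_ct(self) -> float:
        return sum(self.ct_values) / len(self.ct_values)


@dataclass
class Cohort:
    """Joined genotype + phenotype records for a panel of loci.

    Attributes
    ----------
    loci
        The locus panel, in column order of ``genotypes``.
    genotypes
        DataFrame indexed by animal_id, one column per locus id, values
        canonical genotype strings or NaN for missing.
    phenotypes
        DataFrame indexed by animal_id with at least a ``litter_size``
        column (optional ``parity``, ``age_years``).
    """

    loci: list[Locus]
    genotypes: pd.DataFrame
    phenotypes: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        locus_ids = [loc.id for loc in self.loci]
        if len(set(locus_ids)) != len(locus_ids):
            raise ValueError("duplicate locus ids in panel")
        missing = set(self.genotypes.columns) - set(locus_ids)
        if missing:
            raise ValueError(f"genotype columns without panel entry: {sorted(missing)}")
        if self.genotypes.index.has_duplicates:
            dups = self.genotypes.index[self.genotypes.index.duplicated()].tolist()
            raise ValueError(f"duplicate animal_id(s): {dups}")
        if len(self.phenotypes) > 0:
            unknown = set(self.genotypes.index) - set(self.phenotypes.index)
            if unknown:
                raise ValueError(
                    f"genotyped animals without phenotype record: {sorted(unknown)[:5]}"
                )

    @property
    def n_animals(self) -> int:
        return len(self.genotypes.index)

    @property
    def locus_ids(self) -> list[str]:
        return [loc.id for loc in self.loci]

    def locus(self, locus_id: str) -> Locus:
        for loc in self.loci:
            if loc.id == locus_id:
                return loc
        raise KeyError(f"locus {locus_id!r} not in panel")

    def dosage(self, locus_id: str) -> pd.Series:
        """Alternate-allele dosage per animal (NaN where missing)."""
        loc = self.locus(locus_id)
        return self.genotypes[locus_id].map(
            lambda g: loc.n_alt(g) if isinstance(g, str) else None
        )

    def genotype_label(self, locus_id: str) -> pd.Series:
        """Compact genotype labels (e.g. "GG"/"GA"/"AA") per animal."""
        loc = self.locus(locus_id)
        labels = loc.genotype_labels
        return self.dosage(locus_id).map(
            lambda d: labels[int(d)] if d is not None and d == d else None
        )

    def litter_sizes(self, locus_id: str) -> pd.DataFrame:
        """Per-animal genotype label and litter size, missing calls dropped."""
        if "litter_size" not in self.phenotypes.columns:
            raise ValueError("cohort has no phenotypes joined")
        df = pd.DataFrame(
            {
                "genotype": self.genotype_label(locus_id),
                "litter_size": self.phenotypes.loc[
                    self.genotypes.index, "litter_size"
                ].to_numpy(),
            },
            index=self.genotypes.index,
        )
        return df.dropna(subset=["genotype"])

    @classmethod
    def from_records(
        cls,
        loci: Sequence[Locus],
        genotypes: pd.DataFrame,
        phenotypes: Sequence[PhenotypeRecord] | pd.DataFrame = (),
    ) -> "Cohort":
        if isinstance(phenotypes, pd.DataFrame):
            pheno = phenotypes
        else:
            pheno = pd.DataFrame(
                [
                    {
                        "animal_id": p.animal_id,
                        "litter_size": p.litter_size,
                        "parity": p.parity,
                        "age_years": p.age_years,
                    }
                    for p in phenotypes
                ]
            )
            if len(pheno) > 0:
                pheno = pheno.set_index("animal_id")
        return cls(loci=list(loci), genotypes=genotypes, phenotypes=pheno)
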