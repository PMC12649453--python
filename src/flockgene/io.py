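"""CSV readers and TSV/JSON report writers.

Input dialects
--------------
* genotype table: header ``animal_id`` plus one column per locus id;
  cells are slash-separated unphased calls (``G/A``) or empty for missing.
* phenotype table: columns ``animal_id,litter_size[,parity,age_years]``.
* Ct table (long form): columns ``sample_id,group,gene,ct`` with one row
  per technical replicate.

Rows with allele symbols foreign to their locus are rejected with a
diagnostic naming the locus and line; duplicate animal ids are a hard
error. Reports are written with a deterministic column order; TSV floats
are rounded per column (default 2 decimals like the source tables, 3 for
SDs, 1 for percentages) while JSON keeps full precision and round-trips.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import Cohort, CtRecord, Locus, PhenotypeRecord

__all__ = [
    "read_genotype_table",
    "read_phenotype_table",
    "read_ct_table",
    "load_cohort",
    "write_report",
    "write_genotype_table",
    "write_phenotype_table",
    "DEFAULT_DECIMALS",
]

log = logging.getLogger("flockgene")

#: column-suffix → decimals used when rendering TSV reports
DEFAULT_DECIMALS: dict[str, int] = {"sd": 3, "pct": 1, "percent": 1}
_DEFAULT_NDEC = 2


def read_genotype_table(path: str | Path, panel: Sequence[Locus]) -> pd.DataFrame:
    """Parse a genotype CSV into a canonicalized animal x locus frame.

    Heterozygotes are stored reference-allele first, so ``A/G`` and
    ``G/A`` yield identical calls. Animals with an unknown allele symbol
    at any locus are dropped with a logged diagnostic.
    """
    by_id = {loc.id: loc for loc in panel}
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "animal_id" not in raw.columns:
        raise ValueError(f"{path}: genotype table must have an 'animal_id' column")
    unknown_cols = [c for c in raw.columns if c != "animal_id" and c not in by_id]
    if unknown_cols:
        raise ValueError(f"{path}: columns not in locus panel: {unknown_cols}")
    if raw["animal_id"].duplicated().any():
        dups = raw.loc[raw["animal_id"].duplicated(), "animal_id"].tolist()
        raise ValueError(f"{path}: duplicate animal_id(s): {dups}")

    locus_cols = [c for c in raw.columns if c != "animal_id"]
    rows: dict[str, dict[str, Any]] = {}
    n_calls = 0
    for line_no, rec in enumerate(raw.itertuples(index=False), start=2):
        rec_d = dict(zip(raw.columns, rec))
        animal = rec_d["animal_id"]
        parsed: dict[str, Any] = {}
        try:
            for col in locus_cols:
                cell = rec_d[col].strip()
                if cell == "":
                    parsed[col] = np.nan
                    continue
                alleles = cell.split("/")
                if len(alleles) != 2:
                    raise ValueError(f"malformed genotype {cell!r} at locus {col!r}")
                parsed[col] = by_id[col].canonical(alleles[0], alleles[1])
                n_calls += 1
        except ValueError as exc:
            log.warning("%s line %d (animal %s): %s — row rejected", path, line_no, animal, exc)
            continue
        rows[animal] = parsed
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=locus_cols)
    frame.index.name = "animal_id"
    log.info("%s: parsed %d animals x %d loci (%d calls)", path, len(frame), len(locus_cols), n_calls)
    return frame


def read_phenotype_table(path: str | Path) -> list[PhenotypeRecord]:
    """Parse and validate a phenotype CSV (litter_size must be integer >= 1)."""
    raw = pd.read_csv(path)
    if not {"animal_id", "litter_size"} <= set(raw.columns):
        raise ValueError(f"{path}: needs columns animal_id, litter_size")
    records = []
    for rec in raw.itertuples(index=False):
        ls = getattr(rec, "litter_size")
        if pd.isna(ls) or float(ls) != int(float(ls)):
            raise ValueError(
                f"{path}: litter_size {ls!r} for {rec.animal_id} is not an integer"
            )
        parity = getattr(rec, "parity", None)
        age = getattr(rec, "age_years", None)
        records.append(
            PhenotypeRecord(
                animal_id=str(rec.animal_id),
                litter_size=int(float(ls)),
                parity=None if parity is None or pd.isna(parity) else int(parity),
                age_years=None if age is None or pd.isna(age) else float(age),
            )
        )
    log.info("%s: parsed %d phenotype records", path, len(records))
    return records


def read_ct_table(path: str | Path) -> list[CtRecord]:
    """Parse a long-form Ct CSV, pooling replicate rows per sample/gene."""
    raw = pd.read_csv(path)
    needed = {"sample_id", "group", "gene", "ct"}
    if not needed <= set(raw.columns):
        raise ValueError(f"{path}: needs columns {sorted(needed)}")
    records = []
    for (sample, group, gene), sub in raw.groupby(
        ["sample_id", "group", "gene"], sort=True
    ):
        records.append(
            CtRecord(
                sample_id=str(sample),
                group=str(group),
                gene=str(gene),
                ct_values=tuple(float(x) for x in sub["ct"]),
            )
        )
    return records


def load_cohort(
    genotype_path: str | Path,
    phenotype_path: str | Path | None,
    panel: Sequence[Locus],
) -> Cohort:
    """Read and join genotype and (optionally) phenotype tables."""
    geno = read_genotype_table(genotype_path, panel)
    pheno: Any = ()
    if phenotype_path is not None:
        pheno = read_phenotype_table(phenotype_path)
    return Cohort.from_records(panel, geno, pheno)


def _to_frame(results: Any) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        return results.copy()
    results = list(results)
    if results and dataclasses.is_dataclass(results[0]):
        return pd.DataFrame([dataclasses.asdict(r) for r in results])
    return pd.DataFrame(results)


def _ndec_for(col: str, decimals: Mapping[str, int]) -> int:
    name = col.lower()
    for suffix, nd in decimals.items():
        if name == suffix or name.endswith("_" + suffix) or name.endswith(suffix):
            return nd
    return _DEFAULT_NDEC


def write_report(
    results: Any,
    path: str | Path,
    fmt: str = "tsv",
    decimals: Mapping[str, int] | None = None,
    columns: Sequence[str] | None = None,
) -> None:
    """Write a stage result to TSV (rounded) or JSON (full precision).

    An empty result list produces a header-only file (TSV) or ``[]``
    (JSON) and succeeds.
    """
    frame = _to_frame(results)
    if columns is not None:
        frame = frame.reindex(columns=list(columns))
    path = Path(path)
    if fmt == "json":
        payload = frame.to_dict(orient="records")
        path.write_text(json.dumps(payload, indent=1, default=_json_default) + "\n")
    elif fmt == "tsv":
        dec = dict(DEFAULT_DECIMALS)
        if decimals:
            dec.update(decimals)
        out = frame.copy()
        for col in out.columns:
            if pd.api.types.is_float_dtype(out[col]):
                nd = _ndec_for(col, dec)
                out[col] = out[col].map(
                    lambda v, nd=nd: "" if pd.isna(v) else f"{v:.{nd}f}"
                )
        out.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown report format {fmt!r}")


def _json_default(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset, tuple)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
    if obj is pd.NA or (isinstance(obj, float) and obj != obj):
        return None
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_genotype_table(cohort: Cohort, path: str | Path) -> None:
    """Inverse of :func:`read_genotype_table` (round-trip safe)."""
    out = cohort.genotypes.fillna("")
    out.to_csv(path)


def write_phenotype_table(cohort: Cohort, path: str | Path) -> None:
    cols = [c for c in ("litter_size", "parity", "age_years") if c in cohort.phenotypes.columns]
    cohort.phenotypes[cols].to_csv(path)
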