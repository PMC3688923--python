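"""Data model, readers/writers and validation for Cp tables and genotype tables.

The central container is :class:`Dataset`, a collection of per-sample,
per-gene crossing-point (Cp) measurements together with per-gene metadata
(target/reference role, amplification efficiency) and the design levels
(tissues, plates, sexes, animals) observed in the data.  Genotype calls for
the same animals live in :class:`GenotypeTable`.

All tabular I/O is plain CSV through pandas; a *dialect* mapping renames
arbitrary input columns onto the canonical field names.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CpObservation",
    "Dataset",
    "GenotypeTable",
    "ValidationReport",
    "FormatError",
    "IntegrityError",
    "load_dialect",
    "read_cp_table",
    "write_cp_table",
    "read_genotypes",
    "write_genotypes",
    "validate_dataset",
]

#: Cp cycle count above which a well is treated as undetectable by default.
DEFAULT_CP_CUTOFF = 40.0

#: Default minimum fraction of detectable observations for a gene x tissue
#: cell to be considered quantifiable.
DEFAULT_QUANT_THRESHOLD = 0.5

CANONICAL_COLUMNS = {
    "sample": "sample",
    "animal": "animal",
    "tissue": "tissue",
    "plate": "plate",
    "sex": "sex",
    "gene": "gene",
    "gene_role": "gene_role",
    "cp": "cp",
    "cp_replicates": "cp_replicates",
    "efficiency": "efficiency",
}


def load_dialect(path: str) -> dict[str, str]:
    """Read a YAML column-mapping config: canonical field -> column name."""
    import yaml

    with open(path) as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, dict):
        raise FormatError("dialect YAML must be a mapping of field -> column")
    unknown = set(mapping) - set(CANONICAL_COLUMNS)
    if unknown:
        raise FormatError(f"unknown dialect fields: {sorted(unknown)}")
    return {k: str(v) for k, v in mapping.items()}


class FormatError(ValueError):
    """A file does not have the expected columns or value syntax."""


class IntegrityError(ValueError):
    """A file parses but violates a dataset invariant."""


@dataclass(frozen=True)
class CpObservation:
    """One gene x sample Cp measurement (mean of technical replicates)."""

    sample_id: str
    animal_id: str
    tissue: str
    plate_id: str
    sex: str
    gene: str
    gene_role: str
    cp_mean: float
    cp_replicates: tuple[float, ...]
    detectable: bool

    def __post_init__(self) -> None:
        if self.gene_role not in ("target", "reference"):
            raise IntegrityError(
                f"gene_role must be 'target' or 'reference', got {self.gene_role!r}"
            )
        if self.detectable:
            if not math.isfinite(self.cp_mean) or self.cp_mean <= 0:
                raise IntegrityError(
                    f"detectable observation {self.sample_id}/{self.gene} "
                    f"has invalid cp_mean {self.cp_mean!r}"
                )
            if self.cp_replicates:
                mean = float(np.mean(self.cp_replicates))
                if not math.isclose(mean, self.cp_mean, rel_tol=1e-9, abs_tol=1e-9):
                    raise IntegrityError(
                        f"cp_mean {self.cp_mean} does not equal the mean of "
                        f"replicates {self.cp_replicates} for "
                        f"{self.sample_id}/{self.gene}"
                    )


@dataclass
class GeneInfo:
    """Per-gene metadata: role and amplification efficiency fraction."""

    role: str
    efficiency: float | None = None


@dataclass
class Dataset:
    """A full Cp dataset: observations plus gene metadata and design levels."""

    observations: list[CpObservation]
    genes: dict[str, GeneInfo] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genes:
            self.genes = {}
            for obs in self.observations:
                self.genes.setdefault(obs.gene, GeneInfo(role=obs.gene_role))
        seen: set[tuple[str, str]] = set()
        for obs in self.observations:
            key = (obs.sample_id, obs.gene)
            if key in seen:
                raise IntegrityError(f"duplicate observation for {key}")
            seen.add(key)

    # -- design levels -------------------------------------------------
    @property
    def tissues(self) -> list[str]:
        return sorted({o.tissue for o in self.observations})

    @property
    def animals(self) -> list[str]:
        return sorted({o.animal_id for o in self.observations})

    @property
    def plates(self) -> list[str]:
        return sorted({o.plate_id for o in self.observations})

    @property
    def sexes(self) -> list[str]:
        return sorted({o.sex for o in self.observations})

    @property
    def reference_genes(self) -> list[str]:
        return sorted(g for g, info in self.genes.items() if info.role == "reference")

    @property
    def target_genes(self) -> list[str]:
        return sorted(g for g, info in self.genes.items() if info.role == "target")

    def set_efficiencies(self, efficiencies: Mapping[str, float]) -> None:
        """Attach per-gene amplification efficiency fractions (e.g. 0.93)."""
        for gene, eff in efficiencies.items():
            if gene in self.genes:
                self.genes[gene].efficiency = float(eff)

    def efficiency_of(self, gene: str) -> float:
        info = self.genes.get(gene)
        if info is None or info.efficiency is None:
            raise KeyError(f"no amplification efficiency registered for {gene!r}")
        return info.efficiency

    def to_frame(self) -> pd.DataFrame:
        """Flatten to one row per observation."""
        rows = []
        for o in self.observations:
            rows.append(
                {
                    "sample": o.sample_id,
                    "animal": o.animal_id,
                    "tissue": o.tissue,
                    "plate": o.plate_id,
                    "sex": o.sex,
                    "gene": o.gene,
                    "gene_role": o.gene_role,
                    "cp_mean": o.cp_mean,
                    "cp_replicates": ";".join(repr(c) for c in o.cp_replicates),
                    "detectable": o.detectable,
                    "efficiency": self.genes[o.gene].efficiency,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class GenotypeTable:
    """Unordered biallelic genotype calls, animals x SNPs.

    Calls are stored as alphabetically sorted two-character strings
    ("CT", never "TC"); missing calls are ``None``.
    """

    animals: list[str]
    snps: list[str]
    calls: pd.DataFrame  # index animals, columns snps, values str | None

    VALID_ALLELES = set("ACGT-")

    def __post_init__(self) -> None:
        for snp in self.snps:
            col = self.calls[snp]
            alleles: set[str] = set()
            for call in col:
                if call is None:
                    continue
                alleles.update(call)
            if len(alleles) > 2:
                raise IntegrityError(
                    f"SNP {snp} has {len(alleles)} alleles: {sorted(alleles)}"
                )
            if col.isna().all() if col.dtype != object else all(c is None for c in col):
                raise IntegrityError(f"SNP {snp} has no non-missing calls")

    def alleles_of(self, snp: str) -> list[str]:
        alleles: set[str] = set()
        for call in self.calls[snp]:
            if call is not None:
                alleles.update(call)
        return sorted(alleles)

    def genotype_classes(self, snp: str) -> dict[str, list[str]]:
        """Map genotype string -> list of animals carrying it (missing skipped)."""
        classes: dict[str, list[str]] = {}
        for animal in self.animals:
            call = self.calls.at[animal, snp]
            if call is not None:
                classes.setdefault(call, []).append(animal)
        return classes


def _normalize_call(raw: object) -> str | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    s = str(raw).strip().upper()
    if s in ("", "NA", "NN", "--", "./.", "MISSING"):
        return None
    if len(s) != 2:
        raise FormatError(f"genotype call {raw!r} is not a two-allele string")
    if not set(s) <= GenotypeTable.VALID_ALLELES:
        raise FormatError(f"genotype call {raw!r} contains unknown characters")
    return "".join(sorted(s))


def read_genotypes(path: str) -> GenotypeTable:
    """Read an animal x SNP genotype CSV (first column: animal id)."""
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise FormatError("genotype CSV needs an animal column plus >=1 SNP column")
    animal_col = df.columns[0]
    animals = df[animal_col].astype(str).tolist()
    if len(set(animals)) != len(animals):
        raise IntegrityError("duplicate animal ids in genotype table")
    snps = list(df.columns[1:])
    calls = pd.DataFrame(index=animals, columns=snps, dtype=object)
    for snp in snps:
        calls[snp] = [_normalize_call(v) for v in df[snp]]
    return GenotypeTable(animals=animals, snps=snps, calls=calls)


def write_genotypes(gt: GenotypeTable, path: str) -> None:
    out = gt.calls.copy()
    out.index.name = "animal"
    out.fillna("NA").to_csv(path)


# ----------------------------------------------------------------------
# Cp table reading
# ----------------------------------------------------------------------

def _parse_cp(value: object, cutoff: float) -> float | None:
    """Return a finite Cp value, or None when the well is undetectable."""
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    s = str(value).strip()
    if s == "" or s.upper() in ("NA", "NAN", "UNDET", "UNDETERMINED"):
        return None
    cp = float(s)
    if not math.isfinite(cp) or cp > cutoff:
        return None
    return cp


def read_cp_table(
    path: str,
    dialect: Mapping[str, str] | None = None,
    cp_cutoff: float = DEFAULT_CP_CUTOFF,
    efficiencies: Mapping[str, float] | None = None,
) -> Dataset:
    """Read a long-format Cp CSV into a :class:`Dataset`.

    The file may contain either one row per well (``cp`` column; replicate
    rows for the same sample x gene are aggregated to their mean) or one
    row per sample x gene with a ``cp_replicates`` column of
    semicolon-separated well values.  ``dialect`` maps canonical field
    names (sample, animal, tissue, plate, sex, gene, gene_role, cp, ...)
    onto the file's column names.

    Wells that are empty, "NA" or above ``cp_cutoff`` cycles are treated
    as undetectable; a sample x gene with no detectable well gets
    ``detectable=False`` and is excluded from modelling sets downstream.
    """
    colmap = dict(CANONICAL_COLUMNS)
    if dialect:
        colmap.update(dialect)
    df = pd.read_csv(path, dtype=str)

    mandatory = ["sample", "animal", "tissue", "gene"]
    for fieldname in mandatory:
        if colmap[fieldname] not in df.columns:
            raise FormatError(f"missing mandatory column {colmap[fieldname]!r}")
    has_cp = colmap["cp"] in df.columns
    has_reps = colmap["cp_replicates"] in df.columns
    if not has_cp and not has_reps:
        raise FormatError(
            f"missing Cp column: need {colmap['cp']!r} or {colmap['cp_replicates']!r}"
        )

    def col(fieldname: str, default: str) -> pd.Series:
        name = colmap[fieldname]
        if name in df.columns:
            return df[name].fillna(default).astype(str)
        return pd.Series([default] * len(df), index=df.index)

    work = pd.DataFrame(
        {
            "sample": df[colmap["sample"]].astype(str),
            "animal": df[colmap["animal"]].astype(str),
            "tissue": df[colmap["tissue"]].astype(str),
            "plate": col("plate", "plate1"),
            "sex": col("sex", "unknown"),
            "gene": df[colmap["gene"]].astype(str),
            "gene_role": col("gene_role", "target"),
        }
    )

    if has_reps:
        reps_raw = df[colmap["cp_replicates"]]
        replicate_lists = []
        for v in reps_raw:
            if v is None or (isinstance(v, float) and math.isnan(v)) or str(v).strip() == "":
                replicate_lists.append([])
            else:
                parsed = [_parse_cp(p, cp_cutoff) for p in str(v).split(";")]
                replicate_lists.append([p for p in parsed if p is not None])
        work["replicates"] = replicate_lists
    else:
        work["replicates"] = [
            [] if (p := _parse_cp(v, cp_cutoff)) is None else [p]
            for v in df[colmap["cp"]]
        ]

    observations: list[CpObservation] = []
    genes: dict[str, GeneInfo] = {}
    grouped = work.groupby(["sample", "gene"], sort=False)
    for (sample_id, gene), grp in grouped:
        meta = grp.iloc[0]
        if grp["animal"].nunique() > 1 or grp["tissue"].nunique() > 1:
            raise IntegrityError(
                f"sample {sample_id!r} maps to several animals/tissues"
            )
        reps: list[float] = [c for lst in grp["replicates"] for c in lst]
        detectable = len(reps) > 0
        cp_mean = float(np.mean(reps)) if detectable else float("nan")
        obs = CpObservation(
            sample_id=str(sample_id),
            animal_id=meta["animal"],
            tissue=meta["tissue"],
            plate_id=meta["plate"],
            sex=meta["sex"],
            gene=str(gene),
            gene_role=meta["gene_role"],
            cp_mean=cp_mean,
            cp_replicates=tuple(reps),
            detectable=detectable,
        )
        observations.append(obs)
        genes.setdefault(str(gene), GeneInfo(role=meta["gene_role"]))
        if colmap["efficiency"] in df.columns:
            raw = df[colmap["efficiency"]].loc[grp.index[0]]
            if raw is not None and str(raw).strip() not in ("", "nan", "NA"):
                genes[str(gene)].efficiency = float(raw)

    ds = Dataset(observations=observations, genes=genes)
    if efficiencies:
        ds.set_efficiencies(efficiencies)
    if not ds.reference_genes or not ds.target_genes:
        # a dataset may legitimately hold only candidates during reference
        # screening; warn-level validation happens in validate_dataset
        pass
    return ds


def write_cp_table(ds: Dataset, path: str) -> None:
    """Write a Dataset as one row per sample x gene (round-trips exactly)."""
    ds.to_frame().to_csv(path, index=False)


# ----------------------------------------------------------------------
# Validation
# ----------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Per gene x tissue detectability and quantifiability flags."""

    table: pd.DataFrame  # columns: gene, tissue, n, n_detectable, fraction, flagged
    threshold: float

    @property
    def flagged_cells(self) -> set[tuple[str, str]]:
        flagged = self.table[self.table["flagged"]]
        return {(r.gene, r.tissue) for r in flagged.itertuples()}

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def to_json(self, path: str) -> None:
        payload = {
            "threshold": self.threshold,
            "cells": self.table.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def validate_dataset(
    ds: Dataset, threshold: float = DEFAULT_QUANT_THRESHOLD
) -> ValidationReport:
    """Report the detectable fraction per gene x tissue and flag sparse cells.

    A cell whose fraction of detectable observations falls below
    ``threshold`` (default 0.5) is flagged for exclusion from modelling --
    the mechanism by which transcripts that are quantifiable only in a
    subset of tissues (e.g. a brain-restricted receptor isoform) drop out
    of the other tissues.
    """
    rows = []
    cells: dict[tuple[str, str], list[bool]] = {}
    for o in ds.observations:
        cells.setdefault((o.gene, o.tissue), []).append(o.detectable)
    for (gene, tissue), flags in sorted(cells.items()):
        n = len(flags)
        nd = sum(flags)
        frac = nd / n
        rows.append(
            {
                "gene": gene,
                "tissue": tissue,
                "n": n,
                "n_detectable": nd,
                "fraction_detectable": frac,
                "flagged": frac < threshold,
            }
        )
    return ValidationReport(table=pd.DataFrame(rows), threshold=threshold)
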