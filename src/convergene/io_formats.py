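"""Readers, writers and SNP-level quality filters for the pipeline's file formats.

Summary-statistic tables (GWAS, eQTL), gene annotation (BED), gene sets
(GMT) and expression matrices are all plain text.  On-disk BED is 0-based
half-open; every in-memory coordinate in this package is 1-based inclusive.
All writers and readers round-trip losslessly (floats are serialized with
``repr`` precision).

Quality filters mirror the source study's SNP-level inclusion rules:

* GWAS SNPs: minor allele frequency >= 0.001 and imputation info score
  strictly > 0.4.
* Genotyped SNPs (eQTL cohort): Hardy-Weinberg p > 1e-4, call rate > 0.98
  and MAF > 0.01, all strict inequalities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "RowError",
    "GwasSnpRecord",
    "EqtlRecord",
    "GeneModel",
    "GenotypeQcStats",
    "GeneSet",
    "ExpressionMatrix",
    "Removal",
    "read_gwas",
    "write_gwas",
    "filter_gwas_snps",
    "filter_genotype_snps",
    "read_eqtl",
    "write_eqtl",
    "read_genes",
    "write_genes",
    "read_gene_sets",
    "write_gene_sets",
    "read_expression",
    "write_expression",
]


class FormatError(ValueError):
    """A file does not conform to the expected dialect (e.g. missing column)."""


class RowError(FormatError):
    """A single data row is malformed; carries the 1-based line number."""

    def __init__(self, line_no: int, message: str):
        self.line_no = line_no
        super().__init__(f"line {line_no}: {message}")


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, bool):
        return "1" if x else "0"
    if isinstance(x, float):
        return repr(float(x))
    return str(x)


# ---------------------------------------------------------------------------
# domain record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GwasSnpRecord:
    """One SNP's GWAS association summary."""

    snp_id: str
    p_value: float
    chrom: str | None = None
    pos: int | None = None
    ref_allele: str | None = None
    alt_allele: str | None = None
    maf: float | None = None
    info: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value must be in (0, 1], got {self.p_value!r}")
        if self.pos is not None and self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.maf is not None and not (0.0 < self.maf <= 0.5):
            raise ValueError(f"maf must be in (0, 0.5], got {self.maf!r}")
        if not (0.0 <= self.info <= 1.0):
            raise ValueError(f"info must be in [0, 1], got {self.info!r}")


@dataclass(frozen=True)
class EqtlRecord:
    """One SNP-gene expression association."""

    snp_id: str
    gene_id: str
    p_value: float
    beta: float | None = None
    cis_flag: bool | None = None

    def __post_init__(self):
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value must be in (0, 1], got {self.p_value!r}")


@dataclass(frozen=True)
class GeneModel:
    """A gene's genomic footprint, 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str | None = None

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"strand must be '+', '-' or None, got {self.strand!r}")


@dataclass(frozen=True)
class GenotypeQcStats:
    """Per-SNP genotyping quality summary for the eQTL cohort filter."""

    snp_id: str
    hwe_p: float
    call_rate: float
    maf: float

    def __post_init__(self):
        for name in ("hwe_p", "call_rate", "maf"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if not (0.0 <= self.call_rate <= 1.0):
            raise ValueError(f"call_rate must be in [0, 1], got {self.call_rate!r}")
        if not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"maf must be in [0, 0.5], got {self.maf!r}")


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    genes: tuple[str, ...]


@dataclass
class ExpressionMatrix:
    """Genes x samples log-scale expression with a two-level group label."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    group: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.group) != len(self.sample_ids):
            raise ValueError("one group label per sample required")
        bad = sorted(set(self.group) - {"low", "high"})
        if bad:
            raise ValueError(f"group labels must be 'low'/'high', got {bad}")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")

    def group_values(self, label: str) -> np.ndarray:
        cols = [i for i, g in enumerate(self.group) if g == label]
        return self.values[:, cols]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class Removal:
    """One filtered-out item and the rule(s) it failed."""

    snp_id: str
    reasons: tuple[str, ...]


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

_GWAS_COLUMNS = ("snp_id", "chrom", "pos", "ref_allele", "alt_allele",
                 "p_value", "maf", "info")


def read_gwas(path, dialect: Mapping[str, str] | None = None) -> list[GwasSnpRecord]:
    """Read GWAS summary statistics from a tab-separated file with header.

    ``dialect`` maps canonical column names (``snp_id``, ``p_value``,
    ``chrom``, ``pos``, ``maf``, ``info``, ``ref_allele``, ``alt_allele``)
    to the column names used in the file.  ``snp_id`` and ``p_value`` are
    required; a missing ``info`` column defaults to 1.0 (genotyped data
    carries no imputation score).
    """
    dialect = dict(dialect or {})
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    colmap = {canon: dialect.get(canon, canon) for canon in _GWAS_COLUMNS}
    for required in ("snp_id", "p_value"):
        if colmap[required] not in df.columns:
            raise FormatError(
                f"{path}: required column {colmap[required]!r} not found"
            )

    def get(row, canon):
        col = colmap[canon]
        if col not in df.columns:
            return ""
        return row[col]

    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        line_no = i + 2  # header is line 1
        try:
            p = float(get(row, "p_value"))
        except ValueError:
            raise RowError(line_no, f"non-numeric p_value {get(row, 'p_value')!r}") from None
        pos_s = get(row, "pos")
        maf_s = get(row, "maf")
        info_s = get(row, "info")
        try:
            rec = GwasSnpRecord(
                snp_id=get(row, "snp_id"),
                p_value=p,
                chrom=get(row, "chrom") or None,
                pos=int(pos_s) if pos_s else None,
                ref_allele=get(row, "ref_allele") or None,
                alt_allele=get(row, "alt_allele") or None,
                maf=float(maf_s) if maf_s else None,
                info=float(info_s) if info_s else 1.0,
            )
        except ValueError as exc:
            raise RowError(line_no, str(exc)) from None
        records.append(rec)
    return records


def write_gwas(records: Iterable[GwasSnpRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GWAS_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    _fmt(getattr(r, c)) for c in _GWAS_COLUMNS
                )
                + "\n"
            )


def filter_gwas_snps(
    records: Iterable[GwasSnpRecord],
    maf_min: float = 0.001,
    info_min: float = 0.4,
) -> tuple[list[GwasSnpRecord], list[Removal]]:
    """Apply the GWAS inclusion rules: MAF >= ``maf_min`` and info > ``info_min``.

    The MAF bound is inclusive ("down to a MAF of 0.1%"); the info bound is
    strict.  Records without a MAF cannot fail the MAF rule.  Returns the
    surviving records (input order preserved) and a removal log stating,
    per SNP, every rule it failed.
    """
    kept: list[GwasSnpRecord] = []
    removed: list[Removal] = []
    for r in records:
        reasons = []
        if r.maf is not None and r.maf < maf_min:
            reasons.append("maf")
        if not (r.info > info_min):
            reasons.append("info")
        if reasons:
            removed.append(Removal(r.snp_id, tuple(reasons)))
        else:
            kept.append(r)
    return kept, removed


def filter_genotype_snps(
    stats: Iterable[GenotypeQcStats],
    hwe_min: float = 1e-4,
    call_min: float = 0.98,
    maf_min: float = 0.01,
) -> tuple[list[str], list[Removal]]:
    """Genotype QC: keep SNPs with HWE p > hwe_min, call rate > call_min and
    MAF > maf_min (all strict, mirroring the stated ">" thresholds)."""
    kept: list[str] = []
    removed: list[Removal] = []
    for s in stats:
        reasons = []
        if not (s.hwe_p > hwe_min):
            reasons.append("hwe")
        if not (s.call_rate > call_min):
            reasons.append("call_rate")
        if not (s.maf > maf_min):
            reasons.append("maf")
        if reasons:
            removed.append(Removal(s.snp_id, tuple(reasons)))
        else:
            kept.append(s.snp_id)
    return kept, removed


# ---------------------------------------------------------------------------
# eQTL summary statistics
# ---------------------------------------------------------------------------

_EQTL_COLUMNS = ("snp_id", "gene_id", "p_value", "beta", "cis_flag")


def read_eqtl(path) -> list[EqtlRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for required in ("snp_id", "gene_id", "p_value"):
        if required not in df.columns:
            raise FormatError(f"{path}: required column {required!r} not found")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        line_no = i + 2
        try:
            rec = EqtlRecord(
                snp_id=row["snp_id"],
                gene_id=row["gene_id"],
                p_value=float(row["p_value"]),
                beta=float(row["beta"]) if row.get("beta", "") else None,
                cis_flag=(row["cis_flag"] == "1") if row.get("cis_flag", "") else None,
            )
        except ValueError as exc:
            raise RowError(line_no, str(exc)) from None
        records.append(rec)
    return records


def write_eqtl(records: Iterable[EqtlRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_EQTL_COLUMNS) + "\n")
        for r in records:
            fh.write("\t".join(_fmt(getattr(r, c)) for c in _EQTL_COLUMNS) + "\n")


# ---------------------------------------------------------------------------
# gene annotation (BED)
# ---------------------------------------------------------------------------


def read_genes(path) -> list[GeneModel]:
    """Read gene models from BED (0-based half-open on disk -> 1-based
    inclusive in memory).  Requires at least 4 columns (name = gene id)."""
    genes = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise RowError(line_no, f"BED line has {len(fields)} fields, need >= 4")
            try:
                start0, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise RowError(line_no, "non-integer BED coordinates") from None
            strand = fields[5] if len(fields) >= 6 else None
            try:
                genes.append(
                    GeneModel(
                        gene_id=fields[3],
                        chrom=fields[0],
                        start=start0 + 1,
                        end=end,
                        strand=strand,
                    )
                )
            except ValueError as exc:
                raise RowError(line_no, str(exc)) from None
    return genes


def write_genes(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fields = [g.chrom, str(g.start - 1), str(g.end), g.gene_id]
            if g.strand is not None:
                fields += ["0", g.strand]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------


def read_gene_sets(path) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise RowError(line_no, "GMT line needs set name, description and >= 1 member")
            sets.append(GeneSet(fields[0], fields[1], tuple(fields[2:])))
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join((s.set_id, s.description) + s.genes) + "\n")


def gene_sets_as_dict(sets: Iterable[GeneSet]) -> dict[str, set[str]]:
    return {s.set_id: set(s.genes) for s in sets}


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------


def read_expression(expr_path, groups_path) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column ``gene_id``) plus a
    two-column ``sample_id``/``group`` TSV."""
    df = pd.read_csv(expr_path, sep="\t", index_col=0,
                     float_precision="round_trip")
    groups = pd.read_csv(groups_path, sep="\t", dtype=str)
    for required in ("sample_id", "group"):
        if required not in groups.columns:
            raise FormatError(f"{groups_path}: required column {required!r} not found")
    gmap = dict(zip(groups["sample_id"], groups["group"]))
    missing = [s for s in df.columns if s not in gmap]
    if missing:
        raise FormatError(f"{groups_path}: no group label for samples {missing}")
    return ExpressionMatrix(
        gene_ids=list(df.index),
        sample_ids=list(df.columns),
        values=df.to_numpy(dtype=float),
        group=[gmap[s] for s in df.columns],
    )


def write_expression(matrix: ExpressionMatrix, expr_path, groups_path) -> None:
    with open(expr_path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for g, row in zip(matrix.gene_ids, matrix.values):
            fh.write(g + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    with open(groups_path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for s, grp in zip(matrix.sample_ids, matrix.group):
            fh.write(f"{s}\t{grp}\n")
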