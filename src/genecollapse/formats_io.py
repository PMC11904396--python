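"""Readers and writers for the four input table formats and the output matrix.

Supported inputs:

* PLINK additive-recoded genotype text (``--recode A``, the ``.raw`` dialect):
  six metadata columns (FID IID PAT MAT SEX PHENOTYPE) followed by one column
  per variant, headed ``<SNPID>_<counted allele>``, cells in {0, 1, 2, NA}.
* VCF 4.x with a GT FORMAT field (plain or bgzipped), read through cyvcf2.
* Gene/region boundary tables with GENE/START/END columns (1-based, both ends
  inclusive).
* SNP position tables with SNP/BP columns.

Both genotype sources are normalised into the same in-memory container,
:class:`GenotypeMatrix`, so the collapsing engine is format-agnostic.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .errors import DataValidationError, FormatError

logger = logging.getLogger("genecollapse")

PLINK_META_COLUMNS = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")

__all__ = [
    "GenotypeMatrix",
    "GeneBoundarySet",
    "SnpPositionMap",
    "GeneCountMatrix",
    "read_plink_raw",
    "read_vcf_genotypes",
    "dosage_from_gt",
    "read_gene_boundaries",
    "read_snp_positions",
    "read_counts",
    "write_counts",
    "read_id_list",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Individuals × variants additive dosage matrix.

    ``dosages`` is a float array with values in {0, 1, 2} and NaN for missing
    genotypes; rows follow ``individual_ids``, columns follow ``variant_ids``.
    ``counted_alleles`` records, per variant, which allele the dosage counts
    (the ``_A``-style header suffix for PLINK input, the ALT allele for VCF).
    """

    individual_ids: list[str]
    family_ids: list[str]
    variant_ids: list[str]
    counted_alleles: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float).reshape(
            len(self.individual_ids), len(self.variant_ids)
        )
        if len(self.family_ids) != len(self.individual_ids):
            raise DataValidationError("family_ids and individual_ids differ in length")
        if len(self.counted_alleles) != len(self.variant_ids):
            raise DataValidationError("counted_alleles and variant_ids differ in length")
        _require_unique(self.individual_ids, "individual ID (IID)")
        _require_unique(self.variant_ids, "variant ID")
        finite = self.dosages[~np.isnan(self.dosages)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            bad = finite[~np.isin(finite, (0.0, 1.0, 2.0))][0]
            raise DataValidationError(f"dosage value {bad!r} outside {{0, 1, 2, missing}}")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)


@dataclass
class GeneBoundarySet:
    """Named 1-based genomic intervals; both START and END are inclusive."""

    genes: list[str]
    start: np.ndarray
    end: np.ndarray

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        if not (len(self.genes) == self.start.size == self.end.size):
            raise DataValidationError("gene/start/end lengths differ")
        _require_unique(self.genes, "gene name")
        if self.start.size:
            if (self.start <= 0).any() or (self.end <= 0).any():
                raise DataValidationError("gene boundaries must be positive base pairs")
            bad = self.start > self.end
            if bad.any():
                names = [g for g, b in zip(self.genes, bad) if b]
                raise DataValidationError(
                    f"START > END for gene(s): {', '.join(names)}"
                )

    def __len__(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"GENE": self.genes, "START": self.start, "END": self.end})


@dataclass
class SnpPositionMap:
    """SNP identifier → 1-based base-pair position."""

    snps: list[str]
    bp: np.ndarray

    def __post_init__(self) -> None:
        self.bp = np.asarray(self.bp, dtype=np.int64)
        if len(self.snps) != self.bp.size:
            raise DataValidationError("snp/bp lengths differ")
        _require_unique(self.snps, "SNP ID")
        if self.bp.size and (self.bp <= 0).any():
            raise DataValidationError("SNP positions must be positive base pairs")

    def __len__(self) -> int:
        return len(self.snps)

    def to_dict(self) -> dict[str, int]:
        return dict(zip(self.snps, self.bp.tolist()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"SNP": self.snps, "BP": self.bp})


@dataclass
class GeneCountMatrix:
    """Genes × individuals matrix of summed allele counts.

    The empty sentinel — the result when no gene retains any count, mirroring
    the NULL return of the original interface — is an instance with zero gene
    rows; it is falsy and ``is_empty``. Individual columns are preserved so
    the sentinel still serialises to a header-only file.
    """

    genes: list[str]
    individual_ids: list[str]
    counts: np.ndarray
    stats: Optional["object"] = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64).reshape(
            len(self.genes), len(self.individual_ids)
        )
        _require_unique(self.genes, "gene name")
        _require_unique(self.individual_ids, "individual ID")
        if (self.counts < 0).any():
            raise DataValidationError("negative allele count")

    @property
    def is_empty(self) -> bool:
        return len(self.genes) == 0

    def __bool__(self) -> bool:
        return not self.is_empty

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneCountMatrix):
            return NotImplemented
        return (
            self.genes == other.genes
            and self.individual_ids == other.individual_ids
            and np.array_equal(self.counts, other.counts)
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.individual_ids)
        df.insert(0, "GENE", self.genes)
        return df


def _require_unique(values: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for v in values:
        if v in seen:
            raise DataValidationError(f"duplicate {what}: {v!r}")
        seen.add(v)


# ---------------------------------------------------------------------------
# PLINK --recode A
# ---------------------------------------------------------------------------

def read_plink_raw(path: str | Path) -> GenotypeMatrix:
    """Parse a PLINK additive-recoded (``--recode A``) genotype text file.

    The file is whitespace-delimited (any run of spaces or tabs). The first
    six header columns must be FID IID PAT MAT SEX PHENOTYPE; each remaining
    header is split on its *last* underscore into the SNP identifier and the
    counted allele, so SNP IDs may themselves contain underscores. Dosage
    cells must be 0, 1, 2 or NA (missing).
    """
    path = Path(path)
    with open(path) as fh:
        header_line = fh.readline()
    if not header_line.strip():
        raise FormatError(f"{path}: empty file, expected a header row")
    header = header_line.split()
    for i, expected in enumerate(PLINK_META_COLUMNS):
        if i >= len(header) or header[i] != expected:
            raise FormatError(
                f"{path}: mandatory column {expected!r} missing or out of place "
                f"(header starts {header[:6]})"
            )
    if len(header) < 7:
        raise FormatError(f"{path}: no variant columns after the six metadata columns")

    variant_ids: list[str] = []
    counted_alleles: list[str] = []
    for col in header[6:]:
        snp, sep, allele = col.rpartition("_")
        if not sep or not snp or not allele:
            raise FormatError(
                f"{path}: variant column {col!r} lacks the '_<allele>' suffix"
            )
        variant_ids.append(snp)
        counted_alleles.append(allele)
    _require_unique(variant_ids, f"variant column in {path}")

    df = pd.read_csv(
        path,
        sep=r"\s+",
        dtype={c: str for c in PLINK_META_COLUMNS[:4]},
        na_values=["NA"],
        keep_default_na=False,
        header=0,
        names=list(PLINK_META_COLUMNS) + header[6:],
    )
    iids = df["IID"].astype(str).tolist() if len(df) else []
    fids = df["FID"].astype(str).tolist() if len(df) else []
    _require_unique(iids, f"individual ID (IID) in {path}")

    geno = df.iloc[:, 6:]
    numeric = geno.apply(pd.to_numeric, errors="coerce")
    coerced = numeric.isna() & geno.notna()
    if coerced.to_numpy().any():
        r, c = np.argwhere(coerced.to_numpy())[0]
        raise DataValidationError(
            f"{path}: non-numeric dosage {geno.iat[r, c]!r} at individual "
            f"{iids[r]!r}, column {header[6 + c]!r}"
        )
    dosages = numeric.to_numpy(dtype=float)
    finite = ~np.isnan(dosages)
    bad = finite & ~np.isin(dosages, (0.0, 1.0, 2.0))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise DataValidationError(
            f"{path}: dosage {dosages[r, c]!r} outside {{0,1,2,NA}} at individual "
            f"{iids[r]!r}, column {header[6 + c]!r}"
        )
    return GenotypeMatrix(
        individual_ids=iids,
        family_ids=fids,
        variant_ids=variant_ids,
        counted_alleles=counted_alleles,
        dosages=dosages,
    )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def dosage_from_gt(gt: str) -> Optional[int]:
    """Additive dosage of a single GT token, or None when missing.

    Alleles are separated by ``/`` or ``|``; phasing is ignored. Every
    non-reference allele index contributes 1 (multi-allelic genotypes collapse
    all alternates into one count). Any ``.`` allele — including half-calls
    such as ``./1`` — makes the whole genotype missing, which downstream
    counting treats as zero.
    """
    tokens = re.split(r"[/|]", gt.strip())
    if not tokens or any(t == "" for t in tokens):
        raise ValueError(f"malformed GT token {gt!r}")
    dosage = 0
    for t in tokens:
        if t == ".":
            return None
        try:
            allele = int(t)
        except ValueError:
            raise ValueError(f"non-numeric allele {t!r} in GT token {gt!r}") from None
        if allele < 0:
            raise ValueError(f"negative allele index in GT token {gt!r}")
        if allele > 0:
            dosage += 1
    return dosage


def read_vcf_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read per-sample additive dosages from the GT field of a VCF 4.x file.

    Variant IDs come from the ID column, falling back to ``CHROM:POS`` when
    the ID is missing (``.``) so position joining stays possible. VCF carries
    no family structure, so family IDs mirror the sample IDs. The counted
    allele is the (first) ALT allele.
    """
    path = Path(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise FormatError(f"{path}: cannot open as VCF ({exc})") from exc
    samples = list(vcf.samples)

    variant_ids: list[str] = []
    counted_alleles: list[str] = []
    columns: list[np.ndarray] = []
    for var in vcf:
        loc = f"{path}:{var.CHROM}:{var.POS}"
        # a sample-less VCF has no FORMAT column at all; only demand GT when
        # there are genotypes to read
        if samples and "GT" not in (var.FORMAT or []):
            raise FormatError(f"{loc}: record has no GT field in FORMAT")
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        variant_ids.append(vid)
        counted_alleles.append(var.ALT[0] if var.ALT else ".")
        col = np.empty(len(samples), dtype=float)
        for i, entry in enumerate(var.genotypes if samples else []):
            alleles = entry[:-1]  # last element is the phased flag
            if len(alleles) == 0 or any(a < 0 for a in alleles):
                col[i] = np.nan
            else:
                col[i] = sum(1 for a in alleles if a > 0)
        columns.append(col)
    try:
        _require_unique(variant_ids, f"variant ID in {path}")
    except DataValidationError:
        raise
    dosages = (
        np.column_stack(columns) if columns else np.empty((len(samples), 0), dtype=float)
    )
    return GenotypeMatrix(
        individual_ids=samples,
        family_ids=list(samples),
        variant_ids=variant_ids,
        counted_alleles=counted_alleles,
        dosages=dosages,
    )


# ---------------------------------------------------------------------------
# boundary / position tables
# ---------------------------------------------------------------------------

def _read_table(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise FormatError(f"{path}: empty file, expected a header row")
    sep = "," if ("," in first and "\t" not in first) else r"\s+"
    df = pd.read_csv(path, sep=sep)
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: required column {col!r} missing")
    return df


def _int_column(df: pd.DataFrame, col: str, path: Path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    if vals.isna().any():
        bad = df[col][vals.isna()].iloc[0]
        raise DataValidationError(f"{path}: non-integer value {bad!r} in column {col!r}")
    arr = vals.to_numpy()
    if not np.equal(np.mod(arr, 1), 0).all():
        raise DataValidationError(f"{path}: fractional value in column {col!r}")
    return arr.astype(np.int64)


def read_gene_boundaries(path: str | Path) -> GeneBoundarySet:
    """Read a gene/region boundary table with GENE, START and END columns.

    Extra columns are ignored. Intervals are 1-based and inclusive at both
    ends; rows with START > END raise a validation error naming the gene.
    """
    path = Path(path)
    df = _read_table(path, ("GENE", "START", "END"))
    return GeneBoundarySet(
        genes=df["GENE"].astype(str).tolist(),
        start=_int_column(df, "START", path),
        end=_int_column(df, "END", path),
    )


def read_snp_positions(path: str | Path) -> SnpPositionMap:
    """Read a SNP position table with SNP and BP columns (extras ignored)."""
    path = Path(path)
    df = _read_table(path, ("SNP", "BP"))
    return SnpPositionMap(
        snps=df["SNP"].astype(str).tolist(),
        bp=_int_column(df, "BP", path),
    )


# ---------------------------------------------------------------------------
# output matrix
# ---------------------------------------------------------------------------

_SEPS = {"tsv": "\t", "csv": ","}


def write_counts(m: GeneCountMatrix, path: str | Path, format: str = "tsv") -> None:
    """Write a gene × individual count matrix as delimited text.

    The header is ``GENE`` followed by the individual IDs; one row per gene,
    integer cells, rows and columns in the matrix's stored order. The empty
    sentinel serialises to a header-only file (and logs a warning), so the
    write → read round trip is lossless for every valid matrix.
    """
    if format not in _SEPS:
        raise ValueError(f"unknown output format {format!r} (expected tsv or csv)")
    if m.is_empty:
        logger.warning(
            "writing empty result to %s: no gene retained any allele count", path
        )
    m.to_frame().to_csv(path, sep=_SEPS[format], index=False)


def read_counts(path: str | Path, format: str | None = None) -> GeneCountMatrix:
    """Read back a matrix written by :func:`write_counts`."""
    path = Path(path)
    if format is None:
        with open(path) as fh:
            first = fh.readline()
        format = "csv" if ("," in first and "\t" not in first) else "tsv"
    df = pd.read_csv(path, sep=_SEPS[format])
    if df.columns[0] != "GENE":
        raise FormatError(f"{path}: first column must be GENE, got {df.columns[0]!r}")
    counts = df.iloc[:, 1:].to_numpy(dtype=np.int64) if df.shape[1] > 1 else np.empty(
        (len(df), 0), dtype=np.int64
    )
    return GeneCountMatrix(
        genes=df["GENE"].astype(str).tolist(),
        individual_ids=[str(c) for c in df.columns[1:]],
        counts=counts,
    )


def read_id_list(path: str | Path) -> list[str]:
    """Read a one-ID-per-line text file; blank lines are skipped."""
    path = Path(path)
    ids = [line.strip() for line in path.read_text().splitlines()]
    ids = [i for i in ids if i]
    if not ids:
        raise DataValidationError(f"{path}: ID list file contains no IDs")
    _require_unique(ids, f"ID in {path}")
    return ids
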