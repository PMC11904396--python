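"""Synthetic paired genotype datasets with known gene-level count truth.

:func:`generate_dataset` lays non-overlapping gene intervals on a single
coordinate axis, samples SNP positions inside the genes (and optionally in
the intergenic gaps), draws genotypes as Binomial(2, maf) per individual per
SNP, masks a fraction as missing, and writes the same genotypes as both a
PLINK ``--recode A`` text file and a VCF. The gene-level count matrix is
computed *during sampling* from the generator's own bookkeeping of which SNP
belongs to which gene — it never calls the counting engine — so it serves as
independent ground truth for round-trip tests.

The generator emulates only the combinatorial structure the counting engine
consumes (positions, intervals, dosages, missingness); it makes no attempt
at linkage disequilibrium, realistic site-frequency spectra, or pedigrees.

Draw order from the single seeded RNG stream is: per-gene SNP counts and
positions (gene by gene), then genotypes and missingness for the in-gene
SNPs, then — last — intergenic positions, genotypes and missingness. Keep
this order: every intergenic draw coming after every in-gene draw is what
makes the in-gene data — and hence the truth matrix — invariant to the
number of intergenic SNPs, and the single stream is what makes equal seeds
give byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .errors import DataValidationError, GenerationError
from .formats_io import GeneCountMatrix

__all__ = ["FixtureSpec", "FixtureTruth", "FixtureDataset", "ToyDataset",
           "generate_dataset", "toy_dataset"]

_GAP = 200          # intergenic gap width after every gene
_FIRST_START = 1001


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset.

    ``snps_per_gene`` is either a fixed count or an inclusive ``(lo, hi)``
    range drawn per gene. ``maf`` is the counted-allele frequency used for
    the Binomial(2, maf) genotype draws. Defaults describe a small but
    non-trivial cohort: 100 individuals, 20 genes of 1–8 SNPs each, 10
    intergenic SNPs, 5% allele frequency, 2% missingness.
    """

    n_individuals: int = 100
    n_genes: int = 20
    snps_per_gene: Union[int, tuple[int, int]] = (1, 8)
    intergenic_snps: int = 10
    maf: float = 0.05
    missing_rate: float = 0.02
    seed: int = 0
    chrom_label: str = "1"

    def __post_init__(self) -> None:
        if self.n_individuals < 0 or self.n_genes < 0 or self.intergenic_snps < 0:
            raise DataValidationError("counts must be non-negative")
        lo, hi = self._snp_range()
        if lo < 0 or hi < lo:
            raise DataValidationError("snps_per_gene range invalid")
        if not (0 < self.maf <= 0.5):
            raise DataValidationError("maf must lie in (0, 0.5]")
        if not (0 <= self.missing_rate < 1):
            raise DataValidationError("missing_rate must lie in [0, 1)")

    def _snp_range(self) -> tuple[int, int]:
        if isinstance(self.snps_per_gene, tuple):
            return self.snps_per_gene
        return (self.snps_per_gene, self.snps_per_gene)


@dataclass
class FixtureTruth:
    """Ground truth recorded while sampling.

    ``truth_counts`` is the gene × individual matrix (zero-count genes
    already excluded; the empty sentinel when nothing remains), built by
    summing each gene's own non-missing dosages. ``truth_dosages`` holds the
    sampled dosage matrix (NaN = missing) in emitted file column order, with
    ``variant_ids`` naming those columns.
    """

    truth_counts: GeneCountMatrix
    truth_dosages: np.ndarray
    variant_ids: list[str]
    individual_ids: list[str]


@dataclass
class FixtureDataset:
    spec: FixtureSpec
    raw_path: Optional[Path]
    vcf_path: Optional[Path]
    genes_path: Path
    snps_path: Path
    truth: FixtureTruth


def generate_dataset(
    spec: FixtureSpec,
    out_dir: str | Path,
    formats: tuple[str, ...] = ("raw", "vcf"),
) -> FixtureDataset:
    """Sample one dataset and write its files into ``out_dir``.

    ``formats`` selects which genotype encodings to emit ("raw", "vcf");
    the boundary and position tables are always written. Raises
    :class:`GenerationError` when the requested intergenic SNPs exceed the
    available gap space.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec._snp_range()

    # --- layout: genes, in-gene positions, then intergenic positions --------
    gene_names: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    gene_snp_names: list[list[str]] = []
    gene_snp_pos: list[np.ndarray] = []
    cursor = _FIRST_START
    for g in range(spec.n_genes):
        n_snps = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        span = 20 * n_snps + 20
        pos = np.sort(rng.choice(span, size=n_snps, replace=False)) + cursor
        gene_names.append(f"GENE{g + 1}")
        starts.append(cursor)
        ends.append(cursor + span - 1)
        gene_snp_names.append([f"SNP_G{g + 1}_{j + 1}" for j in range(n_snps)])
        gene_snp_pos.append(pos.astype(np.int64))
        cursor += span + _GAP

    # --- in-gene genotypes and missingness (before any intergenic draw) -----
    n = spec.n_individuals
    n_in = sum(len(p) for p in gene_snp_pos)
    genic = rng.binomial(2, spec.maf, size=(n, n_in)).astype(float)
    if spec.missing_rate > 0:
        genic[rng.random(size=genic.shape) < spec.missing_rate] = np.nan

    # --- intergenic SNPs last, so the in-gene data never depends on them ----
    gap_pool = np.concatenate(
        [np.arange(e + 1, e + 1 + _GAP, dtype=np.int64) for e in ends]
        if ends else [np.arange(1, 1001, dtype=np.int64)]
    )
    if spec.intergenic_snps > gap_pool.size:
        raise GenerationError(
            f"{spec.intergenic_snps} intergenic SNPs requested but only "
            f"{gap_pool.size} intergenic positions available"
        )
    inter_pos = np.sort(rng.choice(gap_pool, size=spec.intergenic_snps, replace=False))
    inter_names = [f"SNP_X{j + 1}" for j in range(spec.intergenic_snps)]
    inter = rng.binomial(2, spec.maf, size=(n, spec.intergenic_snps)).astype(float)
    if spec.missing_rate > 0:
        inter[rng.random(size=inter.shape) < spec.missing_rate] = np.nan

    # --- truth counts, straight from the generator's own gene membership ----
    individual_ids = [f"IND{i + 1:04d}" for i in range(n)]
    family_ids = [f"FAM{i + 1:04d}" for i in range(n)]
    truth_full = np.zeros((spec.n_genes, n), dtype=np.int64)
    offset = 0
    for g, pos in enumerate(gene_snp_pos):
        block = genic[:, offset:offset + len(pos)]
        truth_full[g] = np.nansum(block, axis=1).astype(np.int64) if block.size else 0
        offset += len(pos)
    keep = truth_full.any(axis=1)
    if keep.any():
        truth_counts = GeneCountMatrix(
            genes=[g for g, k in zip(gene_names, keep) if k],
            individual_ids=individual_ids,
            counts=truth_full[keep],
        )
    else:
        truth_counts = GeneCountMatrix(
            genes=[], individual_ids=individual_ids,
            counts=np.empty((0, n), dtype=np.int64),
        )

    # --- order variants by position for emission -----------------------------
    all_names = [s for names in gene_snp_names for s in names] + inter_names
    all_pos = np.concatenate(
        [np.concatenate(gene_snp_pos), inter_pos]
        if gene_snp_pos else [inter_pos.astype(np.int64)]
    ) if (gene_snp_pos or spec.intergenic_snps) else np.empty(0, dtype=np.int64)
    all_dosage = np.concatenate([genic, inter], axis=1)
    order = np.argsort(all_pos, kind="stable")
    all_names = [all_names[i] for i in order]
    all_pos = all_pos[order]
    all_dosage = all_dosage[:, order]

    # --- write files ----------------------------------------------------------
    genes_path = out_dir / "genes.tsv"
    snps_path = out_dir / "snps.tsv"
    _write_table(genes_path, ("GENE", "START", "END"),
                 zip(gene_names, starts, ends))
    _write_table(snps_path, ("SNP", "BP"), zip(all_names, all_pos.tolist()))

    raw_path = vcf_path = None
    if "raw" in formats:
        raw_path = out_dir / "genotypes.raw"
        _write_raw(raw_path, family_ids, individual_ids, all_names, all_dosage)
    if "vcf" in formats:
        vcf_path = out_dir / "genotypes.vcf"
        _write_vcf(vcf_path, spec.chrom_label, individual_ids, all_names,
                   all_pos, all_dosage)

    truth = FixtureTruth(
        truth_counts=truth_counts,
        truth_dosages=all_dosage,
        variant_ids=all_names,
        individual_ids=individual_ids,
    )
    return FixtureDataset(spec=spec, raw_path=raw_path, vcf_path=vcf_path,
                          genes_path=genes_path, snps_path=snps_path, truth=truth)


def _write_table(path: Path, header: tuple[str, ...], rows) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def _fmt_dosage(d: float) -> str:
    return "NA" if np.isnan(d) else str(int(d))


def _write_raw(path: Path, fids: list[str], iids: list[str],
               snp_names: list[str], dosage: np.ndarray,
               counted_allele: str = "G") -> None:
    with open(path, "w") as fh:
        cols = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        cols += [f"{s}_{counted_allele}" for s in snp_names]
        fh.write(" ".join(cols) + "\n")
        for i, (fid, iid) in enumerate(zip(fids, iids)):
            meta = [fid, iid, "0", "0", str(i % 2 + 1), "NA"]
            fh.write(" ".join(meta + [_fmt_dosage(d) for d in dosage[i]]) + "\n")


_GT_OF = {0: "0/0", 1: "0/1", 2: "1/1"}


def _write_vcf(path: Path, chrom: str, sample_ids: list[str],
               snp_names: list[str], pos: np.ndarray, dosage: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fixed = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if sample_ids:
            fh.write("\t".join(fixed + ["FORMAT"] + sample_ids) + "\n")
        else:
            fh.write("\t".join(fixed) + "\n")
        for j, (name, p) in enumerate(zip(snp_names, pos.tolist())):
            rec = [chrom, str(p), name, "A", "G", ".", ".", "."]
            if sample_ids:
                gts = ["./." if np.isnan(d) else _GT_OF[int(d)]
                       for d in dosage[:, j]]
                rec += ["GT"] + gts
            fh.write("\t".join(rec) + "\n")


# ---------------------------------------------------------------------------
# hand-written worked example (two genes, five individuals)
# ---------------------------------------------------------------------------

_TOY_RAW = """\
FID IID PAT MAT SEX PHENOTYPE SNP1_A SNP2_T SNP3_G SNP4_C SNP5_C
FID1 IID_sample1 0 0 1 NA 1 1 0 NA NA
FID2 IID_sample2 0 0 1 NA 0 1 0 NA 0
FID3 IID_sample3 0 0 1 1 0 0 1 0 0
FID4 IID_sample4 0 0 1 1 0 0 1 0 0
FID5 IID_sample5 0 0 1 1 0 0 1 0 0
"""

_TOY_GENES = """\
GENE\tSTART\tEND
GENE1\t100\t180
GENE2\t200\t400
"""

_TOY_SNPS = """\
SNP\tBP
SNP1\t100
SNP2\t101
SNP3\t201
"""

# Same five individuals and genotypes as the .raw file. SNP4/SNP5 carry
# placeholder positions outside both genes; the position table (which lacks
# them) is what drives the join, exactly as in the .raw path.
_TOY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tIID_sample1\tIID_sample2\tIID_sample3\tIID_sample4\tIID_sample5
1\t100\tSNP1\tC\tA\t.\t.\t.\tGT\t0/1\t0/0\t0/0\t0/0\t0/0
1\t101\tSNP2\tC\tT\t.\t.\t.\tGT\t0/1\t0/1\t0/0\t0/0\t0/0
1\t201\tSNP3\tC\tG\t.\t.\t.\tGT\t0/0\t0/0\t0/1\t0/1\t0/1
1\t500\tSNP4\tA\tC\t.\t.\t.\tGT\t./.\t./.\t0/0\t0/0\t0/0
1\t501\tSNP5\tA\tC\t.\t.\t.\tGT\t./.\t0/0\t0/0\t0/0\t0/0
"""


@dataclass
class ToyDataset:
    raw_path: Path
    genes_path: Path
    snps_path: Path
    vcf_path: Optional[Path] = None


def toy_dataset(out_dir: str | Path, include_vcf: bool = False) -> ToyDataset:
    """Write the package's worked example: 5 individuals, 5 SNPs, 2 genes.

    GENE1 spans [100, 180] and contains SNP1 (bp 100) and SNP2 (bp 101);
    GENE2 spans [200, 400] and contains SNP3 (bp 201). SNP4 and SNP5 appear
    in the genotype data but not in the position table, so the engine must
    ignore them. Individual 1 carries missing genotypes, exercising the
    missing-counts-as-zero rule. With ``include_vcf`` an equivalent VCF
    encoding of the same genotypes is written as well.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    raw = out_dir / "toy.raw"
    genes = out_dir / "toy_genes.tsv"
    snps = out_dir / "toy_snps.tsv"
    raw.write_text(_TOY_RAW)
    genes.write_text(_TOY_GENES)
    snps.write_text(_TOY_SNPS)
    vcf = None
    if include_vcf:
        vcf = out_dir / "toy.vcf"
        vcf.write_text(_TOY_VCF)
    return ToyDataset(raw_path=raw, genes_path=genes, snps_path=snps, vcf_path=vcf)
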