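# genecollapse

Gene/region-level allelic counting for rare-variant analyses.

Rare variants (minor allele frequency below ~1%) are individually too
infrequent to test for association; the standard remedy is to *collapse*
them — aggregate the variants falling inside each gene or genomic region
into one per-individual burden value. `genecollapse` computes the matrix
that every collapsing test starts from: for each gene *g* with boundaries
[START_g, END_g] and each individual *i*,

    C[g, i] = Σ_{s : START_g ≤ BP_s ≤ END_g}  d_{i,s}

where *d₍i,s₎* ∈ {0, 1, 2} is the additive dosage of the counted allele of
SNP *s* in individual *i* (missing genotypes contribute 0). The result is an
M × N matrix of genes with at least one allele count by individuals, ready
for burden/SKAT-style association testing.

It is aimed at statistical geneticists preparing whole-exome or
whole-genome cohorts: genotypes come in either as a PLINK additive-recoded
text table (`--recode A`) or as a VCF (per-sample GT field), together with a
gene boundary table (`GENE START END`, 1-based, both ends inclusive) and a
SNP position table (`SNP BP`).

## Worked example

The package ships a two-gene, five-individual example
(`genecollapse.toy_dataset`): GENE1 spans [100, 180] and contains SNP1
(bp 100) and SNP2 (bp 101); GENE2 spans [200, 400] and contains SNP3
(bp 201); SNP4 and SNP5 are genotyped but have no entry in the position
table; individual 1 carries missing (NA) genotypes.

```sh
python -c "from genecollapse import toy_dataset; toy_dataset('.')"
genecollapse count --geno toy.raw --genes toy_genes.tsv --snps toy_snps.tsv
```

prints (logging on stderr, matrix on stdout):

```
WARNING 2 SNP(s) have no entry in the SNP position table and were ignored: SNP4, SNP5
INFO counted 5 individual(s); 3 SNP(s) mapped, 2 without position, 0 without genotype; 2 gene(s) retained, 0 excluded
GENE	IID_sample1	IID_sample2	IID_sample3	IID_sample4	IID_sample5
GENE1	2	1	0	0	0
GENE2	0	0	1	1	1
```

Individual 1 carries one copy at SNP1 and one at SNP2, hence GENE1 = 2; its
NA genotypes at SNP4/SNP5 contribute nothing. Individuals 3–5 each carry
one SNP3 copy, giving GENE2 = 1. The same counts come from the library:

```python
from genecollapse import (gene_pos_counts, read_plink_raw,
                          read_gene_boundaries, read_snp_positions)
m = gene_pos_counts(read_plink_raw("toy.raw"),
                    read_gene_boundaries("toy_genes.tsv"),
                    read_snp_positions("toy_snps.tsv"))
print(m.to_frame())
```

and, for VCF input, from `vcf_counts_SNP_genecoords(path, genes, snps)`.

Key semantics (see `docs/methods.md` for the full account):

* missing genotypes count as zero;
* genes with zero counts across all individuals are dropped; if nothing
  remains the result is the falsy empty sentinel (`m.is_empty`);
* `SubsetSpec(keep_indiv=…, filter_gene=…, keep_snps=…)` restricts
  individuals, candidate genes and variants before counting;
* positions carry no chromosome: run one chromosome at a time (the
  `--chrom` flag declares this; otherwise duplicated BP values trigger a
  warning);
* `--carrier-mode` counts each individual at most once per variant.

`genecollapse simulate` writes a synthetic paired dataset (.raw + VCF +
tables) with its exact ground-truth count matrix, for pipeline testing.

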