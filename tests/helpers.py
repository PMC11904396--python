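"""Shared builders for randomized test instances."""

from __future__ import annotations

import numpy as np

from genecollapse import GeneBoundarySet, GenotypeMatrix, SnpPositionMap


def random_instance(rng, max_ind=50, max_snps=200, max_genes=30,
                    missing_rate=0.1, unpositioned_frac=0.1):
    """One random counting problem in both package and primitive form.

    Returns a dict with package containers (``genotypes``, ``genes``,
    ``positions``) and the plain-Python mirrors the brute-force oracle
    consumes (``individual_ids``, ``variant_ids``, ``dosage_lists``,
    ``gene_tuples``, ``position_dict``). Some SNPs are deliberately left out
    of the position table and some phantom positioned SNPs have no genotype
    column, matching real joins.
    """
    n_ind = int(rng.integers(1, max_ind + 1))
    n_snp = int(rng.integers(1, max_snps + 1))
    n_gene = int(rng.integers(1, max_genes + 1))

    individual_ids = [f"I{i}" for i in range(n_ind)]
    variant_ids = [f"S{j}" for j in range(n_snp)]
    dosage = rng.choice([0, 1, 2], size=(n_ind, n_snp),
                        p=[0.7, 0.2, 0.1]).astype(float)
    dosage[rng.random(size=dosage.shape) < missing_rate] = np.nan

    starts = rng.integers(1, 900, size=n_gene)
    lengths = rng.integers(0, 120, size=n_gene)
    gene_tuples = [
        (f"G{k}", int(s), int(s + l)) for k, (s, l) in enumerate(zip(starts, lengths))
    ]

    position_dict = {
        s: int(rng.integers(1, 1050))
        for s in variant_ids
        if rng.random() > unpositioned_frac
    }
    # phantom SNPs: positioned but absent from the genotype matrix
    for p in range(int(rng.integers(0, 4))):
        position_dict[f"PHANTOM{p}"] = int(rng.integers(1, 1050))

    genotypes = GenotypeMatrix(
        individual_ids=individual_ids,
        family_ids=[f"F{i}" for i in range(n_ind)],
        variant_ids=variant_ids,
        counted_alleles=["A"] * n_snp,
        dosages=dosage,
    )
    genes = GeneBoundarySet(
        genes=[g for g, _, _ in gene_tuples],
        start=np.array([s for _, s, _ in gene_tuples]),
        end=np.array([e for _, _, e in gene_tuples]),
    )
    pos_items = list(position_dict.items())
    positions = SnpPositionMap(
        snps=[s for s, _ in pos_items],
        bp=np.array([b for _, b in pos_items], dtype=np.int64),
    )
    dosage_lists = [
        [None if np.isnan(v) else int(v) for v in row] for row in dosage
    ]
    return dict(
        genotypes=genotypes, genes=genes, positions=positions,
        individual_ids=individual_ids, variant_ids=variant_ids,
        dosage_lists=dosage_lists, gene_tuples=gene_tuples,
        position_dict=position_dict,
    )


def counts_match_oracle(result, oracle_out) -> bool:
    """Compare an engine GeneCountMatrix with the oracle triple's output."""
    o_genes, o_indivs, o_rows = oracle_out
    if result.is_empty:
        return o_genes == []
    return (
        result.genes == o_genes
        and result.individual_ids == o_indivs
        and result.counts.tolist() == o_rows
    )
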