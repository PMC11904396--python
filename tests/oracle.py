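"""Naive reference implementation used as an independent test oracle.

Everything here is deliberately dumb: a triple loop over individuals, genes
and SNPs on plain Python structures, with no shared code (and no shared
containers) with the package's engine. Missing dosages are ``None``.
"""

from __future__ import annotations

from typing import Optional


def oracle_counts(
    individual_ids: list[str],
    variant_ids: list[str],
    dosages: list[list[Optional[int]]],
    genes: list[tuple[str, int, int]],
    positions: dict[str, int],
    keep_indiv: Optional[set[str]] = None,
    filter_gene: Optional[set[str]] = None,
    keep_snps: Optional[set[str]] = None,
    carrier: bool = False,
) -> tuple[list[str], list[str], list[list[int]]]:
    """Gene × individual sums by brute force; returns (genes, indivs, rows).

    Zero-count genes are dropped after subsetting, matching the contract
    under test. ``dosages`` is row-per-individual, column-per-variant.
    """
    indivs = [i for i in individual_ids if keep_indiv is None or i in keep_indiv]
    cand = [(g, s, e) for g, s, e in genes if filter_gene is None or g in filter_gene]
    out_genes: list[str] = []
    rows: list[list[int]] = []
    for gname, start, end in cand:
        row = []
        for indiv in indivs:
            i = individual_ids.index(indiv)
            total = 0
            for j, snp in enumerate(variant_ids):
                if keep_snps is not None and snp not in keep_snps:
                    continue
                if snp not in positions:
                    continue
                if not (start <= positions[snp] <= end):
                    continue
                d = dosages[i][j]
                if d is None:
                    continue
                total += min(d, 1) if carrier else d
            row.append(total)
        if any(v > 0 for v in row):
            out_genes.append(gname)
            rows.append(row)
    return out_genes, indivs, rows


def oracle_assignment(
    positions: dict[str, int], genes: list[tuple[str, int, int]]
) -> set[tuple[str, str]]:
    """All (snp, gene) pairs by an O(S×G) double loop, bounds inclusive."""
    return {
        (snp, g)
        for snp, bp in positions.items()
        for g, s, e in genes
        if s <= bp <= e
    }
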