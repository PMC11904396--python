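"""Counting engine: SNP→gene assignment, summation and subsetting semantics."""

import numpy as np
import pytest

from genecollapse import (
    DataValidationError,
    GeneBoundarySet,
    GenotypeMatrix,
    SnpPositionMap,
    SubsetSpec,
    assign_snps_to_genes,
    gene_pos_counts,
    read_gene_boundaries,
    read_plink_raw,
    read_snp_positions,
    validate_single_region_space,
    vcf_counts_SNP_genecoords,
)
from helpers import counts_match_oracle, random_instance
from oracle import oracle_assignment, oracle_counts


def _genes(*rows):
    return GeneBoundarySet(
        genes=[r[0] for r in rows],
        start=np.array([r[1] for r in rows]),
        end=np.array([r[2] for r in rows]),
    )


def _positions(d):
    return SnpPositionMap(snps=list(d), bp=np.array(list(d.values()), dtype=np.int64))


def _geno(ids, variants, rows):
    return GenotypeMatrix(
        individual_ids=ids,
        family_ids=ids,
        variant_ids=variants,
        counted_alleles=["A"] * len(variants),
        dosages=np.array(rows, dtype=float),
    )


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------


def test_assignment_worked_example(toy):
    pairs = assign_snps_to_genes(
        read_snp_positions(toy.snps_path), read_gene_boundaries(toy.genes_path)
    ).pairs
    assert pairs == {("SNP1", "GENE1"), ("SNP2", "GENE1"), ("SNP3", "GENE2")}


@pytest.mark.parametrize(
    "bp, expected",
    [(99, set()), (100, {"G"}), (180, {"G"}), (181, set())],
)
def test_assignment_boundaries_are_inclusive(bp, expected):
    a = assign_snps_to_genes(_positions({"S": bp}), _genes(("G", 100, 180)))
    assert {g for _, g in a.pairs} == expected


def test_snp_in_overlapping_genes_pairs_with_each(rng):
    a = assign_snps_to_genes(
        _positions({"S": 150}), _genes(("GA", 100, 200), ("GB", 140, 160))
    )
    assert a.pairs == {("S", "GA"), ("S", "GB")}


def test_assignment_matches_double_loop_oracle(rng):
    for _ in range(20):
        inst = random_instance(rng)
        got = assign_snps_to_genes(inst["positions"], inst["genes"]).pairs
        assert got == oracle_assignment(inst["position_dict"], inst["gene_tuples"])


# ---------------------------------------------------------------------------
# counting: worked example and stated contracts
# ---------------------------------------------------------------------------


def test_counts_worked_example(toy):
    res = gene_pos_counts(
        read_plink_raw(toy.raw_path),
        read_gene_boundaries(toy.genes_path),
        read_snp_positions(toy.snps_path),
    )
    assert res.genes == ["GENE1", "GENE2"]
    assert res.individual_ids == [f"IID_sample{i}" for i in range(1, 6)]
    assert res.counts.tolist() == [[2, 1, 0, 0, 0], [0, 0, 1, 1, 1]]
    assert res.stats.n_snps_mapped == 3
    assert res.stats.n_snps_without_position == 2  # SNP4, SNP5
    assert res.stats.n_genes_retained == 2


def test_vcf_path_equals_raw_path_on_worked_example(toy):
    genes = read_gene_boundaries(toy.genes_path)
    pos = read_snp_positions(toy.snps_path)
    assert vcf_counts_SNP_genecoords(toy.vcf_path, genes, pos) == gene_pos_counts(
        read_plink_raw(toy.raw_path), genes, pos
    )


def test_missing_dosages_count_as_zero():
    # individual I1 is missing at both SNPs yet still gets a (zero) column;
    # I2's single copy keeps the gene in the output
    g = _geno(["I1", "I2"], ["S1", "S2"],
              [[np.nan, np.nan], [1.0, np.nan]])
    res = gene_pos_counts(g, _genes(("G", 1, 10)), _positions({"S1": 5, "S2": 6}))
    assert res.counts.tolist() == [[0, 1]]


def test_all_zero_gene_excluded_and_empty_sentinel():
    g = _geno(["I1"], ["S1", "S2"], [[2.0, 0.0]])
    genes = _genes(("HOT", 1, 10), ("COLD", 20, 30))
    pos = _positions({"S1": 5, "S2": 25})
    res = gene_pos_counts(g, genes, pos)
    assert res.genes == ["HOT"] and res.stats.n_genes_excluded == 1

    empty = gene_pos_counts(_geno(["I1"], ["S1"], [[0.0]]),
                            _genes(("G", 1, 10)), _positions({"S1": 5}))
    assert empty.is_empty and not empty
    assert empty.individual_ids == ["I1"]


def test_snps_outside_all_genes_give_empty_sentinel():
    res = gene_pos_counts(_geno(["I1"], ["S1"], [[2.0]]),
                          _genes(("G", 100, 110)), _positions({"S1": 5}))
    assert res.is_empty


def test_gene_order_follows_boundary_table_columns_follow_source():
    g = _geno(["B", "A"], ["S2", "S1"], [[1.0, 1.0], [1.0, 2.0]])
    res = gene_pos_counts(
        g, _genes(("GZ", 20, 30), ("GA", 1, 10)),
        _positions({"S1": 5, "S2": 25}),
    )
    assert res.genes == ["GZ", "GA"]
    assert res.individual_ids == ["B", "A"]
    assert res.counts.tolist() == [[1, 1], [1, 2]]


def test_carrier_mode_caps_each_variant_at_one():
    g = _geno(["I1", "I2"], ["S1", "S2"], [[2.0, 2.0], [0.0, 1.0]])
    genes, pos = _genes(("G", 1, 10)), _positions({"S1": 2, "S2": 3})
    assert gene_pos_counts(g, genes, pos).counts.tolist() == [[4, 1]]
    assert gene_pos_counts(g, genes, pos, carrier_mode=True).counts.tolist() == [[2, 1]]


# ---------------------------------------------------------------------------
# subsetting
# ---------------------------------------------------------------------------


@pytest.fixture()
def toy_inputs(toy):
    return (
        read_plink_raw(toy.raw_path),
        read_gene_boundaries(toy.genes_path),
        read_snp_positions(toy.snps_path),
    )


def test_filter_gene_restricts_to_named_genes(toy_inputs):
    g, genes, pos = toy_inputs
    res = gene_pos_counts(g, genes, pos, subset=SubsetSpec(filter_gene={"GENE2"}))
    assert res.genes == ["GENE2"]
    assert res.counts.tolist() == [[0, 0, 1, 1, 1]]


def test_keep_indiv_restricts_columns_before_counting(toy_inputs):
    g, genes, pos = toy_inputs
    res = gene_pos_counts(
        g, genes, pos,
        subset=SubsetSpec(keep_indiv={"IID_sample1", "IID_sample3"}),
    )
    assert res.individual_ids == ["IID_sample1", "IID_sample3"]
    assert res.counts.tolist() == [[2, 0], [0, 1]]


def test_keep_snps_restricts_variants_before_assignment(toy_inputs):
    g, genes, pos = toy_inputs
    res = gene_pos_counts(g, genes, pos, subset=SubsetSpec(keep_snps={"SNP1"}))
    assert res.genes == ["GENE1"]
    assert res.counts.tolist() == [[1, 0, 0, 0, 0]]


def test_all_unknown_keep_lists_raise(toy_inputs):
    g, genes, pos = toy_inputs
    with pytest.raises(DataValidationError, match="individual"):
        gene_pos_counts(g, genes, pos, subset=SubsetSpec(keep_indiv={"NOBODY"}))
    with pytest.raises(DataValidationError, match="gene"):
        gene_pos_counts(g, genes, pos, subset=SubsetSpec(filter_gene={"GENE9"}))


def test_partially_unknown_keep_list_warns_and_proceeds(toy_inputs, caplog):
    g, genes, pos = toy_inputs
    with caplog.at_level("WARNING", logger="genecollapse"):
        res = gene_pos_counts(
            g, genes, pos,
            subset=SubsetSpec(keep_indiv={"IID_sample2", "GHOST"}),
        )
    assert res.individual_ids == ["IID_sample2"]
    assert "GHOST" in caplog.text


def test_empty_subset_sets_are_rejected():
    with pytest.raises(DataValidationError, match="keep_indiv"):
        SubsetSpec(keep_indiv=frozenset())


def test_unmatched_snps_warn_aggregated(toy_inputs, caplog):
    g, genes, pos = toy_inputs
    with caplog.at_level("WARNING", logger="genecollapse"):
        gene_pos_counts(g, genes, pos)
    msgs = [r.message for r in caplog.records if "ignored" in r.message]
    assert len(msgs) == 1  # one aggregated line, not one per SNP
    assert "2 SNP(s)" in msgs[0]


def test_zero_row_exclusion_is_evaluated_after_subsetting():
    # With only I2 kept, gene G keeps no counts and the result is empty —
    # slicing the full run's output instead would have kept a zero row.
    g = _geno(["I1", "I2"], ["S1"], [[2.0], [0.0]])
    genes, pos = _genes(("G", 1, 10)), _positions({"S1": 5})
    full = gene_pos_counts(g, genes, pos)
    assert full.genes == ["G"]
    sub = gene_pos_counts(g, genes, pos, subset=SubsetSpec(keep_indiv={"I2"}))
    assert sub.is_empty


# ---------------------------------------------------------------------------
# randomized properties against the brute-force oracle
# ---------------------------------------------------------------------------


def test_engine_matches_triple_loop_oracle(rng):
    for _ in range(30):
        inst = random_instance(rng)
        res = gene_pos_counts(inst["genotypes"], inst["genes"], inst["positions"])
        expected = oracle_counts(
            inst["individual_ids"], inst["variant_ids"], inst["dosage_lists"],
            inst["gene_tuples"], inst["position_dict"],
        )
        assert counts_match_oracle(res, expected)


def test_engine_matches_oracle_under_subsetting(rng):
    for _ in range(15):
        inst = random_instance(rng, max_ind=20, max_snps=60, max_genes=12)
        keep = set(
            rng.choice(inst["individual_ids"],
                       size=max(1, len(inst["individual_ids"]) // 2),
                       replace=False)
        )
        fg = set(
            rng.choice([g for g, _, _ in inst["gene_tuples"]],
                       size=max(1, len(inst["gene_tuples"]) // 2),
                       replace=False)
        )
        res = gene_pos_counts(
            inst["genotypes"], inst["genes"], inst["positions"],
            subset=SubsetSpec(keep_indiv=frozenset(keep),
                              filter_gene=frozenset(fg)),
        )
        expected = oracle_counts(
            inst["individual_ids"], inst["variant_ids"], inst["dosage_lists"],
            inst["gene_tuples"], inst["position_dict"],
            keep_indiv=keep, filter_gene=fg,
        )
        assert counts_match_oracle(res, expected)


def test_conservation_on_disjoint_fully_positioned_layout(rng):
    # disjoint genes covering every positioned SNP: the grand total of the
    # output equals the total of all non-missing dosages
    n_ind, n_snp = 20, 40
    bp = np.arange(1, n_snp + 1) * 10
    genes = _genes(*[(f"G{k}", int(k * 100 + 1), int(k * 100 + 100))
                     for k in range(4)])
    pos = SnpPositionMap(snps=[f"S{j}" for j in range(n_snp)],
                         bp=np.array([int(b % 400) + 1 for b in bp]))
    dosage = rng.choice([0, 1, 2], size=(n_ind, n_snp)).astype(float)
    dosage[rng.random(size=dosage.shape) < 0.1] = np.nan
    g = _geno([f"I{i}" for i in range(n_ind)], list(pos.snps), dosage)
    res = gene_pos_counts(g, genes, pos)
    assert res.counts.sum() == int(np.nansum(dosage))


def test_adding_an_individual_leaves_other_counts_unchanged(rng):
    inst = random_instance(rng, max_ind=10, max_snps=50, max_genes=8,
                           missing_rate=0.0, unpositioned_frac=0.0)
    g = inst["genotypes"]
    extra = np.full((1, g.n_variants), 2.0)
    g2 = GenotypeMatrix(
        individual_ids=g.individual_ids + ["NEW"],
        family_ids=g.family_ids + ["NEW"],
        variant_ids=g.variant_ids,
        counted_alleles=g.counted_alleles,
        dosages=np.vstack([g.dosages, extra]),
    )
    r1 = gene_pos_counts(g, inst["genes"], inst["positions"])
    r2 = gene_pos_counts(g2, inst["genes"], inst["positions"])
    for k, gene in enumerate(r1.genes):
        row2 = r2.counts[r2.genes.index(gene)]
        assert row2[: g.n_individuals].tolist() == r1.counts[k].tolist()


def test_enlarging_an_interval_never_decreases_its_counts(rng):
    inst = random_instance(rng, max_ind=15, max_snps=60, max_genes=6)
    genes = inst["genes"]
    wide = GeneBoundarySet(
        genes=list(genes.genes),
        start=np.maximum(genes.start - 50, 1),
        end=genes.end + 50,
    )
    r1 = gene_pos_counts(inst["genotypes"], genes, inst["positions"])
    r2 = gene_pos_counts(inst["genotypes"], wide, inst["positions"])
    for k, gene in enumerate(r1.genes):
        assert gene in r2.genes
        assert (r2.counts[r2.genes.index(gene)] >= r1.counts[k]).all()


def test_subset_commutation_on_shared_rows(rng):
    # counting-then-slicing equals slicing-then-counting on genes retained by
    # both; only the zero-row exclusion (post-subset) may differ
    for _ in range(10):
        inst = random_instance(rng, max_ind=15, max_snps=60, max_genes=8)
        ids = inst["individual_ids"]
        keep = list(ids[: max(1, len(ids) // 2)])
        full = gene_pos_counts(inst["genotypes"], inst["genes"], inst["positions"])
        sub = gene_pos_counts(
            inst["genotypes"], inst["genes"], inst["positions"],
            subset=SubsetSpec(keep_indiv=frozenset(keep)),
        )
        cols = [full.individual_ids.index(i) for i in keep] if full else []
        shared = set(full.genes) & set(sub.genes) if (full and sub) else set()
        assert set(sub.genes) <= set(full.genes)  # subsetting can only drop genes
        for gene in shared:
            sliced = full.counts[full.genes.index(gene)][cols]
            assert sliced.tolist() == sub.counts[sub.genes.index(gene)].tolist()


# ---------------------------------------------------------------------------
# duplicate base-pair guard
# ---------------------------------------------------------------------------


def test_duplicate_bp_warns_naming_position(caplog):
    with caplog.at_level("WARNING", logger="genecollapse"):
        warnings = validate_single_region_space(_positions({"A": 500, "B": 500}))
    assert len(warnings) == 1
    assert warnings[0].positions == (500,)
    assert "500" in caplog.text


def test_distinct_bp_and_declared_chrom_do_not_warn():
    assert validate_single_region_space(_positions({"A": 500, "B": 501})) == []
    dup = _positions({"A": 500, "B": 500})
    assert validate_single_region_space(dup, declared_chrom="chr1") == []


def test_duplicate_bp_count_matches_brute_force_scan(rng):
    bp = rng.integers(1, 400, size=1000)
    pos = SnpPositionMap(snps=[f"S{j}" for j in range(1000)], bp=bp)
    warnings = validate_single_region_space(pos)
    brute = sorted({int(v) for v in bp if (bp == v).sum() > 1})
    assert list(warnings[0].positions) == brute
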