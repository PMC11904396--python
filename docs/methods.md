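# Methods

## The counting model

`genecollapse` computes a gene/region × individual matrix of summed allele
counts. Inputs are (a) an individuals × variants additive dosage matrix
*d* with entries in {0, 1, 2, missing} — parsed from PLINK `--recode A`
text or from the GT field of a VCF — (b) a set of named 1-based intervals
[START, END], and (c) a SNP → base-pair map. SNP *s* is assigned to gene
*g* iff START_g ≤ BP_s ≤ END_g, with **both bounds inclusive**; the count
is C[g, i] = Σ over assigned SNPs of d[i, s].

The inclusive-inclusive convention is a design choice: gene boundary tables
in this field conventionally state the first and last base belonging to the
feature (unlike BED's half-open intervals), and it makes a SNP sitting
exactly on START or END count. A SNP inside several overlapping genes
contributes independently to each — counts are per-gene sums, not a
partition of variants, and any exclusive assignment would need a tie-break
rule with no biological justification.

### Output semantics

* **Missing counts as zero.** A missing genotype is evidence of nothing, so
  it adds nothing; it never propagates NA into the output.
* **Zero-row exclusion.** Genes with zero counts across all individuals are
  dropped. Rows therefore always have at least one positive entry.
* **Empty sentinel.** When no gene survives, the result is a distinguished
  empty matrix: zero gene rows, falsy, `is_empty` true, but retaining the
  individual IDs so that serialisation still produces a meaningful
  header-only file. This mirrors a NULL return while staying typed.
* **Determinism.** Rows follow boundary-table order, columns follow
  genotype-source order, so outputs diff cleanly.

### Subsetting

`keep_indiv` (matched on IID) restricts columns before counting,
`filter_gene` restricts candidate genes, `keep_snps` restricts variants
before assignment. A keep/filter list none of whose IDs exist raises — an
all-unknown list almost always means a join mistake (wrong file, wrong ID
scheme) — while a partially-unknown list only warns. Zero-row exclusion
runs **after** subsetting, so a gene that survives a full run can vanish
from a subset run (its counts may live entirely in dropped columns); the
subset-commutation test pins down exactly this difference.

SNPs present in the genotype data but absent from the position table (or
vice versa) are ignored with one aggregated warning per direction — never
one line per SNP, so logs stay readable at biobank scale.

### Dosage conventions

PLINK `--recode A` columns are split on the **last** underscore into SNP ID
and counted allele, so SNP IDs may contain underscores. VCF dosage counts
every non-reference allele index once (`2/1` → 2): the quantity of interest
is "how many non-reference alleles does this individual carry here", which
collapses multi-allelic sites conservatively. Any `.` allele — including
half-calls like `./1` — makes the genotype missing; counting the known half
of a half-call would mix evidence levels within one matrix entry.
Fractional (imputed) dosages are rejected rather than rounded: the engine's
contract is integer allele counts, and silently accepting dosages would
change the output's meaning.

An optional **carrier mode** clips each variant's dosage to 0/1 before
summing, giving "number of variants carried" instead of "number of
alleles". It is off by default.

### Single-axis coordinates

The engine has no chromosome axis: positions are bare base pairs, and users
process one chromosome at a time. `validate_single_region_space` emits a
prominent warning (never an error) when duplicated BP values exist and no
single-chromosome declaration was given, since identical positions on
different chromosomes would otherwise be silently conflated.

## Synthetic data generator

`generate_dataset(FixtureSpec(...))` emulates the combinatorial structure
the engine consumes: non-overlapping gene intervals on one axis, SNP
positions sampled uniquely inside genes plus optional intergenic SNPs in
the gaps, genotypes drawn i.i.d. Binomial(2, maf), and missingness masked
i.i.d. at `missing_rate`. Defaults — 100 individuals, 20 genes of 1–8 SNPs,
10 intergenic SNPs, maf 0.05, 2% missingness — describe a small cohort with
uncommon variants, sized so every property test runs in seconds.

The ground-truth count matrix is computed during sampling from the
generator's own record of which SNP belongs to which gene; it never touches
the counting engine, so engine-equals-truth is a genuine round trip through
the emitted files. Genes are kept non-overlapping so the conservation
property (grand total of counts = total of in-gene non-missing dosages)
holds exactly; overlap behaviour is covered by dedicated hand-built cases.

All draws come from one seeded RNG stream in a fixed order — gene layout,
in-gene genotypes and missingness, then every intergenic draw last — which
gives byte-identical files per seed and makes the in-gene data (hence the
truth matrix) invariant to the number of intergenic SNPs. Refactorings that
reorder draws will change emitted fixtures even at the same seed.

What the generator does **not** emulate: linkage disequilibrium, realistic
site-frequency spectra, genotyping-batch missingness patterns, pedigree
structure, multi-allelic sites, or genotype discordance between formats.
Passing round-trip tests therefore demonstrates the counting and parsing
semantics, not robustness to the messiness of real sequencing data.

## Numerical and implementation choices

* Dosages are held as float64 with NaN for missing; sums are computed by a
  sparse 0/1 assignment-matrix product and rounded to int64. All inputs are
  integers, so no precision is lost.
* Interval lookup uses an interval tree (half-open internally; END + 1 on
  insertion restores inclusive ends).
* Degenerate inputs are legal where they are meaningful: header-only
  genotype files (0 individuals), empty assignments, and sample-less VCFs
  all flow through to the empty sentinel; malformed files raise typed
  errors (`FormatError` vs `DataValidationError`) that the CLI maps to
  distinct exit codes (3 and 4; 0 covers success including the empty
  result, 2 is a usage error, 5 an I/O failure).

## Validation scales

The randomized oracle comparison uses instances up to 50 individuals × 200
SNPs × 30 genes against a brute-force triple loop; generator round trips
run 50 seeds at 20 × ~20 × 6 through both file formats; the cohort-scale
smoke test runs 10,000 individuals × ~5,000 SNPs × 500 genes through the
text `.raw` path end to end, and the acceptance script repeats a
2,000-individual version. These sizes exercise the dense-matrix code paths
well past where shape bugs hide while keeping the default test run fast.

## Known limitations

* No PLINK binary (.bed/.bim/.fam) or bgen input; users pre-recode.
* No annotation-aware filtering (consequence, CADD, etc.); the variant list
  is whatever the position table and `keep_snps` say.
* One chromosome per run, by design; no chromosome column is read.
* Matching `keep_indiv` on IID alone assumes IIDs are unique across
  families (duplicates are rejected at parse time rather than
  disambiguated via FID).
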