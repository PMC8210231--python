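# Methods

## The screen

The package identifies candidate cancer-related non-coding recurrent
mutations (CNRMs) by composing two ideas: *recurrence* — a position
mutated independently in several tumors is unlikely by chance given the
genome's length — and *regulatory context* — a non-coding mutation can
only plausibly act if it sits in active regulatory DNA wired to a gene.
The operational definition is a ten-criterion cascade over two cohorts:
a curated catalog cohort (source of recurrence evidence, with tissue,
individual, somatic-confirmation and SNP annotations) and a WGS cohort
(source of positional confirmation and matched expression). Criteria
1–4 clean the catalog at the record level, criterion 5 removes exonic
positions (exon union from the gene annotation), criterion 6 calls
recurrent positions and requires support from ≥ 2 cancer types (single-
type recurrence is confounded by localized, type-specific mutational
processes such as UV damage at transcription-factor-occupied sites),
criterion 7 intersects with the WGS cohort by position, and criteria
8–10 require containment in an ATAC-seq peak, in either anchor of a
chromatin interaction, and in a TFBS with match score ≥ 400.

Positions are keyed by (chromosome, position) only, not by allele:
this is what makes the downstream pattern-consistency classification
("same" iff exactly one ref→alt pair is observed across supporting
samples) meaningful. Substitution patterns are collapsed to the
standard six pyrimidine-reference classes by reverse-complementing
purine-referenced substitutions.

Coordinates: intervals are 0-based half-open throughout; mutation
positions are stored 1-based (the convention of VCF/COSMIC-style
sources) and converted at query time. Chromosome names are normalized
to `chrN` at ingest. Only single-nucleotide substitutions are admitted:
indels and multi-nucleotide records are rejected at ingest with a
logged count, because both the six-class spectrum and Δbit are defined
for single-base changes.

## Motif impact (Δbit)

For a position frequency matrix with column frequencies p_{b,i}, the
per-column information content is C_i = 2 + Σ_b p_{b,i} log2 p_{b,i}
with 0·log2 0 = 0, ranging from 0 (uniform) to 2 bits (invariant).
The per-substitution impact is expressed on the sequence-logo
letter-height scale, Δbit = (p_alt − p_ref)·C_i. This convention is
antisymmetric in (ref, alt), zero whenever the two alleles are equally
frequent, and negative when the mutation moves the sequence away from
the preferred base — matching the interpretation that negative values
create weaker binding sites. An alternative log-ratio convention
(log2 p_alt − log2 p_ref, with a 1e-6 frequency floor) is selectable
per call; the letter-height form is the default because it keeps the
statistic bounded and interpretable in bits even with zero
frequencies. For minus-strand sites, genomic alleles are complemented
and the column index reversed before lookup. Site-level impact is the
arithmetic mean of Δbit over all deduplicated mutation records in the
site (reported for sites with ≥ 2 records by default), and the
expectation under no selection is estimated by resampling: draw n
mutations from the pool of all TFBS-contained mutations, average their
Δbit, repeat, and report the mean of repetitions. At catalog scale the
natural sizes are 100 draws × 1000 repetitions; the synthetic runs use
25 × 500, matched to the synthetic pool (~60 TFBS-contained
mutations).

## Expression association

Expression from heterogeneous cancer types cannot be pooled directly,
so each gene is standardized to z-scores *within* each cancer type
(sample standard deviation, ddof = 1) before pooling. Strata with zero
variance or a single sample are masked and excluded. The reference
population for the z-scores is all samples of the type, mutated and
wild-type together; because the downstream test is rank-based, results
within a stratum are invariant to this location-scale choice.

For each surviving TFBS, the mutated group is every expression sample
carrying *any* mutation in the site — recurrent or not, since any hit
to a regulatory element can affect its targets — and the comparison is
a two-sided Wilcoxon rank-sum test. Groups of ≤ 8 each are tested by
exact enumeration of all assignments (midranks for ties; the two-sided
p doubles the smaller tail); larger groups use the tie-corrected normal
approximation. Sites with fewer than 5 mutated samples among the
expression cohort are excluded to retain statistical power. Target
genes are assigned through interaction anchors: gene G is a target of
site S iff some interaction has one anchor overlapping S and the other
containing G's TSS. Benjamini–Hochberg step-up adjustment is applied
once across all executed (site, gene) tests, with FDR < 0.25 as the
significance threshold and P < 0.1 as the per-test reporting threshold.
BH is implemented in-package (five lines of numpy) so that the test
suite can verify it against an independent reference implementation.

The neighbor-specificity check applies the identical comparison to the
k genes with the nearest TSSs (default k = 4, configurable per locus)
without multiplicity adjustment — it is a reporting table, not a test
family. The FDR-validation simulation draws random gene subsets and
random pseudo-mutated sample splits, runs the same test + BH pipeline,
and counts discoveries; under the null this mean should be far below
one discovery per repetition.

## Resampling nulls

Empirical p-values use the +1-smoothed estimator (r + 1)/(n_reps + 1),
bounded in [1/(n_reps+1), 1]; enrichment questions expose both tails
and a two-sided p (twice the smaller tail, capped at 1). Sampling is
without replacement within a repetition (a flag enables replacement)
and independent across repetitions; all draws derive from an explicit
seed and are bit-reproducible. The open-chromatin enrichment compares
the in-peak fraction of the recurrent positions against draws from the
full WGS-cohort mutation background (catalog-scale sizes: 10 000 draws
× 10 000 repetitions; synthetic runs: 500 × 1000). The per-peak
mutation-rate comparison divides peaks into those containing ≥ 1
recurrent position and the rest, computes per-sample mutation counts
per peak, and compares the two rate vectors with the two-sided
rank-sum test.

## Synthetic cohorts and what they show

The generator lays out a toy genome (2 chromosomes × 1 Mb; 20 genes per
chromosome with 10 kb spans, 3 exons of 300 bp, strand-aware TSSs)
and plants 7 CNRMs in intergenic gaps. Each planted locus is a motif
instance (score 500) centered in a gap, wrapped in a peak (site ± 50
bp) and in one anchor of an interaction whose partner anchor spans the
adjacent gene's TSS; the planted substitution hits the motif's
consensus base (dominant frequency 0.85, so C_i ≈ 1.15 bits and
Δbit ≈ −0.92), is carried by 3 catalog samples across ≥ 2 of 4 cancer
types and by 12 WGS samples, and down-regulates the target gene by 2
within-type SDs (log-normal expression, σ = 0.5 on the log scale).
Eleven decoys are constructed identically except for exactly one named
defect each — hematopoietic tissue, same-individual duplicate,
unconfirmed somatic, SNP flag, exonic position, single sample, single
cancer type, absence from the WGS cohort, no peak, no anchor, site
score 399 — so every criterion is exercised at least once. Background
mutations (40 per sample; 24 + 60 samples) occupy globally unique
positions outside exclusion zones around the planted loci, so they can
never form a recurrent position: planted-truth recovery is exact by
construction, and the tests verify that it is. A subset of ~60 catalog
background mutations is placed inside background TFBSs with
consensus-matching reference alleles to populate the Δbit null pool.

These choices mean the synthetic cohorts demonstrate the *mechanics*
of the screen — criterion coverage, funnel bookkeeping, strand
handling, statistical calibration, planted-effect power — not its
behavior on real data: real cohorts have non-unique background
positions (hence false-positive recurrence at hotspot-prone sites),
mutational signatures and trinucleotide context biases, correlated
expression, copy-number effects, and far larger element densities.
Passing tests show the implementation is faithful and calibrated, not
that the biological discovery rate of the published screen transfers.

## Defaults and problem sizes

| parameter | default | meaning |
|---|---|---|
| min_samples | 2 | distinct samples required for recurrence |
| min_cancer_types | 2 | cancer types among supporting samples |
| jaspar_min_score | 400 | TFBS match-score threshold |
| min_mutated | 5 | mutated expression samples per tested site |
| p_threshold / fdr_threshold | 0.1 / 0.25 | reporting / significance |
| effect_size δ | 2.0 SD | planted expression shift (generator) |
| consensus_freq | 0.85 | dominant base frequency of toy motifs |

Test and acceptance runs use scaled-down resampling (≤ 1000
repetitions) and cohort sizes (≤ ~3700 mutation records), chosen so the
whole validation executes in seconds while keeping every statistical
check well-powered; the catalog-scale sizes quoted above are the
defaults a real-data run would use.

## Numerical choices and edge cases

- 0·log2 0 = 0 exactly (no pseudocounts; PFM columns are normalized at
  parse time and must sum to 1 within 1e-9; zero-total columns are a
  format error).
- Individual deduplication keeps the lexicographically smallest
  sample id — the criterion itself does not specify a keep rule, and a
  deterministic tie-break is required for reproducibility.
- Empty partitions (per-peak test) and empty groups (expression
  comparison) are flagged rather than producing a p-value; an empty
  stage output completes the run with empty downstream reports.
- The funnel enforces chain consistency (each stage's input equals the
  previous output) and monotonicity at construction time.
- The three containment filters are applied in canonical order for
  funnel comparability; their final set is order-invariant and the
  tests check this indirectly through brute-force oracles.
- The coding-enrichment test is a one-sided exact binomial against the
  exon-union fraction of the genome; the comparison population is an
  explicit argument since published fractions can refer to different
  mutation sets.

## Known limitations

- Recurrence counts distinct sample identifiers after deduplication;
  if a catalog maps multiple samples per individual inconsistently,
  counts shift.
- The two cohorts' sample identifier spaces are treated as independent
  and intersected only on genomic position.
- The Δbit letter-height convention is one of several reasonable
  operationalizations of "difference in Shannon entropy"; the log-ratio
  alternative is provided but changes magnitudes (not the sign
  structure for consensus hits).
- No liftover between genome assemblies: all inputs must share one
  assembly.
- No covariate adjustment (purity, batch, copy number) in the
  expression screen, and no trinucleotide-context modeling in the
  recurrence stage.
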