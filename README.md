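# ncrm — screening candidate cancer-related non-coding recurrent mutations

Most cancer genomics has concentrated on the ~2% of the genome that codes
for protein, yet somatic mutations in regulatory DNA can also drive
disease (the classic example being the *TERT* promoter). `ncrm`
implements a pan-cancer screen for **candidate cancer-related non-coding
recurrent mutations (CNRMs)**: genomic positions mutated in at least two
samples across at least two cancer types that also fall in open
chromatin, inside a chromatin-interaction anchor, and within a predicted
transcription-factor binding site (TFBS). It is written for
computational cancer-genomics researchers who want a tested, end-to-end
reference implementation of this kind of recurrence-plus-regulation
screen, exercised on synthetic cohorts with planted truth rather than on
restricted patient data.

## What the package computes

**Filtering cascade (criteria 1–10).** Starting from a curated somatic
mutation catalog: (1) drop hematopoietic/lymphoid-tissue samples, (2)
keep one sample per individual, (3) keep somatic calls confirmed in
tumor/normal pairs, (4) drop SNP-flagged calls, (5) drop exonic
positions, (6) call *recurrent* positions — shared by ≥ 2 distinct
samples (allele-agnostic) — and require ≥ 2 cancer types, (7) keep
positions also mutated in a second, WGS-based cohort, then intersect
with (8) ATAC-seq open-chromatin peaks, (9) chromatin-interaction
anchors (3C/4C/5C/Hi-C/ChIA-PET/Capture-C/IM-PET pairs) and (10) TFBSs
with database match score ≥ 400. Every stage logs its in/out counts into
a funnel report.

**Motif impact (Δbit).** The information content of motif column *i* is

```
C_i = 2 + Σ_{b∈{A,C,G,T}} p_{b,i} · log2 p_{b,i}        (0·log2 0 = 0)
```

and the impact of a substitution ref→alt at column *i* is the
letter-height difference `Δbit = (p_alt,i − p_ref,i) · C_i`, negative
when the mutation weakens the site. Per-TFBS averages are compared with
a resampled expectation over random TFBS-contained mutations.

**Expression association.** Expression from heterogeneous cancer types
is integrated by per-gene z-scores within each cancer type; samples with
any mutation in a TFBS (recurrent or not) are compared with all others
by a two-sided Wilcoxon rank-sum test (exact for small groups); target
genes are assigned through interaction anchor pairs (one anchor overlaps
the site, the partner contains the gene's TSS); Benjamini–Hochberg
adjustment is applied once across the screen, with FDR < 0.25 and
P < 0.1 as the reporting thresholds. A resampling simulation of random
pseudo-mutated splits validates the FDR threshold.

**Synthetic cohorts.** `ncrm.simulate` generates seeded fixture bundles
— toy genome, two mutation cohorts, peaks, interactions, motifs with
located sites, expression — with planted CNRMs that satisfy all ten
criteria by construction and one decoy per criterion, plus a
machine-readable truth manifest.

## Worked example

```
ncrm simulate --seed 11 --out scratch/bundle
ncrm run --data scratch/bundle --out results/run --no-nulls
```

or equivalently the numbered drivers `python analysis/01_simulate.py`,
`02_screen.py`, … The screen on the seed-11 cohort prints this funnel:

```
            tissue:  1110 ->  1077 mutations (97.0%)
  individual_dedup:  1077 ->  1071 mutations (99.4%)
 somatic_confirmed:  1071 ->  1068 mutations (99.7%)
       snp_flagged:  1068 ->  1065 mutations (99.7%)
            exonic:  1065 ->  1049 mutations (98.5%)
        recurrence:  1049 ->    12 positions (1.1%)
 multi_cancer_type:    12 ->    11 positions (91.7%)
     second_cohort:    11 ->    10 positions (90.9%)
    open_chromatin:    10 ->     9 positions (90.0%)
       interaction:     9 ->     8 positions (88.9%)
              tfbs:     8 ->     7 positions (87.5%)
```

The seven surviving positions are exactly the seven planted CNRMs; the
eleven decoys each drop out at the stage whose criterion they violate.
Downstream, all seven planted site–gene pairs are recovered at
FDR < 0.25 with negative direction (e.g. `site_p0 → G1_18`,
p = 3.2e-07, FDR = 2e-06, direction −1: the target gene is
down-regulated in mutated samples), every planted site has a negative
average Δbit (−0.92: the mutations hit consensus bases of conserved
columns), and the FDR-validation simulation yields ~0.4 mean
discoveries per repetition on unaffected genes — chance discovery at
FDR < 0.25 is rare.

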