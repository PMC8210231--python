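"""Recurrent-mutation calling and the source-level filtering cascade.

The screen's first seven criteria operate here: removal of
hematopoietic/lymphoid-tissue records, one sample per individual,
somatic-confirmed only, no SNP-flagged calls, removal of exonic
positions, recurrence calling (>= 2 distinct samples at a position,
allele-agnostic), the multi-cancer-type requirement, and intersection
with a second cohort. Pattern consistency and the six-class substitution
spectrum, the coding-region enrichment test, and genomic-context
annotation also live here.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from scipy.stats import binomtest

from .core import (
    COMPLEMENT,
    ConfigurationError,
    DataError,
    GeneModel,
    IntervalIndex,
    SomaticMutation,
    total_length,
)

SIX_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

HEMATOPOIETIC_TISSUE = "haematopoietic_and_lymphoid_tissue"


def is_hematopoietic(tissue_site: Optional[str]) -> bool:
    # tolerate both British and American spellings of the COSMIC label
    return tissue_site is not None and "matopoietic" in tissue_site.lower()


def collapse_substitution(ref: str, alt: str) -> str:
    """Collapse a substitution to its pyrimidine-reference six-class label."""
    if ref in ("G", "A"):
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return f"{ref}>{alt}"


@dataclass
class FunnelStep:
    label: str
    n_in: int
    n_out: int
    unit: str = "mutations"

    @property
    def retention_percent(self) -> Optional[float]:
        if self.n_in == 0:
            return None
        return 100.0 * self.n_out / self.n_in


@dataclass
class FunnelReport:
    """Ordered per-criterion input/output counts for a screening run."""

    steps: list = field(default_factory=list)

    def add(self, label: str, n_in: int, n_out: int, unit: str = "mutations") -> None:
        if n_out > n_in:
            raise DataError(
                f"funnel step {label!r} increased the count ({n_in} -> {n_out})"
            )
        if self.steps and self.steps[-1].n_out != n_in:
            raise DataError(
                f"funnel step {label!r} input {n_in} != previous output "
                f"{self.steps[-1].n_out}"
            )
        self.steps.append(FunnelStep(label, n_in, n_out, unit))

    @property
    def final_count(self) -> Optional[int]:
        return self.steps[-1].n_out if self.steps else None

    def to_records(self) -> list:
        return [
            {
                "step": s.label,
                "n_in": s.n_in,
                "n_out": s.n_out,
                "unit": s.unit,
                "retention_percent": (
                    None
                    if s.retention_percent is None
                    else round(s.retention_percent, 1)
                ),
            }
            for s in self.steps
        ]


@dataclass(frozen=True)
class RecurrentPosition:
    """A genomic position mutated in >= 2 distinct samples.

    ``consistency`` is "same" iff exactly one (ref, alt) pair was observed
    across the supporting samples; ``six_class`` is the pyrimidine-
    reference collapse of that pair and is defined only for "same".
    """

    chrom: str
    pos: int  # 1-based
    supporting_samples: frozenset
    cancer_types: frozenset
    recurrence: int
    consistency: str
    six_class: Optional[str]
    alleles: frozenset  # of (ref, alt) pairs
    cohort2_samples: Optional[frozenset] = None

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos)


def retention_percent(n_in: int, n_out: int) -> float:
    """Stage-to-stage retention as a percentage (e.g. 708/1722 -> 41.1)."""
    if n_in <= 0:
        raise DataError("retention undefined for empty input stage")
    return 100.0 * n_out / n_in


def apply_source_filters(
    mutations: Iterable[SomaticMutation],
    funnel: Optional[FunnelReport] = None,
    dedup_individuals: bool = True,
) -> list:
    """Apply the four source-level filters in order.

    1. drop records from hematopoietic/lymphoid tissue;
    2. keep one sample per individual (lexicographically smallest
       sample_id; requires ``individual_id`` on every record);
    3. keep somatic-confirmed records only;
    4. drop SNP-flagged records.
    """
    mutations = list(mutations)

    step1 = [m for m in mutations if not is_hematopoietic(m.tissue_site)]
    if funnel is not None:
        funnel.add("tissue", len(mutations), len(step1))

    if dedup_individuals:
        if any(m.individual_id is None for m in step1):
            raise ConfigurationError(
                "individual deduplication requested but individual_id is missing"
            )
        keeper: dict = {}
        for m in step1:
            prev = keeper.get(m.individual_id)
            if prev is None or m.sample_id < prev:
                keeper[m.individual_id] = m.sample_id
        step2 = [m for m in step1 if m.sample_id == keeper[m.individual_id]]
    else:
        step2 = step1
    if funnel is not None:
        funnel.add("individual_dedup", len(step1), len(step2))

    step3 = [m for m in step2 if m.somatic_confirmed]
    if funnel is not None:
        funnel.add("somatic_confirmed", len(step2), len(step3))

    step4 = [m for m in step3 if not m.snp_flagged]
    if funnel is not None:
        funnel.add("snp_flagged", len(step3), len(step4))

    return step4


def remove_exonic(
    mutations: Iterable[SomaticMutation],
    genes: Iterable[GeneModel],
    funnel: Optional[FunnelReport] = None,
) -> list:
    """Remove mutations whose position lies inside any exon of any gene."""
    mutations = list(mutations)
    exon_index = IntervalIndex(ex for g in genes for ex in g.exons)
    kept = [
        m for m in mutations if not exon_index.containing_pos(m.chrom, m.pos)
    ]
    if funnel is not None:
        funnel.add("exonic", len(mutations), len(kept))
    return kept


def call_recurrent_positions(
    mutations: Iterable[SomaticMutation], min_samples: int = 2
) -> list:
    """Group mutations by (chrom, pos) and call positions with >= min_samples.

    Recurrence counts *distinct* sample_ids; the position key ignores the
    allele, so a position carried as C>T in one sample and C>A in another
    is a single recurrent position with consistency "different".
    """
    if min_samples < 2:
        raise ConfigurationError("min_samples must be >= 2 for recurrence calling")
    groups: dict = {}
    for m in mutations:
        entry = groups.setdefault(m.key, {"samples": set(), "types": set(), "pairs": set()})
        entry["samples"].add(m.sample_id)
        if m.cancer_type is not None:
            entry["types"].add(m.cancer_type)
        entry["pairs"].add((m.ref, m.alt))
    out = []
    for (chrom, pos) in sorted(groups):
        entry = groups[(chrom, pos)]
        if len(entry["samples"]) < min_samples:
            continue
        consistency = "same" if len(entry["pairs"]) == 1 else "different"
        six_class = None
        if consistency == "same":
            (ref, alt), = entry["pairs"]
            six_class = collapse_substitution(ref, alt)
        out.append(
            RecurrentPosition(
                chrom=chrom,
                pos=pos,
                supporting_samples=frozenset(entry["samples"]),
                cancer_types=frozenset(entry["types"]),
                recurrence=len(entry["samples"]),
                consistency=consistency,
                six_class=six_class,
                alleles=frozenset(entry["pairs"]),
            )
        )
    return out


def require_multi_cancer_type(recurrents: Iterable[RecurrentPosition], min_types: int = 2) -> list:
    """Keep positions whose supporting samples span >= min_types cancer types."""
    return [r for r in recurrents if len(r.cancer_types) >= min_types]


def intersect_positions(
    recurrents: Iterable[RecurrentPosition],
    second_cohort_mutations: Iterable[SomaticMutation],
) -> list:
    """Keep positions also mutated in the second cohort.

    The second cohort's supporting samples are attached for the
    downstream expression analysis.
    """
    cohort2_samples: dict = {}
    for m in second_cohort_mutations:
        cohort2_samples.setdefault(m.key, set()).add(m.sample_id)
    out = []
    for r in recurrents:
        samples = cohort2_samples.get(r.key)
        if samples:
            out.append(replace(r, cohort2_samples=frozenset(samples)))
    return out


def consistency_counts(recurrents: Iterable[RecurrentPosition]) -> dict:
    """Counts and percentage of positions with an identical pattern.

    Returns ``{"same": n_same, "different": n_diff, "percent_same": ...}``.
    """
    counter = Counter(r.consistency for r in recurrents)
    n_same = counter.get("same", 0)
    n_diff = counter.get("different", 0)
    total = n_same + n_diff
    if total == 0:
        raise DataError("no recurrent positions to summarize")
    return {
        "same": n_same,
        "different": n_diff,
        "percent_same": 100.0 * n_same / total,
    }


def six_class_spectrum(recurrents: Iterable[RecurrentPosition]) -> dict:
    """Count/proportion of each six-class pattern over the "same" subset."""
    same = [r for r in recurrents if r.consistency == "same"]
    counter = Counter(r.six_class for r in same)
    total = len(same)
    return {
        cls: (counter.get(cls, 0), (counter.get(cls, 0) / total) if total else 0.0)
        for cls in SIX_CLASSES
    }


@dataclass(frozen=True)
class CodingFractionResult:
    n_mutations: int
    n_coding: int
    observed_fraction: float
    expected_fraction: float
    p_value: float


def coding_fraction_test(
    mutations: Iterable[SomaticMutation],
    genes: Iterable[GeneModel],
    genome_length: int,
) -> CodingFractionResult:
    """One-sided exact binomial test of coding (exonic) enrichment.

    The expected coding fraction is the exon-union length divided by the
    genome length; the p-value is the upper tail of Binomial(n, expected)
    at the observed coding count.
    """
    mutations = list(mutations)
    if not mutations:
        raise DataError("coding-fraction test undefined for zero mutations")
    if genome_length <= 0:
        raise DataError("genome_length must be positive")
    genes = list(genes)
    exon_index = IntervalIndex(ex for g in genes for ex in g.exons)
    n_coding = sum(
        1 for m in mutations if exon_index.containing_pos(m.chrom, m.pos)
    )
    expected = total_length(ex for g in genes for ex in g.exons) / genome_length
    p = binomtest(n_coding, len(mutations), expected, alternative="greater").pvalue
    return CodingFractionResult(
        n_mutations=len(mutations),
        n_coding=n_coding,
        observed_fraction=n_coding / len(mutations),
        expected_fraction=expected,
        p_value=float(p),
    )


@dataclass(frozen=True)
class ContextAnnotation:
    chrom: str
    pos: int
    label: str  # exonic | intronic | intergenic
    nearest_gene: Optional[str]
    tss_distance: Optional[int]  # signed, strand-aware; 0 at the TSS


def genomic_context(
    mutations: Iterable[SomaticMutation], genes: Iterable[GeneModel]
) -> tuple:
    """Label each mutation exonic/intronic/intergenic and locate the nearest TSS.

    Intronic means inside a gene span but outside every exon. The TSS
    distance is signed relative to the gene's strand: positive downstream
    of the TSS (into the gene body), negative upstream, 0 at the TSS.
    Returns ``(annotations, fractions)``.
    """
    genes = list(genes)
    exon_index = IntervalIndex(ex for g in genes for ex in g.exons)
    span_index = IntervalIndex(
        # carry the gene through the span's name for containment checks
        g.span for g in genes
    )
    tss_by_chrom: dict = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append(g)

    annotations = []
    for m in mutations:
        if exon_index.containing_pos(m.chrom, m.pos):
            label = "exonic"
        elif span_index.containing_pos(m.chrom, m.pos):
            label = "intronic"
        else:
            label = "intergenic"
        nearest = None
        distance = None
        candidates = tss_by_chrom.get(m.chrom, [])
        if candidates:
            nearest_gene = min(
                candidates, key=lambda g: (abs(m.pos - g.tss), g.gene_id)
            )
            nearest = nearest_gene.gene_id
            if nearest_gene.strand == "+":
                distance = m.pos - nearest_gene.tss
            else:
                distance = nearest_gene.tss - m.pos
        annotations.append(ContextAnnotation(m.chrom, m.pos, label, nearest, distance))

    counter = Counter(a.label for a in annotations)
    total = len(annotations)
    fractions = {
        label: (counter.get(label, 0) / total if total else 0.0)
        for label in ("exonic", "intronic", "intergenic")
    }
    return annotations, fractions
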