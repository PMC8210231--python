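"""Source filters, recurrence calling, spectrum, and context annotation."""

import itertools
import math

import numpy as np
import pytest

from ncrm.core import ConfigurationError, DataError, GeneModel, GenomicInterval
from ncrm.recurrence import (
    FunnelReport,
    apply_source_filters,
    call_recurrent_positions,
    coding_fraction_test,
    collapse_substitution,
    consistency_counts,
    genomic_context,
    intersect_positions,
    remove_exonic,
    require_multi_cancer_type,
    retention_percent,
    six_class_spectrum,
)
from tests.conftest import make_mutation, random_mutations


def make_gene(gene_id="G1", chrom="chr1", strand="+", span=(0, 1000), exons=((9, 20),)):
    exon_ivs = tuple(GenomicInterval(chrom, s, e) for s, e in exons)
    tss = span[0] + 1 if strand == "+" else span[1]
    return GeneModel(
        gene_id=gene_id,
        gene_name=gene_id,
        chrom=chrom,
        strand=strand,
        tss=tss,
        span=GenomicInterval(chrom, *span),
        exons=exon_ivs,
    )


class TestSourceFilters:
    def test_hematopoietic_records_are_removed(self):
        muts = [
            make_mutation(sample_id="A", tissue_site="haematopoietic_and_lymphoid_tissue"),
            make_mutation(sample_id="B", pos=200),
        ]
        assert [m.sample_id for m in apply_source_filters(muts)] == ["B"]

    def test_one_sample_per_individual_smallest_id_kept(self):
        muts = [
            make_mutation(sample_id="S2", individual_id="I1", pos=10),
            make_mutation(sample_id="S1", individual_id="I1", pos=20),
            make_mutation(sample_id="S3", individual_id="I2", pos=30),
        ]
        kept = apply_source_filters(muts)
        assert sorted(m.sample_id for m in kept) == ["S1", "S3"]

    def test_snp_flagged_and_unconfirmed_removed(self):
        muts = [
            make_mutation(sample_id="A", snp_flagged=True),
            make_mutation(sample_id="B", pos=2, somatic_confirmed=False),
            make_mutation(sample_id="C", pos=3),
        ]
        assert [m.sample_id for m in apply_source_filters(muts)] == ["C"]

    def test_missing_individual_id_is_a_configuration_error(self):
        bad = make_mutation()
        object.__setattr__(bad, "individual_id", None)
        with pytest.raises(ConfigurationError):
            apply_source_filters([bad])

    def test_idempotent_and_subfilters_commute(self, rng):
        # tissue is a property of the individual, and every sample keeps
        # unflagged records, so the four sub-filters commute on this input
        muts = []
        for sample in range(24):
            individual = sample // 2  # two samples per individual
            for k in range(8):
                muts.append(
                    make_mutation(
                        sample_id=f"S{sample:02d}",
                        individual_id=f"I{individual:02d}",
                        pos=int(rng.integers(1, 500)),
                        tissue_site=(
                            "haematopoietic_and_lymphoid_tissue"
                            if individual == 3
                            else "lung"
                        ),
                        somatic_confirmed=(k == 0 or rng.random() < 0.9),
                        snp_flagged=(k != 0 and rng.random() < 0.1),
                    )
                )
        once = apply_source_filters(muts)
        assert apply_source_filters(once) == once

        def tissue(ms):
            return [m for m in ms if "matopoietic" not in (m.tissue_site or "")]

        def dedup(ms):
            keep = {}
            for m in ms:
                if m.individual_id not in keep or m.sample_id < keep[m.individual_id]:
                    keep[m.individual_id] = m.sample_id
            return [m for m in ms if keep[m.individual_id] == m.sample_id]

        def somatic(ms):
            return [m for m in ms if m.somatic_confirmed]

        def snp(ms):
            return [m for m in ms if not m.snp_flagged]

        reference = set(once)
        for perm in itertools.permutations([tissue, dedup, somatic, snp]):
            result = muts
            for f in perm:
                result = f(result)
            assert set(result) == reference

    def test_funnel_records_every_subfilter(self):
        funnel = FunnelReport()
        apply_source_filters([make_mutation()], funnel=funnel)
        assert [s.label for s in funnel.steps] == [
            "tissue",
            "individual_dedup",
            "somatic_confirmed",
            "snp_flagged",
        ]


class TestRemoveExonic:
    def test_half_open_exon_boundaries(self):
        gene = make_gene(exons=((9, 20),))
        inside = make_mutation(pos=15)
        boundary = make_mutation(pos=21)  # first base after the exon
        start_edge = make_mutation(pos=10)  # 1-based position of exon start
        kept = remove_exonic([inside, boundary, start_edge], [gene])
        assert [m.pos for m in kept] == [21]

    def test_matches_brute_force_membership(self, rng):
        genes = [
            make_gene(
                gene_id=f"G{i}",
                span=(i * 1000, i * 1000 + 900),
                exons=tuple(
                    (i * 1000 + 100 * j, i * 1000 + 100 * j + 50) for j in range(3)
                ),
            )
            for i in range(10)
        ]
        muts = random_mutations(rng, 300, chroms=("chr1",), max_pos=10_000)
        exons = [ex for g in genes for ex in g.exons]

        def brute(m):
            return any(ex.start <= m.pos - 1 < ex.end for ex in exons)

        expected = [m for m in muts if not brute(m)]
        assert remove_exonic(muts, genes) == expected


class TestRecurrenceCalling:
    def test_positions_shared_by_two_samples_called(self):
        muts = [
            make_mutation(pos=10, sample_id="A"),
            make_mutation(pos=10, sample_id="B"),
            make_mutation(pos=20, sample_id="A"),
            make_mutation(pos=30, sample_id="A"),
            make_mutation(pos=30, sample_id="C"),
        ]
        recs = call_recurrent_positions(muts)
        assert [(r.pos, r.recurrence) for r in recs] == [(10, 2), (30, 2)]

    def test_single_sample_never_recurrent(self):
        muts = [make_mutation(pos=p, sample_id="A") for p in (1, 1, 2)]
        assert call_recurrent_positions(muts) == []

    def test_allele_disagreement_is_different(self):
        muts = [
            make_mutation(pos=5, ref="C", alt="T", sample_id="A"),
            make_mutation(pos=5, ref="C", alt="A", sample_id="B"),
        ]
        (rec,) = call_recurrent_positions(muts)
        assert rec.consistency == "different" and rec.six_class is None

    def test_matches_quadratic_brute_force(self, rng):
        muts = random_mutations(rng, 2000, max_pos=800)
        recs = call_recurrent_positions(muts)
        keys = {(m.chrom, m.pos) for m in muts}
        expected = {}
        for key in keys:
            samples = {m.sample_id for m in muts if (m.chrom, m.pos) == key}
            if len(samples) >= 2:
                expected[key] = samples
        assert {r.key: set(r.supporting_samples) for r in recs} == expected
        for r in recs:
            pairs = {(m.ref, m.alt) for m in muts if (m.chrom, m.pos) == r.key}
            assert r.consistency == ("same" if len(pairs) == 1 else "different")


class TestMultiCancerTypeAndIntersection:
    def _recs(self, muts):
        return call_recurrent_positions(muts)

    def test_single_type_removed_two_types_kept(self):
        same = [
            make_mutation(pos=1, sample_id="A", cancer_type="BRCA"),
            make_mutation(pos=1, sample_id="B", cancer_type="BRCA"),
        ]
        mixed = [
            make_mutation(pos=2, sample_id="A", cancer_type="BRCA"),
            make_mutation(pos=2, sample_id="B", cancer_type="LUAD"),
        ]
        recs = self._recs(same + mixed)
        kept = require_multi_cancer_type(recs)
        assert [r.pos for r in kept] == [2]

    def test_multi_type_matches_brute_force(self, rng):
        muts = random_mutations(rng, 1000, max_pos=300)
        recs = self._recs(muts)
        kept = require_multi_cancer_type(recs, min_types=2)
        expected = {
            r.key
            for r in recs
            if len({m.cancer_type for m in muts if (m.chrom, m.pos) == r.key}) >= 2
        }
        assert {r.key for r in kept} == expected

    def test_intersection_is_set_intersection_on_keys(self, rng):
        cohort1 = random_mutations(rng, 600, max_pos=400)
        cohort2 = random_mutations(rng, 600, max_pos=400)
        recs = self._recs(cohort1)
        kept = intersect_positions(recs, cohort2)
        expected = {r.key for r in recs} & {(m.chrom, m.pos) for m in cohort2}
        assert {r.key for r in kept} == expected
        for r in kept:
            assert r.cohort2_samples == frozenset(
                m.sample_id for m in cohort2 if (m.chrom, m.pos) == r.key
            )


class TestSpectrum:
    def test_purine_reference_collapses_by_reverse_complement(self):
        assert collapse_substitution("G", "A") == "C>T"
        assert collapse_substitution("A", "T") == "T>A"
        assert collapse_substitution("C", "G") == "C>G"

    def test_single_position_spectrum(self):
        muts = [
            make_mutation(pos=1, ref="G", alt="A", sample_id="A"),
            make_mutation(pos=1, ref="G", alt="A", sample_id="B"),
        ]
        spectrum = six_class_spectrum(call_recurrent_positions(muts))
        assert spectrum["C>T"] == (1, 1.0)

    def test_counts_equal_brute_force_tally_and_sum_to_one(self, rng):
        muts = random_mutations(rng, 3000, max_pos=600)
        recs = call_recurrent_positions(muts)
        spectrum = six_class_spectrum(recs)
        same = [r for r in recs if r.consistency == "same"]
        for cls, (count, _prop) in spectrum.items():
            assert count == sum(1 for r in same if r.six_class == cls)
        assert math.isclose(
            sum(p for _, p in spectrum.values()), 1.0, abs_tol=1e-12
        )

    def test_consistency_counts_percentage(self):
        muts = [
            make_mutation(pos=1, sample_id="A"),
            make_mutation(pos=1, sample_id="B"),
            make_mutation(pos=2, ref="C", alt="T", sample_id="A"),
            make_mutation(pos=2, ref="C", alt="G", sample_id="B"),
        ]
        summary = consistency_counts(call_recurrent_positions(muts))
        assert summary == {"same": 1, "different": 1, "percent_same": 50.0}


class TestCodingFraction:
    def test_degenerate_zero_coding_tail_is_one(self):
        gene = make_gene(exons=((0, 28),), span=(0, 1000))
        muts = [make_mutation(pos=500 + i) for i in range(100)]
        result = coding_fraction_test(muts, [gene], genome_length=1000)
        assert result.p_value == pytest.approx(1.0)
        assert result.expected_fraction == pytest.approx(0.028)

    def test_all_coding_observed_fraction_is_one(self):
        gene = make_gene(exons=((0, 100),), span=(0, 1000))
        muts = [make_mutation(pos=i + 1) for i in range(50)]
        result = coding_fraction_test(muts, [gene], genome_length=1000)
        assert result.observed_fraction == 1.0

    def test_matches_exact_binomial_enumeration(self):
        gene = make_gene(exons=((0, 28),), span=(0, 1000))
        muts = [make_mutation(pos=i + 1) for i in range(10)]  # 10 coding
        muts += [make_mutation(pos=500 + i) for i in range(90)]
        result = coding_fraction_test(muts, [gene], genome_length=1000)
        f = 0.028
        oracle = sum(
            math.comb(100, k) * f**k * (1 - f) ** (100 - k) for k in range(10, 101)
        )
        assert result.p_value == pytest.approx(oracle, rel=1e-9)

    def test_zero_mutations_is_an_error(self):
        with pytest.raises(DataError):
            coding_fraction_test([], [make_gene()], genome_length=1000)


class TestGenomicContext:
    def test_intronic_and_tss_distance(self):
        gene = make_gene(strand="+", span=(100, 900), exons=((100, 200), (800, 900)))
        intronic = make_mutation(pos=500)
        at_tss = make_mutation(pos=101)
        annotations, _ = genomic_context([intronic, at_tss], [gene])
        assert annotations[0].label == "intronic"
        assert annotations[1].tss_distance == 0

    def test_matches_brute_force_scan(self, rng):
        genes = [
            make_gene(
                gene_id=f"G{i}",
                strand="+" if i % 2 == 0 else "-",
                span=(i * 1500, i * 1500 + 1000),
                exons=((i * 1500, i * 1500 + 200), (i * 1500 + 800, i * 1500 + 1000)),
            )
            for i in range(5)
        ]
        muts = random_mutations(rng, 50, chroms=("chr1",), max_pos=9000)
        annotations, fractions = genomic_context(muts, genes)
        for m, a in zip(muts, annotations):
            in_exon = any(
                ex.start <= m.pos - 1 < ex.end for g in genes for ex in g.exons
            )
            in_span = any(g.span.start <= m.pos - 1 < g.span.end for g in genes)
            label = "exonic" if in_exon else ("intronic" if in_span else "intergenic")
            assert a.label == label
            nearest = min(genes, key=lambda g: (abs(m.pos - g.tss), g.gene_id))
            assert a.nearest_gene == nearest.gene_id
            expected = (
                m.pos - nearest.tss if nearest.strand == "+" else nearest.tss - m.pos
            )
            assert a.tss_distance == expected
        assert math.isclose(sum(fractions.values()), 1.0, abs_tol=1e-12)


class TestFunnelReport:
    def test_chain_consistency_enforced(self):
        funnel = FunnelReport()
        funnel.add("a", 100, 80)
        with pytest.raises(DataError):
            funnel.add("b", 90, 70)

    def test_count_increase_rejected(self):
        funnel = FunnelReport()
        with pytest.raises(DataError):
            funnel.add("a", 10, 11)

    def test_retention_percentages(self):
        assert retention_percent(1722, 708) == pytest.approx(41.1, abs=0.05)
        funnel = FunnelReport()
        funnel.add("a", 1000, 700)
        funnel.add("b", 700, 700)
        records = funnel.to_records()
        assert [r["retention_percent"] for r in records] == [70.0, 100.0]
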