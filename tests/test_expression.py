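"""Target assignment, z-score integration, rank-sum screen, BH, simulations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from ncrm.core import (
    ChromatinInteraction,
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    TFBSInstance,
)
from ncrm.expression import (
    AssociationResult,
    ZScoreMatrix,
    _u_statistic,
    assign_target_genes,
    bh_adjust,
    compare_expression,
    fdr_null_simulation,
    nearest_neighbor_genes,
    neighbor_specificity,
    screen_tfbs_expression,
    zscore_by_cancer_type,
)


def make_gene(gene_id, tss, chrom="chr1", strand="+"):
    return GeneModel(
        gene_id=gene_id,
        gene_name=gene_id,
        chrom=chrom,
        strand=strand,
        tss=tss,
        span=GenomicInterval(chrom, max(0, tss - 1), tss + 100),
        exons=(),
    )


def make_site(start=1000, end=1010, chrom="chr1"):
    return TFBSInstance(
        "site1", GenomicInterval(chrom, start, end), "+", "MA0001.1", 500.0
    )


def make_z(values: np.ndarray, genes=None, samples=None, types=None) -> ZScoreMatrix:
    n_genes, n_samples = values.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    samples = samples or [f"s{j}" for j in range(n_samples)]
    meta = pd.Series(types or ["X"] * n_samples, index=samples)
    return ZScoreMatrix(
        z=pd.DataFrame(values, index=genes, columns=samples), cancer_type=meta
    )


class TestTargetAssignment:
    def _interaction(self, a, b):
        return ChromatinInteraction(
            GenomicInterval("chr1", *a), GenomicInterval("chr1", *b), "HMEC", "Hi-C"
        )

    def test_partner_anchor_containing_tss_yields_target(self):
        site = make_site(1000, 1010)
        gene = make_gene("G1", tss=5000)
        it = self._interaction((900, 1100), (4500, 5500))
        assert assign_target_genes(site, [it], [gene]) == ["G1"]

    def test_site_outside_all_anchors_has_no_targets(self):
        site = make_site(10_000, 10_010)
        gene = make_gene("G1", tss=5000)
        it = self._interaction((900, 1100), (4500, 5500))
        assert assign_target_genes(site, [it], [gene]) == []

    def test_union_over_interactions_matches_brute_force(self, rng):
        genes = [make_gene(f"G{i}", tss=int(rng.integers(1, 50_000))) for i in range(30)]
        interactions = []
        for _ in range(50):
            a = int(rng.integers(0, 49_000))
            b = int(rng.integers(0, 49_000))
            interactions.append(
                self._interaction((a, a + 800), (b, b + 800))
            )
        site = make_site(20_000, 20_010)
        result = assign_target_genes(site, interactions, genes)
        expected = set()
        for it in interactions:
            for anchor, partner in ((it.anchor_a, it.anchor_b), (it.anchor_b, it.anchor_a)):
                if anchor.overlaps(site.interval):
                    expected |= {
                        g.gene_id for g in genes if partner.contains_pos(g.chrom, g.tss)
                    }
        assert result == sorted(expected)


class TestZScores:
    def _expr(self, data, types):
        samples = [f"s{j}" for j in range(data.shape[1])]
        return ExpressionMatrix(
            values=pd.DataFrame(data, index=["g0"], columns=samples),
            cancer_type=pd.Series(types, index=samples),
        )

    def test_simple_stratum_standardization(self):
        z = zscore_by_cancer_type(self._expr(np.array([[1.0, 2.0, 3.0]]), ["A"] * 3))
        np.testing.assert_allclose(z.z.loc["g0"], [-1.0, 0.0, 1.0])

    def test_zero_variance_stratum_is_masked(self):
        z = zscore_by_cancer_type(self._expr(np.array([[5.0, 5.0, 5.0]]), ["A"] * 3))
        assert z.z.loc["g0"].isna().all()

    def test_singleton_stratum_is_masked_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            z = zscore_by_cancer_type(
                self._expr(np.array([[1.0, 2.0, 9.0]]), ["A", "A", "B"])
            )
        assert np.isnan(z.z.loc["g0", "s2"]) and "masked" in caplog.text

    def test_strata_standardized_independently(self, rng):
        data = rng.normal(10, 3, size=(1, 40))
        types = ["A"] * 25 + ["B"] * 15
        expr = self._expr(data, types)
        z = zscore_by_cancer_type(expr)
        for t, n in (("A", 25), ("B", 15)):
            cols = [f"s{j}" for j in range(40) if types[j] == t]
            sub = expr.values[cols].loc["g0"]
            expected = (sub - sub.mean()) / sub.std(ddof=1)
            np.testing.assert_allclose(z.z.loc["g0", cols], expected)
            assert z.z.loc["g0", cols].mean() == pytest.approx(0.0, abs=1e-12)
            assert z.z.loc["g0", cols].std(ddof=1) == pytest.approx(1.0, abs=1e-12)
        assert abs(z.z.loc["g0"].mean()) < 1e-12  # pooled mean of z-scores


class TestCompareExpression:
    def _exact_oracle(self, x, y):
        values = np.concatenate([x, y])
        n = len(x)
        observed = _u_statistic(x, y)
        stats = []
        for comb in itertools.combinations(range(len(values)), n):
            rest = [i for i in range(len(values)) if i not in comb]
            stats.append(_u_statistic(values[list(comb)], values[rest]))
        stats = np.array(stats)
        lo = np.mean(stats <= observed)
        hi = np.mean(stats >= observed)
        return min(1.0, 2.0 * min(lo, hi))

    def test_complete_separation_matches_exact_enumeration(self):
        values = np.array([[-2.0, -2.0, -2.0, 1.0, 1.0, 1.0, 1.0]])
        z = make_z(values)
        result = compare_expression(z, "g0", {"s0", "s1", "s2"})
        assert result.p_value == pytest.approx(2.0 / 35.0)
        assert result.direction == -1

    @pytest.mark.parametrize("case", range(6))
    def test_matches_exact_permutation_oracle(self, case, rng):
        nx, ny = int(rng.integers(2, 6)), int(rng.integers(2, 6))
        values = np.round(rng.normal(size=nx + ny), 1)  # induces occasional ties
        z = make_z(values[None, :])
        mutated = {f"s{j}" for j in range(nx)}
        result = compare_expression(z, "g0", mutated)
        oracle = self._exact_oracle(values[:nx], values[nx:])
        assert result.p_value == pytest.approx(oracle, abs=1e-12)

    def test_identical_groups_give_p_one(self):
        values = np.array([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]])
        z = make_z(values)
        result = compare_expression(z, "g0", {"s0", "s1", "s2"})
        assert result.p_value == pytest.approx(1.0)

    def test_swapping_labels_flips_direction_not_p(self, rng):
        values = rng.normal(size=(1, 12))
        z = make_z(values)
        group = {f"s{j}" for j in range(5)}
        rest = {f"s{j}" for j in range(5, 12)}
        a = compare_expression(z, "g0", group)
        b = compare_expression(z, "g0", rest)
        assert a.p_value == pytest.approx(b.p_value)
        assert a.direction == -b.direction

    def test_empty_group_is_flagged(self):
        z = make_z(np.ones((1, 4)) * np.nan)
        result = compare_expression(z, "g0", {"s0"})
        assert not result.tested


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37]).tolist() == [0.37]

    def test_monotone_in_sorted_p(self, rng):
        p = np.sort(rng.random(50))
        q = bh_adjust(p)
        assert (np.diff(q) >= -1e-15).all()

    def test_matches_statsmodels_reference(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(100):
            p = rng.random(int(rng.integers(1, 40)))
            expected = multipletests(p, method="fdr_bh")[1]
            assert np.abs(bh_adjust(p) - expected).max() < 1e-12

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestScreen:
    def _null_screen(self, rng, n_sites, n_mut=10, n_samples=60, planted=None):
        genes = [f"g{i}" for i in range(n_sites)]
        values = rng.normal(size=(n_sites, n_samples))
        samples = [f"s{j}" for j in range(n_samples)]
        site_map = {}
        targets = {}
        for i in range(n_sites):
            mutated = rng.choice(n_samples, size=n_mut, replace=False)
            site_map[f"site{i}"] = {samples[j] for j in mutated}
            targets[f"site{i}"] = [genes[i]]
            if planted is not None and i == 0:
                for j in mutated:
                    values[0, j] += planted
        z = make_z(values, genes=genes, samples=samples)
        return site_map, z, targets

    def test_sites_below_min_mutated_excluded(self, rng):
        site_map, z, targets = self._null_screen(rng, 5, n_mut=4)
        assert screen_tfbs_expression(site_map, z, targets, min_mutated=5) == []

    def test_planted_effect_recovered_among_nulls(self, rng):
        site_map, z, targets = self._null_screen(rng, 51, n_mut=10, planted=-2.0)
        results = screen_tfbs_expression(site_map, z, targets)
        best = min(results, key=lambda a: a.p_value)
        assert (best.site_id, best.gene_id) == ("site0", "g0")
        assert best.fdr < 0.25 and best.direction == -1

    def test_type_one_error_calibrated_at_ten_percent(self, rng):
        site_map, z, targets = self._null_screen(rng, 500, n_mut=10)
        results = screen_tfbs_expression(site_map, z, targets)
        rate = np.mean([a.p_value < 0.1 for a in results])
        se = np.sqrt(0.1 * 0.9 / len(results))
        assert abs(rate - 0.10) <= 3 * se


class TestNeighborSpecificity:
    def test_nearest_neighbors_sorted_by_tss_distance(self):
        genes = [make_gene(f"G{i}", tss=1000 * (i + 1)) for i in range(6)]
        assert nearest_neighbor_genes("G2", genes, k=4) == ["G1", "G3", "G0", "G4"]

    def test_focal_effect_is_specific(self, rng):
        n_samples = 60
        samples = [f"s{j}" for j in range(n_samples)]
        values = rng.normal(size=(5, n_samples))
        mutated = {samples[j] for j in rng.choice(n_samples, size=10, replace=False)}
        for j, s in enumerate(samples):
            if s in mutated:
                values[0, j] -= 2.5
        z = make_z(values, genes=[f"g{i}" for i in range(5)], samples=samples)
        focal = compare_expression(z, "g0", mutated)
        table = neighbor_specificity("g0", ["g1", "g2", "g3", "g4"], z, mutated)
        assert focal.p_value < 0.1
        assert all(p >= 0.1 for _, p, _ in table)

    def test_null_neighbor_p_values_are_uniform(self, rng):
        n_samples = 60
        samples = [f"s{j}" for j in range(n_samples)]
        values = rng.normal(size=(200, n_samples))
        z = make_z(values, genes=[f"g{i}" for i in range(200)], samples=samples)
        mutated = {samples[j] for j in rng.choice(n_samples, size=10, replace=False)}
        table = neighbor_specificity("focal", [f"g{i}" for i in range(200)], z, mutated)
        pvals = [p for _, p, _ in table]
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_zero_neighbors_gives_empty_table(self, rng):
        z = make_z(rng.normal(size=(2, 10)))
        assert neighbor_specificity("g0", [], z, {"s0"}) == []


class TestFdrNullSimulation:
    def test_deterministic_per_rep_counts(self, rng):
        z = make_z(rng.normal(size=(50, 40)))
        runs = [
            fdr_null_simulation(z, z.z.index, n_genes=20, n_mut=8, n_reps=5, seed=3)
            for _ in range(2)
        ]
        assert runs[0].per_rep_counts.tolist() == runs[1].per_rep_counts.tolist()

    def test_planted_shifts_inflate_discoveries(self, rng):
        values = rng.normal(size=(100, 60))
        mutated_idx = rng.choice(60, size=12, replace=False)
        for gi in range(10):  # 10% of genes strongly shifted in "mutated" samples
            values[gi, mutated_idx] -= 3.0
        genes = [f"g{i}" for i in range(100)]
        samples = [f"s{j}" for j in range(60)]
        z = make_z(values, genes=genes, samples=samples)
        mutated = {samples[j] for j in mutated_idx}
        pvals = [compare_expression(z, g, mutated).p_value for g in genes]
        n_hits = int((bh_adjust(pvals) < 0.25).sum())
        null = fdr_null_simulation(z, genes[10:], n_genes=50, n_mut=12, n_reps=10, seed=1)
        assert n_hits >= 8 and n_hits > 10 * null.mean_discoveries
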