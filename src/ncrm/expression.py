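"""Target-gene assignment and the mutated-vs-wild-type expression screen.

Expression from heterogeneous cancer types is integrated by per-gene
z-scores computed within each cancer type; samples carrying any mutation
in a TFBS (recurrent or not) are compared with all remaining samples by
a two-sided Wilcoxon rank-sum test, and Benjamini-Hochberg adjustment is
applied once across the whole screen. Target genes are assigned to a
TFBS through chromatin-interaction anchor pairs: a gene is a target when
one anchor overlaps the site and the partner anchor contains the gene's
TSS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, permutation_test, rankdata

from .core import DataError, ExpressionMatrix, GeneModel, TFBSInstance

logger = logging.getLogger(__name__)


def assign_target_genes(
    site: TFBSInstance,
    interactions,
    genes: Iterable[GeneModel],
) -> list:
    """Genes whose TSS sits in the partner anchor of an interaction
    overlapping the site. Union over all interactions, deduplicated and
    sorted."""
    genes = list(genes)
    targets = set()
    for it in interactions:
        for anchor, partner in (
            (it.anchor_a, it.anchor_b),
            (it.anchor_b, it.anchor_a),
        ):
            if anchor.overlaps(site.interval):
                for g in genes:
                    if partner.contains_pos(g.chrom, g.tss):
                        targets.add(g.gene_id)
    return sorted(targets)


@dataclass
class ZScoreMatrix:
    """Per-gene z-scores computed within each cancer type.

    Strata with zero variance or a single sample are masked (NaN) and
    excluded from downstream tests.
    """

    z: pd.DataFrame
    cancer_type: pd.Series


def zscore_by_cancer_type(expr: ExpressionMatrix) -> ZScoreMatrix:
    """Standardize each gene within each cancer type (sample sd, ddof=1)."""
    z = pd.DataFrame(
        np.nan, index=expr.values.index, columns=expr.values.columns, dtype=float
    )
    for cancer_type, samples in expr.cancer_type.groupby(expr.cancer_type).groups.items():
        columns = [s for s in samples if s in expr.values.columns]
        if len(columns) < 2:
            logger.warning(
                "cancer type %s has %d sample(s); stratum masked",
                cancer_type,
                len(columns),
            )
            continue
        sub = expr.values[columns]
        mu = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        standardized = sub.sub(mu, axis=0).div(sd, axis=0)
        standardized = standardized.where(sd > 0)  # zero-variance strata -> NaN
        z[columns] = standardized
    return ZScoreMatrix(z=z, cancer_type=expr.cancer_type)


@dataclass(frozen=True)
class ComparisonResult:
    statistic: Optional[float]
    p_value: Optional[float]
    direction: int  # sign of (median z mutated - median z WT)
    n_mutated: int
    n_wt: int

    @property
    def tested(self) -> bool:
        return self.p_value is not None


@dataclass(frozen=True)
class _RankSumOutcome:
    statistic: float
    pvalue: float


def _u_statistic(x, y, axis: int = -1):
    """Mann-Whitney U of the first sample, midranks for ties."""
    x = np.asarray(x, dtype=float)
    nx = x.shape[axis]
    ranks = rankdata(np.concatenate([x, np.asarray(y, dtype=float)], axis=axis), axis=axis)
    rank_sum = np.take(ranks, np.arange(nx), axis=axis).sum(axis=axis)
    return rank_sum - nx * (nx + 1) / 2


def _ranksum(x: np.ndarray, y: np.ndarray) -> _RankSumOutcome:
    """Two-sided Wilcoxon rank-sum.

    Groups of at most 8 each are tested by exact enumeration of all
    group assignments (ties handled by midranks); larger groups use the
    tie-corrected normal approximation.
    """
    if len(x) <= 8 and len(y) <= 8:
        # n_resamples above C(16, 8) forces full enumeration
        res = permutation_test(
            (x, y),
            _u_statistic,
            permutation_type="independent",
            alternative="two-sided",
            n_resamples=20_000,
            vectorized=True,
        )
        return _RankSumOutcome(float(res.statistic), float(min(1.0, res.pvalue)))
    res = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return _RankSumOutcome(float(res.statistic), float(res.pvalue))


def compare_expression(z: ZScoreMatrix, gene: str, mutated_samples) -> ComparisonResult:
    """Compare a gene's z-scores between mutated and wild-type samples."""
    if gene not in z.z.index:
        raise DataError(f"gene {gene!r} not in the expression matrix")
    row = z.z.loc[gene].dropna()
    mutated_samples = set(mutated_samples)
    mut = row[row.index.isin(mutated_samples)]
    wt = row[~row.index.isin(mutated_samples)]
    if mut.empty or wt.empty:
        return ComparisonResult(None, None, 0, len(mut), len(wt))
    res = _ranksum(mut.to_numpy(), wt.to_numpy())
    direction = int(np.sign(np.median(mut.to_numpy()) - np.median(wt.to_numpy())))
    return ComparisonResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        direction=direction,
        n_mutated=len(mut),
        n_wt=len(wt),
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = q_sorted
    return out


@dataclass(frozen=True)
class AssociationResult:
    site_id: str
    gene_id: str
    n_mutated: int
    n_wt: int
    statistic: float
    p_value: float
    fdr: float
    direction: int


def screen_tfbs_expression(
    site_mutation_map: dict,
    z: ZScoreMatrix,
    targets: dict,
    min_mutated: int = 5,
    fdr_threshold: float = 0.25,
) -> list:
    """Test every (site, target gene) pair with enough mutated samples.

    ``site_mutation_map`` maps site_id to the set of sample_ids carrying
    any mutation in the site; ``targets`` maps site_id to its target
    gene list. Sites with fewer than ``min_mutated`` mutated samples
    among the expression cohort are excluded before testing; BH is
    applied once across all executed tests. Returns all tested pairs
    (callers filter by ``fdr < fdr_threshold``).
    """
    expression_samples = set(z.z.columns)
    tested = []
    for site_id in sorted(targets):
        mutated = set(site_mutation_map.get(site_id, ())) & expression_samples
        if len(mutated) < min_mutated:
            continue
        for gene_id in targets[site_id]:
            if gene_id not in z.z.index:
                continue
            comparison = compare_expression(z, gene_id, mutated)
            if not comparison.tested:
                continue
            tested.append((site_id, gene_id, comparison))
    if not tested:
        return []
    fdr = bh_adjust([c.p_value for _, _, c in tested])
    return [
        AssociationResult(
            site_id=site_id,
            gene_id=gene_id,
            n_mutated=c.n_mutated,
            n_wt=c.n_wt,
            statistic=c.statistic,
            p_value=c.p_value,
            fdr=float(q),
            direction=c.direction,
        )
        for (site_id, gene_id, c), q in zip(tested, fdr)
    ]


def nearest_neighbor_genes(focal_gene_id: str, genes: Iterable[GeneModel], k: int = 4) -> list:
    """The k genes whose TSS is nearest the focal gene's TSS (same chromosome)."""
    genes = list(genes)
    focal = next((g for g in genes if g.gene_id == focal_gene_id), None)
    if focal is None:
        raise DataError(f"gene {focal_gene_id!r} not found")
    others = [g for g in genes if g.gene_id != focal_gene_id and g.chrom == focal.chrom]
    others.sort(key=lambda g: (abs(g.tss - focal.tss), g.gene_id))
    return [g.gene_id for g in others[:k]]


def neighbor_specificity(
    focal_gene: str,
    neighbor_genes,
    z: ZScoreMatrix,
    mutated_samples,
) -> list:
    """Apply the mutated-vs-WT comparison to each neighboring gene.

    No multiplicity adjustment is applied inside the specificity check;
    the result is a reporting table of (gene_id, p, direction).
    """
    table = []
    for gene_id in neighbor_genes:
        if gene_id == focal_gene or gene_id not in z.z.index:
            continue
        comparison = compare_expression(z, gene_id, mutated_samples)
        table.append((gene_id, comparison.p_value, comparison.direction))
    return table


@dataclass
class FdrSimulationResult:
    per_rep_counts: np.ndarray
    mean_discoveries: float
    n_genes: int
    n_mut: int
    n_reps: int
    seed: Optional[int]

    def to_dict(self) -> dict:
        return {
            "per_rep_counts": [int(c) for c in self.per_rep_counts],
            "mean_discoveries": self.mean_discoveries,
            "n_genes": self.n_genes,
            "n_mut": self.n_mut,
            "n_reps": self.n_reps,
            "seed": self.seed,
        }


def fdr_null_simulation(
    z: ZScoreMatrix,
    eligible_genes,
    n_genes: int,
    n_mut: int,
    n_reps: int,
    seed: Optional[int],
    fdr_threshold: float = 0.25,
) -> FdrSimulationResult:
    """Validate the FDR threshold by repeated random gene/sample splits.

    Each repetition draws ``n_genes`` genes and ``n_mut`` pseudo-mutated
    samples, tests each gene mutated-vs-rest, adjusts with BH across the
    drawn genes, and counts discoveries below the threshold.
    """
    eligible = [g for g in eligible_genes if g in z.z.index]
    if n_genes > len(eligible):
        raise DataError(f"cannot draw {n_genes} genes from {len(eligible)} eligible")
    samples = list(z.z.columns)
    if n_mut >= len(samples):
        raise DataError("n_mut must be smaller than the sample count")
    rng = np.random.default_rng(seed)
    counts = np.zeros(n_reps, dtype=int)
    for rep in range(n_reps):
        drawn_genes = rng.choice(len(eligible), size=n_genes, replace=False)
        mutated = set(
            samples[i] for i in rng.choice(len(samples), size=n_mut, replace=False)
        )
        pvals = []
        for gi in drawn_genes:
            comparison = compare_expression(z, eligible[gi], mutated)
            if comparison.tested:
                pvals.append(comparison.p_value)
        if pvals:
            counts[rep] = int((bh_adjust(pvals) < fdr_threshold).sum())
    return FdrSimulationResult(
        per_rep_counts=counts,
        mean_discoveries=float(counts.mean()),
        n_genes=n_genes,
        n_mut=n_mut,
        n_reps=n_reps,
        seed=seed,
    )
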