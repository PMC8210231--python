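"""Regulatory-element overlap filters and the two enrichment analyses.

Criteria 8-10 of the screen: containment in open-chromatin peaks, in
chromatin-interaction anchors (either anchor of a pair), and in
predicted TFBSs above the database score threshold. Also the resampled
open-chromatin fraction null and the per-peak mutation-rate comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from scipy.stats import mannwhitneyu

from .core import (
    ChromatinInteraction,
    GenomicInterval,
    IntervalIndex,
    TFBSInstance,
)
from .nulls import ResampleNull, resample_mean_null

import numpy as np


def overlap_intervals(positions, intervals: Iterable[GenomicInterval], source_label="intervals"):
    """Keep positions contained in >= 1 interval; annotate all containments.

    ``positions`` is any iterable of objects with ``chrom`` and 1-based
    ``pos`` attributes. Returns ``(kept, annotations)`` where
    ``annotations`` maps (chrom, pos) to a list of (source_label,
    interval) pairs.
    """
    index = IntervalIndex(intervals)
    kept = []
    annotations: dict = {}
    for p in positions:
        hits = index.containing_pos(p.chrom, p.pos)
        if hits:
            kept.append(p)
            annotations[(p.chrom, p.pos)] = [(source_label, h) for h in hits]
    return kept, annotations


def overlap_interaction_anchors(positions, interactions: Iterable[ChromatinInteraction]):
    """Keep positions inside either anchor of any interaction.

    Returns ``(kept, matches)``; ``matches`` maps (chrom, pos) to the
    interactions whose anchor contained it (needed later for target-gene
    assignment).
    """
    interactions = list(interactions)
    anchor_ivs = []
    owner: dict = {}
    for i, it in enumerate(interactions):
        for which, anchor in (("a", it.anchor_a), ("b", it.anchor_b)):
            tagged = GenomicInterval(
                anchor.chrom, anchor.start, anchor.end, name=f"{i}:{which}"
            )
            anchor_ivs.append(tagged)
            owner[tagged.name] = it
    index = IntervalIndex(anchor_ivs)
    kept = []
    matches: dict = {}
    for p in positions:
        hits = index.containing_pos(p.chrom, p.pos)
        if hits:
            kept.append(p)
            seen: list = []
            for h in hits:
                it = owner[h.name]
                if it not in seen:
                    seen.append(it)
            matches[(p.chrom, p.pos)] = seen
    return kept, matches


def overlap_tfbs(positions, sites: Iterable[TFBSInstance], min_score: float = 400.0):
    """Keep positions inside >= 1 TFBS with match_score >= min_score.

    A position may fall in several overlapping sites; all are recorded.
    Returns ``(kept, site_hits)`` where ``site_hits`` maps site_id to the
    sorted list of contained (chrom, pos) keys.
    """
    eligible = [s for s in sites if s.match_score >= min_score]
    tagged = [
        GenomicInterval(
            s.interval.chrom, s.interval.start, s.interval.end, name=s.site_id
        )
        for s in eligible
    ]
    by_id = {s.site_id: s for s in eligible}
    index = IntervalIndex(tagged)
    kept = []
    site_hits: dict = {}
    for p in positions:
        hits = index.containing_pos(p.chrom, p.pos)
        if hits:
            kept.append(p)
            for h in hits:
                site_hits.setdefault(h.name, []).append((p.chrom, p.pos))
    for site_id in site_hits:
        site_hits[site_id] = sorted(set(site_hits[site_id]))
    return kept, site_hits, by_id


def resample_open_chromatin_fraction(
    background_mutations,
    peaks: Iterable[GenomicInterval],
    n_draw: int,
    n_reps: int,
    observed_set,
    seed: Optional[int],
    replace: bool = False,
) -> ResampleNull:
    """Null distribution of the in-peak fraction of random mutation draws.

    Each repetition draws ``n_draw`` mutations from the background
    (without replacement by default) and records the fraction falling in
    peaks; the observed statistic is the in-peak fraction of
    ``observed_set``. Fractions are on the 0-1 scale.
    """
    peaks = list(peaks)
    index = IntervalIndex(peaks)
    background = list(background_mutations)
    membership = np.array(
        [1.0 if index.containing_pos(m.chrom, m.pos) else 0.0 for m in background]
    )
    observed_set = list(observed_set)
    observed = float(
        np.mean(
            [1.0 if index.containing_pos(p.chrom, p.pos) else 0.0 for p in observed_set]
        )
    )
    return resample_mean_null(
        membership, n_draw, n_reps, seed, observed=observed, replace=replace
    )


@dataclass
class PerPeakRateResult:
    """Per-sample mutation rates per peak, split by recurrent-position content."""

    rates_with_recurrent: np.ndarray
    rates_without_recurrent: np.ndarray
    p_value: Optional[float]

    @property
    def mean_with(self) -> float:
        return float(self.rates_with_recurrent.mean())

    @property
    def mean_without(self) -> float:
        return float(self.rates_without_recurrent.mean())


def per_peak_mutation_rate(
    mutations,
    peaks: Iterable[GenomicInterval],
    n_samples: int,
    recurrent_positions,
) -> PerPeakRateResult:
    """Compare per-sample mutation rates between peaks with and without
    a recurrent position (two-sided Wilcoxon rank-sum, tie-corrected
    normal approximation). ``p_value`` is None when a partition is empty.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    peaks = list(peaks)
    tagged = [
        GenomicInterval(pk.chrom, pk.start, pk.end, name=str(i))
        for i, pk in enumerate(peaks)
    ]
    index = IntervalIndex(tagged)
    counts = np.zeros(len(peaks))
    for m in mutations:
        for hit in index.containing_pos(m.chrom, m.pos):
            counts[int(hit.name)] += 1
    has_recurrent = np.zeros(len(peaks), dtype=bool)
    for r in recurrent_positions:
        for hit in index.containing_pos(r.chrom, r.pos):
            has_recurrent[int(hit.name)] = True
    rates = counts / n_samples
    with_rec = rates[has_recurrent]
    without_rec = rates[~has_recurrent]
    p: Optional[float] = None
    if with_rec.size and without_rec.size:
        p = float(
            mannwhitneyu(
                with_rec, without_rec, alternative="two-sided", method="asymptotic"
            ).pvalue
        )
    return PerPeakRateResult(with_rec, without_rec, p)
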