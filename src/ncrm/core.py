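"""Core domain types shared by every stage of the screen.

Two coordinate conventions coexist, mirroring the source formats:

* genomic *intervals* (peaks, interaction anchors, TFBSs, exons, gene
  spans) are 0-based half-open, BED-style;
* point *mutations* carry a 1-based ``pos``, VCF/COSMIC-style, and are
  converted at query time (a 1-based position ``p`` lies in interval
  ``[start, end)`` iff ``start <= p - 1 < end``).

Chromosome names are normalized to the ``chrN`` form at ingest so that
sources that disagree ("1" vs "chr1") can be intersected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from intervaltree import IntervalTree

BASES = ("A", "C", "G", "T")
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

INTERACTION_METHODS = frozenset(
    {"3C", "4C", "5C", "Hi-C", "ChIA-PET", "Capture-C", "IM-PET"}
)


class FormatError(ValueError):
    """A file does not conform to its documented dialect."""


class ConfigurationError(ValueError):
    """A run or generator configuration is inconsistent."""


class DataError(ValueError):
    """Input data violate an operation's preconditions."""


def normalize_chrom(name: str) -> str:
    """Normalize a chromosome name to the ``chrN`` form ("1" -> "chr1")."""
    name = name.strip()
    if not name:
        raise FormatError("empty chromosome name")
    if name.lower().startswith("chr"):
        return "chr" + name[3:]
    if name in ("MT", "M"):
        return "chrM"
    return "chr" + name


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("interval chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"interval start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"interval start must precede end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains_pos(self, chrom: str, pos: int) -> bool:
        """Whether a 1-based position lies inside this interval."""
        return chrom == self.chrom and self.start <= pos - 1 < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class SomaticMutation:
    """One single-nucleotide somatic call in one sample.

    ``somatic_confirmed`` means the call came from sequencing both the
    tumor and the matched normal of the same patient; ``snp_flagged``
    marks calls annotated as germline polymorphisms in the source
    catalog. Both flags feed the source filters.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    sample_id: str
    individual_id: Optional[str] = None
    cancer_type: Optional[str] = None
    tissue_site: Optional[str] = None
    somatic_confirmed: bool = True
    snp_flagged: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"mutation pos must be >= 1, got {self.pos}")
        if self.ref not in BASE_INDEX or self.alt not in BASE_INDEX:
            raise ValueError(
                f"alleles must be single A/C/G/T, got {self.ref!r}>{self.alt!r}"
            )
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ, got {self.ref!r} twice")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos)


@dataclass(frozen=True)
class GeneModel:
    """A gene with its span, strand-aware TSS and exon union."""

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    tss: int  # 1-based
    span: GenomicInterval
    exons: tuple = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        for ex in self.exons:
            if ex.chrom != self.chrom:
                raise ValueError(
                    f"exon on {ex.chrom} but gene {self.gene_id} on {self.chrom}"
                )


@dataclass(frozen=True)
class ChromatinInteraction:
    """A pair of spatially contacting anchors from a 3C-family assay."""

    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    cell_type: str = ""
    method: str = "Hi-C"

    def anchors(self) -> tuple:
        return (self.anchor_a, self.anchor_b)


@dataclass(frozen=True, eq=False)
class MotifModel:
    """A position frequency matrix p_{b,i}, rows A/C/G/T, columns 1..L."""

    motif_id: str
    freq: np.ndarray
    name: Optional[str] = None

    def __post_init__(self) -> None:
        freq = np.asarray(self.freq, dtype=float)
        object.__setattr__(self, "freq", freq)
        if freq.ndim != 2 or freq.shape[0] != 4:
            raise ValueError("freq must have shape (4, L)")
        if (freq < 0).any():
            raise ValueError("frequencies must be non-negative")
        colsums = freq.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError("every PFM column must sum to 1")

    @property
    def length(self) -> int:
        return self.freq.shape[1]

    def p(self, base: str, i: int) -> float:
        """Frequency of ``base`` at 1-based motif column ``i``."""
        return float(self.freq[BASE_INDEX[base], i - 1])

    def consensus(self) -> str:
        return "".join(BASES[j] for j in self.freq.argmax(axis=0))


@dataclass(frozen=True)
class TFBSInstance:
    """A located motif match carrying its database match score."""

    site_id: str
    interval: GenomicInterval
    strand: str
    motif_id: str
    match_score: float

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.match_score < 0:
            raise ValueError("match_score must be >= 0")


@dataclass
class ExpressionMatrix:
    """A genes x samples expression table with per-sample cancer-type labels."""

    values: "object"  # pandas DataFrame, genes x samples
    cancer_type: "object"  # pandas Series indexed by sample_id

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.cancer_type.index]
        if missing:
            raise DataError(f"samples without cancer-type label: {missing[:5]}")
        if self.cancer_type.isna().any():
            raise DataError("cancer-type labels must not be missing")

    @property
    def genes(self) -> list:
        return list(self.values.index)

    @property
    def samples(self) -> list:
        return list(self.values.columns)


class IntervalIndex:
    """Per-chromosome containment/overlap queries over genomic intervals."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self._trees: dict = {}
        self._n = 0
        for iv in intervals:
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
            self._n += 1

    def __len__(self) -> int:
        return self._n

    @staticmethod
    def _sort_key(iv: GenomicInterval) -> tuple:
        return (iv.start, iv.end, iv.name or "")

    def containing_pos(self, chrom: str, pos: int) -> list:
        """All intervals containing a 1-based position, sorted by coordinate."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((hit.data for hit in tree.at(pos - 1)), key=self._sort_key)

    def overlapping(self, interval: GenomicInterval) -> list:
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return []
        return sorted(
            (hit.data for hit in tree.overlap(interval.start, interval.end)),
            key=self._sort_key,
        )


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list:
    """Merge overlapping/adjacent intervals per chromosome (union)."""
    by_chrom: dict = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda v: (v.start, v.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    """Total genomic length covered by the union of intervals."""
    return sum(iv.length for iv in merge_intervals(intervals))
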