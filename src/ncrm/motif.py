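"""Shannon-entropy motif-impact statistics (Δbit).

The information content of motif column *i* is

    C_i = 2 + Σ_{b ∈ {A,C,G,T}} p_{b,i} · log2 p_{b,i}

with the convention 0·log2 0 = 0, so C_i ranges from 0 bits (uniform
column) to 2 bits (invariant column). The impact of substituting the
reference base with the alternate base at column *i* is expressed on the
sequence-logo letter-height scale,

    Δbit = p_{alt,i}·C_i − p_{ref,i}·C_i,

which is antisymmetric in (ref, alt) and negative when the mutation
moves the sequence away from the motif's preferred base — i.e. a
weakened binding site. A log-ratio alternative
(log2 p_{alt,i} − log2 p_{ref,i}) is selectable per call.

For a site on the minus strand the genomic alleles are complemented and
the motif column index reversed before lookup. The average Δbit over all
mutations observed in one TFBS summarizes the site-level impact, and a
resampled null of average Δbit over random TFBS-contained mutations
provides the expectation for comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import BASE_INDEX, COMPLEMENT, DataError, MotifModel, TFBSInstance
from .nulls import ResampleNull, resample_mean_null

_LOG_RATIO_FLOOR = 1e-6  # frequency floor for the log-ratio convention only


def column_information(freq_column: Sequence[float]) -> float:
    """Information content C_i of one PFM column, in bits."""
    col = np.asarray(freq_column, dtype=float)
    if col.shape != (4,):
        raise ValueError("a frequency column has exactly 4 entries (A, C, G, T)")
    if (col < 0).any():
        raise ValueError("frequencies must be non-negative")
    if not math.isclose(col.sum(), 1.0, abs_tol=1e-6):
        raise ValueError(f"column must sum to 1, got {col.sum()!r}")
    nonzero = col[col > 0]
    return 2.0 + float((nonzero * np.log2(nonzero)).sum())


def delta_bit(
    motif: MotifModel,
    i: int,
    ref: str,
    alt: str,
    convention: str = "letter_height",
) -> float:
    """Δbit of substituting ref -> alt at 1-based motif column ``i``."""
    if not 1 <= i <= motif.length:
        raise DataError(f"column {i} outside motif of length {motif.length}")
    if ref == alt:
        raise DataError("ref and alt must differ")
    if ref not in BASE_INDEX or alt not in BASE_INDEX:
        raise DataError(f"alleles must be A/C/G/T, got {ref!r}>{alt!r}")
    p_ref = motif.p(ref, i)
    p_alt = motif.p(alt, i)
    if convention == "letter_height":
        c = column_information(motif.freq[:, i - 1])
        return (p_alt - p_ref) * c
    if convention == "log_ratio":
        return math.log2(max(p_alt, _LOG_RATIO_FLOOR)) - math.log2(
            max(p_ref, _LOG_RATIO_FLOOR)
        )
    raise ValueError(f"unknown convention {convention!r}")


@dataclass(frozen=True)
class MutationImpact:
    chrom: str
    pos: int
    motif_column: int  # 1-based, on the motif's own strand
    motif_ref: str
    motif_alt: str
    delta_bit: float


@dataclass(frozen=True)
class DeltaBitResult:
    site_id: str
    motif_id: str
    impacts: tuple
    average_delta_bit: float

    @property
    def n_mutations(self) -> int:
        return len(self.impacts)


def map_to_motif(site: TFBSInstance, motif: MotifModel, pos: int, ref: str, alt: str):
    """Map a genomic substitution onto motif coordinates/alleles.

    Returns ``(column, motif_ref, motif_alt)``; for a minus-strand site
    the alleles are complemented and the column index reversed.
    """
    offset = pos - 1 - site.interval.start
    if not 0 <= offset < motif.length:
        raise DataError(
            f"position {pos} outside site {site.site_id} "
            f"[{site.interval.start}, {site.interval.end})"
        )
    if site.strand == "+":
        return offset + 1, ref, alt
    return motif.length - offset, COMPLEMENT[ref], COMPLEMENT[alt]


def average_delta_bit(
    site: TFBSInstance,
    mutations_in_site,
    motif: MotifModel,
    convention: str = "letter_height",
) -> DeltaBitResult:
    """Average Δbit over all mutations observed in one TFBS.

    Each record is counted once; duplicate (sample, position, alleles)
    entries should be deduplicated by the caller so that one sample's
    mutation contributes a single term.
    """
    if site.interval.length != motif.length:
        raise DataError(
            f"site {site.site_id} length {site.interval.length} != motif "
            f"length {motif.length}"
        )
    impacts = []
    for m in mutations_in_site:
        column, mref, malt = map_to_motif(site, motif, m.pos, m.ref, m.alt)
        impacts.append(
            MutationImpact(
                chrom=m.chrom,
                pos=m.pos,
                motif_column=column,
                motif_ref=mref,
                motif_alt=malt,
                delta_bit=delta_bit(motif, column, mref, malt, convention),
            )
        )
    if not impacts:
        raise DataError(f"site {site.site_id} has no mutations to average")
    average = float(np.mean([im.delta_bit for im in impacts]))
    return DeltaBitResult(
        site_id=site.site_id,
        motif_id=motif.motif_id,
        impacts=tuple(impacts),
        average_delta_bit=average,
    )


def expected_delta_bit_null(
    delta_values,
    n_draw: int = 100,
    n_reps: int = 1000,
    seed: Optional[int] = None,
    replace: bool = False,
) -> ResampleNull:
    """Resampled expectation of the average Δbit of random TFBS mutations.

    ``delta_values`` are the per-(mutation, site) Δbit values of the full
    pool of mutations falling in any TFBS; each repetition draws
    ``n_draw`` of them without replacement and averages.
    """
    return resample_mean_null(delta_values, n_draw, n_reps, seed, replace=replace)
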