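"""Readers and writers for the flat-file dialects the screen consumes.

Formats
-------
mutation TSV
    header ``chrom  pos  ref  alt  sample_id`` plus, in the ``cosmic``
    dialect, ``individual_id  cancer_type  tissue_site  somatic_confirmed
    snp_flagged``. ``pos`` is 1-based. Indels and multi-nucleotide records
    are rejected at ingest with a logged count (the screen is defined for
    single-base substitutions only).
BED3+ / narrowPeak
    0-based half-open; columns beyond name/score are ignored.
paired-interval TSV
    ``chrom_a start_a end_a chrom_b start_b end_b cell_type method``,
    anchors 0-based half-open.
JASPAR PFM text
    ``>ID NAME`` followed by four count rows; counts are normalized per
    column to frequencies at parse time.
Ensembl-dialect GTF
    1-based inclusive coordinates, converted to the internal 0-based
    half-open convention; ``gene`` and ``exon`` features are used.
expression TSV
    genes x samples, first column ``gene_id``.
sample metadata TSV
    ``sample_id  cancer_type``.
"""

from __future__ import annotations

import logging
import re
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from .core import (
    BASES,
    ChromatinInteraction,
    ExpressionMatrix,
    FormatError,
    GeneModel,
    GenomicInterval,
    INTERACTION_METHODS,
    MotifModel,
    SomaticMutation,
    TFBSInstance,
    merge_intervals,
    normalize_chrom,
)

logger = logging.getLogger(__name__)

_MUTATION_CORE_COLUMNS = ("chrom", "pos", "ref", "alt", "sample_id")
_MUTATION_COSMIC_COLUMNS = _MUTATION_CORE_COLUMNS + (
    "individual_id",
    "cancer_type",
    "tissue_site",
    "somatic_confirmed",
    "snp_flagged",
)

_TRUE_STRINGS = {"1", "true", "t", "y", "yes"}
_FALSE_STRINGS = {"0", "false", "f", "n", "no", ""}


def _parse_bool(value, column: str) -> bool:
    text = str(value).strip().lower()
    if text in _TRUE_STRINGS:
        return True
    if text in _FALSE_STRINGS or text == "nan":
        return False
    raise FormatError(f"cannot interpret {value!r} as boolean in column {column}")


def read_mutation_table(path, dialect: str = "cosmic") -> list:
    """Read a mutation TSV into validated :class:`SomaticMutation` records.

    Records with non-ACGT or multi-nucleotide alleles are dropped and the
    rejection count is logged; a missing mandatory column raises
    :class:`FormatError` naming the column.
    """
    if dialect not in ("cosmic", "simple"):
        raise ValueError(f"unknown dialect {dialect!r}")
    required = _MUTATION_COSMIC_COLUMNS if dialect == "cosmic" else _MUTATION_CORE_COLUMNS
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for column in required:
        if column not in table.columns:
            raise FormatError(f"mutation table missing mandatory column {column!r}")
    records = []
    n_rejected = 0
    for row in table.itertuples(index=False):
        row = row._asdict()
        try:
            records.append(
                SomaticMutation(
                    chrom=normalize_chrom(row["chrom"]),
                    pos=int(row["pos"]),
                    ref=row["ref"].strip().upper(),
                    alt=row["alt"].strip().upper(),
                    sample_id=row["sample_id"],
                    individual_id=row.get("individual_id") or None,
                    cancer_type=row.get("cancer_type") or None,
                    tissue_site=row.get("tissue_site") or None,
                    somatic_confirmed=_parse_bool(
                        row.get("somatic_confirmed", "1"), "somatic_confirmed"
                    ),
                    snp_flagged=_parse_bool(row.get("snp_flagged", "0"), "snp_flagged"),
                )
            )
        except (ValueError, KeyError) as exc:  # record-level rejection
            n_rejected += 1
            logger.debug("rejected mutation record %r: %s", row, exc)
    if n_rejected:
        logger.info("read_mutation_table: rejected %d non-SNV records", n_rejected)
    return records


def write_mutation_table(mutations: Iterable[SomaticMutation], path) -> None:
    rows = [
        {
            "chrom": m.chrom,
            "pos": m.pos,
            "ref": m.ref,
            "alt": m.alt,
            "sample_id": m.sample_id,
            "individual_id": m.individual_id or "",
            "cancer_type": m.cancer_type or "",
            "tissue_site": m.tissue_site or "",
            "somatic_confirmed": int(m.somatic_confirmed),
            "snp_flagged": int(m.snp_flagged),
        }
        for m in mutations
    ]
    pd.DataFrame(rows, columns=list(_MUTATION_COSMIC_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def read_bed(path) -> list:
    """Read BED3+/narrowPeak intervals (0-based half-open), keeping name/score."""
    intervals = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end or start < 0:
                raise FormatError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-numeric score") from exc
            intervals.append(
                GenomicInterval(normalize_chrom(fields[0]), start, end, name, score)
            )
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as handle:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None:
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None:
                score = iv.score
                fields.append(str(int(score)) if float(score).is_integer() else str(score))
            handle.write("\t".join(fields) + "\n")


_INTERACTION_COLUMNS = (
    "chrom_a",
    "start_a",
    "end_a",
    "chrom_b",
    "start_b",
    "end_b",
    "cell_type",
    "method",
)


def read_interactions(path) -> list:
    """Read the 8-column paired-interval TSV of chromatin interactions."""
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for column in _INTERACTION_COLUMNS:
        if column not in table.columns:
            raise FormatError(f"interaction table missing column {column!r}")
    interactions = []
    for row in table.itertuples(index=False):
        anchor_a = GenomicInterval(
            normalize_chrom(row.chrom_a), int(row.start_a), int(row.end_a)
        )
        anchor_b = GenomicInterval(
            normalize_chrom(row.chrom_b), int(row.start_b), int(row.end_b)
        )
        method = row.method
        if method not in INTERACTION_METHODS:
            logger.warning("unknown interaction method %r; record kept", method)
        interactions.append(
            ChromatinInteraction(anchor_a, anchor_b, row.cell_type, method)
        )
    return interactions


def write_interactions(interactions: Iterable[ChromatinInteraction], path) -> None:
    rows = [
        {
            "chrom_a": it.anchor_a.chrom,
            "start_a": it.anchor_a.start,
            "end_a": it.anchor_a.end,
            "chrom_b": it.anchor_b.chrom,
            "start_b": it.anchor_b.start,
            "end_b": it.anchor_b.end,
            "cell_type": it.cell_type,
            "method": it.method,
        }
        for it in interactions
    ]
    pd.DataFrame(rows, columns=list(_INTERACTION_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def read_jaspar_pfm(path) -> list:
    """Read a JASPAR-format text PFM file into frequency-normalized motifs."""
    with open(path) as handle:
        try:
            parsed = bio_motifs.parse(handle, "jaspar")
            parsed = list(parsed)
        except Exception as exc:
            raise FormatError(f"{path}: not parseable as JASPAR PFM text: {exc}") from exc
    models = []
    for record in parsed:
        counts = np.array([list(record.counts[b]) for b in BASES], dtype=float)
        if (counts < 0).any():
            raise FormatError(f"motif {record.matrix_id}: negative counts")
        totals = counts.sum(axis=0)
        if (totals <= 0).any():
            bad = int(np.argmin(totals)) + 1
            raise FormatError(
                f"motif {record.matrix_id}: column {bad} has zero total count"
            )
        models.append(
            MotifModel(
                motif_id=record.matrix_id or record.name,
                freq=counts / totals,
                name=record.name or None,
            )
        )
    return models


def write_jaspar_pfm(motifs: Iterable, path, counts_scale: int = 100) -> None:
    """Write motifs in JASPAR bracket format (frequencies scaled to counts)."""
    with open(path, "w") as handle:
        for m in motifs:
            handle.write(f">{m.motif_id} {m.name or m.motif_id}\n")
            counts = np.rint(m.freq * counts_scale).astype(int)
            for bi, base in enumerate(BASES):
                row = "  ".join(f"{c:5d}" for c in counts[bi])
                handle.write(f"{base}  [ {row} ]\n")


_GTF_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def read_gtf_genes(path) -> list:
    """Read gene models from an Ensembl-dialect GTF.

    GTF coordinates are 1-based inclusive and converted to the internal
    0-based half-open convention. The TSS is the strand-aware gene start;
    exons are unioned per gene. A gene with no exon features is kept with
    an empty exon list (with a warning).
    """
    spans: dict = {}
    meta: dict = {}
    exons: dict = {}
    order: list = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}:{lineno}: fewer than 9 GTF columns")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature not in ("gene", "exon"):
                continue
            attributes = dict(_GTF_ATTR_RE.findall(attrs))
            gene_id = attributes.get("gene_id")
            if gene_id is None:
                raise FormatError(f"{path}:{lineno}: {feature} without gene_id")
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            interval = GenomicInterval(normalize_chrom(chrom), start_i - 1, end_i)
            if feature == "gene":
                if gene_id not in meta:
                    order.append(gene_id)
                spans[gene_id] = interval
                meta[gene_id] = (attributes.get("gene_name", gene_id), strand)
            else:
                if gene_id not in meta:
                    order.append(gene_id)
                    meta[gene_id] = (attributes.get("gene_name", gene_id), strand)
                exons.setdefault(gene_id, []).append(interval)
    genes = []
    for gene_id in order:
        gene_name, strand = meta[gene_id]
        exon_union = tuple(merge_intervals(exons.get(gene_id, [])))
        span = spans.get(gene_id)
        if span is None:
            if not exon_union:
                logger.warning("gene %s has no span and no exons; skipped", gene_id)
                continue
            span = GenomicInterval(
                exon_union[0].chrom, exon_union[0].start, exon_union[-1].end
            )
        if not exon_union:
            logger.warning("gene %s has no exon features", gene_id)
        tss = span.start + 1 if strand == "+" else span.end
        genes.append(
            GeneModel(
                gene_id=gene_id,
                gene_name=gene_name,
                chrom=span.chrom,
                strand=strand,
                tss=tss,
                span=span,
                exons=exon_union,
            )
        )
    return genes


def write_gtf(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as handle:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}";'
            handle.write(
                "\t".join(
                    [
                        g.chrom,
                        "ncrm",
                        "gene",
                        str(g.span.start + 1),
                        str(g.span.end),
                        ".",
                        g.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
            for ex in g.exons:
                handle.write(
                    "\t".join(
                        [
                            g.chrom,
                            "ncrm",
                            "exon",
                            str(ex.start + 1),
                            str(ex.end),
                            ".",
                            g.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


_TFBS_COLUMNS = ("chrom", "start", "end", "site_id", "motif_id", "score", "strand")


def read_tfbs_table(path) -> list:
    """Read TFBS instances from a 7-column TSV (interval 0-based half-open)."""
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for column in _TFBS_COLUMNS:
        if column not in table.columns:
            raise FormatError(f"TFBS table missing column {column!r}")
    sites = []
    for row in table.itertuples(index=False):
        sites.append(
            TFBSInstance(
                site_id=row.site_id,
                interval=GenomicInterval(
                    normalize_chrom(row.chrom), int(row.start), int(row.end)
                ),
                strand=row.strand,
                motif_id=row.motif_id,
                match_score=float(row.score),
            )
        )
    return sites


def write_tfbs_table(sites: Iterable[TFBSInstance], path) -> None:
    rows = [
        {
            "chrom": s.interval.chrom,
            "start": s.interval.start,
            "end": s.interval.end,
            "site_id": s.site_id,
            "motif_id": s.motif_id,
            "score": s.match_score,
            "strand": s.strand,
        }
        for s in sites
    ]
    pd.DataFrame(rows, columns=list(_TFBS_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_expression(path, metadata_path) -> ExpressionMatrix:
    """Read a genes x samples TSV plus a sample-metadata TSV into a matrix."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index.name = "gene_id"
    meta = read_sample_metadata(metadata_path)
    return ExpressionMatrix(values=values, cancer_type=meta)


def read_sample_metadata(path) -> pd.Series:
    table = pd.read_csv(path, sep="\t", dtype=str)
    for column in ("sample_id", "cancer_type"):
        if column not in table.columns:
            raise FormatError(f"sample metadata missing column {column!r}")
    return table.set_index("sample_id")["cancer_type"]


def write_expression(expr: ExpressionMatrix, path, metadata_path) -> None:
    expr.values.to_csv(path, sep="\t", float_format="%.6g")
    expr.cancer_type.rename("cancer_type").rename_axis("sample_id").to_frame().to_csv(
        metadata_path, sep="\t"
    )
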