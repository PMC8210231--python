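"""Seeded synthetic cohorts with planted truth.

The generator emits a complete fixture bundle — a toy genome with genes
and exons, two somatic-mutation cohorts (a curated-catalog-like cohort 1
and a WGS-like cohort 2 with matched expression), open-chromatin peaks,
chromatin-interaction anchor pairs, PFMs with located binding-site
instances, and an expression matrix — together with a machine-readable
truth manifest.

Planted candidate positions satisfy all ten screening criteria by
construction: each sits in an intergenic binding site inside a peak and
inside one anchor of an interaction whose partner anchor contains a
target gene's TSS; it is carried by multiple samples across multiple
cancer types in both cohorts, with a single substitution pattern hitting
the motif's consensus base (so its Δbit is negative); and the target
gene's expression is shifted in the mutated samples. Decoys are built
identically except for exactly one named defect each, covering every
criterion. Background mutations occupy globally unique positions away
from the planted loci, so they can never form a recurrent position and
the pipeline's final set equals the planted set exactly.

All randomness flows from a single seed; the same configuration and
seed reproduce a byte-identical bundle.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from . import io as gio
from .core import (
    BASES,
    COMPLEMENT,
    ChromatinInteraction,
    ConfigurationError,
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    MotifModel,
    SomaticMutation,
    TFBSInstance,
)

_TISSUE_BY_TYPE = {
    "BRCA": "breast",
    "COAD": "large_intestine",
    "LUAD": "lung",
    "STAD": "stomach",
    "LIHC": "liver",
    "KIRC": "kidney",
}

HEMATOPOIETIC_TISSUE = "haematopoietic_and_lymphoid_tissue"

#: decoy construction name -> funnel stage at which the position disappears
DECOY_STAGES = {
    "hematopoietic_tissue": "tissue",
    "same_individual_duplicate": "recurrence",
    "unconfirmed_somatic": "somatic_confirmed",
    "snp_flagged": "snp_flagged",
    "exonic": "exonic",
    "single_sample": "recurrence",
    "single_cancer_type": "multi_cancer_type",
    "absent_from_cohort2": "second_cohort",
    "outside_peaks": "open_chromatin",
    "outside_anchors": "interaction",
    "sub_threshold_site_score": "tfbs",
}


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort bundle."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    genes_per_chrom: int = 20
    gene_span: int = 10_000
    gene_gap: int = 15_000
    exons_per_gene: int = 3
    exon_length: int = 300
    n_samples_cohort1: int = 24
    n_samples_cohort2: int = 60
    cancer_types: tuple = ("BRCA", "COAD", "LUAD", "STAD")
    background_mutations_per_sample: int = 40
    n_planted_cnrms: int = 7
    planted_support_cohort1: int = 3
    planted_support_cohort2: int = 12
    n_background_peaks: int = 60
    peak_length: int = 400
    n_background_interactions: int = 40
    anchor_length: int = 1_000
    n_motifs: int = 4
    motif_length: int = 10
    consensus_freq: float = 0.85
    n_background_sites: int = 40
    n_tfbs_background_mutations: int = 60
    jaspar_score: float = 500.0
    effect_size: float = 2.0
    effect_direction: int = -1
    affected_fraction: float = 1.0
    expression_sigma: float = 0.5
    with_decoys: bool = True

    def validate(self) -> None:
        n_loci = self.n_planted_cnrms + (len(DECOY_STAGES) if self.with_decoys else 0)
        n_slots = self.n_chroms * self.genes_per_chrom
        if n_loci > n_slots:
            raise ConfigurationError(
                f"{n_loci} planted loci exceed the {n_slots} intergenic slots"
            )
        layout = self.gene_gap + self.genes_per_chrom * (self.gene_span + self.gene_gap)
        if layout > self.chrom_length:
            raise ConfigurationError("gene layout exceeds chromosome length")
        if len(self.cancer_types) < 2:
            raise ConfigurationError("need at least two cancer types")
        if self.planted_support_cohort1 > self.n_samples_cohort1:
            raise ConfigurationError("planted cohort-1 support exceeds sample count")
        if self.planted_support_cohort2 > self.n_samples_cohort2:
            raise ConfigurationError("planted cohort-2 support exceeds sample count")
        if self.exon_length * self.exons_per_gene > self.gene_span:
            raise ConfigurationError("exons do not fit in the gene span")
        if self.motif_length >= self.exon_length:
            raise ConfigurationError("motif must fit inside an exon")


@dataclass
class TruthManifest:
    """Machine-readable record of what was planted and why decoys fail."""

    planted: List[dict] = field(default_factory=list)
    decoys: List[dict] = field(default_factory=list)
    effects: List[dict] = field(default_factory=list)

    def planted_keys(self) -> set:
        return {(p["chrom"], p["pos"]) for p in self.planted}

    def decoy_keys(self) -> set:
        return {(d["chrom"], d["pos"]) for d in self.decoys}

    def to_json(self, path) -> None:
        with open(path, "w") as handle:
            json.dump(
                {"planted": self.planted, "decoys": self.decoys, "effects": self.effects},
                handle,
                indent=2,
                sort_keys=True,
            )
            handle.write("\n")

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as handle:
            data = json.load(handle)
        return cls(
            planted=data["planted"], decoys=data["decoys"], effects=data["effects"]
        )


BUNDLE_FILES = {
    "cohort1": "cohort1_mutations.tsv",
    "cohort2": "cohort2_mutations.tsv",
    "genes": "genes.gtf",
    "peaks": "peaks.bed",
    "interactions": "interactions.tsv",
    "motifs": "motifs.jaspar",
    "sites": "tfbs_sites.tsv",
    "expression": "expression.tsv",
    "metadata": "samples.tsv",
    "truth": "truth_manifest.json",
    "config": "cohort_config.json",
}


@dataclass
class CohortBundle:
    """An in-memory fixture bundle plus its truth manifest."""

    config: CohortConfig
    cohort1: list
    cohort2: list
    genes: list
    peaks: list
    interactions: list
    motifs: list
    sites: list
    expression: ExpressionMatrix
    truth: TruthManifest

    def write(self, outdir) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        gio.write_mutation_table(self.cohort1, outdir / BUNDLE_FILES["cohort1"])
        gio.write_mutation_table(self.cohort2, outdir / BUNDLE_FILES["cohort2"])
        gio.write_gtf(self.genes, outdir / BUNDLE_FILES["genes"])
        gio.write_bed(self.peaks, outdir / BUNDLE_FILES["peaks"])
        gio.write_interactions(self.interactions, outdir / BUNDLE_FILES["interactions"])
        gio.write_jaspar_pfm(self.motifs, outdir / BUNDLE_FILES["motifs"])
        gio.write_tfbs_table(self.sites, outdir / BUNDLE_FILES["sites"])
        gio.write_expression(
            self.expression,
            outdir / BUNDLE_FILES["expression"],
            outdir / BUNDLE_FILES["metadata"],
        )
        self.truth.to_json(outdir / BUNDLE_FILES["truth"])
        with open(outdir / BUNDLE_FILES["config"], "w") as handle:
            json.dump(asdict(self.config), handle, indent=2, sort_keys=True)
            handle.write("\n")
        return outdir

    @classmethod
    def load(cls, directory) -> "CohortBundle":
        directory = Path(directory)
        with open(directory / BUNDLE_FILES["config"]) as handle:
            raw = json.load(handle)
        raw["cancer_types"] = tuple(raw["cancer_types"])
        config = CohortConfig(**raw)
        return cls(
            config=config,
            cohort1=gio.read_mutation_table(directory / BUNDLE_FILES["cohort1"]),
            cohort2=gio.read_mutation_table(directory / BUNDLE_FILES["cohort2"]),
            genes=gio.read_gtf_genes(directory / BUNDLE_FILES["genes"]),
            peaks=gio.read_bed(directory / BUNDLE_FILES["peaks"]),
            interactions=gio.read_interactions(
                directory / BUNDLE_FILES["interactions"]
            ),
            motifs=gio.read_jaspar_pfm(directory / BUNDLE_FILES["motifs"]),
            sites=gio.read_tfbs_table(directory / BUNDLE_FILES["sites"]),
            expression=gio.read_expression(
                directory / BUNDLE_FILES["expression"],
                directory / BUNDLE_FILES["metadata"],
            ),
            truth=TruthManifest.from_json(directory / BUNDLE_FILES["truth"]),
        )


def _tissue_for(cancer_type: str) -> str:
    return _TISSUE_BY_TYPE.get(cancer_type, cancer_type.lower())


def _make_genes(config: CohortConfig, rng: np.random.Generator) -> list:
    genes = []
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        for gi in range(config.genes_per_chrom):
            span_start = config.gene_gap + gi * (config.gene_span + config.gene_gap)
            span_end = span_start + config.gene_span
            strand = "+" if rng.random() < 0.5 else "-"
            first = GenomicInterval(chrom, span_start, span_start + config.exon_length)
            last = GenomicInterval(chrom, span_end - config.exon_length, span_end)
            middle_lo = span_start + config.exon_length + 100
            middle_hi = span_end - 2 * config.exon_length - 100
            mstart = int(rng.integers(middle_lo, middle_hi))
            middle = GenomicInterval(chrom, mstart, mstart + config.exon_length)
            gene_id = f"G{ci}_{gi:02d}"
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    gene_name=f"GENE{ci}_{gi:02d}",
                    chrom=chrom,
                    strand=strand,
                    tss=span_start + 1 if strand == "+" else span_end,
                    span=GenomicInterval(chrom, span_start, span_end),
                    exons=(first, middle, last),
                )
            )
    return genes


def _make_motifs(config: CohortConfig, rng: np.random.Generator) -> list:
    motifs = []
    for mi in range(config.n_motifs):
        consensus = rng.integers(0, 4, size=config.motif_length)
        freq = np.full((4, config.motif_length), (1 - config.consensus_freq) / 3)
        freq[consensus, np.arange(config.motif_length)] = config.consensus_freq
        motifs.append(
            MotifModel(motif_id=f"MA{mi:04d}.1", freq=freq, name=f"TF{mi}")
        )
    return motifs


def _blocked(blocks: list, chrom: str, start: int, end: int) -> bool:
    return any(bc == chrom and start < be and bs < end for bc, bs, be in blocks)


def _draw_interval(
    config: CohortConfig,
    rng: np.random.Generator,
    length: int,
    blocks: list,
    avoid: Optional[list] = None,
) -> GenomicInterval:
    for _ in range(10_000):
        ci = int(rng.integers(0, config.n_chroms))
        chrom = f"chr{ci + 1}"
        start = int(rng.integers(0, config.chrom_length - length))
        end = start + length
        if _blocked(blocks, chrom, start, end):
            continue
        if avoid is not None and _blocked(avoid, chrom, start, end):
            continue
        return GenomicInterval(chrom, start, end)
    raise ConfigurationError("could not place a background interval; genome too dense")


def _draw_positions(
    config: CohortConfig,
    rng: np.random.Generator,
    n: int,
    blocks: list,
    used: set,
) -> list:
    total = config.n_chroms * config.chrom_length
    out: list = []
    while len(out) < n:
        for value in rng.integers(0, total, size=2 * (n - len(out)) + 16):
            chrom = f"chr{int(value) // config.chrom_length + 1}"
            pos = int(value) % config.chrom_length + 1
            if _blocked(blocks, chrom, pos - 1, pos):
                continue
            if (chrom, pos) in used:
                continue
            used.add((chrom, pos))
            out.append((chrom, pos))
            if len(out) == n:
                break
    return out


@dataclass
class _Sample:
    sample_id: str
    individual_id: str
    cancer_type: str
    tissue_site: str


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Generate a complete fixture bundle with its truth manifest."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    types = list(config.cancer_types)

    genes = _make_genes(config, rng)
    genes_by_slot = {
        (g.chrom, int(g.gene_id.split("_")[1])): g for g in genes
    }
    motifs = _make_motifs(config, rng)
    L = config.motif_length

    # --- samples ------------------------------------------------------
    cohort1_samples = [
        _Sample(
            sample_id=f"C1S{i:03d}",
            individual_id=f"IND{i:03d}",
            cancer_type=types[i % len(types)],
            tissue_site=_tissue_for(types[i % len(types)]),
        )
        for i in range(config.n_samples_cohort1)
    ]
    dup_samples = []
    hema_samples = []
    if config.with_decoys:
        dup_samples = [
            _Sample("C1S900", "IND900", types[0], _tissue_for(types[0])),
            _Sample("C1S901", "IND900", types[1], _tissue_for(types[1])),
        ]
        hema_samples = [
            _Sample(f"C1S9{10 + i:02d}", f"IND9{10 + i:02d}", types[i % len(types)],
                    HEMATOPOIETIC_TISSUE)
            for i in range(3)
        ]
    cohort2_samples = [
        _Sample(
            sample_id=f"C2S{j:03d}",
            individual_id=f"IND2{j:03d}",
            cancer_type=types[j % len(types)],
            tissue_site=_tissue_for(types[j % len(types)]),
        )
        for j in range(config.n_samples_cohort2)
    ]

    # --- locus layout -------------------------------------------------
    slots = [
        (f"chr{ci + 1}", gi)
        for ci in range(config.n_chroms)
        for gi in range(config.genes_per_chrom)
    ]
    order = rng.permutation(len(slots))
    decoy_names = list(DECOY_STAGES) if config.with_decoys else []
    n_loci = config.n_planted_cnrms + len(decoy_names)
    chosen = [slots[i] for i in order[:n_loci]]

    truth = TruthManifest()
    cohort1: list = []
    cohort2: list = []
    peaks: list = []
    interactions: list = []
    sites: list = []
    blocks: list = []  # exclusion zones around every planted/decoy locus
    used_positions: set = set()

    def place_site(slot, kind: str, exonic: bool):
        chrom, gi = slot
        gene = genes_by_slot[(chrom, gi)]
        if exonic:
            exon = gene.exons[1]
            site_start = (exon.start + exon.end) // 2 - L // 2
        else:
            gap_center = gene.span.end + config.gene_gap // 2
            site_start = gap_center - L // 2
        strand = "+" if rng.random() < 0.5 else "-"
        motif = motifs[int(rng.integers(0, len(motifs)))]
        interval = GenomicInterval(chrom, site_start, site_start + L)
        return gene, interval, strand, motif

    def motif_alleles(motif: MotifModel, strand: str, offset: int):
        """Genomic (ref, alt) hitting the consensus base at ``offset``."""
        if strand == "+":
            column = offset + 1
        else:
            column = L - offset
        consensus = motif.consensus()[column - 1]
        genomic_ref = consensus if strand == "+" else COMPLEMENT[consensus]
        others = [b for b in BASES if b != genomic_ref]
        genomic_alt = others[int(rng.integers(0, 3))]
        return genomic_ref, genomic_alt

    def add_cohort1_records(samples, chrom, pos, ref, alt, *, somatic=True, snp=False):
        for s in samples:
            cohort1.append(
                SomaticMutation(
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    sample_id=s.sample_id,
                    individual_id=s.individual_id,
                    cancer_type=s.cancer_type,
                    tissue_site=s.tissue_site,
                    somatic_confirmed=somatic,
                    snp_flagged=snp,
                )
            )

    def add_cohort2_records(samples, chrom, pos, ref, alt):
        for s in samples:
            cohort2.append(
                SomaticMutation(
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    sample_id=s.sample_id,
                    individual_id=s.individual_id,
                    cancer_type=s.cancer_type,
                    tissue_site=s.tissue_site,
                )
            )

    def pick_regular(n: int, single_type: bool = False):
        base = int(rng.integers(0, config.n_samples_cohort1))
        step = len(types) if single_type else 1
        return [
            cohort1_samples[(base + k * step) % config.n_samples_cohort1]
            for k in range(n)
        ]

    locus_index = 0
    for k in range(config.n_planted_cnrms):
        slot = chosen[locus_index]
        locus_index += 1
        gene, interval, strand, motif = place_site(slot, "planted", exonic=False)
        site_id = f"site_p{k}"
        offset = L // 2
        pos = interval.start + offset + 1
        ref, alt = motif_alleles(motif, strand, offset)
        used_positions.add((interval.chrom, pos))
        blocks.append((interval.chrom, interval.start - 600, interval.end + 600))

        sites.append(
            TFBSInstance(site_id, interval, strand, motif.motif_id, config.jaspar_score)
        )
        peaks.append(
            GenomicInterval(
                interval.chrom, interval.start - 50, interval.end + 50, name=f"peak_{site_id}"
            )
        )
        tss0 = gene.tss - 1
        interactions.append(
            ChromatinInteraction(
                anchor_a=GenomicInterval(
                    interval.chrom, interval.start - 100, interval.end + 100
                ),
                anchor_b=GenomicInterval(gene.chrom, tss0 - 500, tss0 + 500),
                cell_type="HMEC",
                method="Hi-C",
            )
        )

        support1 = pick_regular(config.planted_support_cohort1)
        base2 = int(rng.integers(0, config.n_samples_cohort2))
        support2 = [
            cohort2_samples[(base2 + k2) % config.n_samples_cohort2]
            for k2 in range(config.planted_support_cohort2)
        ]
        add_cohort1_records(support1, interval.chrom, pos, ref, alt)
        add_cohort2_records(support2, interval.chrom, pos, ref, alt)

        truth.planted.append(
            {
                "chrom": interval.chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "site_id": site_id,
                "motif_id": motif.motif_id,
                "target_gene": gene.gene_id,
                "cohort1_samples": sorted(s.sample_id for s in support1),
                "cohort2_samples": sorted(s.sample_id for s in support2),
                "expected_delta_bit_sign": -1,
            }
        )
        if k < int(round(config.affected_fraction * config.n_planted_cnrms)):
            truth.effects.append(
                {
                    "site_id": site_id,
                    "gene_id": gene.gene_id,
                    "delta": config.effect_size,
                    "direction": config.effect_direction,
                    "mutated_samples": sorted(s.sample_id for s in support2),
                }
            )

    for name in decoy_names:
        slot = chosen[locus_index]
        locus_index += 1
        gene, interval, strand, motif = place_site(slot, name, exonic=(name == "exonic"))
        site_id = f"site_d_{name}"
        offset = L // 2
        pos = interval.start + offset + 1
        ref, alt = motif_alleles(motif, strand, offset)
        used_positions.add((interval.chrom, pos))
        blocks.append((interval.chrom, interval.start - 600, interval.end + 600))

        score = 399.0 if name == "sub_threshold_site_score" else config.jaspar_score
        sites.append(TFBSInstance(site_id, interval, strand, motif.motif_id, score))
        if name != "outside_peaks":
            peaks.append(
                GenomicInterval(
                    interval.chrom,
                    interval.start - 50,
                    interval.end + 50,
                    name=f"peak_{site_id}",
                )
            )
        if name != "outside_anchors":
            tss0 = gene.tss - 1
            interactions.append(
                ChromatinInteraction(
                    anchor_a=GenomicInterval(
                        interval.chrom, interval.start - 100, interval.end + 100
                    ),
                    anchor_b=GenomicInterval(gene.chrom, tss0 - 500, tss0 + 500),
                    cell_type="HMEC",
                    method="Hi-C",
                )
            )

        if name == "hematopoietic_tissue":
            support1 = hema_samples
        elif name == "same_individual_duplicate":
            support1 = dup_samples
        elif name == "single_sample":
            support1 = pick_regular(1)
        elif name == "single_cancer_type":
            support1 = pick_regular(2, single_type=True)
        else:
            support1 = pick_regular(config.planted_support_cohort1)

        add_cohort1_records(
            support1,
            interval.chrom,
            pos,
            ref,
            alt,
            somatic=(name != "unconfirmed_somatic"),
            snp=(name == "snp_flagged"),
        )
        if name != "absent_from_cohort2":
            base2 = int(rng.integers(0, config.n_samples_cohort2))
            support2 = [
                cohort2_samples[(base2 + k2) % config.n_samples_cohort2]
                for k2 in range(config.planted_support_cohort2)
            ]
            add_cohort2_records(support2, interval.chrom, pos, ref, alt)

        truth.decoys.append(
            {
                "name": name,
                "chrom": interval.chrom,
                "pos": pos,
                "site_id": site_id,
                "removed_at": DECOY_STAGES[name],
            }
        )

    # --- background regulatory elements -------------------------------
    background_sites = []
    site_regions: list = []
    for i in range(config.n_background_sites):
        interval = _draw_interval(config, rng, L, blocks, avoid=site_regions)
        site_regions.append((interval.chrom, interval.start, interval.end))
        strand = "+" if rng.random() < 0.5 else "-"
        motif = motifs[int(rng.integers(0, len(motifs)))]
        background_sites.append(
            TFBSInstance(
                f"site_bg{i:03d}", interval, strand, motif.motif_id, config.jaspar_score
            )
        )
    sites.extend(background_sites)
    motifs_by_id = {m.motif_id: m for m in motifs}

    for i in range(config.n_background_peaks):
        interval = _draw_interval(config, rng, config.peak_length, blocks)
        peaks.append(
            GenomicInterval(
                interval.chrom, interval.start, interval.end, name=f"peak_bg{i:03d}"
            )
        )
    cell_types = ["HMEC", "IMR90", "K562", "GM12878"]
    methods = ["Hi-C", "ChIA-PET", "IM-PET", "4C"]
    for _ in range(config.n_background_interactions):
        anchor_a = _draw_interval(config, rng, config.anchor_length, blocks)
        anchor_b = _draw_interval(config, rng, config.anchor_length, blocks)
        interactions.append(
            ChromatinInteraction(
                anchor_a,
                anchor_b,
                cell_types[int(rng.integers(0, len(cell_types)))],
                methods[int(rng.integers(0, len(methods)))],
            )
        )

    # --- background mutations -----------------------------------------
    all_cohort1_samples = cohort1_samples + dup_samples + hema_samples
    bg_counts = {
        s.sample_id: config.background_mutations_per_sample for s in cohort1_samples
    }
    for s in dup_samples:
        bg_counts[s.sample_id] = 5
    for s in hema_samples:
        bg_counts[s.sample_id] = 10
    n_bg1 = sum(bg_counts.values())
    positions1 = _draw_positions(config, rng, n_bg1, blocks, used_positions)
    idx = 0
    for s in all_cohort1_samples:
        for _ in range(bg_counts[s.sample_id]):
            chrom, pos = positions1[idx]
            idx += 1
            ref = BASES[int(rng.integers(0, 4))]
            alt = [b for b in BASES if b != ref][int(rng.integers(0, 3))]
            cohort1.append(
                SomaticMutation(
                    chrom, pos, ref, alt, s.sample_id, s.individual_id,
                    s.cancer_type, s.tissue_site,
                )
            )

    # cohort-1 mutations planted inside background TFBSs: these populate
    # the pool for the expected-Δbit null, with ref matching the motif
    for _ in range(config.n_tfbs_background_mutations):
        for _attempt in range(1000):
            site = background_sites[int(rng.integers(0, len(background_sites)))]
            offset = int(rng.integers(0, L))
            pos = site.interval.start + offset + 1
            if (site.interval.chrom, pos) in used_positions:
                continue
            used_positions.add((site.interval.chrom, pos))
            break
        else:  # pragma: no cover - generator capacity exhausted
            raise ConfigurationError("could not place TFBS background mutations")
        motif = motifs_by_id[site.motif_id]
        ref, alt = motif_alleles(motif, site.strand, offset)
        s = cohort1_samples[int(rng.integers(0, len(cohort1_samples)))]
        cohort1.append(
            SomaticMutation(
                site.interval.chrom, pos, ref, alt, s.sample_id, s.individual_id,
                s.cancer_type, s.tissue_site,
            )
        )

    n_bg2 = config.n_samples_cohort2 * config.background_mutations_per_sample
    positions2 = _draw_positions(config, rng, n_bg2, blocks, used_positions)
    idx = 0
    for s in cohort2_samples:
        for _ in range(config.background_mutations_per_sample):
            chrom, pos = positions2[idx]
            idx += 1
            ref = BASES[int(rng.integers(0, 4))]
            alt = [b for b in BASES if b != ref][int(rng.integers(0, 3))]
            cohort2.append(
                SomaticMutation(
                    chrom, pos, ref, alt, s.sample_id, s.individual_id,
                    s.cancer_type, s.tissue_site,
                )
            )

    # --- expression ----------------------------------------------------
    meta = pd.Series(
        {s.sample_id: s.cancer_type for s in cohort2_samples}, name="cancer_type"
    )
    expression = generate_expression(
        gene_ids=[g.gene_id for g in genes],
        cancer_type=meta,
        effects=[
            (e["gene_id"], set(e["mutated_samples"]), e["delta"], e["direction"])
            for e in truth.effects
        ],
        sigma=config.expression_sigma,
        rng=rng,
    )

    return CohortBundle(
        config=config,
        cohort1=cohort1,
        cohort2=cohort2,
        genes=genes,
        peaks=peaks,
        interactions=interactions,
        motifs=motifs,
        sites=sites,
        expression=expression,
        truth=truth,
    )


def generate_expression(
    gene_ids,
    cancer_type: pd.Series,
    effects,
    sigma: float = 0.5,
    rng: Optional[np.random.Generator] = None,
) -> ExpressionMatrix:
    """Generate a log-normal expression matrix with planted shifts.

    Baselines are drawn per gene with a per-cancer-type offset; noise is
    Gaussian on the log scale with standard deviation ``sigma``. For each
    effect ``(gene_id, mutated_samples, delta, direction)`` the mutated
    samples' log-values are shifted by ``direction * delta * sigma``,
    i.e. ``delta`` is expressed in within-type standard-deviation units.
    Downstream analysis is rank-based within cancer type, so results are
    invariant to the monotone location-scale choices made here.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    gene_ids = list(gene_ids)
    samples = list(cancer_type.index)
    types = sorted(set(cancer_type))
    type_of = cancer_type.to_dict()
    n_genes, n_samples = len(gene_ids), len(samples)

    base = rng.normal(3.0, 0.5, size=n_genes)
    offsets = rng.normal(0.0, 0.3, size=(n_genes, len(types)))
    type_index = {t: i for i, t in enumerate(types)}
    log_values = (
        base[:, None]
        + offsets[:, [type_index[type_of[s]] for s in samples]]
        + rng.normal(0.0, sigma, size=(n_genes, n_samples))
    )
    gene_row = {g: i for i, g in enumerate(gene_ids)}
    sample_col = {s: j for j, s in enumerate(samples)}
    for gene_id, mutated, delta, direction in effects:
        gi = gene_row[gene_id]
        for s in mutated:
            if s in sample_col:
                log_values[gi, sample_col[s]] += direction * delta * sigma
    values = pd.DataFrame(
        np.exp(log_values), index=pd.Index(gene_ids, name="gene_id"), columns=samples
    )
    return ExpressionMatrix(values=values, cancer_type=cancer_type)
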