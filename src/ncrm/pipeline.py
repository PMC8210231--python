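"""End-to-end orchestration of the ten-criterion screen and its reports.

The criteria are applied strictly in their canonical order so the funnel
counts are comparable run to run, even though the three containment
filters (open chromatin, interaction anchors, TFBS) commute as set
operations. Every stage logs its input/output counts into a
:class:`~ncrm.recurrence.FunnelReport`; all resampling is seeded and a
hash of the run parameters is recorded in every output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import io as gio
from .core import DataError, ExpressionMatrix
from .expression import (
    assign_target_genes,
    screen_tfbs_expression,
    zscore_by_cancer_type,
)
from .motif import average_delta_bit, expected_delta_bit_null, delta_bit, map_to_motif
from .recurrence import (
    FunnelReport,
    apply_source_filters,
    call_recurrent_positions,
    coding_fraction_test,
    intersect_positions,
    remove_exonic,
    require_multi_cancer_type,
)
from .regulatory import (
    overlap_interaction_anchors,
    overlap_intervals,
    overlap_tfbs,
    per_peak_mutation_rate,
    resample_open_chromatin_fraction,
)

logger = logging.getLogger(__name__)


@dataclass
class ScreenParams:
    """Thresholds and resampling settings for one screening run."""

    min_samples: int = 2
    min_cancer_types: int = 2
    jaspar_min_score: float = 400.0
    min_mutated: int = 5
    p_threshold: float = 0.1
    fdr_threshold: float = 0.25
    delta_convention: str = "letter_height"
    min_delta_mutations: int = 2
    run_nulls: bool = False
    resample_n_draw: int = 500
    resample_n_reps: int = 1000
    delta_n_draw: int = 25
    delta_n_reps: int = 500
    seed: int = 0
    genome_length: Optional[int] = None

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class PipelineResult:
    funnel: FunnelReport
    cnrms: list
    peak_annotations: dict
    interaction_matches: dict
    site_hits: dict
    sites_by_id: dict
    site_sample_map: dict
    delta_results: list
    targets: dict
    associations: list
    significant: list
    open_chromatin_null: Optional[object] = None
    delta_null: Optional[object] = None
    per_peak: Optional[object] = None
    coding: Optional[object] = None
    config_hash: str = ""

    @property
    def final_positions(self) -> set:
        return {(r.chrom, r.pos) for r in self.cnrms}


def run_screen(
    cohort1,
    cohort2,
    genes,
    peaks,
    interactions,
    sites,
    motifs,
    expression: Optional[ExpressionMatrix] = None,
    params: Optional[ScreenParams] = None,
) -> PipelineResult:
    """Run criteria 1-10 and the downstream motif/expression analyses."""
    params = params or ScreenParams()
    cohort1 = list(cohort1)
    cohort2 = list(cohort2)
    genes = list(genes)
    peaks = list(peaks)
    interactions = list(interactions)
    sites = list(sites)
    motifs = list(motifs)

    funnel = FunnelReport()
    filtered = apply_source_filters(cohort1, funnel=funnel)
    noncoding = remove_exonic(filtered, genes, funnel=funnel)

    recurrents = call_recurrent_positions(noncoding, min_samples=params.min_samples)
    funnel.add("recurrence", len(noncoding), len(recurrents), unit="positions")

    multi_type = require_multi_cancer_type(recurrents, min_types=params.min_cancer_types)
    funnel.add("multi_cancer_type", len(recurrents), len(multi_type), unit="positions")

    shared = intersect_positions(multi_type, cohort2)
    funnel.add("second_cohort", len(multi_type), len(shared), unit="positions")

    in_peaks, peak_annotations = overlap_intervals(shared, peaks, source_label="peak")
    funnel.add("open_chromatin", len(shared), len(in_peaks), unit="positions")

    in_anchors, interaction_matches = overlap_interaction_anchors(in_peaks, interactions)
    funnel.add("interaction", len(in_peaks), len(in_anchors), unit="positions")

    cnrms, site_hits, sites_by_id = overlap_tfbs(
        in_anchors, sites, min_score=params.jaspar_min_score
    )
    funnel.add("tfbs", len(in_anchors), len(cnrms), unit="positions")

    # ---- downstream: per-site mutation sets from the WGS-like cohort ----
    # every cohort-2 mutation in a surviving site counts, recurrent or not
    surviving_sites = [sites_by_id[sid] for sid in sorted(site_hits)]
    site_sample_map: dict = {s.site_id: set() for s in surviving_sites}
    site_records: dict = {s.site_id: {} for s in surviving_sites}
    for site in surviving_sites:
        for m in cohort2:
            if site.interval.contains_pos(m.chrom, m.pos):
                site_sample_map[site.site_id].add(m.sample_id)
                site_records[site.site_id][(m.sample_id, m.pos, m.ref, m.alt)] = m

    motifs_by_id = {m.motif_id: m for m in motifs}
    delta_results = []
    for site in surviving_sites:
        records = [site_records[site.site_id][k] for k in sorted(site_records[site.site_id])]
        if len(records) < params.min_delta_mutations:
            continue
        motif = motifs_by_id.get(site.motif_id)
        if motif is None:
            logger.warning("site %s references unknown motif %s", site.site_id, site.motif_id)
            continue
        delta_results.append(
            average_delta_bit(site, records, motif, convention=params.delta_convention)
        )

    targets = {
        site.site_id: assign_target_genes(site, interactions, genes)
        for site in surviving_sites
    }

    associations: list = []
    significant: list = []
    if expression is not None and surviving_sites:
        z = zscore_by_cancer_type(expression)
        associations = screen_tfbs_expression(
            site_sample_map,
            z,
            targets,
            min_mutated=params.min_mutated,
            fdr_threshold=params.fdr_threshold,
        )
        significant = [a for a in associations if a.fdr < params.fdr_threshold]

    result = PipelineResult(
        funnel=funnel,
        cnrms=cnrms,
        peak_annotations=peak_annotations,
        interaction_matches=interaction_matches,
        site_hits=site_hits,
        sites_by_id=sites_by_id,
        site_sample_map={k: sorted(v) for k, v in site_sample_map.items()},
        delta_results=delta_results,
        targets=targets,
        associations=associations,
        significant=significant,
        config_hash=params.config_hash(),
    )

    if params.run_nulls:
        _attach_nulls(result, cohort2, noncoding, shared, peaks, sites, motifs_by_id, genes, params)
    return result


def _attach_nulls(result, cohort2, noncoding_cohort1, shared_positions, peaks, sites, motifs_by_id, genes, params):
    # observed set for the open-chromatin enrichment: the recurrent
    # positions present in the second cohort (before the peak filter)
    n_draw = min(params.resample_n_draw, len(cohort2))
    if n_draw < params.resample_n_draw:
        logger.info("clamped open-chromatin resample draw to background size %d", n_draw)
    if shared_positions and cohort2:
        result.open_chromatin_null = resample_open_chromatin_fraction(
            cohort2,
            peaks,
            n_draw=n_draw,
            n_reps=params.resample_n_reps,
            observed_set=shared_positions,
            seed=params.seed,
        )
    else:
        logger.info("open-chromatin null skipped: empty observed set or background")
    n_samples = len({m.sample_id for m in cohort2})
    result.per_peak = per_peak_mutation_rate(
        cohort2, peaks, n_samples=n_samples, recurrent_positions=shared_positions
    )
    # expected-Δbit null: pool = filtered non-coding cohort-1 mutations in any TFBS
    eligible_sites = [s for s in sites if s.match_score >= params.jaspar_min_score]
    pool = []
    for site in eligible_sites:
        motif = motifs_by_id.get(site.motif_id)
        if motif is None:
            continue
        for m in noncoding_cohort1:
            if site.interval.contains_pos(m.chrom, m.pos):
                column, mref, malt = map_to_motif(site, motif, m.pos, m.ref, m.alt)
                pool.append(
                    delta_bit(motif, column, mref, malt, params.delta_convention)
                )
    if len(pool) >= params.delta_n_draw:
        result.delta_null = expected_delta_bit_null(
            pool,
            n_draw=params.delta_n_draw,
            n_reps=params.delta_n_reps,
            seed=params.seed,
        )
    else:
        logger.info("Δbit pool of %d below draw size; null skipped", len(pool))
    if params.genome_length:
        result.coding = coding_fraction_test(cohort2, genes, params.genome_length)


def run_bundle(bundle, params: Optional[ScreenParams] = None) -> PipelineResult:
    """Run the full screen on a synthetic cohort bundle."""
    return run_screen(
        bundle.cohort1,
        bundle.cohort2,
        bundle.genes,
        bundle.peaks,
        bundle.interactions,
        bundle.sites,
        bundle.motifs,
        expression=bundle.expression,
        params=params,
    )


def report_funnel(funnel: FunnelReport, out_base, formats=("tsv", "json")) -> list:
    """Render the funnel as TSV and/or JSON with retention percentages."""
    out_base = Path(out_base)
    written = []
    records = funnel.to_records()
    if "tsv" in formats:
        path = out_base.with_suffix(".tsv")
        pd.DataFrame(
            records, columns=["step", "n_in", "n_out", "unit", "retention_percent"]
        ).to_csv(path, sep="\t", index=False)
        written.append(path)
    if "json" in formats:
        path = out_base.with_suffix(".json")
        with open(path, "w") as handle:
            json.dump({"steps": records}, handle, indent=2)
            handle.write("\n")
        written.append(path)
    return written


def write_outputs(result: PipelineResult, out_dir) -> Path:
    """Write all report files for a completed run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report_funnel(result.funnel, out_dir / "funnel")

    pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "pos": r.pos,
                "recurrence": r.recurrence,
                "n_cancer_types": len(r.cancer_types),
                "consistency": r.consistency,
                "six_class": r.six_class or "",
                "samples": ",".join(sorted(r.supporting_samples)),
                "cohort2_samples": ",".join(sorted(r.cohort2_samples or ())),
            }
            for r in result.cnrms
        ],
        columns=[
            "chrom",
            "pos",
            "recurrence",
            "n_cancer_types",
            "consistency",
            "six_class",
            "samples",
            "cohort2_samples",
        ],
    ).to_csv(out_dir / "cnrms.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "site_id": d.site_id,
                "motif_id": d.motif_id,
                "n_mutations": d.n_mutations,
                "average_delta_bit": d.average_delta_bit,
            }
            for d in result.delta_results
        ],
        columns=["site_id", "motif_id", "n_mutations", "average_delta_bit"],
    ).to_csv(out_dir / "delta_bits.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "site_id": a.site_id,
                "gene_id": a.gene_id,
                "n_mutated": a.n_mutated,
                "n_wt": a.n_wt,
                "statistic": a.statistic,
                "p_value": a.p_value,
                "fdr": a.fdr,
                "direction": a.direction,
            }
            for a in result.associations
        ],
        columns=[
            "site_id",
            "gene_id",
            "n_mutated",
            "n_wt",
            "statistic",
            "p_value",
            "fdr",
            "direction",
        ],
    ).to_csv(out_dir / "associations.tsv", sep="\t", index=False)

    summary: dict = {
        "config_hash": result.config_hash,
        "final_cnrm_count": len(result.cnrms),
        "n_sites": len(result.site_hits),
        "n_associations_tested": len(result.associations),
        "n_significant": len(result.significant),
    }
    if result.open_chromatin_null is not None:
        summary["open_chromatin_null"] = result.open_chromatin_null.to_dict()
    if result.delta_null is not None:
        summary["delta_null"] = result.delta_null.to_dict()
    if result.per_peak is not None and result.per_peak.p_value is not None:
        summary["per_peak"] = {
            "mean_rate_with_recurrent": result.per_peak.mean_with,
            "mean_rate_without_recurrent": result.per_peak.mean_without,
            "p_value": result.per_peak.p_value,
        }
    if result.coding is not None:
        summary["coding_fraction"] = {
            "observed": result.coding.observed_fraction,
            "expected": result.coding.expected_fraction,
            "p_value": result.coding.p_value,
        }
    with open(out_dir / "summary.json", "w") as handle:
        json.dump(summary, handle, indent=2)
        handle.write("\n")
    return out_dir


@dataclass
class RunConfig:
    """File-level configuration for a CLI run."""

    data_dir: str
    out_dir: str
    params: ScreenParams = field(default_factory=ScreenParams)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        params = ScreenParams(**raw.get("params", {}))
        try:
            return cls(data_dir=raw["data_dir"], out_dir=raw["out_dir"], params=params)
        except KeyError as exc:
            raise DataError(f"run config missing key {exc}") from exc


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Load a bundle directory, run the screen, and write all reports."""
    from .simulate import BUNDLE_FILES

    data = Path(config.data_dir)
    expression = None
    expr_path = data / BUNDLE_FILES["expression"]
    meta_path = data / BUNDLE_FILES["metadata"]
    if expr_path.exists() and meta_path.exists():
        expression = gio.read_expression(expr_path, meta_path)
    result = run_screen(
        cohort1=gio.read_mutation_table(data / BUNDLE_FILES["cohort1"]),
        cohort2=gio.read_mutation_table(data / BUNDLE_FILES["cohort2"]),
        genes=gio.read_gtf_genes(data / BUNDLE_FILES["genes"]),
        peaks=gio.read_bed(data / BUNDLE_FILES["peaks"]),
        interactions=gio.read_interactions(data / BUNDLE_FILES["interactions"]),
        sites=gio.read_tfbs_table(data / BUNDLE_FILES["sites"]),
        motifs=gio.read_jaspar_pfm(data / BUNDLE_FILES["motifs"]),
        expression=expression,
        params=config.params,
    )
    write_outputs(result, config.out_dir)
    return result
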