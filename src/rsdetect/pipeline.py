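"""End-to-end orchestration of the RS, AGNN, and cryptic-exon pipelines.

These functions wire the modules together exactly as the command-line
interface exposes them: load genome + annotation, scan acceptor motifs,
restrict to long introns, extract and count junction reads against an
mRNA control, apply the filter cascade, and classify survivors from
coverage evidence.  Attrition counts at every stage are recorded so a
run can be audited filter by filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pysam

from rsdetect.config import PipelineThresholds
from rsdetect.gene_models import GeneModel, SampleDepth, load_gene_models
from rsdetect.intermediates import CrypticExonCall, call_cryptic_exons
from rsdetect.junctions import (JunctionRecord, SiteJunctionCounts,
                                combine_counts, count_down_junctions,
                                count_up_junctions, extract_junctions)
from rsdetect.motif_scan import (MotifSite, exclude_gt_core,
                                 filter_intronic_sites, scan_motif_sites)
from rsdetect.rs_caller import RSCall, call_candidates, classify_candidate
from rsdetect.sawtooth import DepthTrack, SawtoothEvidence, site_evidence
from rsdetect.sequtil import GenomeLike, load_genome


def count_mapped_reads(path) -> int:
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        return sum(1 for seg in fh if not seg.is_unmapped)


@dataclass
class PipelineInputs:
    genome: dict[str, str]
    gene_models: dict[str, GeneModel]
    junctions_by_sample: dict[str, list[JunctionRecord]]
    depths: dict[str, SampleDepth]
    depth_track: DepthTrack
    total_samples: list[str]


def load_inputs(genome_source: GenomeLike, annotation_source,
                total_sams: Mapping[str, Path],
                mrna_sams: Mapping[str, Path]) -> PipelineInputs:
    """Load genome/annotation and extract junctions + depth per sample."""
    if not mrna_sams:
        raise ValueError("at least one mRNA control sample is required")
    if not total_sams:
        raise ValueError("at least one total-RNA sample is required")
    genome = load_genome(genome_source)
    models = load_gene_models(annotation_source, genome)
    references = {c: len(s) for c, s in genome.items()}
    track = DepthTrack(references)
    junctions: dict[str, list[JunctionRecord]] = {}
    depths: dict[str, SampleDepth] = {}
    for role, sams in (("total_rna", total_sams), ("mrna_control", mrna_sams)):
        for sample, path in sams.items():
            junctions[sample] = extract_junctions(str(path))
            depths[sample] = SampleDepth(sample, count_mapped_reads(path), role)
            if role == "total_rna":
                track.add_alignments(str(path))
    return PipelineInputs(genome=genome, gene_models=models,
                          junctions_by_sample=junctions, depths=depths,
                          depth_track=track,
                          total_samples=list(total_sams))


@dataclass
class RSPipelineResult:
    sites: list[MotifSite]
    filtered_sites: list[MotifSite]
    site_counts: dict[str, SiteJunctionCounts]
    candidates: list[RSCall]
    calls: list[RSCall]
    evidence: dict[str, SawtoothEvidence]
    attrition: dict[str, int] = field(default_factory=dict)

    @property
    def rs_calls(self) -> list[RSCall]:
        return [c for c in self.calls if c.classification == "RS"]


def run_rs_pipeline(inputs: PipelineInputs,
                    thresholds: PipelineThresholds = PipelineThresholds(),
                    pattern: str | None = None,
                    exclude_gt: bool = False) -> RSPipelineResult:
    """The RS-site pipeline (or the AGNN variant with ``exclude_gt``)."""
    pattern = pattern or thresholds.motif
    sites = scan_motif_sites(inputs.genome, inputs.gene_models, pattern)
    if exclude_gt:
        sites = exclude_gt_core(sites)
    filtered = filter_intronic_sites(sites, thresholds.min_intron)

    total_junc = {s: inputs.junctions_by_sample[s] for s in inputs.total_samples}
    up = count_up_junctions(inputs.junctions_by_sample, filtered,
                            inputs.gene_models, inputs.depths,
                            thresholds.strandedness)
    down = count_down_junctions(total_junc, filtered, inputs.gene_models,
                                inputs.depths, thresholds.window,
                                thresholds.strandedness)
    combined = combine_counts(up, down)
    candidates = call_candidates(combined, inputs.depths, thresholds)

    evidence: dict[str, SawtoothEvidence] = {}
    calls = []
    for cand in candidates:
        sid = cand.site.site_id
        ev = site_evidence(inputs.depth_track, cand.site,
                           inputs.gene_models[cand.site.gene_id], thresholds,
                           down_donor_pos=combined[sid].down_donor_pos)
        evidence[sid] = ev
        calls.append(classify_candidate(cand, ev, thresholds))

    by_class: dict[str, int] = {}
    for call in calls:
        by_class[call.classification] = by_class.get(call.classification, 0) + 1
    attrition = {
        "sites_scanned": len(sites),
        "sites_in_long_introns": len(filtered),
        "candidates": len(candidates),
        **{f"classified_{k}": v for k, v in sorted(by_class.items())},
    }
    return RSPipelineResult(sites=sites, filtered_sites=filtered,
                            site_counts=combined, candidates=candidates,
                            calls=calls, evidence=evidence,
                            attrition=attrition)


@dataclass
class CrypticPipelineResult:
    filtered_sites: list[MotifSite]
    site_counts: dict[str, SiteJunctionCounts]
    pre_candidates: list[CrypticExonCall]
    calls: list[CrypticExonCall]
    evidence: dict[str, SawtoothEvidence]
    attrition: dict[str, int] = field(default_factory=dict)


def run_cryptic_pipeline(inputs: PipelineInputs,
                         thresholds: PipelineThresholds = PipelineThresholds(),
                         ) -> CrypticPipelineResult:
    """The RS-like cryptic exon pipeline (>= 50 kb introns, >1-fold)."""
    sites = scan_motif_sites(inputs.genome, inputs.gene_models, thresholds.motif)
    filtered = filter_intronic_sites(sites, thresholds.cryptic_min_intron)

    total_junc = {s: inputs.junctions_by_sample[s] for s in inputs.total_samples}
    up = count_up_junctions(inputs.junctions_by_sample, filtered,
                            inputs.gene_models, inputs.depths,
                            thresholds.strandedness)
    down = count_down_junctions(total_junc, filtered, inputs.gene_models,
                                inputs.depths, thresholds.window,
                                thresholds.strandedness)
    combined = combine_counts(up, down)

    pre = call_cryptic_exons(combined, inputs.depths, thresholds, evidence=None)
    evidence: dict[str, SawtoothEvidence] = {}
    pre_counts = {}
    for cand in pre:
        sid = cand.site.site_id
        pre_counts[sid] = combined[sid]
        evidence[sid] = site_evidence(
            inputs.depth_track, cand.site,
            inputs.gene_models[cand.site.gene_id], thresholds,
            down_donor_pos=combined[sid].down_donor_pos)
    calls = call_cryptic_exons(pre_counts, inputs.depths, thresholds,
                               evidence=evidence)
    attrition = {
        "sites_scanned": len(sites),
        "sites_in_long_introns": len(filtered),
        "pre_pattern_candidates": len(pre),
        "cryptic_exons": len(calls),
    }
    return CrypticPipelineResult(filtered_sites=filtered, site_counts=combined,
                                 pre_candidates=pre, calls=calls,
                                 evidence=evidence, attrition=attrition)
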