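"""The RS-candidate filter cascade and candidate classification.

Candidates are intronic acceptor-motif sites passing, in order:
host intron length >= 1 kb, pooled total-RNA RPM more than two-fold the
pooled mRNA-control RPM (the mRNA control removes annotated/unannotated
exon junctions), and a replicate-merged up-junction count of at least
10.  Candidates are then classified from coverage evidence as RS
(saw-tooth step at the site), unannotated exon (coverage island),
nascent transcript (covered intron, neither pattern) or unknown.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from rsdetect.config import PipelineThresholds
from rsdetect.gene_models import SampleDepth
from rsdetect.junctions import SiteJunctionCounts
from rsdetect.motif_scan import MotifSite
from rsdetect.sawtooth import SawtoothEvidence

CLASSIFICATIONS = ("RS", "unannotated_exon", "nascent_transcript",
                   "unknown", "cryptic_exon", "fail")


@dataclass
class RSCall:
    site: MotifSite
    merged_up_count: int
    total_rpm: float
    mrna_rpm: float
    fold_enrichment: float          # may be +inf (zero mRNA reads)
    fold_display: float             # finite, 0.5-read mRNA pseudocount
    sawtooth_score: float = math.nan
    exon_score: float = math.nan
    classification: str = "unknown"
    filter_trace: list[tuple[str, bool]] = field(default_factory=list)
    evidence: SawtoothEvidence | None = None

    @property
    def passed_filters(self) -> bool:
        return all(ok for _, ok in self.filter_trace)


def merge_replicates(per_sample_counts: Mapping[str, int],
                     depths: Mapping[str, SampleDepth],
                     ) -> tuple[int, float]:
    """Merged raw count and pooled RPM across biological replicates.

    Pooled RPM = sum(counts) / sum(depths) x 1e6, i.e. replicates are
    merged at the read level before normalization.
    """
    if not per_sample_counts:
        raise ValueError("no replicates to merge")
    merged = sum(per_sample_counts.values())
    total_depth = sum(depths[s].uniquely_mapped_reads for s in per_sample_counts)
    return merged, merged / total_depth * 1e6


def _split_roles(depths: Mapping[str, SampleDepth]):
    total = {s: d for s, d in depths.items() if d.role == "total_rna"}
    mrna = {s: d for s, d in depths.items() if d.role == "mrna_control"}
    return total, mrna


def call_candidates(site_counts: Mapping[str, SiteJunctionCounts],
                    depths: Mapping[str, SampleDepth],
                    thresholds: PipelineThresholds = PipelineThresholds(),
                    include_failed: bool = False) -> list[RSCall]:
    """Apply the filter cascade; returns pre-classification candidates.

    Filter order (recorded in ``filter_trace``): intron length, mRNA
    enrichment, junction count.  With ``include_failed`` every site is
    returned with its trace and classification "fail" where any filter
    failed.
    """
    total_depths, mrna_depths = _split_roles(depths)
    if not mrna_depths:
        raise ValueError("no mRNA control sample: enrichment filter undefined")
    if not total_depths:
        raise ValueError("no total-RNA sample provided")

    calls = []
    for counts in site_counts.values():
        site = counts.site
        total_counts = {s: counts.up_count.get(s, 0) for s in total_depths}
        mrna_counts = {s: counts.up_count.get(s, 0) for s in mrna_depths}
        merged, total_rpm = merge_replicates(total_counts, total_depths)
        mrna_merged, mrna_rpm = merge_replicates(mrna_counts, mrna_depths)

        ok_intron = (site.intron_ordinal is not None
                     and site.intron_length >= thresholds.min_intron)
        ok_enrich = total_rpm > thresholds.min_fold * mrna_rpm
        ok_count = merged >= thresholds.min_count
        trace = [("intron_length", ok_intron),
                 ("mrna_enrichment", ok_enrich),
                 ("junction_count", ok_count)]

        fold = math.inf if mrna_rpm == 0 else total_rpm / mrna_rpm
        mrna_depth_sum = sum(d.uniquely_mapped_reads for d in mrna_depths.values())
        pseudo_rpm = (mrna_merged + 0.5) / mrna_depth_sum * 1e6
        call = RSCall(site=site, merged_up_count=merged, total_rpm=total_rpm,
                      mrna_rpm=mrna_rpm, fold_enrichment=fold,
                      fold_display=total_rpm / pseudo_rpm,
                      filter_trace=trace,
                      classification="unknown" if all(
                          ok for _, ok in trace) else "fail")
        if call.passed_filters or include_failed:
            calls.append(call)
    return calls


def classify_candidate(call: RSCall, evidence: SawtoothEvidence,
                       thresholds: PipelineThresholds = PipelineThresholds(),
                       ) -> RSCall:
    """Classify a candidate from its coverage evidence.

    RS if the saw-tooth score reaches tau_saw; unannotated exon if the
    exon-likeness score reaches tau_exon without a saw-tooth; nascent
    transcript if neither pattern but the intron carries background
    coverage; otherwise unknown.
    """
    if evidence is None:
        raise ValueError("missing coverage evidence")
    saw = evidence.sawtooth.score
    is_rs = saw >= thresholds.tau_saw
    if is_rs:
        cls = "RS"
    elif evidence.exon_score >= thresholds.tau_exon:
        cls = "unannotated_exon"
    elif evidence.background_mean >= thresholds.tau_bg:
        cls = "nascent_transcript"
    else:
        cls = "unknown"
    return dataclasses.replace(
        call, sawtooth_score=saw, exon_score=evidence.exon_score,
        classification=cls, evidence=evidence,
        filter_trace=call.filter_trace + [("sawtooth_pattern", is_rs)])


def compare_site_sets(calls_a: Iterable, calls_b: Iterable,
                      ) -> dict[str, set[tuple[str, int, str]]]:
    """Partition two call sets into shared / only_a / only_b.

    Accepts RSCall or MotifSite objects; sites are keyed by
    (chrom, a_pos, strand).
    """
    def keys(calls):
        out = set()
        for c in calls:
            site = c.site if hasattr(c, "site") else c
            out.add(site.key)
        return out

    a, b = keys(calls_a), keys(calls_b)
    return {"shared": a & b, "only_a": a - b, "only_b": b - a}
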