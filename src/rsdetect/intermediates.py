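"""Splicing-intermediate characterization and RS-like cryptic exon calling.

After the first recursive step, the upstream exon is fused directly to
the GT of the intronic AGGT, creating a reconstituted 5' splice site
(r5'SS).  The putative RS exon ends at a downstream donor (Down 5'SS),
observed directly from down-junction reads when present.  This module
assembles both sequence flavours used for logos (30 exon nt + GT +
20 nt) and for 9-mer donor scoring (3 nt + GT + 4 nt), calls RS-like
cryptic exons (sites with both upstream and downstream intermediates
and an exon-like, non-saw-tooth coverage profile in a >= 50 kb intron),
and computes the up/down junction-count correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from scipy import stats

from rsdetect.config import PipelineThresholds
from rsdetect.gene_models import GeneModel, SampleDepth
from rsdetect.junctions import SiteJunctionCounts
from rsdetect.motif_scan import MotifSite
from rsdetect.rs_caller import merge_replicates, _split_roles
from rsdetect.sawtooth import SawtoothEvidence
from rsdetect.sequtil import GenomeLike, load_genome, sense_offset, sense_sequence
from rsdetect.splice_scoring import SpliceSiteModel, score_donor

LOGO_EXON = 30   # exonic nt in the logo flavour
LOGO_DOWN = 20   # nt after the 4-mer in the logo flavour
NINE_EXON = 3
NINE_DOWN = 4


@dataclass(frozen=True)
class SpliceSiteSequences:
    """r5'SS and Down 5'SS sequences for one site, both flavours."""

    site_id: str
    r5ss_logo: str                # 52-mer: 30 + GT + 20
    r5ss_maxent: str              # 9-mer: 3 + GT + 4
    down5ss_logo: str | None
    down5ss_maxent: str | None
    down_donor_source: str        # observed_junction | best_window_donor | none
    down_donor_pos: int | None = None


@dataclass
class CrypticExonCall:
    site: MotifSite
    merged_up_count: int
    merged_down_count: int
    total_rpm: float
    mrna_rpm: float
    exon_start: int               # acceptor_pos (first exon base, ref coord)
    exon_end_donor: int | None    # modal donor base, ref coord
    sawtooth_score: float = math.nan
    exon_score: float = math.nan
    classification: str = "cryptic_exon"
    filter_trace: list[tuple[str, bool]] = field(default_factory=list)

    @property
    def passed_filters(self) -> bool:
        return all(ok for _, ok in self.filter_trace)


def _gene_sense(genome: Mapping[str, str], gene: GeneModel) -> str:
    return sense_sequence(genome, gene.chrom, gene.start, gene.end, gene.strand)


def _sense_exons(gene: GeneModel) -> list[tuple[int, int]]:
    out = []
    for s, e in gene.exons:
        if gene.strand == "-":
            out.append((gene.end - e, gene.end - s))
        else:
            out.append((s - gene.start, e - gene.start))
    return sorted(out)


def _pad_slice(seq: str, start: int, end: int) -> str:
    """Slice padded with N beyond the sequence bounds."""
    left = "N" * max(0, -start)
    right = "N" * max(0, end - len(seq))
    return left + seq[max(0, start):min(len(seq), end)] + right


def build_splice_site_sequences(site: MotifSite,
                                gene_models: Mapping[str, GeneModel],
                                genome_source: GenomeLike,
                                down_donor_pos: int | None = None,
                                donor_model: SpliceSiteModel | None = None,
                                window: int = 350) -> SpliceSiteSequences:
    """Assemble r5'SS and Down 5'SS sequences for one motif site.

    The r5'SS fuses the 3' end of the nearest upstream collapsed exon to
    the GT of the site's 4-mer.  The Down 5'SS is built at the observed
    down-junction donor when provided, otherwise at the best-scoring GT
    donor in the ``window`` nt downstream (scored with ``donor_model``
    when given, else the first GT); the provenance is flagged.
    Upstream exons shorter than the logo width are left-padded with N.
    """
    gene = gene_models[site.gene_id]
    genome = load_genome(genome_source)
    seq = _gene_sense(genome, gene)
    a_off = sense_offset(site.a_pos, gene.start, gene.end, gene.strand)

    exon_ends = [e for s, e in _sense_exons(gene) if e <= a_off]
    if not exon_ends:
        raise ValueError(f"site {site.site_id} has no upstream exon")
    e1 = max(exon_ends)
    exon_start = max(s for s, e in _sense_exons(gene) if e == e1)
    exon_avail = e1 - exon_start

    def exon_tail(n: int) -> str:
        tail = seq[e1 - min(n, exon_avail):e1]
        return "N" * (n - len(tail)) + tail

    gt = seq[a_off + 2:a_off + 4]
    r5ss_logo = exon_tail(LOGO_EXON) + gt + _pad_slice(
        seq, a_off + 4, a_off + 4 + LOGO_DOWN)
    r5ss_maxent = exon_tail(NINE_EXON) + gt + seq[a_off + 4:a_off + 4 + NINE_DOWN]

    acc = a_off + 2
    donor_off = None
    source = "none"
    if down_donor_pos is not None:
        donor_off = sense_offset(down_donor_pos, gene.start, gene.end,
                                 gene.strand)
        source = "observed_junction"
    else:
        best = None
        for p in range(acc + 1, min(acc + window, len(seq) - 2) + 1):
            if seq[p + 1:p + 3] != "GT":
                continue
            nine = seq[p - 2:p + 7]
            if len(nine) != 9 or set(nine) - set("ACGT"):
                continue
            if donor_model is None:
                best = p
                break
            s = score_donor(donor_model, nine)
            if best is None or s > best[0]:
                best = (s, p)
        if best is not None:
            donor_off = best if isinstance(best, int) else best[1]
            source = "best_window_donor"

    down_logo = down_nine = None
    ref_donor = None
    if donor_off is not None:
        down_logo = _pad_slice(seq, donor_off - LOGO_EXON + 1,
                               donor_off + 1 + 2 + LOGO_DOWN)
        down_nine = _pad_slice(seq, donor_off - 2, donor_off + 7)
        if gene.strand == "-":
            ref_donor = gene.end - 1 - donor_off
        else:
            ref_donor = gene.start + donor_off
    return SpliceSiteSequences(
        site_id=site.site_id, r5ss_logo=r5ss_logo, r5ss_maxent=r5ss_maxent,
        down5ss_logo=down_logo, down5ss_maxent=down_nine,
        down_donor_source=source, down_donor_pos=ref_donor)


def call_cryptic_exons(site_counts: Mapping[str, SiteJunctionCounts],
                       depths: Mapping[str, SampleDepth],
                       thresholds: PipelineThresholds = PipelineThresholds(),
                       evidence: Mapping[str, SawtoothEvidence] | None = None,
                       include_failed: bool = False,
                       ) -> list[CrypticExonCall]:
    """Call RS-like cryptic exons.

    Filters, in order: host intron >= 50 kb, total-RNA pooled RPM larger
    than the mRNA pooled RPM (>1-fold, not >2-fold), merged up-junction
    count >= 10, merged down-junction count >= 2, then an exon-like but
    not saw-tooth-like coverage pattern.
    """
    total_depths, mrna_depths = _split_roles(depths)
    if not mrna_depths:
        raise ValueError("no mRNA control sample: enrichment filter undefined")
    if not total_depths:
        raise ValueError("no total-RNA sample provided")

    calls = []
    for site_id, counts in site_counts.items():
        site = counts.site
        up_total = {s: counts.up_count.get(s, 0) for s in total_depths}
        up_mrna = {s: counts.up_count.get(s, 0) for s in mrna_depths}
        down_total = {s: counts.down_count.get(s, 0) for s in total_depths}
        merged_up, total_rpm = merge_replicates(up_total, total_depths)
        _, mrna_rpm = merge_replicates(up_mrna, mrna_depths)
        merged_down = sum(down_total.values())

        trace = [
            ("intron_length", site.intron_ordinal is not None
             and site.intron_length >= thresholds.cryptic_min_intron),
            ("mrna_enrichment",
             total_rpm > thresholds.cryptic_min_fold * mrna_rpm),
            ("up_count", merged_up >= thresholds.cryptic_min_up),
            ("down_count", merged_down >= thresholds.cryptic_min_down),
        ]
        call = CrypticExonCall(
            site=site, merged_up_count=merged_up,
            merged_down_count=merged_down, total_rpm=total_rpm,
            mrna_rpm=mrna_rpm, exon_start=site.acceptor_pos,
            exon_end_donor=counts.down_donor_pos, filter_trace=trace)
        if all(ok for _, ok in trace) and evidence is not None:
            ev = evidence.get(site_id)
            if ev is None:
                raise ValueError(f"missing coverage evidence for {site_id}")
            call.sawtooth_score = ev.sawtooth.score
            call.exon_score = ev.exon_score
            pattern_ok = (ev.exon_score >= thresholds.tau_exon
                          and ev.sawtooth.score < thresholds.tau_saw)
            call.filter_trace.append(("exon_like_pattern", pattern_ok))
        call.classification = ("cryptic_exon" if call.passed_filters else "fail")
        if call.passed_filters or include_failed:
            calls.append(call)
    return calls


def up_down_correlation(calls_or_pairs) -> tuple[float, float]:
    """Pearson correlation of up- vs down-junction read counts."""
    pairs = []
    for item in calls_or_pairs:
        if hasattr(item, "merged_up_count"):
            pairs.append((item.merged_up_count, item.merged_down_count))
        else:
            pairs.append(tuple(item))
    if len(pairs) < 3:
        raise ValueError("need at least 3 observations for a correlation")
    ups = [p[0] for p in pairs]
    downs = [p[1] for p in pairs]
    if len(set(ups)) == 1 or len(set(downs)) == 1:
        raise ValueError("zero variance in junction counts")
    r, p = stats.pearsonr(ups, downs)
    return float(r), float(p)
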