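"""Intron coverage profiles and the saw-tooth / exon-likeness statistics.

Under nascent transcription, intron coverage declines toward each splice
point (older positions have had more time to be spliced out) and jumps
back up immediately after a recursive splice site, because the next
segment persists until its own splicing — the classic saw-tooth.  The
saw-tooth score quantifies the step at a candidate site:

    score = log2((mean depth over W nt sense-downstream + eps)
                 / (mean depth over W nt sense-upstream + eps))

with both flanks additionally required to show a declining rank trend
(Spearman) for the ``trend_ok`` flag.  Exon-likeness instead contrasts
the putative exon interval with its two flanking windows, capturing the
coverage island of an unannotated or cryptic exon.  These statistics
automate what was historically a visual inspection of browser tracks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pysam
from scipy import stats

from rsdetect.config import PipelineThresholds, Strandedness
from rsdetect.gene_models import GeneModel, Intron
from rsdetect.motif_scan import MotifSite
from rsdetect.sequtil import sense_offset


@dataclass
class CoverageProfile:
    """Binned mean per-base depth across an intron, sense-oriented.

    ``values[0]`` is the bin at the intron's 5' end in transcription
    direction.
    """

    chrom: str
    start: int
    end: int
    strand: str
    bin_size: int
    values: np.ndarray

    @property
    def nbins(self) -> int:
        return len(self.values)


class DepthTrack:
    """Per-base depth arrays per (chromosome, read strand)."""

    def __init__(self, references: Mapping[str, int]):
        self.references = dict(references)
        self.arrays: dict[tuple[str, str], np.ndarray] = {}

    def _array(self, chrom: str, strand: str) -> np.ndarray:
        key = (chrom, strand)
        if key not in self.arrays:
            self.arrays[key] = np.zeros(self.references[chrom], dtype=np.float64)
        return self.arrays[key]

    def add_alignments(self, alignments) -> int:
        if isinstance(alignments, (str, Path)):
            alignments = pysam.AlignmentFile(str(alignments), check_sq=False)
        n = 0
        for seg in alignments:
            if seg.is_unmapped:
                continue
            n += 1
            arr = self._array(seg.reference_name,
                              "-" if seg.is_reverse else "+")
            for s, e in seg.get_blocks():
                arr[s:e] += 1.0
        return n

    def slice(self, chrom: str, start: int, end: int,
              gene_strand: str, strandedness: Strandedness) -> np.ndarray:
        if chrom not in self.references:
            raise ValueError(f"unknown reference {chrom!r}")
        if start < 0 or end > self.references[chrom]:
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside reference bounds")
        if strandedness == "unstranded":
            strands = "+-"
        elif strandedness == "forward":
            strands = gene_strand
        else:
            strands = "-" if gene_strand == "+" else "+"
        total = np.zeros(end - start)
        for st in strands:
            arr = self.arrays.get((chrom, st))
            if arr is not None:
                total += arr[start:end]
        return total


def build_depth(alignments, references: Mapping[str, int]) -> DepthTrack:
    """Accumulate a :class:`DepthTrack` from SAM/BAM alignments."""
    track = DepthTrack(references)
    track.add_alignments(alignments)
    return track


def _bin_means(values: np.ndarray, bin_size: int) -> np.ndarray:
    if bin_size == 1:
        return values.copy()
    nbins = math.ceil(len(values) / bin_size)
    out = np.empty(nbins)
    for i in range(nbins):
        out[i] = values[i * bin_size:(i + 1) * bin_size].mean()
    return out


def intron_coverage(source, chrom: str, start: int, end: int, strand: str,
                    bin_size: int = 1,
                    strandedness: Strandedness = "forward",
                    references: Mapping[str, int] | None = None,
                    ) -> CoverageProfile:
    """Mean per-bin depth across [start, end), sense-oriented.

    ``source`` is a prebuilt :class:`DepthTrack` or a SAM/BAM path (in
    which case ``references`` must supply chromosome lengths).
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if not isinstance(source, DepthTrack):
        if references is None:
            raise ValueError("references required when source is not a DepthTrack")
        source = build_depth(source, references)
    per_base = source.slice(chrom, start, end, strand, strandedness)
    if strand == "-":
        per_base = per_base[::-1]
    return CoverageProfile(chrom=chrom, start=start, end=end, strand=strand,
                           bin_size=bin_size,
                           values=_bin_means(per_base, bin_size))


@dataclass
class SawtoothResult:
    score: float
    up_mean: float
    down_mean: float
    w_up: int           # nt actually used upstream
    w_down: int
    rho_up: float
    rho_down: float
    trend_ok: bool
    shrunk: bool        # a flank was shorter than the requested W


def _trend_rho(values: np.ndarray, chunk: int) -> float:
    """Spearman rho of coarse-binned coverage against position."""
    if chunk > 1:
        values = _bin_means(values, chunk)
    if len(values) < 3 or np.allclose(values, values[0]):
        return float("nan")
    rho, _ = stats.spearmanr(np.arange(len(values)), values)
    return float(rho)


def sawtooth_score(profile: CoverageProfile, site_offset: int,
                   w: int = 5000, eps: float = 0.1,
                   rho_max: float = -0.3, trend_bin: int = 200,
                   ) -> SawtoothResult:
    """Step statistic at a candidate RS site.

    ``site_offset`` is the sense offset (nt) of the motif's A within the
    profiled intron; the upstream window ends at the A and the
    downstream window starts at the first retained base (A + 2).
    """
    bs = profile.bin_size
    length_nt = profile.nbins * bs
    if not (0 <= site_offset < length_nt):
        raise ValueError("site offset outside the profiled intron")
    a_bin = site_offset // bs
    acc_bin = (site_offset + 2) // bs
    wb = max(1, w // bs)

    up = profile.values[max(0, a_bin - wb):a_bin]
    down = profile.values[acc_bin:acc_bin + wb]
    if len(up) == 0 or len(down) == 0:
        raise ValueError("site too close to the intron boundary to score")
    shrunk = len(up) < wb or len(down) < wb

    up_mean = float(up.mean())
    down_mean = float(down.mean())
    score = math.log2((down_mean + eps) / (up_mean + eps))
    chunk = max(1, trend_bin // bs)
    rho_up = _trend_rho(up, chunk)
    rho_down = _trend_rho(down, chunk)
    trend_ok = bool(
        not math.isnan(rho_up) and not math.isnan(rho_down)
        and rho_up <= rho_max and rho_down <= rho_max)
    return SawtoothResult(score=score, up_mean=up_mean, down_mean=down_mean,
                          w_up=len(up) * bs, w_down=len(down) * bs,
                          rho_up=rho_up, rho_down=rho_down,
                          trend_ok=trend_ok, shrunk=shrunk)


def exon_likeness(profile: CoverageProfile, site_offset: int,
                  down_donor_offset: int | None = None,
                  window: int = 350, flank: int = 5000,
                  eps: float = 0.1) -> float:
    """log2 ratio of depth inside the putative exon vs its two flanks.

    The exon interval runs from the first retained base (site A + 2) to
    the observed down-junction donor, or ``window`` nt when no donor was
    observed.
    """
    bs = profile.bin_size
    acc = (site_offset + 2) // bs
    if down_donor_offset is not None:
        end = (down_donor_offset // bs) + 1
    else:
        end = acc + max(1, window // bs)
    inside = profile.values[acc:end]
    fb = max(1, flank // bs)
    left = profile.values[max(0, (site_offset // bs) - fb):site_offset // bs]
    right = profile.values[end:end + fb]
    flanks = np.concatenate([left, right]) if len(left) or len(right) else np.array([0.0])
    if len(inside) == 0:
        raise ValueError("empty exon interval")
    return math.log2((float(inside.mean()) + eps) / (float(flanks.mean()) + eps))


@dataclass
class SawtoothEvidence:
    """Coverage evidence for classifying one candidate site."""

    site_id: str
    sawtooth: SawtoothResult
    exon_score: float
    background_mean: float


def site_evidence(depth: DepthTrack, site: MotifSite, gene: GeneModel,
                  thresholds: PipelineThresholds,
                  down_donor_pos: int | None = None) -> SawtoothEvidence:
    """Compute all coverage evidence for one intronic site."""
    if site.intron_ordinal is None:
        raise ValueError(f"site {site.site_id} is not intronic")
    intron: Intron = gene.intron_by_ordinal(site.intron_ordinal)
    profile = intron_coverage(
        depth, site.chrom, intron.start, intron.end, gene.strand,
        bin_size=1, strandedness=thresholds.strandedness)
    a_off = sense_offset(site.a_pos, intron.start, intron.end, gene.strand)
    donor_off = None
    if down_donor_pos is not None:
        donor_off = sense_offset(down_donor_pos, intron.start, intron.end,
                                 gene.strand)
    saw = sawtooth_score(profile, a_off, w=thresholds.flank_w,
                         eps=thresholds.epsilon, rho_max=thresholds.rho_max,
                         trend_bin=thresholds.bin_size)
    exon = exon_likeness(profile, a_off, donor_off,
                         window=thresholds.window, flank=thresholds.flank_w,
                         eps=thresholds.epsilon)
    return SawtoothEvidence(site_id=site.site_id, sawtooth=saw,
                            exon_score=exon,
                            background_mean=float(profile.values.mean()))
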