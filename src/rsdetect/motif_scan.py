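"""Enumerate AGGT (or generalized AGNN) acceptor motifs on gene sense strands.

An RS acceptor candidate is an AG dinucleotide acting as a 3' splice
site whose following two bases (GT in the canonical case) are
immediately reconstituted as a 5' splice site.  Sites are therefore
scanned as 4-mers beginning with AG on the sense strand of each gene
span, annotated with their host intron, and filtered by intron length.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

from rsdetect.gene_models import GeneModel
from rsdetect.sequtil import GenomeLike, load_genome, sense_sequence

_PATTERN_CHARS = set("ACGTN")


class MotifPatternError(ValueError):
    """Pattern violates the acceptor convention (must be a 4-mer starting AG)."""


@dataclass(frozen=True)
class MotifSite:
    """A motif occurrence on a gene's sense strand.

    ``a_pos`` is the reference coordinate (0-based) of the sense-strand
    'A'; on the minus strand the reference shows the reverse complement
    and ``a_pos`` is the highest coordinate of the 4-mer.
    ``acceptor_pos`` is the reference coordinate of the first retained
    base after AG (sense a_pos + 2 mapped through strand).
    """

    chrom: str
    a_pos: int
    strand: str
    motif: str
    gene_id: str
    acceptor_pos: int
    intron_ordinal: int | None = None
    intron_length: int | None = None

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.a_pos + 1}:{self.strand}:{self.gene_id}"

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.a_pos, self.strand)

    @property
    def ref_interval(self) -> tuple[int, int]:
        """Reference interval [start, end) occupied by the 4-mer."""
        if self.strand == "-":
            return (self.a_pos - 3, self.a_pos + 1)
        return (self.a_pos, self.a_pos + 4)


def compile_pattern(motif_pattern: str) -> re.Pattern:
    if len(motif_pattern) != 4 or not motif_pattern.startswith("AG"):
        raise MotifPatternError(
            f"motif pattern must be a 4-mer starting with AG, "
            f"got {motif_pattern!r}")
    if set(motif_pattern) - _PATTERN_CHARS:
        raise MotifPatternError(f"pattern {motif_pattern!r} has invalid letters")
    # lookahead regex so overlapping occurrences are all found; genome N
    # or other ambiguity codes never match (wildcard N = [ACGT] only)
    body = "".join("[ACGT]" if c == "N" else c for c in motif_pattern)
    return re.compile(f"(?=({body}))")


def _sense_intron_intervals(gene: GeneModel) -> list[tuple[int, int, int]]:
    """(sense_start, sense_end, ordinal) for each intron, sorted by sense."""
    out = []
    for intron in gene.introns:
        if gene.strand == "-":
            s = gene.end - intron.end
            e = gene.end - intron.start
        else:
            s = intron.start - gene.start
            e = intron.end - gene.start
        out.append((s, e, intron.ordinal))
    return sorted(out)


def scan_motif_sites(genome_source: GenomeLike,
                     gene_models: Mapping[str, GeneModel],
                     motif_pattern: str = "AGGT") -> list[MotifSite]:
    """All occurrences of the pattern on each gene's sense strand.

    The search covers the full gene span (TSS to TES) in transcription
    orientation only; intergenic sequence is never scanned.  Sites
    falling entirely inside an intron are annotated with the intron's
    ordinal and length.  Overlapping genes yield one site per gene.
    """
    regex = compile_pattern(motif_pattern)
    genome = load_genome(genome_source)
    sites: list[MotifSite] = []
    for gene in gene_models.values():
        seq = sense_sequence(genome, gene.chrom, gene.start, gene.end, gene.strand)
        introns = _sense_intron_intervals(gene)
        for m in regex.finditer(seq):
            i = m.start()
            motif = m.group(1)
            if gene.strand == "-":
                a_pos = gene.end - 1 - i
                acceptor_pos = a_pos - 2
            else:
                a_pos = gene.start + i
                acceptor_pos = a_pos + 2
            ordinal = length = None
            for s, e, order in introns:
                if s <= i and i + 4 <= e:
                    ordinal, length = order, e - s
                    break
            sites.append(MotifSite(
                chrom=gene.chrom, a_pos=a_pos, strand=gene.strand,
                motif=motif, gene_id=gene.gene_id, acceptor_pos=acceptor_pos,
                intron_ordinal=ordinal, intron_length=length))
    return sites


def filter_intronic_sites(sites: Iterable[MotifSite],
                          min_intron_length: int) -> list[MotifSite]:
    """Keep sites whose host intron is at least ``min_intron_length`` nt."""
    return [
        s for s in sites
        if s.intron_ordinal is not None and s.intron_length >= min_intron_length
    ]


def exclude_gt_core(sites: Iterable[MotifSite]) -> list[MotifSite]:
    """Drop AGGT from an AGNN scan (the AGNN-where-NN-is-not-GT pipeline)."""
    return [s for s in sites if s.motif[2:4] != "GT"]
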