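"""Collapsed per-gene exon/intron models and read-level quantification.

A :class:`GeneModel` is the union of all transcript exons of a gene
("collapsed" exons) with introns derived as the gaps between them.
Intron ordinals are strand-aware: ordinal 1 is the 5'-most intron in the
direction of transcription.  Quantification operations (FPKM, intronic
read fraction) follow the standard definitions: FPKM normalizes exonic
read counts to collapsed exonic kilobases and sequencing depth in
millions; the intronic fraction partitions uniquely mapped reads into
exonic / intronic / intergenic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import gffutils
import pysam
from intervaltree import IntervalTree

from rsdetect.config import Strandedness
from rsdetect.sequtil import GenomeLike, load_genome


class AnnotationError(ValueError):
    """Malformed annotation input."""


class GenomeMismatchError(ValueError):
    """Annotation refers to a chromosome absent from the genome."""


@dataclass(frozen=True)
class Intron:
    """An intron of a collapsed gene model (0-based half-open)."""

    start: int
    end: int
    ordinal: int  # 1 = 5'-most in transcription direction

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SampleDepth:
    """Sequencing depth of one sample, in uniquely mapped reads."""

    sample_id: str
    uniquely_mapped_reads: int
    role: str = "total_rna"  # or "mrna_control"

    def __post_init__(self):
        if self.uniquely_mapped_reads <= 0:
            raise ValueError(
                f"sample {self.sample_id}: depth must be > 0, "
                f"got {self.uniquely_mapped_reads}")
        if self.role not in ("total_rna", "mrna_control"):
            raise ValueError(f"unknown sample role {self.role!r}")


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    introns: tuple[Intron, ...] = field(default=())

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def length(self) -> int:
        return self.end - self.start

    def intron_by_ordinal(self, ordinal: int) -> Intron:
        for intron in self.introns:
            if intron.ordinal == ordinal:
                return intron
        raise KeyError(f"{self.gene_id}: no intron with ordinal {ordinal}")


def collapse_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals; touching intervals merge."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if e <= s:
            raise ValueError(f"empty or inverted interval [{s}, {e})")
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def derive_introns(exons: Sequence[tuple[int, int]], strand: str) -> tuple[Intron, ...]:
    gaps = [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)]
    if strand == "-":
        # 5'-most gap in transcription direction = highest coordinates
        ordered = list(reversed(gaps))
    else:
        ordered = gaps
    introns = [Intron(s, e, i + 1) for i, (s, e) in enumerate(ordered)]
    return tuple(sorted(introns, key=lambda x: x.start))


def build_gene_model(gene_id: str, chrom: str, strand: str,
                     exon_intervals: Iterable[tuple[int, int]]) -> GeneModel:
    exons = tuple(collapse_intervals(exon_intervals))
    if not exons:
        raise AnnotationError(f"gene {gene_id} has no exons")
    if strand not in "+-":
        raise AnnotationError(f"gene {gene_id}: bad strand {strand!r}")
    return GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand,
        start=exons[0][0], end=exons[-1][1],
        exons=exons, introns=derive_introns(exons, strand))


def _validate_gtf_lines(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise AnnotationError(
                    f"malformed GTF line {lineno}: expected 9 tab-separated "
                    f"fields, got {len(fields)}")
            try:
                int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise AnnotationError(
                    f"malformed GTF line {lineno}: non-integer coordinates") from exc


def load_gene_models(annotation_source: Union[str, Path],
                     genome_source: GenomeLike | None = None,
                     ) -> dict[str, GeneModel]:
    """Load an Ensembl-dialect GTF into collapsed gene models.

    Exons are collapsed across all transcripts of each gene; introns are
    the gaps.  If ``genome_source`` is given, every chromosome used by
    the annotation must exist in it.
    """
    path = Path(annotation_source)
    _validate_gtf_lines(path)
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True)

    per_gene: dict[str, dict] = {}
    for exon in db.features_of_type("exon"):
        gene_id = exon.attributes["gene_id"][0]
        rec = per_gene.setdefault(
            gene_id, {"chrom": exon.seqid, "strand": exon.strand, "exons": []})
        if rec["chrom"] != exon.seqid or rec["strand"] != exon.strand:
            raise AnnotationError(
                f"gene {gene_id}: exons on inconsistent chrom/strand")
        # GTF is 1-based inclusive -> 0-based half-open
        rec["exons"].append((exon.start - 1, exon.end))

    if genome_source is not None:
        genome = load_genome(genome_source)
        for gene_id, rec in per_gene.items():
            if rec["chrom"] not in genome:
                raise GenomeMismatchError(
                    f"chromosome {rec['chrom']!r} (gene {gene_id}) "
                    f"is missing from the genome")

    return {
        gid: build_gene_model(gid, rec["chrom"], rec["strand"], rec["exons"])
        for gid, rec in per_gene.items()
    }


def gene_fpkm(per_gene_exonic_read_counts: Mapping[str, int],
              gene_models: Mapping[str, GeneModel],
              depth: SampleDepth) -> dict[str, float]:
    """FPKM = count / (collapsed exonic kb x depth in millions)."""
    out = {}
    millions = depth.uniquely_mapped_reads / 1e6
    for gene_id, count in per_gene_exonic_read_counts.items():
        model = gene_models[gene_id]
        kb = model.exonic_length / 1000.0
        if kb <= 0:
            raise ValueError(f"gene {gene_id}: zero exonic length")
        out[gene_id] = count / (kb * millions)
    return out


def _open_alignments(alignments):
    if isinstance(alignments, (str, Path)):
        return pysam.AlignmentFile(str(alignments), check_sq=False)
    return alignments


def _read_strand(segment, strandedness: Strandedness) -> str | None:
    if strandedness == "unstranded":
        return None
    strand = "-" if segment.is_reverse else "+"
    if strandedness == "reverse":
        strand = "-" if strand == "+" else "+"
    return strand


def intronic_fraction(alignments, gene_models: Mapping[str, GeneModel],
                      strandedness: Strandedness = "unstranded",
                      ) -> dict[str, float]:
    """Partition uniquely mapped reads into exonic/intronic/intergenic.

    A read is exonic if any aligned block overlaps a collapsed exon of a
    gene on the read's assigned strand; otherwise intronic if it overlaps
    any gene span; otherwise intergenic.  A read counts once even when it
    lies in several genes.
    """
    exon_trees: dict[tuple[str, str], IntervalTree] = {}
    span_trees: dict[tuple[str, str], IntervalTree] = {}
    for model in gene_models.values():
        key = (model.chrom, model.strand)
        et = exon_trees.setdefault(key, IntervalTree())
        for s, e in model.exons:
            et.addi(s, e)
        span_trees.setdefault(key, IntervalTree()).addi(model.start, model.end)

    def hits(trees, chrom, strand, blocks) -> bool:
        strands = "+-" if strand is None else strand
        for st in strands:
            tree = trees.get((chrom, st))
            if tree is None:
                continue
            for s, e in blocks:
                if tree.overlap(s, e):
                    return True
        return False

    counts = {"exonic": 0, "intronic": 0, "intergenic": 0}
    n = 0
    for seg in _open_alignments(alignments):
        if seg.is_unmapped:
            continue
        n += 1
        blocks = seg.get_blocks()
        strand = _read_strand(seg, strandedness)
        chrom = seg.reference_name
        if hits(exon_trees, chrom, strand, blocks):
            counts["exonic"] += 1
        elif hits(span_trees, chrom, strand, blocks):
            counts["intronic"] += 1
        else:
            counts["intergenic"] += 1
    if n == 0:
        raise ValueError("no mapped reads in alignment input")
    return {k: v / n for k, v in counts.items()}
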