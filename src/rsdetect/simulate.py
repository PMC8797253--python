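"""Synthetic genome, annotation, and alignment generator with ground truth.

The simulator builds a toy world that reproduces the data structures the
detection pipelines consume, scaled roughly ten-fold below mammalian
dimensions so a full end-to-end run takes seconds: multi-exon genes with
long (~50 kb) first introns, recursive splice sites planted as AGGTAAGT
motifs with a polypyrimidine tract, cryptic exons planted with a weak
reconstituted donor context and a strong downstream GT donor, and a
junction-poor mRNA control.

Intronic read starts in nascent introns are drawn with density
proportional to (sense distance to the segment's next splice point +
delay d), the steady-state expectation for co-transcriptional splicing:
coverage declines linearly toward each splice point and steps up
immediately after an RS site, producing the saw-tooth.  Cryptic-exon
introns instead carry flat background coverage with a uniform coverage
island over the planted exon.  Planted junction-read counts are emitted
exactly and split round-robin across replicates, so replicate-merged
counts equal the planted truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from rsdetect.gene_models import GeneModel, SampleDepth, build_gene_model
from rsdetect.sawtooth import CoverageProfile, sawtooth_score
from rsdetect.sequtil import revcomp

_BASES = np.array(list("ACGT"))

POLYPY_TRACT = "TTTCTTTCTTTCTTTCTTTC"       # planted 20-nt tract before acceptors
ACCEPTOR_TAIL = "TTCTTTCTTTCCTTTCTCAG"      # annotated intron 3' end (ends AG)
DONOR_HEAD = "GTAAGT"                       # annotated/planted donor intron start


@dataclass(frozen=True)
class ReferenceConfig:
    n_rs_genes: int = 5
    n_cryptic_genes: int = 3
    n_null_genes: int = 1            # plain gene; hosts a nascent decoy site
    rs_intron_length: int = 52_000
    cryptic_intron_length: int = 55_000
    second_intron_length: int = 2_000
    exon_length: int = 300
    spacer: int = 5_000              # intergenic flank per chromosome
    rs_site_frac: float = 0.45       # site position within the first intron
    cryptic_site_frac: float = 0.5
    cryptic_exon_length: int = 150
    plant_decoy: bool = True


@dataclass(frozen=True)
class ReadConfig:
    read_len: int = 100
    intron_depth: float = 30.0       # mean nascent coverage of RS/null introns
    cryptic_bg_depth: float = 4.0    # flat background in cryptic introns
    cryptic_boost: float = 10.0      # exon coverage = boost x background
    intronic_fraction: float = 0.77  # planted intronic read fraction (total RNA)
    polymerase_delay: int = 2_000    # d, nt: splicing lag behind the polymerase
    n_total_replicates: int = 2
    mrna_junction_fraction: float = 0.02
    uniform_introns: bool = False    # flat coverage everywhere (calibration)


@dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one planted site (all offsets gene-sense, nt)."""

    gene_id: str
    chrom: str
    strand: str
    kind: str                 # "rs" | "cryptic" | "decoy"
    a_pos: int                # reference coordinate of the sense A
    acceptor_pos: int         # reference coordinate of the first retained base
    a_off: int                # gene-sense offset of the A
    intron_ordinal: int
    up_count: int
    down_count: int
    donor_off: int | None     # gene-sense offset of the down donor base
    down_donor_pos: int | None
    exon_length: int | None

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.a_pos, self.strand)


@dataclass
class SimulationTruth:
    genome: dict[str, str]
    genes: dict[str, GeneModel]
    sites: list[PlantedSite]
    config: ReferenceConfig
    seed: int
    # gene-sense exon intervals per gene, sorted 5'->3'
    sense_exons: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def sites_of_kind(self, kind: str) -> list[PlantedSite]:
        return [s for s in self.sites if s.kind == kind]


@dataclass
class SimulatedData:
    truth: SimulationTruth
    sample_paths: dict[str, Path]
    depths: dict[str, SampleDepth]


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n)


def _to_str(codes: np.ndarray) -> str:
    return "".join(_BASES[codes])


def _plant(codes: np.ndarray, offset: int, motif: str) -> None:
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for i, b in enumerate(motif):
        codes[offset + i] = idx[b]


def generate_reference(config: ReferenceConfig = ReferenceConfig(),
                       seed: int = 0) -> SimulationTruth:
    """Build the toy genome, gene models, and planted-site truth.

    Same seed, same config: byte-identical genome and annotation.
    """
    if min(config.rs_intron_length, config.cryptic_intron_length) < 2000:
        raise ValueError("planted sites require host introns of at least 2 kb")
    rng = np.random.default_rng([int(seed), 101])
    genome: dict[str, str] = {}
    genes: dict[str, GeneModel] = {}
    sense_exons: dict[str, list[tuple[int, int]]] = {}
    sites: list[PlantedSite] = []

    kinds = (["rs"] * config.n_rs_genes
             + ["cryptic"] * config.n_cryptic_genes
             + ["null"] * config.n_null_genes)
    for gi, kind in enumerate(kinds):
        gene_id = f"G{kind.upper()}{gi + 1}"
        chrom = f"chr{gi + 1}"
        strand = "+" if gi % 2 == 0 else "-"
        ex = config.exon_length
        l1 = (config.cryptic_intron_length if kind == "cryptic"
              else config.rs_intron_length)
        l2 = config.second_intron_length
        glen = 3 * ex + l1 + l2
        codes = _random_seq(rng, glen)

        # sense layout: exon1 intron1 exon2 intron2 exon3
        exons_sense = [(0, ex), (ex + l1, 2 * ex + l1),
                       (2 * ex + l1 + l2, glen)]
        introns_sense = [(ex, ex + l1), (2 * ex + l1, 2 * ex + l1 + l2)]
        for i_s, i_e in introns_sense:   # annotated donor/acceptor context
            _plant(codes, i_s, DONOR_HEAD)
            _plant(codes, i_e - len(ACCEPTOR_TAIL), ACCEPTOR_TAIL)

        site_spec = None
        if kind == "rs":
            a_off = ex + int(l1 * config.rs_site_frac)
            _plant(codes, a_off - len(POLYPY_TRACT), POLYPY_TRACT)
            _plant(codes, a_off, "AGGTAAGT")
            has_down = gi % 2 == 0
            up = int(rng.integers(12, 41))
            down = int(rng.integers(3, 13)) if has_down else 0
            donor_off = None
            if has_down:
                donor_off = a_off + 2 + int(rng.integers(80, 301))
                _plant(codes, donor_off + 1, DONOR_HEAD)
            site_spec = ("rs", a_off, up, down, donor_off, None)
        elif kind == "cryptic":
            a_off = ex + int(l1 * config.cryptic_site_frac)
            _plant(codes, a_off - len(POLYPY_TRACT), POLYPY_TRACT)
            _plant(codes, a_off, "AGGT")
            if _to_str(codes[a_off + 4:a_off + 8]) == "AAGT":
                _plant(codes, a_off + 4, "CCTC")   # keep the r5'SS weak
            donor_off = a_off + 2 + config.cryptic_exon_length - 1
            _plant(codes, donor_off + 1, DONOR_HEAD)
            up = int(rng.integers(10, 31))
            down = max(2, int(round(0.3 * up)) + int(rng.integers(-1, 2)))
            site_spec = ("cryptic", a_off, up, down, donor_off,
                         config.cryptic_exon_length)
        elif config.plant_decoy:
            a_off = ex + int(l1 * 0.5)
            _plant(codes, a_off, "AGGT")
            site_spec = ("decoy", a_off, 11, 0, None, None)

        sense = _to_str(codes)
        flank5 = _to_str(_random_seq(rng, config.spacer))
        flank3 = _to_str(_random_seq(rng, config.spacer))
        gstart = config.spacer
        if strand == "-":
            genome[chrom] = flank5 + revcomp(sense) + flank3
            ref_exons = [(gstart + glen - e, gstart + glen - s)
                         for s, e in exons_sense]
        else:
            genome[chrom] = flank5 + sense + flank3
            ref_exons = [(gstart + s, gstart + e) for s, e in exons_sense]
        model = build_gene_model(gene_id, chrom, strand, ref_exons)
        genes[gene_id] = model
        sense_exons[gene_id] = exons_sense

        if site_spec is not None:
            skind, a_off, up, down, donor_off, exon_len = site_spec
            assert sense[a_off:a_off + 2] == "AG"

            def to_ref(off: int) -> int:
                return (model.end - 1 - off) if strand == "-" else (model.start + off)

            sites.append(PlantedSite(
                gene_id=gene_id, chrom=chrom, strand=strand, kind=skind,
                a_pos=to_ref(a_off), acceptor_pos=to_ref(a_off + 2),
                a_off=a_off, intron_ordinal=1, up_count=up, down_count=down,
                donor_off=donor_off,
                down_donor_pos=None if donor_off is None else to_ref(donor_off),
                exon_length=exon_len))

    return SimulationTruth(genome=genome, genes=genes, sites=sites,
                           config=config, seed=int(seed),
                           sense_exons=sense_exons)


# ---------------------------------------------------------------------------
# file writers (deterministic byte output)

def write_fasta(truth: SimulationTruth, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in truth.genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
    return path


def write_gtf(truth: SimulationTruth, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for gene in truth.genes.values():
            attrs = f'gene_id "{gene.gene_id}"; gene_name "{gene.gene_id}";'
            tattrs = attrs + f' transcript_id "{gene.gene_id}.T1";'
            fh.write("\t".join([
                gene.chrom, "rsdetect_sim", "gene", str(gene.start + 1),
                str(gene.end), ".", gene.strand, ".", attrs]) + "\n")
            fh.write("\t".join([
                gene.chrom, "rsdetect_sim", "transcript", str(gene.start + 1),
                str(gene.end), ".", gene.strand, ".", tattrs]) + "\n")
            for s, e in gene.exons:
                fh.write("\t".join([
                    gene.chrom, "rsdetect_sim", "exon", str(s + 1), str(e),
                    ".", gene.strand, ".", tattrs]) + "\n")
    return path


def write_truth_table(truth: SimulationTruth, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\tkind\ta_pos_1based\tacceptor_pos_1based"
                 "\tup_count\tdown_count\tdown_donor_1based\texon_length\n")
        for s in truth.sites:
            donor = "" if s.down_donor_pos is None else str(s.down_donor_pos + 1)
            exon = "" if s.exon_length is None else str(s.exon_length)
            fh.write(f"{s.gene_id}\t{s.chrom}\t{s.strand}\t{s.kind}\t"
                     f"{s.a_pos + 1}\t{s.acceptor_pos + 1}\t{s.up_count}\t"
                     f"{s.down_count}\t{donor}\t{exon}\n")
    return path


# ---------------------------------------------------------------------------
# read simulation

def _sense_introns(truth: SimulationTruth, gene_id: str) -> list[tuple[int, int]]:
    exons = truth.sense_exons[gene_id]
    return [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)]


def _intron_weights(truth: SimulationTruth, gene_id: str,
                    intron_index: int, config: ReadConfig) -> np.ndarray:
    """Per-position read-start weights for one intron (sense space).

    Nascent introns: weight = distance to the segment's downstream
    splice point + polymerase delay, per segment (segments split at RS
    acceptors).  Cryptic introns: flat background with a coverage island
    over the planted exon.  ``uniform_introns`` forces flat weights.
    """
    i_s, i_e = _sense_introns(truth, gene_id)[intron_index]
    length = i_e - i_s
    if config.uniform_introns:
        return np.ones(length)
    planted = [s for s in truth.sites
               if s.gene_id == gene_id and s.intron_ordinal == intron_index + 1]
    cryptic = [s for s in planted if s.kind == "cryptic"]
    if cryptic:
        w = np.ones(length)
        for site in cryptic:
            acc = site.a_off + 2 - i_s
            w[acc:acc + site.exon_length] = config.cryptic_boost
        return w
    boundaries = sorted(s.a_off + 2 - i_s for s in planted if s.kind == "rs")
    edges = [0] + boundaries + [length]
    w = np.empty(length)
    for a, b in zip(edges, edges[1:]):
        w[a:b] = (b - np.arange(a, b)) + config.polymerase_delay
    return w


class _ReadBuffer:
    def __init__(self):
        self.reads: dict[str, list] = {}

    def add(self, sample: str, chrom: str, ref_blocks: list[tuple[int, int]],
            flag: int) -> None:
        self.reads.setdefault(sample, []).append((chrom, ref_blocks, flag))


def _sense_blocks_to_ref(gene: GeneModel, blocks: Sequence[tuple[int, int]],
                         ) -> list[tuple[int, int]]:
    if gene.strand == "-":
        out = [(gene.end - e, gene.end - s) for s, e in blocks]
    else:
        out = [(gene.start + s, gene.start + e) for s, e in blocks]
    return sorted(out)


def simulate_reads(truth: SimulationTruth,
                   config: ReadConfig = ReadConfig(),
                   outdir=None, seed: int = 0) -> SimulatedData:
    """Emit coordinate-sorted SAM files for total-RNA replicates + mRNA.

    Planted junction-read counts are exact; the mRNA control carries
    exon-confined and annotated-junction reads only.
    """
    if config.intron_depth <= 0 and any(
            s.up_count for s in truth.sites):
        raise ValueError("zero depth with nonzero planted junction counts")
    rng = np.random.default_rng([int(seed), 202])
    outdir = Path(outdir) if outdir is not None else None
    rl = config.read_len
    total_samples = [f"total_rep{i + 1}" for i in range(config.n_total_replicates)]
    buf = _ReadBuffer()
    for sample in total_samples + ["mrna_rep1"]:
        buf.reads[sample] = []

    # --- intronic nascent / background coverage (total RNA only)
    n_intronic = 0
    for gene_id, gene in truth.genes.items():
        flag = 16 if gene.strand == "-" else 0
        for idx, (i_s, i_e) in enumerate(_sense_introns(truth, gene_id)):
            length = i_e - i_s
            w = _intron_weights(truth, gene_id, idx, config)
            is_cryptic = any(s.kind == "cryptic" for s in truth.sites
                             if s.gene_id == gene_id
                             and s.intron_ordinal == idx + 1)
            depth = (config.cryptic_bg_depth if is_cryptic
                     else config.intron_depth)
            if is_cryptic:
                n = int(round(depth * w.sum() / rl))
            else:
                n = int(round(depth * length / rl))
            if n == 0:
                continue
            starts = rng.choice(length, size=n, p=w / w.sum())
            reps = rng.integers(len(total_samples), size=n)
            for start, rep in zip(starts, reps):
                s = i_s + int(start)
                e = min(s + rl, i_e)
                buf.add(total_samples[rep], gene.chrom,
                        _sense_blocks_to_ref(gene, [(s, e)]), flag)
            n_intronic += n

    # --- exonic reads: total RNA (to the planted intronic fraction) + mRNA
    exon_index = []
    for gene_id, gene in truth.genes.items():
        for s, e in truth.sense_exons[gene_id]:
            exon_index.append((gene_id, s, e))
    exon_lens = np.array([e - s for _, s, e in exon_index])
    cum = np.concatenate([[0], np.cumsum(exon_lens)])
    total_exonic = int(cum[-1])

    f = config.intronic_fraction
    n_exonic = int(round(n_intronic * (1 - f) / f)) if n_intronic else 1000

    def emit_exonic(samples: list[str], n: int):
        offsets = rng.integers(total_exonic, size=n)
        which = np.searchsorted(cum, offsets, side="right") - 1
        reps = rng.integers(len(samples), size=n)
        for off, wi, rep in zip(offsets, which, reps):
            gene_id, s, e = exon_index[wi]
            gene = truth.genes[gene_id]
            pos = s + int(off - cum[wi])
            end = min(pos + rl, e)
            buf.add(samples[rep], gene.chrom,
                    _sense_blocks_to_ref(gene, [(pos, end)]),
                    16 if gene.strand == "-" else 0)

    emit_exonic(total_samples, n_exonic)
    n_mrna = n_exonic
    emit_exonic(["mrna_rep1"], n_mrna)

    # --- annotated junction reads in the mRNA control (junction-poor)
    gene_ids = list(truth.genes)
    h = rl // 2
    for _ in range(int(round(config.mrna_junction_fraction * n_mrna))):
        gene_id = gene_ids[int(rng.integers(len(gene_ids)))]
        gene = truth.genes[gene_id]
        exons = truth.sense_exons[gene_id]
        k = int(rng.integers(len(exons) - 1))
        blocks = [(exons[k][1] - h, exons[k][1]),
                  (exons[k + 1][0], exons[k + 1][0] + h)]
        buf.add("mrna_rep1", gene.chrom, _sense_blocks_to_ref(gene, blocks),
                16 if gene.strand == "-" else 0)

    # --- planted junction reads (total RNA, split round-robin over reps)
    for site in truth.sites:
        gene = truth.genes[site.gene_id]
        flag = 16 if gene.strand == "-" else 0
        exons = truth.sense_exons[site.gene_id]
        up_exon_end = exons[site.intron_ordinal - 1][1]
        acc = site.a_off + 2
        for i in range(site.up_count):
            blocks = [(up_exon_end - h, up_exon_end), (acc, acc + h)]
            buf.add(total_samples[i % len(total_samples)], gene.chrom,
                    _sense_blocks_to_ref(gene, blocks), flag)
        if site.down_count and site.donor_off is not None:
            next_exon_start = exons[site.intron_ordinal][0]
            for i in range(site.down_count):
                blocks = [(site.donor_off - h + 1, site.donor_off + 1),
                          (next_exon_start, next_exon_start + h)]
                buf.add(total_samples[i % len(total_samples)], gene.chrom,
                        _sense_blocks_to_ref(gene, blocks), flag)

    # --- write coordinate-sorted SAM
    chroms = list(truth.genome)
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": c, "LN": len(truth.genome[c])} for c in chroms]}
    tid = {c: i for i, c in enumerate(chroms)}
    paths: dict[str, Path] = {}
    depths: dict[str, SampleDepth] = {}
    for sample, reads in buf.reads.items():
        named = [(tid[chrom], blocks[0][0], f"{sample}.r{i}", chrom, blocks, flag)
                 for i, (chrom, blocks, flag) in enumerate(reads)]
        named.sort(key=lambda r: (r[0], r[1], r[2]))
        role = "mrna_control" if sample.startswith("mrna") else "total_rna"
        depths[sample] = SampleDepth(sample, len(named), role)
        if outdir is None:
            continue
        outdir.mkdir(parents=True, exist_ok=True)
        path = outdir / f"{sample}.sam"
        with pysam.AlignmentFile(str(path), "wh", header=header) as out:
            hdr = out.header
            for _, _, name, chrom, blocks, flag in named:
                a = pysam.AlignedSegment(hdr)
                a.query_name = name
                a.flag = flag
                a.reference_id = tid[chrom]
                a.reference_start = blocks[0][0]
                a.mapping_quality = 255
                cig = []
                seq = []
                for bi, (s, e) in enumerate(blocks):
                    if bi > 0:
                        cig.append((3, s - blocks[bi - 1][1]))
                    cig.append((0, e - s))
                    seq.append(truth.genome[chrom][s:e])
                a.cigartuples = cig
                a.query_sequence = "".join(seq)
                out.write(a)
        paths[sample] = path
    return SimulatedData(truth=truth, sample_paths=paths, depths=depths)


# ---------------------------------------------------------------------------
# closed-form expectations from the simulation density

def expected_intron_coverage(truth: SimulationTruth, site: PlantedSite,
                             config: ReadConfig = ReadConfig()) -> np.ndarray:
    """Expected per-base depth of the site's host intron (sense space).

    Deterministic function of the planted density: expected coverage is
    the read-start density convolved with the read length, scaled by the
    pooled read count across total-RNA replicates.
    """
    idx = site.intron_ordinal - 1
    i_s, i_e = _sense_introns(truth, site.gene_id)[idx]
    length = i_e - i_s
    w = _intron_weights(truth, site.gene_id, idx, config)
    is_cryptic = site.kind == "cryptic"
    depth = config.cryptic_bg_depth if is_cryptic else config.intron_depth
    rl = config.read_len
    n = (int(round(depth * w.sum() / rl)) if is_cryptic
         else int(round(depth * length / rl)))
    p = w / w.sum()
    return n * np.convolve(p, np.ones(rl))[:length]


def expected_sawtooth_score(truth: SimulationTruth, site: PlantedSite,
                            config: ReadConfig = ReadConfig(),
                            w: int = 5000, eps: float = 0.1) -> float:
    """Saw-tooth score of the analytic expected coverage at a planted site."""
    idx = site.intron_ordinal - 1
    i_s, i_e = _sense_introns(truth, site.gene_id)[idx]
    cov = expected_intron_coverage(truth, site, config)
    gene = truth.genes[site.gene_id]
    profile = CoverageProfile(chrom=site.chrom, start=0, end=i_e - i_s,
                              strand="+", bin_size=1, values=cov)
    return sawtooth_score(profile, site.a_off - i_s, w=w, eps=eps).score
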