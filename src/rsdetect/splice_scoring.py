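"""Splice-site strength models and sequence-context statistics.

Donor (5'SS) strength is scored on 9-mers laid out as 3 exonic nt + GT
+ 4 intronic nt; acceptor (3'SS) strength on 23-mers laid out as 18 nt
upstream + AGGT + 1 nt, so the AG sits at positions 19-20.  Models are
pluggable: published log-odds parameter tables can be loaded from TSV,
or a weight-matrix / first-order-Markov model can be trained from the
annotated GT donors and AG acceptors of a supplied annotation + genome.
Scores are log-odds in log2 units against a background base
composition; absolute values are model-specific, and all pipeline
decisions reduce to score comparisons, which any monotone model
preserves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from rsdetect.gene_models import GeneModel
from rsdetect.motif_scan import MotifSite
from rsdetect.sequtil import GenomeLike, load_genome, sense_sequence

BASES = "ACGT"
_B2I = {b: i for i, b in enumerate(BASES)}

DONOR_LEN = 9        # 3 + GT + 4
DONOR_GT = (3, 5)    # 0-based slice of the GT core
ACCEPTOR_LEN = 23    # 18 + AGGT + 1
ACCEPTOR_AG = (18, 20)


class TableFormatError(ValueError):
    """Malformed scoring-table file."""


def _validate(seq: str, length: int, core: tuple[int, int], core_seq: str,
              what: str) -> str:
    seq = seq.upper()
    if len(seq) != length:
        raise ValueError(f"{what} must be {length} nt, got {len(seq)}")
    if seq[core[0]:core[1]] != core_seq:
        raise ValueError(
            f"{what} must have {core_seq} at positions "
            f"{core[0] + 1}-{core[1]}, got {seq[core[0]:core[1]]!r}")
    if set(seq) - set(BASES):
        raise ValueError(f"{what} contains non-ACGT characters")
    return seq


@dataclass
class PositionWeightScorer:
    """Per-position log-odds (weight matrix model), log2 units."""

    log_odds: np.ndarray  # shape (L, 4)

    @property
    def length(self) -> int:
        return self.log_odds.shape[0]

    def score(self, seq: str) -> float:
        return float(sum(self.log_odds[i, _B2I[b]] for i, b in enumerate(seq)))


@dataclass
class Markov1Scorer:
    """First-order Markov chain log-odds, log2 units."""

    log_odds0: np.ndarray            # (4,)
    log_odds_trans: np.ndarray       # (L-1, 4, 4) prev x cur

    @property
    def length(self) -> int:
        return self.log_odds_trans.shape[0] + 1

    def score(self, seq: str) -> float:
        total = float(self.log_odds0[_B2I[seq[0]]])
        for t in range(1, len(seq)):
            total += float(
                self.log_odds_trans[t - 1, _B2I[seq[t - 1]], _B2I[seq[t]]])
        return total


@dataclass
class SpliceSiteModel:
    """A donor + acceptor scoring model.

    ``kind`` is one of loaded_tables / trained_wmm / trained_markov1.
    """

    kind: str
    donor: PositionWeightScorer | Markov1Scorer
    acceptor: PositionWeightScorer | Markov1Scorer
    background: dict[str, float]


def score_donor(model: SpliceSiteModel, nine_mer: str) -> float:
    seq = _validate(nine_mer, DONOR_LEN, DONOR_GT, "GT", "donor 9-mer")
    return model.donor.score(seq)


def score_acceptor(model: SpliceSiteModel, seq23: str) -> float:
    seq = _validate(seq23, ACCEPTOR_LEN, ACCEPTOR_AG, "AG", "acceptor 23-mer")
    return model.acceptor.score(seq)


def uniform_background() -> dict[str, float]:
    return {b: 0.25 for b in BASES}


def genome_background(genome_source: GenomeLike) -> dict[str, float]:
    """Genome-wide mononucleotide composition (non-ACGT ignored)."""
    genome = load_genome(genome_source)
    counts = {b: 0 for b in BASES}
    for seq in genome.values():
        for b in BASES:
            counts[b] += seq.count(b)
    total = sum(counts.values())
    if total == 0:
        return uniform_background()
    return {b: c / total for b, c in counts.items()}


def _wmm_matrix(seqs: Sequence[str], length: int,
                background: Mapping[str, float]) -> np.ndarray:
    # Add-one smoothing at an effective sample size equal to the number
    # of distinct sequences: scores depend only on training frequencies,
    # so duplicating every training sequence leaves the model unchanged.
    counts = np.zeros((length, 4))
    for s in seqs:
        for i, b in enumerate(s):
            counts[i, _B2I[b]] += 1
    k = len(set(seqs))
    freq = (counts / len(seqs) * k + 1.0) / (k + 4.0)
    bg = np.array([background[b] for b in BASES])
    return np.log2(freq / bg)


def _markov1(seqs: Sequence[str], length: int,
             background: Mapping[str, float]) -> Markov1Scorer:
    c0 = np.zeros(4)
    ct = np.zeros((length - 1, 4, 4))
    for s in seqs:
        c0[_B2I[s[0]]] += 1
        for t in range(1, length):
            ct[t - 1, _B2I[s[t - 1]], _B2I[s[t]]] += 1
    bg = np.array([background[b] for b in BASES])
    # same frequency-scale smoothing as the weight matrix
    k = len(set(seqs))
    scale = k / len(seqs)
    p0 = (c0 * scale + 1.0) / (k + 4.0)
    ct_scaled = ct * scale
    ptrans = (ct_scaled + 1.0) / (ct_scaled.sum(axis=2, keepdims=True) + 4.0)
    return Markov1Scorer(log_odds0=np.log2(p0 / bg),
                         log_odds_trans=np.log2(ptrans / bg[None, None, :]))


def _clean_training(seqs: Iterable[str], length: int, core: tuple[int, int],
                    core_seq: str) -> list[str]:
    out = []
    for s in seqs:
        s = s.upper()
        if (len(s) == length and s[core[0]:core[1]] == core_seq
                and not set(s) - set(BASES)):
            out.append(s)
    if not out:
        raise ValueError("no valid training sequences")
    return out


def train_wmm(donor_seqs: Iterable[str], acceptor_seqs: Iterable[str],
              background: Mapping[str, float] | None = None) -> SpliceSiteModel:
    bg = dict(background) if background else uniform_background()
    donors = _clean_training(donor_seqs, DONOR_LEN, DONOR_GT, "GT")
    acceptors = _clean_training(acceptor_seqs, ACCEPTOR_LEN, ACCEPTOR_AG, "AG")
    return SpliceSiteModel(
        kind="trained_wmm",
        donor=PositionWeightScorer(_wmm_matrix(donors, DONOR_LEN, bg)),
        acceptor=PositionWeightScorer(_wmm_matrix(acceptors, ACCEPTOR_LEN, bg)),
        background=bg)


def train_markov1(donor_seqs: Iterable[str], acceptor_seqs: Iterable[str],
                  background: Mapping[str, float] | None = None,
                  ) -> SpliceSiteModel:
    bg = dict(background) if background else uniform_background()
    donors = _clean_training(donor_seqs, DONOR_LEN, DONOR_GT, "GT")
    acceptors = _clean_training(acceptor_seqs, ACCEPTOR_LEN, ACCEPTOR_AG, "AG")
    return SpliceSiteModel(
        kind="trained_markov1",
        donor=_markov1(donors, DONOR_LEN, bg),
        acceptor=_markov1(acceptors, ACCEPTOR_LEN, bg),
        background=bg)


def collect_training_sites(gene_models: Mapping[str, GeneModel],
                           genome_source: GenomeLike,
                           ) -> tuple[list[str], list[str]]:
    """Annotated donor 9-mers and acceptor 23-mers from collapsed models.

    The donor 9-mer is the last 3 exonic nt + first 6 intronic nt of
    each GT-intron boundary; the acceptor 23-mer the last 20 intronic nt
    + first 3 exonic nt of each AG-intron boundary, so AG lands at
    positions 19-20.
    """
    genome = load_genome(genome_source)
    donors, acceptors = [], []
    for gene in gene_models.values():
        seq = sense_sequence(genome, gene.chrom, gene.start, gene.end,
                             gene.strand)
        exon_sense = []
        for s, e in gene.exons:
            if gene.strand == "-":
                exon_sense.append((gene.end - e, gene.end - s))
            else:
                exon_sense.append((s - gene.start, e - gene.start))
        for (s1, e1), (s2, e2) in zip(sorted(exon_sense), sorted(exon_sense)[1:]):
            d = seq[e1 - 3:e1 + 6]
            a = seq[s2 - 20:s2 + 3]
            if len(d) == DONOR_LEN and d[3:5] == "GT" and not set(d) - set(BASES):
                donors.append(d)
            if len(a) == ACCEPTOR_LEN and a[18:20] == "AG" and not set(a) - set(BASES):
                acceptors.append(a)
    return donors, acceptors


def train_from_annotation(gene_models: Mapping[str, GeneModel],
                          genome_source: GenomeLike,
                          kind: str = "wmm") -> SpliceSiteModel:
    donors, acceptors = collect_training_sites(gene_models, genome_source)
    bg = genome_background(genome_source)
    if kind == "wmm":
        return train_wmm(donors, acceptors, bg)
    if kind == "markov1":
        return train_markov1(donors, acceptors, bg)
    raise ValueError(f"unknown model kind {kind!r}")


# ---------------------------------------------------------------------------
# scoring-table serialization (WMM-style tables only)

def save_scoring_tables(model: SpliceSiteModel, path) -> None:
    """Export position log-odds tables as TSV: site, position, base, log_odds."""
    for name in ("donor", "acceptor"):
        if not isinstance(getattr(model, name), PositionWeightScorer):
            raise NotImplementedError(
                "only position-weight models can be exported to tables")
    rows = []
    for name in ("donor", "acceptor"):
        mat = getattr(model, name).log_odds
        for pos in range(mat.shape[0]):
            for bi, base in enumerate(BASES):
                rows.append((name, pos + 1, base, float(mat[pos, bi])))
    with open(path, "w") as fh:
        fh.write(f"# rsdetect scoring tables kind={model.kind}\n")
        fh.write("site\tposition\tbase\tlog_odds\n")
        for site, pos, base, lo in rows:
            fh.write(f"{site}\t{pos}\t{base}\t{lo:.10g}\n")


def load_scoring_tables(path) -> SpliceSiteModel:
    """Load a TSV scoring table (see :func:`save_scoring_tables`)."""
    lengths = {"donor": DONOR_LEN, "acceptor": ACCEPTOR_LEN}
    mats = {k: np.full((v, 4), np.nan) for k, v in lengths.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("site\t"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise TableFormatError(f"line {lineno}: expected 4 columns")
            site, pos_s, base, lo_s = fields
            if site not in mats:
                raise TableFormatError(f"line {lineno}: unknown site {site!r}")
            try:
                pos, lo = int(pos_s), float(lo_s)
            except ValueError as exc:
                raise TableFormatError(f"line {lineno}: bad number") from exc
            if not (1 <= pos <= lengths[site]) or base not in _B2I:
                raise TableFormatError(f"line {lineno}: bad position or base")
            mats[site][pos - 1, _B2I[base]] = lo
    for site, mat in mats.items():
        if np.isnan(mat).any():
            pos = int(np.argwhere(np.isnan(mat))[0][0]) + 1
            raise TableFormatError(
                f"{site} table incomplete: missing entry at position {pos}")
    return SpliceSiteModel(kind="loaded_tables",
                           donor=PositionWeightScorer(mats["donor"]),
                           acceptor=PositionWeightScorer(mats["acceptor"]),
                           background=uniform_background())


# ---------------------------------------------------------------------------
# sequence context statistics

@dataclass
class ContextStats:
    """Per-position base frequencies and composition around motif sites."""

    freq_matrix: pd.DataFrame       # index ACGT, one column per position
    pct_t: float                    # mean %T in the upstream tract
    pct_c: float
    pct_pyrimidine: float           # %(T+C)
    consensus_match_fraction: float  # AGGT followed by AAGT
    n_sites: int
    n_skipped: int


def context_stats(sites: Sequence[MotifSite], genome_source: GenomeLike,
                  window: int = 64, upstream: int = 20) -> ContextStats:
    """Sequence context of motif sites on the sense strand.

    The window is centered on the 4-mer: (window - 4) / 2 nt each side.
    Sites too close to a contig edge (or with ambiguous bases) are
    skipped with a warning.
    """
    genome = load_genome(genome_source)
    up = (window - 4) // 2
    down = window - 4 - up
    seqs = []
    skipped = 0
    t = c = 0
    match = 0
    for site in sites:
        chrom_seq = genome[site.chrom]
        if site.strand == "-":
            lo, hi = site.a_pos - 3 - down, site.a_pos + 1 + up
        else:
            lo, hi = site.a_pos - up, site.a_pos + 4 + down
        if lo < 0 or hi > len(chrom_seq):
            warnings.warn(f"site {site.site_id} too close to contig edge; skipped")
            skipped += 1
            continue
        seq = sense_sequence(genome, site.chrom, lo, hi, site.strand)
        if set(seq) - set(BASES):
            warnings.warn(f"site {site.site_id} has ambiguous bases; skipped")
            skipped += 1
            continue
        seqs.append(seq)
        tract = seq[up - upstream:up]
        t += tract.count("T")
        c += tract.count("C")
        if seq[up:up + 8] == "AGGTAAGT":
            match += 1
    if not seqs:
        raise ValueError("no usable sites for context statistics")
    counts = np.zeros((4, window))
    for seq in seqs:
        for i, b in enumerate(seq):
            counts[_B2I[b], i] += 1
    freq = pd.DataFrame(counts / len(seqs), index=list(BASES),
                        columns=range(1, window + 1))
    denom = len(seqs) * upstream
    return ContextStats(
        freq_matrix=freq,
        pct_t=100.0 * t / denom,
        pct_c=100.0 * c / denom,
        pct_pyrimidine=100.0 * (t + c) / denom,
        consensus_match_fraction=match / len(seqs),
        n_sites=len(seqs),
        n_skipped=skipped)
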