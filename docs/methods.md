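# Methods

This note documents the models, defaults, and design choices behind
`rsdetect`, and what the simulator-based tests do and do not
demonstrate about real data.

## Coordinate and strand conventions

All in-memory coordinates are 0-based half-open on the reference; every
exported table is 1-based inclusive.  "Sense" coordinates count in the
direction of transcription, so for a minus-strand gene sense offset 0
is the highest reference coordinate.  A motif site's `a_pos` is the
reference position of the sense-strand A of the `AGNN` 4-mer; the
acceptor boundary (the first retained base of the splicing
intermediate) is sense `a_pos + 2`, i.e. the G of the reconstituted GT.
Junction matching is exact: aligners report junction boundaries
precisely, so no positional tolerance is applied.  On minus-strand
genes the acceptor side of a junction is the lower-coordinate gap edge,
and all window arithmetic is done in sense space.

Library strandedness (`forward` / `reverse` / `unstranded`) is a
configuration flag.  When stranded, junction reads must match the host
gene's strand and coverage is taken from the matching read strand only.

## Gene models and quantification

Exons are collapsed (interval union) across all transcripts of a gene;
introns are the gaps, with strand-aware ordinals (ordinal 1 = 5'-most
in transcription direction).  FPKM normalizes exonic read counts to
collapsed exonic kilobases and depth in millions of uniquely mapped
reads; RPM is count / depth × 1e6.  For the exonic/intronic/intergenic
partition, a read is exonic if any aligned block overlaps a collapsed
exon on its assigned strand, else intronic if it overlaps a gene span,
else intergenic; reads straddling an exon boundary therefore count as
exonic, and a read inside two genes counts once.  This rule is
deterministic; majority-overlap alternatives differ negligibly on the
data this tool targets.

## The filter cascade

Filters are applied in a fixed, recorded order (each candidate carries
a `filter_trace`): host intron length, mRNA enrichment, junction count,
then the coverage pattern.  Defaults:

| parameter | RS pipeline | cryptic pipeline | unit |
|---|---|---|---|
| minimum host intron | 1,000 | 50,000 | nt |
| enrichment (total vs mRNA pooled RPM, strict >) | 2-fold | 1-fold | — |
| merged up-junction count | ≥ 10 | ≥ 10 | reads |
| merged down-junction count | — | ≥ 2 | reads |
| down-junction scan window | 350 | 350 | nt |

Replicates are merged at the read level: merged count = Σ counts,
pooled RPM = Σ counts / Σ depths × 1e6.  The enrichment decision uses
strict inequality on pooled RPM, so a zero mRNA count needs no
pseudocount (fold = +inf); the *reported* fold adds 0.5 reads to the
mRNA side only, to keep display values finite.  Pooling across
replicates (rather than requiring every replicate to pass) is more
powerful at low counts and matches the merged-count convention.

The modal down-junction donor defines the RS-exon 3' end; ties are
broken toward the donor closest to the site (deterministic).

## Saw-tooth and exon-likeness statistics

Under steady-state co-transcriptional splicing, the expected nascent
coverage at an intron position is proportional to the distance to its
segment's downstream splice point plus a lag `d` (the residence time
of the cleaved segment).  Coverage therefore declines linearly toward
each splice point and steps up immediately after an RS site.  The step
statistic is

    score = log2((mean depth over W nt sense-downstream of the site + ε)
               / (mean depth over W nt sense-upstream + ε))

with defaults `W = 5000` nt (RS introns are tens of kilobases, so a
5 kb flank averages over noise while staying inside one segment) and
`ε = 0.1` reads/base (guards against division blow-ups in sparse
introns).  Both flanks must additionally show a declining rank trend
(Spearman ρ ≤ −0.3 on 200-nt bins) to set the `trend_ok` flag; Spearman
is used for robustness to depth spikes.  When a flank is shorter than
W the window shrinks and the result is flagged.  The statistic is
antisymmetric under reversing the profile about the site (ε = 0,
equal flanks).

Exon-likeness is the log2 ratio of mean depth inside the putative exon
(acceptor to the observed down-junction donor, or 350 nt when no donor
was observed) to the mean of the two flanking 5-kb windows.

Classification replaces manual inspection of browser tracks with
thresholds calibrated on the simulator: τ_saw = 1.0 log2 units (planted
saw-tooth sites score ≈ 2.5 at the default geometry, flat or exon-like
profiles < 0.7), τ_exon = 1.0 (planted coverage islands score ≈ 3,
saw-tooth sites ≤ ~1), τ_bg = 0.05 reads/base for calling a covered
intron "nascent".  Every call also exports its raw evidence numbers so
a human can re-inspect borderline cases, mirroring the visual-inspection
workflow the statistic automates.  Any claim about real data must
report these thresholds, since no quantitative community standard for
"a clear saw-tooth" exists.

## Splice-site scoring

Donor 9-mers are laid out `3 exon nt + GT + 4 nt`, acceptor 23-mers
`18 nt + AGGT + 1 nt` (AG at positions 19–20).  The r5'SS fuses the
last 30 nt (logo flavour) or 3 nt (9-mer flavour) of the upstream
collapsed exon to the GT of the site's 4-mer; upstream exons shorter
than the logo width are left-padded with N (excluded from logo
counts).  For sites without observed down-junctions, the Down 5'SS is
built at the best-scoring GT donor in the 350-nt window (first GT when
no model is supplied) and flagged `best_window_donor`, versus
`observed_junction` otherwise.

Scoring models are pluggable because published maximum-entropy scores
come from external parameter sets: the package loads log-odds tables
verbatim when provided, and otherwise trains a weight-matrix or
first-order-Markov model from the annotated GT donors and AG acceptors
of the supplied annotation, with the genome-wide mononucleotide
composition as background and scores in log2 units.  Absolute values
are model-specific; every internal decision reduces to score
comparisons, which any monotone transform preserves.

Smoothing: pseudocounts are applied at an effective sample size equal
to the number of *distinct* training sequences — position frequencies
`(f·K + 1) / (K + 4)` with `K = |distinct|`.  This keeps the model a
function of training *frequencies* (duplicating every training
sequence changes nothing) while reproducing classic add-one behaviour
on small sets.

Context statistics use a 64-nt sense window centered on the 4-mer
(30 + 4 + 30), report the per-position base-frequency matrix, %T / %C /
%pyrimidine in the 20 nt upstream of the A (the polypyrimidine tract
position), and the fraction of sites matching the U1-complementary
`AGGTAAGT` consensus.  Sites too close to a contig edge are skipped
with a warning.

## The simulator

The simulator is dimensioned roughly ten-fold below mammalian scale so
an end-to-end run takes seconds: one gene per chromosome, three
300-nt exons, a long first intron (52 kb for RS/decoy genes, 55 kb for
cryptic genes — long enough that the 50-kb cryptic filter is exercised
on both classes), a 2-kb second intron, and 5-kb intergenic flanks.
Defaults: 5 RS genes, 3 cryptic genes, 1 decoy gene, alternating
strands.

Planted features: RS sites carry the `AGGTAAGT` consensus and a 20-nt
polypyrimidine tract, placed at 45% of the first intron; every second
RS site also gets a strong planted down-donor (`GTAAGT`) 80–300 nt
downstream and 3–12 down-junction reads.  Cryptic exons are 150-nt
islands with a deliberately weak r5'SS context and a strong `GTAAGT`
Down 5'SS; their up/down counts are drawn positively correlated
(down ≈ 0.3 × up), so the up/down Pearson correlation is positive by
construction.  The decoy site is an `AGGT` with 11 planted up-junction
reads in a covered intron without any planted coverage pattern — it
passes every count filter and must be rejected by classification.
Annotated intron boundaries carry `GTAAGT` donors and polypyrimidine
`...AG` acceptors so that annotation-trained scoring models are
non-degenerate.

Reads are single-end 100 nt, error-free, emitted directly as
coordinate-sorted SAM from truth (no aligner).  Nascent intron read
starts are drawn with density ∝ (distance to the segment's downstream
splice point + d), d = 2 kb, at 30× mean intron depth by default;
cryptic introns carry flat 4× background with a 10× island over the
exon.  Exonic reads are added so the intronic read fraction of the
total-RNA sample is 0.77 by construction, and the mRNA control gets
the same number of exon-confined reads plus 2% annotated junction
reads and no intronic or RS-junction reads.  Planted junction-read
counts are emitted exactly and split round-robin across replicates, so
replicate-merged counts equal the truth.  The closed-form expectation
used to validate the saw-tooth statistic is the same start density
convolved with the read length — an analytic function of the
configuration, independent of the sampled reads.

What the simulator does **not** model: sequencing errors, multimapping
and mapping bias, fragment-length distributions, PCR duplicates,
expression heterogeneity across genes, overlapping genes, alternative
transcript structure, and spurious junction reads at non-planted sites.
Passing the recovery tests therefore demonstrates the correctness of
the bookkeeping and the discriminative geometry of the statistics under
the stated noise model, not detection performance on real libraries.

## Problem sizes and numerical choices

The default test world is ~0.6 Mb of genome and ~1.7 × 10⁵ reads; the
acceptance run uses 14 genes (~1.1 Mb, ~2.4 × 10⁵ reads) plus a
dedicated 50×-depth single-gene world for the saw-tooth closed-form
comparison and a 40×-depth uniform-coverage world for the flat-intron
calibration (at 5-kb windows and 100-nt reads, the sampling standard
deviation of the log2 ratio is ≈ 0.45 / √(depth × 50), so 40×
background puts the ±0.1 band at roughly two standard deviations).
All simulator randomness flows from a single integer seed through
fixed-derivation substreams; identical seeds give byte-identical FASTA,
GTF, SAM, and TSV outputs.

## Known limitations

* Thresholds τ_saw/τ_exon/τ_bg are calibrated on the simulator's noise
  model; real introns with irregular coverage may need per-dataset
  tuning, which is why every call ships its evidence values.
* The fallback scoring models are not maximum-entropy models and do
  not reproduce published absolute scores; use loaded tables for
  cross-study comparability of score values.
* The background set for context contrasts (non-RS AGGT sites) is an
  explicit input; the package does not impose a particular choice.
* Intron ordinals and intron lengths come from collapsed exons, so
  genes whose transcripts disagree wildly on exon boundaries get
  conservative (shortest-gap) introns.
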