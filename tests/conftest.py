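"""Shared fixtures: a session-scoped simulated world with known truth."""

from types import SimpleNamespace

import pysam
import pytest

from rsdetect import simulate as sim
from rsdetect.pipeline import load_inputs, run_cryptic_pipeline, run_rs_pipeline

WORLD_SEED = 11


@pytest.fixture(scope="session")
def world(tmp_path_factory):
    """Default simulated world: 5 RS genes, 3 cryptic genes, 1 decoy gene."""
    out = tmp_path_factory.mktemp("world")
    truth = sim.generate_reference(seed=WORLD_SEED)
    fasta = sim.write_fasta(truth, out / "genome.fa")
    gtf = sim.write_gtf(truth, out / "annotation.gtf")
    data = sim.simulate_reads(truth, sim.ReadConfig(), outdir=out,
                              seed=WORLD_SEED)
    totals = {s: p for s, p in data.sample_paths.items()
              if s.startswith("total")}
    mrnas = {s: p for s, p in data.sample_paths.items()
             if s.startswith("mrna")}
    inputs = load_inputs(fasta, gtf, totals, mrnas)
    return SimpleNamespace(truth=truth, data=data, inputs=inputs,
                           fasta=fasta, gtf=gtf, outdir=out,
                           totals=totals, mrnas=mrnas)


@pytest.fixture(scope="session")
def rs_result(world):
    return run_rs_pipeline(world.inputs)


@pytest.fixture(scope="session")
def cryptic_result(world):
    return run_cryptic_pipeline(world.inputs)


@pytest.fixture()
def sam_writer(tmp_path):
    """Write simple single-block/spliced reads to a SAM file."""

    def write(name, references, reads):
        # reads: iterable of (chrom, pos, cigartuples, is_reverse)
        path = tmp_path / f"{name}.sam"
        header = {"HD": {"VN": "1.6"},
                  "SQ": [{"SN": c, "LN": ln} for c, ln in references.items()]}
        tid = {c: i for i, c in enumerate(references)}
        with pysam.AlignmentFile(str(path), "wh", header=header) as out:
            for i, (chrom, pos, cigar, rev) in enumerate(reads):
                a = pysam.AlignedSegment(out.header)
                a.query_name = f"read{i}"
                a.flag = 16 if rev else 0
                a.reference_id = tid[chrom]
                a.reference_start = pos
                a.mapping_quality = 255
                a.cigartuples = cigar
                a.query_sequence = "A" * sum(
                    ln for op, ln in cigar if op in (0, 1, 4, 7, 8))
                out.write(a)
        return path

    return write
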