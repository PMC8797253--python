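"""CIGAR junction extraction and up/down junction counting rules."""

import re

import numpy as np
import pysam
import pytest

from rsdetect.gene_models import SampleDepth, build_gene_model
from rsdetect.junctions import (CigarError, JunctionRecord, combine_counts,
                                count_down_junctions, count_up_junctions,
                                extract_junctions, rpm, walk_cigar)
from rsdetect.motif_scan import MotifSite

_CIG_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_OPS = "MIDNSHP=X"


def string_walk_oracle(pos, cigar_string):
    """Independent regex-based CIGAR walk over the raw string."""
    ref = pos
    gaps = []
    for num, op in _CIG_RE.findall(cigar_string):
        n = int(num)
        if op in "MD=X":
            ref += n
        elif op == "N":
            gaps.append((ref - 1, ref + n))
            ref += n
    return gaps


def random_cigar(rng):
    """Random valid CIGAR starting and ending with M."""
    parts = [f"{rng.integers(1, 80)}M"]
    for _ in range(rng.integers(0, 5)):
        op = "MIDNS"[rng.integers(0, 5)]
        parts.append(f"{rng.integers(1, 200)}{op}")
        parts.append(f"{rng.integers(1, 80)}M")
    return "".join(parts)


def segments_from_cigars(cigars_with_pos, chrom="c", length=10_000_000):
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": chrom, "LN": length}]})
    segs = []
    for i, (pos, cig) in enumerate(cigars_with_pos):
        a = pysam.AlignedSegment(header)
        a.query_name = f"r{i}"
        a.reference_id = 0
        a.reference_start = pos
        a.mapping_quality = 255
        a.cigarstring = cig
        qlen = sum(int(n) for n, op in _CIG_RE.findall(cig) if op in "MIS=X")
        a.query_sequence = "A" * qlen
        segs.append(a)
    return segs


class TestExtract:
    def test_no_junction(self):
        assert walk_cigar(1000, [(0, 50)]) == []

    def test_manual_walk(self):
        # 20M100N30M at 0-based pos 1000 -> donor 1019, acceptor 1120
        gaps = walk_cigar(1000, [(0, 20), (3, 100), (0, 30)])
        assert gaps == [(1019, 1120)]
        # 1-based reporting convention adds one to each
        assert (gaps[0][0] + 1, gaps[0][1] + 1) == (1020, 1121)

    def test_two_gaps_one_read(self):
        gaps = walk_cigar(0, [(0, 10), (3, 50), (0, 10), (3, 50), (0, 10)])
        assert gaps == [(9, 60), (69, 120)]

    def test_unknown_op_is_error_with_read_id(self):
        with pytest.raises(CigarError, match="readX"):
            walk_cigar(0, [(0, 10), (11, 5)], "readX")

    def test_matches_string_oracle_on_randomized_cigars(self):
        rng = np.random.default_rng(42)
        cigars = [(int(rng.integers(0, 10000)), random_cigar(rng))
                  for _ in range(300)]
        records = extract_junctions(segments_from_cigars(cigars))
        expect = []
        for pos, cig in cigars:
            expect.extend(string_walk_oracle(pos, cig))
        assert [(r.donor_end, r.acceptor_start) for r in records] == expect

    def test_per_gap_emission_counts(self):
        segs = segments_from_cigars([(0, "10M50N10M50N10M"), (0, "30M")])
        assert len(extract_junctions(segs)) == 2


class TestRpm:
    def test_arithmetic(self):
        assert rpm(10, 5_000_000) == pytest.approx(2.0)
        assert rpm(0, 5_000_000) == 0.0
        assert rpm(30, 15_000_000) == rpm(10, 5_000_000)

    def test_bad_depth(self):
        with pytest.raises(ValueError):
            rpm(1, 0)


def _plus_world():
    """Plus-strand gene, exons [100,200) and [1000,1100), AGGT at 500."""
    gene = build_gene_model("g", "c", "+", [(100, 200), (1000, 1100)])
    site = MotifSite(chrom="c", a_pos=500, strand="+", motif="AGGT",
                     gene_id="g", acceptor_pos=502, intron_ordinal=1,
                     intron_length=800)
    return {"g": gene}, site


def _minus_world():
    """Minus-strand gene; sense 5' exon is [1000,1100), AGGT sense A at 500."""
    gene = build_gene_model("g", "c", "-", [(100, 200), (1000, 1100)])
    site = MotifSite(chrom="c", a_pos=500, strand="-", motif="AGGT",
                     gene_id="g", acceptor_pos=498, intron_ordinal=1,
                     intron_length=800)
    return {"g": gene}, site


DEPTHS = {"t": SampleDepth("t", 1_000_000, "total_rna")}


def _count_up(models, site, junctions):
    return count_up_junctions({"t": junctions}, [site], models, DEPTHS,
                              strandedness="unstranded")[site.site_id]


class TestUpJunctions:
    def test_exact_acceptor_and_exon_end_donor(self):
        models, site = _plus_world()
        j = JunctionRecord("c", 199, 502, "+", "r1")
        assert _count_up(models, site, [j]).up_count["t"] == 1

    def test_off_by_one_acceptor_rejected(self):
        models, site = _plus_world()
        j = JunctionRecord("c", 199, 503, "+", "r1")
        assert _count_up(models, site, [j]).up_count["t"] == 0

    def test_mid_exon_donor_rejected(self):
        models, site = _plus_world()
        j = JunctionRecord("c", 150, 502, "+", "r1")
        assert _count_up(models, site, [j]).up_count["t"] == 0

    def test_minus_strand_roles_swap(self):
        models, site = _minus_world()
        # sense donor = upstream exon sense 3' end = reference start 1000;
        # sense acceptor = first retained base = reference 498
        good = JunctionRecord("c", 498, 1000, "-", "r1")
        bad = JunctionRecord("c", 497, 1000, "-", "r2")
        counts = _count_up(models, site, [good, bad])
        assert counts.up_count["t"] == 1

    def test_missing_depth_is_error(self):
        models, site = _plus_world()
        with pytest.raises(ValueError, match="depth"):
            count_up_junctions({"x": []}, [site], models, DEPTHS)

    def test_planted_counts_recovered_exactly(self, world, rs_result):
        by_key = {c.site.key: c for c in rs_result.site_counts.values()}
        for planted in world.truth.sites:
            counts = rs_result.site_counts[
                next(sid for sid, c in rs_result.site_counts.items()
                     if c.site.key == planted.key)]
            merged_up = sum(v for s, v in counts.up_count.items()
                            if s.startswith("total"))
            merged_down = sum(v for s, v in counts.down_count.items())
            assert merged_up == planted.up_count
            assert merged_down == planted.down_count
            assert counts.up_count.get("mrna_1", 0) == 0
            if planted.down_count:
                assert counts.down_donor_pos == planted.down_donor_pos


class TestDownJunctions:
    def _count(self, models, site, junctions, window=350):
        return count_down_junctions({"t": junctions}, [site], models, DEPTHS,
                                    window=window,
                                    strandedness="unstranded")[site.site_id]

    def test_window_boundary(self):
        models, site = _plus_world()
        at_350 = JunctionRecord("c", 852, 1000, "+", "r1")   # 502 + 350
        at_351 = JunctionRecord("c", 853, 1000, "+", "r2")
        counts = self._count(models, site, [at_350, at_351])
        assert counts.down_count["t"] == 1
        assert counts.down_donor_pos == 852

    def test_acceptor_must_be_exon_start(self):
        models, site = _plus_world()
        j = JunctionRecord("c", 600, 1001, "+", "r1")
        assert self._count(models, site, [j]).down_count["t"] == 0

    def test_modal_donor(self):
        models, site = _plus_world()
        js = ([JunctionRecord("c", 600, 1000, "+", f"a{i}") for i in range(5)]
              + [JunctionRecord("c", 650, 1000, "+", f"b{i}") for i in range(3)])
        counts = self._count(models, site, js)
        assert counts.down_count["t"] == 8
        assert counts.down_donor_pos == 600

    def test_modal_tie_breaks_toward_site(self):
        models, site = _plus_world()
        js = ([JunctionRecord("c", 600, 1000, "+", f"a{i}") for i in range(3)]
              + [JunctionRecord("c", 650, 1000, "+", f"b{i}") for i in range(3)])
        assert self._count(models, site, js).down_donor_pos == 600

    def test_minus_strand_window(self):
        models, site = _minus_world()
        # sense donor 100 nt past the acceptor (498) = reference 398;
        # downstream exon (sense) = [100,200), sense start = ref 199
        good = JunctionRecord("c", 199, 398, "-", "r1")
        counts = self._count(models, site, [good])
        assert counts.down_count["t"] == 1
        assert counts.down_donor_pos == 398

    def test_combine_counts_merges_sides(self):
        models, site = _plus_world()
        up = _count_up(models, site, [JunctionRecord("c", 199, 502, "+", "u")])
        down = self._count(models, site,
                           [JunctionRecord("c", 600, 1000, "+", "d")])
        both = combine_counts({site.site_id: up}, {site.site_id: down})
        rec = both[site.site_id]
        assert rec.up_count["t"] == 1 and rec.down_count["t"] == 1
        assert rec.down_donor_pos == 600


def test_up_counts_bounded_by_junction_total(world, rs_result):
    # a junction record supports at most one site per gene
    for sample, junctions in world.inputs.junctions_by_sample.items():
        total = sum(c.up_count.get(sample, 0)
                    for c in rs_result.site_counts.values())
        assert total <= len(junctions)
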