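"""r5'SS / Down 5'SS assembly, cryptic-exon calling, up/down correlation."""

import pytest

from rsdetect.config import PipelineThresholds
from rsdetect.gene_models import SampleDepth, build_gene_model
from rsdetect.intermediates import (build_splice_site_sequences,
                                    call_cryptic_exons, up_down_correlation)
from rsdetect.junctions import SiteJunctionCounts
from rsdetect.motif_scan import MotifSite
from rsdetect.sawtooth import SawtoothEvidence, SawtoothResult
from rsdetect.splice_scoring import train_wmm

TH = PipelineThresholds()


def toy_gene(seq_len=600, context="AGGTAAGT"):
    """Plus-strand gene: exon [0,40), intron [40,500), exon [500,540)."""
    seq = list("A" * seq_len)
    seq[37:40] = "ACG"            # upstream exon 3' end
    seq[100:108] = context        # the RS site and its context
    genome = {"c": "".join(seq)}
    models = {"g": build_gene_model("g", "c", "+", [(0, 40), (500, 540)])}
    site = MotifSite(chrom="c", a_pos=100, strand="+", motif="AGGT",
                     gene_id="g", acceptor_pos=102, intron_ordinal=1,
                     intron_length=460)
    return genome, models, site


class TestSequenceAssembly:
    def test_r5ss_hand_assembly(self):
        genome, models, site = toy_gene()
        out = build_splice_site_sequences(site, models, genome)
        assert out.r5ss_maxent == "ACGGTAAGT"
        assert len(out.r5ss_logo) == 52
        assert out.r5ss_logo[30:32] == "GT"
        assert out.r5ss_logo[27:36] == out.r5ss_maxent

    def test_nine_mer_embedded_in_logo(self):
        genome, models, site = toy_gene()
        out = build_splice_site_sequences(site, models, genome,
                                          down_donor_pos=250)
        assert out.r5ss_logo[27:36] == out.r5ss_maxent
        assert out.down5ss_logo[27:36] == out.down5ss_maxent

    def test_observed_down_donor_hand_assembly(self):
        genome, models, site = toy_gene()
        seq = list(genome["c"])
        seq[248:251] = "AAG"      # RS-exon 3' end ...AAG
        seq[251:257] = "GTAAGA"   # | GTAAGA intron
        genome = {"c": "".join(seq)}
        out = build_splice_site_sequences(site, models, genome,
                                          down_donor_pos=250)
        assert out.down5ss_maxent == "AAGGTAAGA"
        assert out.down_donor_source == "observed_junction"
        assert out.down_donor_pos == 250

    def test_best_window_donor_uses_model(self):
        genome, models, site = toy_gene(context="AGGTCCCC")
        seq = list(genome["c"])
        seq[151:157] = "GTCCCC"   # weak donor candidate at 150
        seq[221:227] = "GTAAGT"   # strong (consensus) candidate at 220
        genome = {"c": "".join(seq)}
        model = train_wmm(["AAGGTAAGT"], ["T" * 18 + "AG" + "GTA"])
        out = build_splice_site_sequences(site, models, genome,
                                          donor_model=model)
        assert out.down_donor_source == "best_window_donor"
        assert out.down_donor_pos == 220
        # without a model the first GT in the window wins
        out2 = build_splice_site_sequences(site, models, genome)
        assert out2.down_donor_pos == 150

    def test_no_gt_in_window_yields_none(self):
        genome, models, site = toy_gene(context="AGGTCCCC")
        out = build_splice_site_sequences(site, models, genome)
        assert out.down5ss_maxent is None
        assert out.down_donor_source == "none"

    def test_short_upstream_exon_left_pads(self):
        seq = "AA" + "C" * 98 + "AGGTAAGT" + "C" * 492
        genome = {"c": seq}
        models = {"g": build_gene_model("g", "c", "+", [(0, 2), (500, 540)])}
        site = MotifSite(chrom="c", a_pos=100, strand="+", motif="AGGT",
                         gene_id="g", acceptor_pos=102, intron_ordinal=1,
                         intron_length=398)
        out = build_splice_site_sequences(site, models, genome)
        assert out.r5ss_maxent == "NAAGTAAGT"
        assert out.r5ss_logo.startswith("N" * 28)

    def test_minus_strand_consistency_with_planted_truth(self, world):
        planted = next(p for p in world.truth.sites_of_kind("cryptic")
                       if p.strand == "-")
        site = MotifSite(chrom=planted.chrom, a_pos=planted.a_pos,
                         strand="-", motif="AGGT", gene_id=planted.gene_id,
                         acceptor_pos=planted.acceptor_pos, intron_ordinal=1,
                         intron_length=55000)
        out = build_splice_site_sequences(
            site, world.truth.genes, world.truth.genome,
            down_donor_pos=planted.down_donor_pos)
        assert out.r5ss_maxent[3:5] == "GT"
        assert out.down5ss_maxent[3:5] == "GT"
        # the planted strong donor context is recovered on the sense strand
        assert out.down5ss_maxent[3:9] == "GTAAGT"


DEPTHS = {
    "t1": SampleDepth("t1", 10_000_000, "total_rna"),
    "m1": SampleDepth("m1", 10_000_000, "mrna_control"),
}


def cryptic_counts(up, down, intron_length=60000):
    site = MotifSite(chrom="c", a_pos=100000, strand="+", motif="AGGT",
                     gene_id="g", acceptor_pos=100002, intron_ordinal=1,
                     intron_length=intron_length)
    c = SiteJunctionCounts(site=site, up_count={"t1": up, "m1": 0},
                           down_count={"t1": down}, down_donor_pos=100150)
    return {site.site_id: c}


def evidence_for(counts, saw, exon):
    res = SawtoothResult(score=saw, up_mean=1, down_mean=1, w_up=5000,
                         w_down=5000, rho_up=0, rho_down=0, trend_ok=False,
                         shrunk=False)
    return {sid: SawtoothEvidence(site_id=sid, sawtooth=res,
                                  exon_score=exon, background_mean=1.0)
            for sid in counts}


class TestCrypticCalls:
    def test_exon_like_candidate_called(self):
        counts = cryptic_counts(12, 4)
        calls = call_cryptic_exons(counts, DEPTHS, TH,
                                   evidence_for(counts, 0.3, 3.0))
        assert len(calls) == 1
        assert calls[0].classification == "cryptic_exon"
        assert calls[0].exon_end_donor == 100150

    def test_too_few_down_junctions(self):
        counts = cryptic_counts(12, 1)
        assert call_cryptic_exons(counts, DEPTHS, TH,
                                  evidence_for(counts, 0.3, 3.0)) == []

    def test_sawtooth_pattern_vetoes(self):
        counts = cryptic_counts(12, 4)
        assert call_cryptic_exons(counts, DEPTHS, TH,
                                  evidence_for(counts, 2.5, 3.0)) == []

    def test_short_intron_excluded(self):
        counts = cryptic_counts(12, 4, intron_length=20000)
        assert call_cryptic_exons(counts, DEPTHS, TH,
                                  evidence_for(counts, 0.3, 3.0)) == []

    def test_world_recovery_and_disjointness(self, world, rs_result,
                                             cryptic_result):
        planted = {p.key for p in world.truth.sites_of_kind("cryptic")}
        called = {c.site.key for c in cryptic_result.calls}
        assert called == planted
        rs_called = {c.site.key for c in rs_result.calls
                     if c.classification == "RS"}
        assert not (called & rs_called)

    def test_world_donor_matches_planted_exon_end(self, world, cryptic_result):
        by_key = {p.key: p for p in world.truth.sites_of_kind("cryptic")}
        for call in cryptic_result.calls:
            assert call.exon_end_donor == by_key[call.site.key].down_donor_pos


class TestUpDownCorrelation:
    def test_proportional_is_one(self):
        r, _ = up_down_correlation([(10, 3), (20, 6), (30, 9)])
        assert r == pytest.approx(1.0)

    def test_anti_ordered_is_minus_one(self):
        r, _ = up_down_correlation([(1, 3), (2, 2), (3, 1)])
        assert r == pytest.approx(-1.0)

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            up_down_correlation([(1, 2), (2, 1)])

    def test_zero_variance(self):
        with pytest.raises(ValueError):
            up_down_correlation([(1, 2), (1, 3), (1, 4)])
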