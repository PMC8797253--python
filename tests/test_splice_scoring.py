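"""Splice-site scoring models, table round-trip, and context statistics."""

import math

import numpy as np
import pytest

from rsdetect.splice_scoring import (TableFormatError, context_stats,
                                     load_scoring_tables, save_scoring_tables,
                                     score_acceptor, score_donor,
                                     train_from_annotation, train_markov1,
                                     train_wmm)
from rsdetect.motif_scan import MotifSite

ACCEPTOR_OK = "T" * 18 + "AG" + "GTA"   # 23-mer with AG at 19-20


def random_nine_mers(rng, n):
    out = []
    for _ in range(n):
        s = "".join(rng.choice(list("ACGT"), size=9))
        out.append(s[:3] + "GT" + s[5:])
    return out


class TestWmm:
    def test_single_sequence_hand_arithmetic(self):
        # one training 9-mer, uniform background, add-one smoothing:
        # matching base freq = (1+1)/(1+4) = 0.4 at each position
        model = train_wmm(["CAGGTAAGT"], [ACCEPTOR_OK])
        expected = 9 * math.log2(0.4 / 0.25)
        assert score_donor(model, "CAGGTAAGT") == pytest.approx(expected)

    def test_duplication_invariance(self):
        donors = ["CAGGTAAGT", "AAGGTCAGT", "TTGGTAAGC"]
        m1 = train_wmm(donors, [ACCEPTOR_OK])
        m2 = train_wmm(donors * 3, [ACCEPTOR_OK] * 3)
        rng = np.random.default_rng(0)
        for nine in random_nine_mers(rng, 20):
            assert score_donor(m1, nine) == pytest.approx(score_donor(m2, nine))

    def test_consensus_maximality_by_hill_climbing(self):
        rng = np.random.default_rng(1)
        model = train_wmm(random_nine_mers(rng, 50),
                          [ACCEPTOR_OK])
        mat = model.donor.log_odds
        consensus = "".join("ACGT"[i] for i in mat.argmax(axis=1))
        consensus = consensus[:3] + "GT" + consensus[5:]
        best = score_donor(model, consensus)
        for start in random_nine_mers(rng, 200):
            cur, cur_score = start, score_donor(model, start)
            improved = True
            while improved:
                improved = False
                for i in [0, 1, 2, 5, 6, 7, 8]:
                    for b in "ACGT":
                        cand = cur[:i] + b + cur[i + 1:]
                        s = score_donor(model, cand)
                        if s > cur_score:
                            cur, cur_score, improved = cand, s, True
            assert cur_score <= best + 1e-9

    def test_validation_errors(self):
        model = train_wmm(["CAGGTAAGT"], [ACCEPTOR_OK])
        with pytest.raises(ValueError, match="9 nt"):
            score_donor(model, "CAGGTAAGTT")
        with pytest.raises(ValueError, match="GT"):
            score_donor(model, "CAGCAAAGT")
        with pytest.raises(ValueError, match="23 nt"):
            score_acceptor(model, "AG")
        with pytest.raises(ValueError, match="AG"):
            score_acceptor(model, "T" * 18 + "CC" + "GTA")

    def test_pyrimidine_trained_acceptor_ordering(self):
        acceptors = ["TCTTTCTCTTTCCTTTCT" + "AG" + "GTA",
                     "TTTCCTTTCTTCTTTTTC" + "AG" + "GTA"]
        model = train_wmm(["CAGGTAAGT"], acceptors)
        py = score_acceptor(model, "T" * 18 + "AG" + "GTA")
        pu = score_acceptor(model, "A" * 18 + "AG" + "GTA")
        assert py > pu


class TestMarkov1:
    def test_duplication_invariance(self):
        donors = ["CAGGTAAGT", "AAGGTCAGT"]
        m1 = train_markov1(donors, [ACCEPTOR_OK])
        m2 = train_markov1(donors * 4, [ACCEPTOR_OK] * 4)
        assert score_donor(m1, "CAGGTAAGT") == pytest.approx(
            score_donor(m2, "CAGGTAAGT"))

    def test_scores_finite_and_deterministic(self):
        model = train_markov1(["CAGGTAAGT"], [ACCEPTOR_OK])
        s = score_donor(model, "TTTGTTTTT")
        assert math.isfinite(s)
        assert s == score_donor(model, "TTTGTTTTT")


class TestTables:
    def test_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(3)
        model = train_wmm(random_nine_mers(rng, 30), [ACCEPTOR_OK] * 2)
        path = tmp_path / "tables.tsv"
        save_scoring_tables(model, path)
        loaded = load_scoring_tables(path)
        assert loaded.kind == "loaded_tables"
        for nine in random_nine_mers(rng, 100):
            assert score_donor(loaded, nine) == pytest.approx(
                score_donor(model, nine))

    def test_missing_entry_is_error(self, tmp_path):
        rng = np.random.default_rng(4)
        model = train_wmm(random_nine_mers(rng, 5), [ACCEPTOR_OK])
        path = tmp_path / "tables.tsv"
        save_scoring_tables(model, path)
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[:-1]) + "\n")  # drop one record
        with pytest.raises(TableFormatError, match="incomplete"):
            load_scoring_tables(path)

    def test_malformed_line_is_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("donor\t1\tA\tnot-a-number\n")
        with pytest.raises(TableFormatError, match="line 1"):
            load_scoring_tables(path)


class TestAnnotationTraining:
    def test_trained_model_prefers_planted_consensus(self, world):
        model = train_from_annotation(world.truth.genes, world.truth.genome)
        # simulated annotated donors all carry the GTAAGT intron head
        strong = score_donor(model, "AAGGTAAGT")
        weak = score_donor(model, "AAGGTCCCC")
        assert strong > weak


def site_at(genome, a_pos, strand="+", chrom="c"):
    return MotifSite(chrom=chrom, a_pos=a_pos, strand=strand, motif="AGGT",
                     gene_id="g",
                     acceptor_pos=a_pos - 2 if strand == "-" else a_pos + 2)


class TestContextStats:
    def test_hand_counted_composition(self):
        seq = "G" * 10 + "TCTCTCTCTCTCTCTCTCTC" + "AGGTAAGT" + "G" * 40
        genome = {"c": seq}
        stats = context_stats([site_at(genome, 30)], genome)
        assert stats.pct_t == pytest.approx(50.0)
        assert stats.pct_c == pytest.approx(50.0)
        assert stats.pct_pyrimidine == pytest.approx(100.0)
        assert stats.consensus_match_fraction == 1.0

    def test_all_t_upstream(self):
        seq = "G" * 10 + "T" * 20 + "AGGTCCCC" + "G" * 40
        genome = {"c": seq}
        stats = context_stats([site_at(genome, 30)], genome)
        assert stats.pct_t == pytest.approx(100.0)
        assert stats.consensus_match_fraction == 0.0

    def test_frequency_columns_sum_to_one(self, world):
        sites = [site_at(world.truth.genome, p.a_pos, p.strand, p.chrom)
                 for p in world.truth.sites]
        stats = context_stats(sites, world.truth.genome)
        assert np.allclose(stats.freq_matrix.sum(axis=0), 1.0)
        assert stats.freq_matrix.shape == (4, 64)
        # the planted polypyrimidine tract dominates upstream composition
        assert stats.pct_pyrimidine > 60.0

    def test_edge_site_skipped_with_warning(self):
        genome = {"c": "AGGT" + "C" * 100}
        with pytest.warns(UserWarning, match="edge"):
            with pytest.raises(ValueError):
                context_stats([site_at(genome, 0)], genome)
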