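"""Consensus calling, BLOSUM62 conservation scoring, and epitope mapping."""

import numpy as np
import pytest

from allerprofile import conservation as cons
from allerprofile import synthetic as syn


def column_oracle(row, consensus, matrix, cutoff):
    """Independent per-column tally of the similarity classification."""
    identical = similar = dissimilar = excluded = 0
    for r, s in zip(row, consensus):
        if s == "X" or (r == "-" and s == "-"):
            excluded += 1
        elif r == s:
            identical += 1
        elif r == "-" or s == "-":
            dissimilar += 1
        elif matrix.scores[r, s] >= cutoff:
            similar += 1
        else:
            dissimilar += 1
    denom = len(row) - excluded
    percent = (identical + similar) / denom * 100 if denom else float("nan")
    return percent, identical, similar, dissimilar, excluded


class TestReadAlignment:
    FASTA = ">CF\nMKT-LI\n>PP\nMKTALI\n>SP\nMRTALI\n"
    CLUSTAL = (
        "CLUSTAL W multiple sequence alignment\n\n"
        "CF  MKT-LI\nPP  MKTALI\nSP  MRTALI\n"
    )

    def test_fasta_and_clustal_give_identical_blocks(self, tmp_path):
        fa = tmp_path / "a.fasta"
        fa.write_text(self.FASTA)
        cl = tmp_path / "a.aln"
        cl.write_text(self.CLUSTAL)
        block_fa = cons.read_alignment(fa, "fasta")
        block_cl = cons.read_alignment(cl, "clustal")
        assert block_fa.seq_ids == block_cl.seq_ids == ["CF", "PP", "SP"]
        assert block_fa.rows == block_cl.rows

    def test_ragged_row_rejected_with_id(self):
        with pytest.raises(ValueError, match="shorty"):
            cons.AlignmentBlock(["ok", "shorty"], ["MKTAL", "MKT"])

    def test_unknown_characters_listed(self):
        with pytest.raises(ValueError, match=r"[JZ]"):
            cons.AlignmentBlock(["a", "b"], ["MKJZL", "MKTAL"])


class TestConsensus:
    def test_unanimous_column(self):
        a = cons.AlignmentBlock(list("abcdef"), ["A"] * 6)
        assert cons.build_consensus(a).sequence == "A"

    def test_majority_four_of_six_at_default_threshold(self):
        a = cons.AlignmentBlock(list("abcdef"), ["K", "K", "K", "K", "R", "R"])
        c = cons.build_consensus(a)
        assert c.threshold_count == 4  # floor(6/2)+1
        assert c.sequence == "K"

    def test_three_three_split_is_ambiguous(self):
        a = cons.AlignmentBlock(list("abcdef"), ["K", "K", "K", "R", "R", "R"])
        assert cons.build_consensus(a).sequence == "X"

    def test_gap_counts_as_a_symbol(self):
        a = cons.AlignmentBlock(list("abcdef"), ["-", "-", "-", "-", "R", "R"])
        assert cons.build_consensus(a).sequence == "-"

    def test_threshold_above_row_count_rejected(self):
        a = cons.AlignmentBlock(["a", "b"], ["K", "K"])
        with pytest.raises(ValueError):
            cons.build_consensus(a, threshold_count=3)

    def test_deterministic_across_runs(self, toy_alignment):
        s1 = cons.build_consensus(toy_alignment).sequence
        s2 = cons.build_consensus(toy_alignment).sequence
        assert s1 == s2


class TestSimilarityToConsensus:
    def test_row_equal_to_consensus_scores_100(self, blosum62, toy_alignment):
        c = cons.build_consensus(toy_alignment)
        score = cons.similarity_to_consensus(c.sequence, c, blosum62)
        assert score.percent == pytest.approx(100.0)

    def test_all_similar_pairs_reach_100(self, blosum62):
        # K~R=2, I~L=2, D=D, E~Q=2 under BLOSUM62 -> everything identical/similar
        c = cons.ConsensusSequence("RLDQ", threshold_count=4)
        score = cons.similarity_to_consensus("KIDE", c, blosum62)
        assert (score.identical, score.similar) == (1, 3)
        assert score.percent == pytest.approx(100.0)

    def test_all_dissimilar_pairs_score_0(self, blosum62):
        c = cons.ConsensusSequence("WWWW", threshold_count=4)
        score = cons.similarity_to_consensus("PGPG", c, blosum62)
        assert score.percent == pytest.approx(0.0)
        assert score.dissimilar == 4

    def test_counts_partition_alignment_length(self, blosum62, rng):
        alphabet = list(cons.AMINO_ACIDS + "-")
        for _ in range(50):
            n = int(rng.integers(4, 30))
            rows = [
                "".join(rng.choice(alphabet, n)) for _ in range(4)
            ]
            try:
                a = cons.AlignmentBlock(list("abcd"), rows)
            except ValueError:
                continue
            c = cons.build_consensus(a)
            for row in rows:
                s = cons.similarity_to_consensus(row, c, blosum62)
                assert s.total_columns == n
                oracle = column_oracle(row, c.sequence, blosum62, 1)
                if np.isnan(oracle[0]):
                    assert not s.defined
                else:
                    assert s.percent == pytest.approx(oracle[0])
                assert (s.identical, s.similar, s.dissimilar, s.excluded) == oracle[1:]

    def test_raising_cutoff_never_increases_percent(self, blosum62, rng):
        a = syn.gen_protein_family(seed=17, length=120,
                                   epitope_regions=((20, 40),))
        c = cons.build_consensus(a)
        prev = None
        for cutoff in (0, 1, 2, 3, 5):
            percents = [
                cons.similarity_to_consensus(row, c, blosum62, cutoff).percent
                for row in a.rows
            ]
            if prev is not None:
                assert all(p <= q + 1e-12 for p, q in zip(percents, prev))
            prev = percents

    def test_length_mismatch_rejected(self, blosum62):
        c = cons.ConsensusSequence("KK", threshold_count=1)
        with pytest.raises(ValueError, match="length"):
            cons.similarity_to_consensus("K", c, blosum62)


class TestEpitopeMapping:
    def test_gapless_alignment_maps_directly(self):
        a = cons.AlignmentBlock(["r", "s"], ["MKTAL", "MRTAL"])
        e = cons.EpitopeRegion("TM", "TM_E1", "r", 1, 5, "MKTAL")
        assert cons.map_epitope(a, e).rows == ["MKTAL", "MRTAL"]

    def test_reference_gaps_do_not_consume_coordinates(self):
        # reference "M-KL": ungapped positions 2..3 = "KL" -> columns 3..4
        a = cons.AlignmentBlock(["r", "s"], ["M-KL", "MAKL"])
        e = cons.EpitopeRegion("TM", "TM_E1", "r", 2, 3, "KL")
        sub = cons.map_epitope(a, e)
        assert sub.rows == ["KL", "KL"]

    def test_peptide_mismatch_quoted_in_error(self):
        a = cons.AlignmentBlock(["r", "s"], ["MKTAL", "MRTAL"])
        e = cons.EpitopeRegion("TM", "TM_E1", "r", 1, 3, "MRT")
        with pytest.raises(ValueError, match="'MRT'.*'MKT'"):
            cons.map_epitope(a, e)

    def test_region_beyond_reference_rejected(self):
        a = cons.AlignmentBlock(["r", "s"], ["MK-", "MKT"])
        e = cons.EpitopeRegion("TM", "TM_E1", "r", 2, 3, "KX")
        with pytest.raises(ValueError, match="beyond"):
            cons.map_epitope(a, e)


class TestEpitopeSimilarityTable:
    def test_identical_sequences_score_100_everywhere(self, blosum62):
        a = cons.AlignmentBlock(list("abcdef"), ["MKTALIVE"] * 6)
        eps = [cons.EpitopeRegion("TM", "TM_E1", "a", 2, 5, "KTAL")]
        table = cons.epitope_similarity_table(a, eps, blosum62)
        assert np.allclose(table.to_numpy(), 100.0)

    def test_conserved_epitopes_beat_whole_protein(self, blosum62):
        wins = 0
        for seed in range(20):
            a = syn.gen_protein_family(seed=seed)
            regions = [(40, 60), (150, 175), (230, 250)]
            ref = a.row("SP")
            eps = [
                cons.EpitopeRegion("SYN", f"E{i}", "SP", s, e, ref[s - 1:e])
                for i, (s, e) in enumerate(regions)
            ]
            table = cons.epitope_similarity_table(a, eps, blosum62)
            whole = cons.consensus_similarity_table(a, blosum62)
            wins += table.mean().mean() > whole.mean()
        assert wins >= 18

    def test_fully_ambiguous_epitope_flagged_as_nan(self, blosum62):
        rows = ["K", "K", "K", "R", "R", "R"]
        a = cons.AlignmentBlock(list("abcdef"), rows)
        eps = [cons.EpitopeRegion("TM", "TM_E1", "a", 1, 1, "K")]
        table = cons.epitope_similarity_table(a, eps, blosum62)
        assert table.isna().all().all()

    def test_row_order_invariance(self, blosum62):
        a = syn.gen_protein_family(seed=9, length=80, epitope_regions=((10, 30),))
        perm = cons.AlignmentBlock(a.seq_ids[::-1], a.rows[::-1])
        t1 = cons.consensus_similarity_table(a, blosum62)
        t2 = cons.consensus_similarity_table(perm, blosum62)
        assert t1.sort_index().equals(t2.sort_index())


def test_count_conservation_under_column_split(blosum62):
    """Whole-alignment percent equals the count-weighted average of two blocks."""
    a = syn.gen_protein_family(seed=23, length=100, epitope_regions=((20, 40),))
    c = cons.build_consensus(a)
    cols_a = list(range(0, 50))
    cols_b = list(range(50, 100))
    for row in a.rows:
        whole = cons.similarity_to_consensus(row, c, blosum62)
        parts = []
        for cols in (cols_a, cols_b):
            sub_row = "".join(row[i] for i in cols)
            sub_cons = cons.ConsensusSequence(
                "".join(c.sequence[i] for i in cols), c.threshold_count
            )
            parts.append(cons.similarity_to_consensus(sub_row, sub_cons, blosum62))
        hits = sum(p.identical + p.similar for p in parts)
        denom = sum(p.total_columns - p.excluded for p in parts)
        assert whole.percent == pytest.approx(hits / denom * 100)


def test_outgroup_attains_minimum_similarity(blosum62):
    """Longest-branch species scores lowest against the consensus (recovery)."""
    hits = 0
    for seed in range(50):
        fam = syn.gen_protein_family(seed=seed)
        sims = cons.consensus_similarity_table(fam, blosum62)
        hits += sims.idxmin() == "PC"
    assert hits >= 47
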