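"""Band-profile similarity, clustering, and Newick export."""

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from allerprofile import band_profiles as bp
from allerprofile import synthetic as syn
from allerprofile.trees import Node, leaf, to_newick


def dice_oracle(a, b) -> float:
    """Independent set-overlap Dice: 2|A∩B| / (|A|+|B|) x 100."""
    sa = {i for i, v in enumerate(a) if v}
    sb = {i for i, v in enumerate(b) if v}
    return 2 * len(sa & sb) / (len(sa) + len(sb)) * 100


class TestSimilarityIndex:
    def test_identity_is_100(self):
        v = np.tile([1, 0, 1, 1], 5)
        assert bp.similarity_index(v, v) == 100.0

    def test_disjoint_band_sets_are_0(self):
        a = [1] * 5 + [0] * 5
        b = [0] * 5 + [1] * 5
        assert bp.similarity_index(a, b) == 0.0

    def test_direct_formula_arithmetic(self):
        # X=20, Y=20, Z=18 -> 2*18/40*100 = 90.0
        a = [1] * 20 + [0] * 2
        b = [1] * 18 + [0, 0] + [1, 1]
        assert bp.similarity_index(a, b) == pytest.approx(90.0)

    def test_both_empty_profiles_rejected(self):
        with pytest.raises(bp.DegenerateProfileError):
            bp.similarity_index([0, 0, 0], [0, 0, 0])

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(0, 2**30), st.integers(5, 60))
    def test_matches_dice_oracle_on_random_pairs(self, seed, n):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 2, n)
        b = rng.integers(0, 2, n)
        if a.sum() + b.sum() == 0:
            return
        si = bp.similarity_index(a, b)
        assert si == pytest.approx(dice_oracle(a, b))
        assert si == pytest.approx(bp.similarity_index(b, a))
        assert 0.0 <= si <= 100.0


class TestPairwiseMatrices:
    def test_identical_species_give_all_100(self):
        m = bp.BandProfileMatrix(
            ["a", "b"], ["B1", "B2"], [50.0, 30.0], [[1, 0], [1, 0]]
        )
        assert np.allclose(bp.pairwise_si_matrix(m).values, 100.0)

    def test_three_species_equal_brute_force_double_loop(self, rng):
        calls = rng.integers(0, 2, (3, 25))
        calls[:, 0] = 1  # avoid empty profiles
        m = bp.BandProfileMatrix(
            ["s1", "s2", "s3"],
            [f"B{j}" for j in range(25)],
            np.linspace(200, 20, 25),
            calls,
        )
        got = bp.pairwise_si_matrix(m).values
        for i in range(3):
            for j in range(3):
                z = int((calls[i] & calls[j]).sum())
                xy = int(calls[i].sum() + calls[j].sum())
                assert got[i, j] == pytest.approx(2 * z / xy * 100)

    def test_outgroup_row_has_minimum_mean_similarity(self):
        m = syn.gen_band_profiles(seed=11)
        s = bp.pairwise_si_matrix(m)
        off = s.values.copy()
        np.fill_diagonal(off, np.nan)
        means = np.nanmean(off, axis=1)
        assert s.labels[int(np.argmin(means))] == "PC"

    def test_pearson_identical_and_complementary_rows(self):
        m = bp.BandProfileMatrix(
            ["a", "b", "c"],
            ["B1", "B2", "B3", "B4"],
            [90.0, 60.0, 40.0, 20.0],
            [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1]],
        )
        got = bp.pearson_similarity_matrix(m).values
        assert got[0, 1] == pytest.approx(1.0)
        assert got[0, 2] == pytest.approx(-1.0)

    def test_pearson_hand_computed_zero_correlation(self):
        m = bp.BandProfileMatrix(
            ["a", "b"],
            ["B1", "B2", "B3", "B4"],
            [90.0, 60.0, 40.0, 20.0],
            [[1, 1, 0, 0], [1, 0, 1, 0]],
        )
        assert bp.pearson_similarity_matrix(m).values[0, 1] == pytest.approx(0.0)

    def test_pearson_rejects_constant_row_naming_species(self):
        m = bp.BandProfileMatrix(
            ["ok", "allon"], ["B1", "B2"], [50.0, 30.0], [[1, 0], [1, 1]]
        )
        with pytest.raises(ValueError, match="allon"):
            bp.pearson_similarity_matrix(m)


class TestReadBandCalls:
    def _write(self, tmp_path, text, name="calls.tsv"):
        p = tmp_path / name
        p.write_text(text)
        return p

    def test_plus_minus_symbols_and_shape(self, tmp_path):
        lines = ["species\tband_label\tmw_kda\tpresent"]
        for sp in ["CF", "PP"]:
            for j in range(4):
                mark = "+" if (j + len(sp)) % 2 else "−"
                lines.append(f"{sp}\tB{j}\t{100 - 10 * j}\t{mark}")
        m = bp.read_band_calls(self._write(tmp_path, "\n".join(lines)))
        assert m.calls.shape == (2, 4)
        assert set(np.unique(m.calls)) <= {0, 1}
        # bands ordered by descending molecular weight
        assert list(m.mw_kda) == sorted(m.mw_kda, reverse=True)

    def test_duplicate_pair_rejected_with_row_number(self, tmp_path):
        text = (
            "species\tband_label\tmw_kda\tpresent\n"
            "CF\tB1\t50\t+\nCF\tB1\t50\t-\n"
        )
        with pytest.raises(ValueError, match="B1"):
            bp.read_band_calls(self._write(tmp_path, text))

    def test_non_binary_call_rejected(self, tmp_path):
        text = "species\tband_label\tmw_kda\tpresent\nCF\tB1\t50\tmaybe\n"
        with pytest.raises(ValueError, match="maybe"):
            bp.read_band_calls(self._write(tmp_path, text))

    def test_comma_delimited_accepted(self, tmp_path):
        text = "species,band_label,mw_kda,present\nCF,B1,50,1\nCF,B2,30,0\nPP,B1,50,1\n"
        m = bp.read_band_calls(self._write(tmp_path, text, "calls.csv"))
        assert m.species_ids == ["CF", "PP"]
        assert m.calls[1, 1] == 0  # PP x B2 absent from the table -> 0


class TestDendrogram:
    def test_two_species_cherry_at_their_distance(self):
        s = bp.SimilarityMatrix(["A", "B"], [[100.0, 80.0], [80.0, 100.0]], "percent_0_100")
        t = bp.build_dendrogram(s)
        assert t.height == pytest.approx(20.0)
        assert sorted(t.leaf_labels()) == ["A", "B"]

    def test_three_species_hand_run_upgma(self):
        # distances: d(A,B)=4, d(A,C)=10, d(B,C)=8. UPGMA merges (A,B) at 4,
        # then C at (10+8)/2 = 9.
        values = 100.0 - np.array([[0, 4, 10], [4, 0, 8], [10, 8, 0]], dtype=float)
        s = bp.SimilarityMatrix(["A", "B", "C"], values, "percent_0_100")
        t = bp.build_dendrogram(s)
        assert t.height == pytest.approx(9.0)
        (child,) = [c for c in t.children if not c.is_leaf]
        assert child.height == pytest.approx(4.0)
        assert sorted(child.leaf_labels()) == ["A", "B"]

    def test_matches_scipy_average_linkage_cophenetics(self, rng):
        n = 7
        d = rng.random((n, n)) * 50
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        labels = [f"s{i}" for i in range(n)]
        s = bp.SimilarityMatrix(labels, 100.0 - d, "percent_0_100")
        tree = bp.build_dendrogram(s)
        ours = bp.cophenetic_matrix(tree, labels)
        theirs = squareform(cophenet(linkage(squareform(d), method="average")))
        assert np.allclose(ours, theirs)

    def test_heights_monotone_rootward(self):
        m = syn.gen_band_profiles(seed=5)
        t = bp.build_dendrogram(bp.pairwise_si_matrix(m))

        def check(node):
            for c in node.children:
                assert c.height <= node.height + 1e-12
                check(c)

        check(t)

    def test_cophenetics_exact_for_ultrametric_input(self):
        # an exactly ultrametric distance matrix is reproduced by UPGMA
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 4], [6, 6, 4, 0]], dtype=float
        )
        s = bp.SimilarityMatrix(labels, 100.0 - d, "percent_0_100")
        t = bp.build_dendrogram(s)
        assert np.allclose(bp.cophenetic_matrix(t, labels), d)

    def test_outgroup_attaches_last_on_band_fixture(self, species_tree):
        m = syn.gen_band_profiles(seed=7)
        t = bp.build_dendrogram(bp.pairwise_si_matrix(m))
        # root must split PC from the five true crabs
        kids = sorted(t.children, key=lambda c: len(c.leaves()))
        assert kids[0].label == "PC"
        assert set(kids[1].leaf_labels()) == {"CF", "PP", "SP", "CO", "ES"}

    def test_rejects_asymmetric_matrix(self):
        with pytest.raises(ValueError, match="symmetric"):
            bp.SimilarityMatrix(["A", "B"], [[100, 60], [70, 100]], "percent_0_100")


class TestNewick:
    def test_cherry_serialization(self):
        t = Node(height=5.0, children=(leaf("A"), leaf("B")))
        assert to_newick(t) in ("(A:5,B:5);", "(B:5,A:5);")

    def test_six_leaf_round_trip_topology(self, tmp_path):
        m = syn.gen_band_profiles(seed=3)
        t = bp.build_dendrogram(bp.pairwise_si_matrix(m))
        path = tmp_path / "tree.nwk"
        bp.write_newick(t, path)
        reread = dendropy.Tree.get(
            path=str(path), schema="newick", rooting="force-rooted"
        )
        clades = {
            frozenset(leafn.taxon.label for leafn in node.leaf_iter())
            for node in reread.preorder_node_iter()
            if not node.is_leaf()
        }
        assert t.clades() <= clades

    def test_labels_with_spaces_are_quoted(self):
        t = Node(height=2.0, children=(leaf("king crab"), leaf("mud")))
        s = to_newick(t)
        assert "'king crab'" in s
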