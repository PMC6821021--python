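import numpy as np
import pytest

from clmdca import (
    ContactSet,
    precision_topk,
    rank_contacts,
    representative_coordinates,
    true_contacts,
)

# a tiny synthetic PDB fragment: three residues on a line 5 A apart, with a
# glycine (no CB) in the middle; coordinates are invented for the test
SYNTHETIC_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       0.500   0.000   0.000  1.00  0.00           C
ATOM      3  CB  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      4  N   GLY A   2       5.000   0.000   0.000  1.00  0.00           N
ATOM      5  CA  GLY A   2       5.000   0.000   0.000  1.00  0.00           C
ATOM      6  N   LEU A   3      10.000   0.000   0.000  1.00  0.00           N
ATOM      7  CA  LEU A   3      10.500   0.000   0.000  1.00  0.00           C
ATOM      8  CB  LEU A   3      10.000   0.000   0.000  1.00  0.00           C
END
"""


class TestTrueContacts:
    def test_strict_cutoff(self):
        coords = np.array([[0.0, 0, 0], [7.9, 0, 0], [100.0, 0, 0]])
        cs = true_contacts(coords)
        assert cs.pairs() == {(0, 1)}
        coords[1, 0] = 8.0
        assert true_contacts(coords).pairs() == set()

    def test_collinear_hand_distances(self):
        coords = np.array([[0.0, 0, 0], [5.0, 0, 0], [10.0, 0, 0]])
        assert true_contacts(coords).pairs() == {(0, 1), (1, 2)}

    def test_matches_double_loop_oracle(self, rng):
        coords = rng.uniform(0, 20, size=(20, 3))
        cs = true_contacts(coords)
        brute = {
            (i, j)
            for i in range(20)
            for j in range(i + 1, 20)
            if np.linalg.norm(coords[i] - coords[j]) < 8.0
        }
        assert cs.pairs() == brute

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="empty"):
            true_contacts(np.empty((0, 3)))

    def test_pdb_representative_atoms(self, tmp_path):
        pdb = tmp_path / "toy.pdb"
        pdb.write_text(SYNTHETIC_PDB)
        coords, names, resids = representative_coordinates(pdb)
        assert names == ["ALA", "GLY", "LEU"]
        # ALA/LEU use CB, GLY falls back to CA
        np.testing.assert_allclose(coords[:, 0], [0.0, 5.0, 10.0])
        cs = true_contacts(coords, names)
        assert cs.pairs() == {(0, 1), (1, 2)}


class TestRankContacts:
    def test_short_protein_no_qualifying_pairs(self, rng):
        scores = np.abs(rng.normal(size=(5, 5)))
        scores = scores + scores.T
        assert len(rank_contacts(scores, min_separation=6)) == 0

    def test_unique_maximum_first(self, rng):
        scores = np.zeros((12, 12))
        scores[2, 9] = scores[9, 2] = 5.0
        ranked = rank_contacts(scores, min_separation=2)
        assert ranked.entries[0][:2] == (2, 9)

    def test_matches_sort_and_filter_oracle(self, rng):
        raw = rng.random((10, 10))
        scores = raw + raw.T
        np.fill_diagonal(scores, 0)
        ranked = rank_contacts(scores, min_separation=3)
        brute = sorted(
            (
                (i, j, scores[i, j])
                for i in range(10)
                for j in range(i + 3, 10)
            ),
            key=lambda t: (-t[2], t[0], t[1]),
        )
        assert ranked.entries == [(i, j, pytest.approx(s)) for i, j, s in brute]

    def test_min_separation_validation(self, rng):
        with pytest.raises(ValueError):
            rank_contacts(np.zeros((5, 5)), min_separation=0)


class TestPrecision:
    def make_sets(self, pred_pairs, true_pairs, length=40):
        pred = ContactSet(
            [(i, j, 1.0 - 0.01 * k) for k, (i, j) in enumerate(pred_pairs)],
            length,
            kind="predicted",
        )
        truth = ContactSet([(i, j, 0.0) for i, j in true_pairs], length, kind="truth")
        return pred, truth

    def test_half_right(self):
        pred, truth = self.make_sets(
            [(0, 10), (1, 11), (2, 12), (3, 13)], [(0, 10), (1, 11)]
        )
        assert precision_topk(pred, truth, 4) == 0.5

    def test_empty_truth_gives_zero(self):
        pred, truth = self.make_sets([(0, 10), (1, 11)], [])
        assert precision_topk(pred, truth, 2) == 0.0

    def test_perfect_predictor(self):
        pairs = [(0, 10), (1, 11), (2, 12)]
        pred, truth = self.make_sets(pairs, pairs)
        assert precision_topk(pred, truth, 3) == 1.0

    def test_fraction_labels(self):
        pairs = [(i, i + 10) for i in range(10)]
        pred, truth = self.make_sets(pairs, pairs[:4], length=40)
        assert precision_topk(pred, truth, "L/10") == 1.0   # k = 4
        assert precision_topk(pred, truth, "L/5") == 0.5    # k = 8
        assert precision_topk(pred, truth, "L") == 0.4      # capped at 10

    def test_k_zero_errors(self):
        pred, truth = self.make_sets([(0, 10)], [(0, 10)])
        with pytest.raises(ValueError):
            precision_topk(pred, truth, 0)
        # floor(L/denominator) can also hit zero for short proteins
        short_pred, short_truth = self.make_sets([(0, 3)], [(0, 3)], length=4)
        with pytest.raises(ValueError):
            precision_topk(short_pred, short_truth, "L/10")

    def test_nested_prefixes_and_monotone_hits(self, rng):
        pairs = [(i, i + 8) for i in range(12)]
        rng.shuffle(pairs)
        pred, truth = self.make_sets(pairs, pairs[:6], length=50)
        hits = [precision_topk(pred, truth, k) * k for k in range(1, 13)]
        assert all(b - a in (0, 1) for a, b in zip(hits, hits[1:]))

    def test_invariant_to_monotone_score_rescaling(self):
        entries = [(0, 10, 3.0), (1, 11, 2.0), (2, 12, 1.0)]
        pred1 = ContactSet(entries, 40)
        pred2 = ContactSet([(i, j, 10 * s + 5) for i, j, s in entries], 40)
        truth = ContactSet([(0, 10, 0.0), (2, 12, 0.0)], 40, kind="truth")
        for k in (1, 2, 3):
            assert precision_topk(pred1, truth, k) == precision_topk(pred2, truth, k)


class TestContactSetInvariants:
    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            ContactSet([(3, 2, 1.0)], 10)
        with pytest.raises(ValueError):
            ContactSet([(0, 10, 1.0)], 10)

    def test_rejects_duplicates(self):
        with pytest.raises(ValueError):
            ContactSet([(0, 5, 1.0), (0, 5, 0.5)], 10)

    def test_predicted_sorted_on_construction(self):
        cs = ContactSet([(0, 5, 0.1), (1, 6, 0.9)], 10)
        assert cs.entries[0][:2] == (1, 6)
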