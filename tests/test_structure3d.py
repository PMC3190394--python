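import numpy as np
import pytest

from coevoscan import evomodel as em
from coevoscan import structure3d as s3
from coevoscan import synthdata as sd


@pytest.fixture(scope="module")
def toy_structure():
    pdb = sd.simulate_structure(40, close_pairs=[(3, 30)], seed=7)
    return s3.read_structure(pdb, state="activated")


class TestReadStructure:
    def test_residue_count(self, toy_structure):
        assert len(toy_structure) == 40

    def test_missing_chain_lists_available(self):
        pdb = sd.simulate_structure(5, seed=1)
        with pytest.raises(ValueError, match="available chains"):
            s3.read_structure(pdb, chain="Z")

    def test_altloc_highest_occupancy_kept(self):
        lines = [
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.60  0.00           C",
            "ATOM      2  CA BALA A   1       9.000   0.000   0.000  0.40  0.00           C",
            "END",
        ]
        st = s3.read_structure("\n".join(lines))
        com = s3.residue_centers(st)[1]
        assert abs(com[0]) < 1e-6  # conformer A at the origin retained

    def test_waters_and_hydrogens_excluded(self):
        lines = [
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C",
            "ATOM      2  H   ALA A   1       1.000   0.000   0.000  1.00  0.00           H",
            "HETATM    3  O   HOH A 100       5.000   5.000   5.000  1.00  0.00           O",
            "END",
        ]
        st = s3.read_structure("\n".join(lines))
        assert list(st.residues) == [1]
        assert len(st.residues[1]) == 1


class TestResidueCenters:
    def test_single_atom_residue(self):
        lines = [
            "ATOM      1  CA  GLY A   7       1.000   2.000   3.000  1.00  0.00           C",
            "END",
        ]
        com = s3.residue_centers(s3.read_structure("\n".join(lines)))[7]
        assert np.allclose(com, [1, 2, 3])

    def test_carbon_oxygen_diatomic_hand_value(self):
        lines = [
            "ATOM      1  C   ALA A   1       0.000   0.000   0.000  1.00  0.00           C",
            "ATOM      2  O   ALA A   1       0.000   0.000   2.800  1.00  0.00           O",
            "END",
        ]
        com = s3.residue_centers(s3.read_structure("\n".join(lines)))[1]
        # 2.8 * 15.999 / (12.011 + 15.999) = 1.6002
        assert abs(com[2] - 1.600) < 1e-3

    def test_translation_equivariance(self, toy_structure):
        coms = s3.residue_centers(toy_structure)
        shifted = s3.StructureModel(
            chain_id="A", state="", residues={
                r: [(el, m, xyz + np.array([1.0, 2.0, 3.0]))
                    for el, m, xyz in atoms]
                for r, atoms in toy_structure.residues.items()
            },
        )
        coms2 = s3.residue_centers(shifted)
        for r in coms.residue_numbers:
            assert np.allclose(coms2[r] - coms[r], [1, 2, 3])

    def test_com_inside_bounding_box(self, toy_structure):
        coms = s3.residue_centers(toy_structure)
        for r, atoms in toy_structure.residues.items():
            coords = np.array([xyz for _, _, xyz in atoms])
            assert np.all(coms[r] >= coords.min(axis=0) - 1e-9)
            assert np.all(coms[r] <= coords.max(axis=0) + 1e-9)


class TestDistances:
    def test_three_four_five(self):
        coms = s3.ResidueCOM("A", "", {1: np.zeros(3), 2: np.array([3.0, 4.0, 0.0])})
        d = s3.pairwise_distances(coms, [(1, 2)])
        assert d.distances[0] == 5.0

    def test_all_pairs_count(self, toy_structure):
        coms = s3.residue_centers(toy_structure)
        d = s3.pairwise_distances(coms, "all")
        assert len(d.distances) == 40 * 39 // 2

    def test_duplicate_position_zero_distance(self):
        coms = s3.ResidueCOM("A", "", {1: np.ones(3), 2: np.ones(3)})
        d = s3.pairwise_distances(coms, [(1, 2)])
        assert d.distances[0] == 0.0

    def test_missing_residue_warned_and_excluded(self, toy_structure):
        coms = s3.residue_centers(toy_structure)
        with pytest.warns(UserWarning, match="absent"):
            d = s3.pairwise_distances(coms, [(1, 2), (1, 999)])
        assert len(d.distances) == 1

    def test_triangle_inequality(self, toy_structure):
        coms = s3.residue_centers(toy_structure)
        d12 = s3.pairwise_distances(coms, [(1, 2)]).distances[0]
        d23 = s3.pairwise_distances(coms, [(2, 3)]).distances[0]
        d13 = s3.pairwise_distances(coms, [(1, 3)]).distances[0]
        assert d13 <= d12 + d23 + 1e-9


class TestMinOverStates:
    def test_idempotent_on_identical_states(self, toy_structure):
        coms = s3.residue_centers(toy_structure)
        d = s3.pairwise_distances(coms, "all")
        m = s3.min_over_states([d, d])
        assert np.allclose(np.sort(m.distances), np.sort(d.distances))

    def test_pointwise_minimum(self):
        a = s3.DistanceSummary(pairs=[(1, 2)], distances=[10.0])
        b = s3.DistanceSummary(pairs=[(1, 2)], distances=[8.0])
        m = s3.min_over_states([a, b])
        assert m.distances[0] == 8.0

    def test_combined_mean_below_each_state(self):
        rng = np.random.default_rng(3)
        pairs = [(i, i + 1) for i in range(50)]
        a = s3.DistanceSummary(pairs=pairs, distances=rng.uniform(5, 30, 50))
        b = s3.DistanceSummary(pairs=pairs, distances=rng.uniform(5, 30, 50))
        m = s3.min_over_states([a, b])
        assert m.mean <= a.mean and m.mean <= b.mean

    def test_empty_intersection_rejected(self):
        a = s3.DistanceSummary(pairs=[(1, 2)], distances=[1.0])
        b = s3.DistanceSummary(pairs=[(3, 4)], distances=[1.0])
        with pytest.raises(ValueError):
            s3.min_over_states([a, b])


class TestProximityZTest:
    def test_subset_equals_background(self, toy_structure):
        coms = s3.residue_centers(toy_structure)
        d = s3.pairwise_distances(coms, "all")
        z, p1, p2, diff = s3.proximity_ztest(d, d)
        assert z == 0.0 and diff == 0.0

    def test_planted_close_pairs_significant(self):
        pairs = [(i, i + 25) for i in range(0, 24, 2)]  # 12 close pairs
        pdb = sd.simulate_structure(80, close_pairs=pairs, seed=9)
        coms = s3.residue_centers(s3.read_structure(pdb))
        background = s3.pairwise_distances(coms, "all")
        subset = s3.pairwise_distances(
            coms, [(i + 1, j + 1) for i, j in pairs]
        )
        z, p1, p2, diff = s3.proximity_ztest(subset, background)
        assert p1 < 0.01
        assert diff > 0  # subset closer => positive difference

    def test_empty_subset_rejected(self, toy_structure):
        coms = s3.residue_centers(toy_structure)
        bg = s3.pairwise_distances(coms, "all")
        with pytest.raises(ValueError):
            s3.proximity_ztest(
                s3.DistanceSummary(pairs=[], distances=[]), bg
            )


class TestNeighborsWithin:
    def test_radius_zero_empty_without_self(self, toy_structure):
        assert s3.neighbors_within(toy_structure, 5, 0.0) == []
        assert s3.neighbors_within(toy_structure, 5, 0.0, include_self=True) == [5]

    def test_two_residue_toy(self):
        coms = s3.ResidueCOM("A", "", {1: np.zeros(3), 2: np.array([5.0, 0, 0])})
        assert s3.neighbors_within(coms, 1, 6.0) == [2]
        assert s3.neighbors_within(coms, 1, 4.0) == []

    def test_absent_residue_rejected(self, toy_structure):
        with pytest.raises(ValueError):
            s3.neighbors_within(toy_structure, 999, 9.0)


class TestSiteStructureMap:
    def test_gapless_reference_identity(self):
        aln = em.ProteinAlignment(["ref", "o"], ["ACDE", "ACDF"])
        m = s3.map_sites_to_structure(aln, "ref")
        assert m.column_to_residue == {0: 1, 1: 2, 2: 3, 3: 4}

    def test_gap_shifts_numbering(self):
        aln = em.ProteinAlignment(["ref", "o"], ["AC-DE", "ACFDE"])
        m = s3.map_sites_to_structure(aln, "ref")
        assert 2 in m.unmapped_columns
        assert m.column_to_residue[3] == 3

    def test_absent_reference_rejected(self):
        aln = em.ProteinAlignment(["a"], ["ACD"])
        with pytest.raises(ValueError):
            s3.map_sites_to_structure(aln, "zz")
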