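"""Superposition, domain displacement, contact distances, pocket proxy."""

import numpy as np
import pandas as pd
import pytest

from ryrcicr import structure_compare as sc
from ryrcicr.structure_compare import (
    SelectionError,
    StructureModel,
    StructureParseError,
    domain_displacement,
    kabsch,
    load_structure,
    pocket_gauge,
    residue_pair_distance,
    superpose,
)


def _toy_model(coords, resnames=None, atoms=None):
    n = len(coords)
    rows = [
        dict(
            resnum=i + 1,
            icode="",
            resname=(resnames or ["ALA"] * n)[i],
            atom=(atoms or ["CA"] * n)[i],
            x=c[0], y=c[1], z=c[2],
        )
        for i, c in enumerate(coords)
    ]
    return StructureModel(pd.DataFrame(rows), "synthetic", "A")


def _random_rigid(seed):
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q, rng.uniform(-10, 10, 3)


class TestLoadStructure:
    def test_small_fixture_atom_count_and_numbering(self, two_domain_files):
        model = load_structure(two_domain_files["stateA.pdb"])
        assert len(model.atoms) == 60
        assert sorted(model.atoms["resnum"]) == list(range(1, 61))

    def test_pdb_and_mmcif_agree(self, two_domain_files):
        pdb = load_structure(two_domain_files["stateA.pdb"])
        cif = load_structure(two_domain_files["stateA.cif"])
        assert np.allclose(
            pdb.atoms[["x", "y", "z"]].to_numpy(),
            cif.atoms[["x", "y", "z"]].to_numpy(),
            atol=1e-3,  # PDB fixed-width coordinate precision
        )

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        pdb = tmp_path / "altloc.pdb"
        pdb.write_text(
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.30 20.00"
            "           C\n"
            "ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.70 20.00"
            "           C\n"
            "END\n"
        )
        model = load_structure(pdb)
        assert len(model.atoms) == 1
        assert model.atoms.iloc[0]["x"] == pytest.approx(5.0)

    def test_missing_chain_rejected(self, two_domain_files):
        with pytest.raises(StructureParseError):
            load_structure(two_domain_files["stateA.pdb"], chain="Z")


class TestSuperpose:
    def test_self_superposition_is_identity(self, two_domain_files):
        model = load_structure(two_domain_files["stateA.pdb"])
        R, t, rmsd = superpose(model, model)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(R, np.eye(3), atol=1e-9)
        assert np.allclose(t, 0.0, atol=1e-9)

    def test_pure_translation_removed(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 10, (12, 3))
        a = _toy_model(coords)
        b = _toy_model(coords + np.array([3.0, 4.0, 0.0]))
        R, t, rmsd = superpose(b, a)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(t, [-3.0, -4.0, 0.0], atol=1e-9)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_rmsd_invariant_under_global_rigid_transform(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.standard_normal((20, 3))
        Q = P + rng.normal(0, 0.3, (20, 3))
        _, _, rmsd0 = kabsch(P, Q)
        R0, t0 = _random_rigid(seed + 100)
        _, _, rmsd1 = kabsch(P @ R0.T + t0, Q)
        assert rmsd1 == pytest.approx(rmsd0, abs=1e-9)

    def test_matches_gemmi_superposition(self):
        import gemmi

        rng = np.random.default_rng(4)
        P = rng.standard_normal((25, 3))
        R0, t0 = _random_rigid(5)
        Q = P @ R0.T + t0 + rng.normal(0, 0.1, (25, 3))
        _, _, rmsd = kabsch(P, Q)
        oracle = gemmi.superpose_positions(
            [gemmi.Position(*p) for p in P], [gemmi.Position(*q) for q in Q]
        )
        assert rmsd == pytest.approx(oracle.rmsd, rel=1e-9)

    def test_too_few_atoms_rejected(self):
        a = _toy_model([(0, 0, 0), (1, 0, 0)])
        with pytest.raises(SelectionError):
            superpose(a, a)


class TestDomainDisplacement:
    def test_identical_states_show_no_motion(self, two_domain_files):
        a = load_structure(two_domain_files["stateA.pdb"])
        result = domain_displacement(a, a, (1, 30), (31, 60))
        assert result["mean_displacement_A"] == pytest.approx(0.0, abs=1e-9)

    def test_known_rigid_shift_recovered_exactly(self, two_domain_files):
        a = load_structure(two_domain_files["stateA.pdb"])
        b = load_structure(two_domain_files["stateB.pdb"])
        result = domain_displacement(a, b, (1, 30), (31, 60))
        assert result["mean_displacement_A"] == pytest.approx(2.0, abs=1e-9)
        assert np.allclose(result["centroid_shift_A"], [2.0, 0.0, 0.0], atol=1e-9)
        assert result["reference_rmsd_A"] == pytest.approx(0.0, abs=1e-9)

    def test_missing_residues_dropped_pairwise(self, two_domain_files):
        a = load_structure(two_domain_files["stateA.pdb"])
        b = load_structure(two_domain_files["stateB.pdb"])
        trimmed = StructureModel(
            b.atoms[b.atoms["resnum"] != 35].reset_index(drop=True), b.source, b.chain
        )
        result = domain_displacement(a, trimmed, (1, 30), (31, 60))
        assert result["n_residues"] == 29
        assert result["mean_displacement_A"] == pytest.approx(2.0, abs=1e-9)


class TestResiduePairDistance:
    def test_known_atom_separation(self):
        model = _toy_model([(0.0, 0.0, 0.0), (3.5, 0.0, 0.0)])
        assert residue_pair_distance(model, 1, 2) == pytest.approx(3.5)

    def test_same_residue_is_zero(self):
        model = _toy_model([(1.0, 2.0, 3.0)])
        assert residue_pair_distance(model, 1, 1) == 0.0

    def test_centroid_mode_uses_side_chain(self):
        rows = pd.DataFrame(
            [
                dict(resnum=1, icode="", resname="TRP", atom="CA", x=0.0, y=0.0, z=0.0),
                dict(resnum=1, icode="", resname="TRP", atom="CD1", x=2.0, y=0.0, z=0.0),
                dict(resnum=2, icode="", resname="PHE", atom="CA", x=10.0, y=0.0, z=0.0),
                dict(resnum=2, icode="", resname="PHE", atom="CZ", x=4.0, y=0.0, z=0.0),
            ]
        )
        model = StructureModel(rows, "synthetic", "A")
        assert residue_pair_distance(model, 1, 2, mode="centroid") == pytest.approx(2.0)
        assert residue_pair_distance(model, 1, 2) == pytest.approx(2.0)

    def test_missing_residue_reported(self):
        model = _toy_model([(0.0, 0.0, 0.0)])
        with pytest.raises(SelectionError, match="99"):
            residue_pair_distance(model, 1, 99)


class TestPocketGauge:
    SQUARE = [(0.0, 0.0, 0.0), (2.0, 0.0, 0.0), (2.0, 2.0, 0.0), (0.0, 2.0, 0.0)]

    def _square_model(self, coords):
        return _toy_model(
            coords,
            resnames=["GLU", "GLU", "GLN", "THR"],
            atoms=["OE1", "OE1", "OE1", "O"],
        )

    def test_unit_square_area(self):
        g = pocket_gauge(self._square_model(self.SQUARE), [1, 2, 3, 4])
        assert g["area_A2"] == pytest.approx(4.0, abs=1e-12)
        assert g["pairwise_A"].loc["1:OE1", "3:OE1"] == pytest.approx(np.sqrt(8))

    def test_area_scales_quadratically(self):
        doubled = [(2 * x, 2 * y, 2 * z) for x, y, z in self.SQUARE]
        g = pocket_gauge(self._square_model(doubled), [1, 2, 3, 4])
        assert g["area_A2"] == pytest.approx(16.0, abs=1e-12)

    def test_shrink_toward_centroid(self):
        centroid = np.mean(self.SQUARE, axis=0)
        shrunk = [tuple(centroid + 0.9 * (np.asarray(p) - centroid)) for p in self.SQUARE]
        g = pocket_gauge(self._square_model(shrunk), [1, 2, 3, 4])
        assert g["area_A2"] == pytest.approx(4.0 * 0.81, abs=1e-12)

    @pytest.mark.parametrize("seed", [11, 12])
    def test_rigid_transform_invariance(self, seed):
        R0, t0 = _random_rigid(seed)
        moved = [tuple(R0 @ np.asarray(p) + t0) for p in self.SQUARE]
        g = pocket_gauge(self._square_model(moved), [1, 2, 3, 4])
        assert g["area_A2"] == pytest.approx(4.0, abs=1e-9)

    def test_too_few_gauge_atoms_rejected(self):
        model = _toy_model([(0, 0, 0), (1, 0, 0)])
        with pytest.raises(SelectionError):
            pocket_gauge(model, [1, 2])


def test_ryr1_ryr2_correspondence_is_one_to_one():
    values = list(sc.RYR1_TO_RYR2.values())
    assert len(values) == len(set(values))
    assert sc.RYR1_TO_RYR2[4716] == 4644  # Trp pair of the caffeine site
    assert sc.RYR1_TO_RYR2[3753] == 3713  # Phe pair
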