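"""Complex featurization: PDB loading, Sybyl typing, truncation, edge sets."""

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from atomscreen.complexes import (
    Atom3D,
    Bond,
    ComplexPose,
    PDBRecordError,
    TruncationConfig,
    assign_sybyl_types,
    build_complex_graph,
    ligand_atoms_from_rdmol,
    load_receptor,
    perceive_bonds,
    truncate_receptor,
)

TOY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C
END
"""


def _atom(x, y, z, element="C", role="receptor", typ=""):
    return Atom3D(element=element, coords=np.array([x, y, z]), role=role, sybyl_type=typ)


class TestLoadReceptor:
    def test_toy_fixture_parses_three_atoms(self, tmp_path):
        path = tmp_path / "toy.pdb"
        path.write_text(TOY_PDB)
        atoms = load_receptor(path)
        assert len(atoms) == 3
        assert atoms[0].element == "N"
        assert np.allclose(atoms[1].coords, [1.458, 0.0, 0.0])

    def test_waters_dropped(self, tmp_path):
        pdb = TOY_PDB.replace("END\n", "") + (
            "HETATM    4  O   HOH A   2       5.000   5.000   5.000  1.00  0.00           O\nEND\n"
        )
        path = tmp_path / "wat.pdb"
        path.write_text(pdb)
        assert len(load_receptor(path)) == 3

    def test_hydrogens_dropped_by_default(self, tmp_path):
        pdb = TOY_PDB.replace("END\n", "") + (
            "ATOM      4  H   ALA A   1       0.500   0.500   0.000  1.00  0.00           H\nEND\n"
        )
        path = tmp_path / "h.pdb"
        path.write_text(pdb)
        assert len(load_receptor(path)) == 3
        assert len(load_receptor(path, keep_hydrogens=True)) == 4

    def test_malformed_coordinate_names_line(self, tmp_path):
        bad = TOY_PDB.replace("1.458", "xx458")
        path = tmp_path / "bad.pdb"
        path.write_text(bad)
        with pytest.raises(PDBRecordError, match="line 2"):
            load_receptor(path)


class TestSybylTyping:
    def _types(self, smiles):
        rd = Chem.MolFromSmiles(smiles)
        AllChem.Compute2DCoords(rd)
        return [a.sybyl_type for a in ligand_atoms_from_rdmol(rd)]

    def test_benzene_carbons_aromatic(self):
        assert self._types("c1ccccc1") == ["C.ar"] * 6

    def test_amide_nitrogen(self):
        types = self._types("CC(=O)NC")  # N-methylacetamide
        assert "N.am" in types and "O.2" in types

    def test_sp3_carbon_base_rule(self):
        assert self._types("CC") == ["C.3", "C.3"]

    def test_carboxylate_oxygens(self):
        types = self._types("CC(=O)[O-]")
        assert types.count("O.co2") == 2

    def test_nitrile_and_sp2(self):
        types = self._types("C=CC#N")
        assert "C.2" in types and "C.1" in types and "N.1" in types

    def test_sulfone_and_pyridine(self):
        types = self._types("CS(=O)(=O)c1ccncc1")
        assert "S.o2" in types and "N.ar" in types

    def test_unknown_element_falls_back_with_warning(self):
        atoms = [_atom(0, 0, 0, element="Fe")]
        with pytest.warns(UserWarning, match="generic"):
            typed = assign_sybyl_types(atoms, [])
        assert typed[0].sybyl_type == "X.generic"

    def test_existing_types_honored(self):
        atoms = [_atom(0, 0, 0, typ="C.cat")]
        assert assign_sybyl_types(atoms, [])[0].sybyl_type == "C.cat"

    def test_perceived_bonds_on_geometry(self):
        atoms = [_atom(0, 0, 0), _atom(1.5, 0, 0), _atom(9, 9, 9)]
        bonds = perceive_bonds(atoms)
        assert [(b.i, b.j) for b in bonds] == [(0, 1)]


class TestTruncation:
    def test_boundary_construction(self):
        ligand = [_atom(0, 0, 0, role="ligand", typ="C.3")]
        near = _atom(6.9, 0, 0)
        far = _atom(7.1, 0, 0)
        kept = truncate_receptor([near, far], ligand)
        assert kept == [near]

    def test_exactly_at_cutoff_kept(self):
        ligand = [_atom(0, 0, 0, role="ligand")]
        edge = _atom(7.0, 0, 0)
        assert truncate_receptor([edge], ligand) == [edge]

    def test_fully_distant_receptor_gives_empty(self):
        ligand = [_atom(0, 0, 0, role="ligand", typ="C.3")]
        rec = [_atom(20, 0, 0, typ="C.3")]
        assert truncate_receptor(rec, ligand) == []
        pose = ComplexPose(ligand_atoms=ligand, receptor_atoms=[], pose_id="lonely")
        graph = build_complex_graph(pose)
        assert graph.n_atoms == 1 and graph.ligand_mask.all()

    def test_empty_ligand_rejected(self):
        with pytest.raises(ValueError):
            truncate_receptor([_atom(0, 0, 0)], [])

    def test_matches_brute_force_on_random_pocket(self):
        rng = np.random.default_rng(7)
        ligand = [_atom(*c, role="ligand") for c in rng.normal(0, 2, (10, 3))]
        receptor = [_atom(*c) for c in rng.normal(0, 6, (200, 3))]
        kept = truncate_receptor(receptor, ligand, TruncationConfig(7.0))
        expected = []
        for r in receptor:
            dmin = min(np.linalg.norm(r.coords - l.coords) for l in ligand)
            if dmin <= 7.0:
                expected.append(r)
        assert kept == expected


class TestComplexGraph:
    def _pose(self, coords, n_ligand):
        atoms = [
            _atom(*c, role="ligand" if i < n_ligand else "receptor", typ="C.3")
            for i, c in enumerate(coords)
        ]
        return ComplexPose(ligand_atoms=atoms[:n_ligand], receptor_atoms=atoms[n_ligand:])

    def test_edge_membership_by_cutoff(self):
        g = build_complex_graph(self._pose([[0, 0, 0], [4.9, 0, 0]], 1))
        assert len(g.edge_sets[5.0]["src"]) == 2  # both directions
        assert len(g.edge_sets[7.0]["src"]) == 2
        g2 = build_complex_graph(self._pose([[0, 0, 0], [6.0, 0, 0]], 1))
        assert len(g2.edge_sets[5.0]["src"]) == 0
        assert len(g2.edge_sets[7.0]["src"]) == 2

    def test_matches_brute_force_adjacency(self):
        rng = np.random.default_rng(11)
        coords = rng.uniform(-5, 5, (50, 3))
        g = build_complex_graph(self._pose(coords, 20))
        for r in (5.0, 7.0):
            got = set(zip(g.edge_sets[r]["src"].tolist(), g.edge_sets[r]["dst"].tolist()))
            expected = set()
            for i in range(50):
                for j in range(50):
                    if i != j and 0 < np.linalg.norm(coords[i] - coords[j]) <= r:
                        expected.add((i, j))
            assert got == expected

    def test_edges_symmetric_and_within_cutoff(self):
        rng = np.random.default_rng(3)
        g = build_complex_graph(self._pose(rng.uniform(-4, 4, (30, 3)), 12))
        for r, es in g.edge_sets.items():
            pairs = set(zip(es["src"].tolist(), es["dst"].tolist()))
            assert all((j, i) in pairs for i, j in pairs)
            assert (es["dist"] > 0).all() and (es["dist"] <= r).all()
            assert not any(i == j for i, j in pairs)

    def test_edge_counts_monotone_in_cutoff(self):
        rng = np.random.default_rng(5)
        g = build_complex_graph(
            self._pose(rng.uniform(-6, 6, (40, 3)), 15), cutoffs=(3.0, 5.0, 7.0, 9.0)
        )
        counts = [len(g.edge_sets[r]["src"]) for r in (3.0, 5.0, 7.0, 9.0)]
        assert counts == sorted(counts)

    def test_rigid_motion_preserves_distances(self):
        rng = np.random.default_rng(13)
        coords = rng.uniform(-5, 5, (25, 3))
        g1 = build_complex_graph(self._pose(coords, 10))
        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
        )
        moved = coords @ rot.T + np.array([3.0, -2.0, 11.0])
        g2 = build_complex_graph(self._pose(moved, 10))
        for r in (5.0, 7.0):
            assert np.array_equal(g1.edge_sets[r]["src"], g2.edge_sets[r]["src"])
            assert np.allclose(g1.edge_sets[r]["dist"], g2.edge_sets[r]["dist"], atol=1e-9)

    def test_coincident_atoms_warn_and_skip(self):
        with pytest.warns(UserWarning, match="coincident"):
            g = build_complex_graph(self._pose([[0, 0, 0], [0, 0, 0], [1, 0, 0]], 3))
        pairs = set(zip(g.edge_sets[5.0]["src"].tolist(), g.edge_sets[5.0]["dst"].tolist()))
        assert (0, 1) not in pairs and (1, 0) not in pairs

    def test_untyped_atom_rejected(self):
        pose = ComplexPose(ligand_atoms=[_atom(0, 0, 0, role="ligand")], receptor_atoms=[])
        with pytest.raises(ValueError, match="Sybyl"):
            build_complex_graph(pose)

    def test_truncation_invariant_validator(self):
        ligand = [_atom(0, 0, 0, role="ligand", typ="C.3")]
        good = ComplexPose(ligand_atoms=ligand, receptor_atoms=[_atom(5, 0, 0, typ="C.3")])
        bad = ComplexPose(ligand_atoms=ligand, receptor_atoms=[_atom(9, 0, 0, typ="C.3")])
        assert good.validate_truncation() and not bad.validate_truncation()
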