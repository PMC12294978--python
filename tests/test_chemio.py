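"""Featurization, conformer generation, rotations, and table I/O."""

import numpy as np
import pytest
from rdkit import Chem

from stereoddi.chemio import (ATOM_SYMBOLS, DDITriple, InputError, Rotation,
                              build_graph, euler_to_matrix, featurize_atoms,
                              featurize_bonds, generate_conformer,
                              parse_smiles, random_rotation, read_ddi_table,
                              read_smiles_registry, rotate_coordinates,
                              sample_rotation, write_ddi_table,
                              write_smiles_registry)


def pdist(x):
    return np.linalg.norm(x[:, None, :] - x[None, :, :], axis=-1)


class TestAtomFeatures:
    @pytest.mark.parametrize("smiles", ["C", "CCO", "c1ccccc1", "CC(=O)O",
                                        "F/C=C\\F", "[Na+].[Cl-]"])
    def test_feature_widths(self, smiles):
        g = build_graph(smiles)
        assert g.node_features.shape == (g.n_atoms, 55)
        assert g.edge_features.shape[1] == 6
        # one-hot blocks sum to at most 1
        assert (g.node_features[:, :44].sum(axis=1) <= 1).all()
        assert (g.node_features[:, 48:53].sum(axis=1) <= 1).all()

    def test_methane_single_heavy_atom(self):
        rows = featurize_atoms(parse_smiles("C"))
        assert rows.shape == (1, 55)
        assert rows[0, ATOM_SYMBOLS.index("C")] == 1
        assert rows[0, 44] == 0      # heavy-atom degree
        assert rows[0, 54] == 4      # total hydrogens

    def test_benzene_against_per_atom_loop(self):
        """Recompute every descriptor independently per atom."""
        mol = parse_smiles("c1ccccc1")
        rows = featurize_atoms(mol)
        assert rows.shape == (6, 55)
        assert (rows == rows[0]).all()  # six equivalent aromatic carbons
        for i, atom in enumerate(mol.GetAtoms()):
            expected = np.zeros(55)
            expected[ATOM_SYMBOLS.index(atom.GetSymbol())] = 1
            expected[44] = atom.GetDegree()
            expected[45] = atom.GetImplicitValence()
            expected[46] = atom.GetFormalCharge()
            expected[47] = atom.GetNumRadicalElectrons()
            expected[48 + 1] = 1.0  # aromatic carbon is SP2
            expected[53] = 1.0
            expected[54] = atom.GetTotalNumHs()
            assert np.array_equal(rows[i], expected)

    def test_out_of_vocabulary_maps_to_other(self):
        rows = featurize_atoms(parse_smiles("[U]"))
        assert rows[0, 43] == 1  # last slot = "other"

    def test_unparseable_smiles_raises_with_string(self):
        with pytest.raises(InputError, match="not-a-smiles"):
            build_graph("not-a-smiles")


class TestBondFeatures:
    def test_ethane_two_directed_edges(self):
        edges, feats = featurize_bonds(parse_smiles("CC"))
        assert edges.shape == (2, 2)
        assert {tuple(e) for e in edges} == {(0, 1), (1, 0)}
        assert np.array_equal(feats[:, :4], [[1, 0, 0, 0]] * 2)
        assert (feats[:, 4:] == 0).all()

    def test_benzene_aromatic_ring_bonds(self):
        edges, feats = featurize_bonds(parse_smiles("c1ccccc1"))
        assert edges.shape == (12, 2)
        assert (feats[:, 3] == 1).all()   # aromatic one-hot
        assert (feats[:, 5] == 1).all()   # in-ring flag

    def test_every_edge_has_reverse_with_same_features(self):
        g = build_graph("CC(=O)Oc1ccccc1C(=O)O", "aspirin")
        table = {tuple(e): f for e, f in zip(g.edges, g.edge_features)}
        for (i, j), f in table.items():
            assert np.array_equal(table[(j, i)], f)


class TestConformers:
    def test_deterministic_given_seed(self):
        a = generate_conformer("CCO", seed=11)
        b = generate_conformer("CCO", seed=11)
        assert np.array_equal(a.coordinates, b.coordinates)

    def test_single_atom_finite(self):
        c = generate_conformer("C", seed=1)
        assert c.coordinates.shape == (1, 3)
        assert np.all(np.isfinite(c.coordinates))

    def test_cis_fluorines_closer_than_trans(self):
        cis = generate_conformer("F/C=C\\F", seed=3)
        trans = generate_conformer("F/C=C/F", seed=3)
        g = build_graph("F/C=C\\F")
        f_idx = np.flatnonzero(g.node_features[:, ATOM_SYMBOLS.index("F")])
        d_cis = np.linalg.norm(np.diff(cis.coordinates[f_idx], axis=0))
        d_trans = np.linalg.norm(np.diff(trans.coordinates[f_idx], axis=0))
        assert d_cis < d_trans

    def test_ez_isomers_identical_graphs_distinct_geometry(self):
        g_cis = build_graph("F/C=C\\F", "z")
        g_trans = build_graph("F/C=C/F", "e")
        assert np.array_equal(g_cis.node_features, g_trans.node_features)
        assert np.array_equal(g_cis.edge_features, g_trans.edge_features)
        cis = generate_conformer("F/C=C\\F", seed=5)
        trans = generate_conformer("F/C=C/F", seed=5)
        assert np.abs(pdist(cis.coordinates) -
                      pdist(trans.coordinates)).max() > 0.1

    def test_heavy_atom_count_matches_graph(self):
        smiles = "CC(=O)Oc1ccccc1C(=O)O"
        assert generate_conformer(smiles, 2).coordinates.shape[0] == \
            build_graph(smiles).n_atoms


class TestRotations:
    def test_identity_angles_give_identity(self, ethanol_conformer):
        rot = Rotation((0.0, 0.0, 0.0))
        assert np.allclose(rot.matrix, np.eye(3), atol=1e-12)
        assert np.array_equal(
            rotate_coordinates(ethanol_conformer.coordinates, rot),
            ethanol_conformer.coordinates @ np.eye(3))

    def test_matrix_is_proper_rotation(self, rng):
        for _ in range(20):
            rot = sample_rotation(rng)
            assert np.allclose(rot.matrix.T @ rot.matrix, np.eye(3),
                               atol=1e-6)
            assert np.isclose(np.linalg.det(rot.matrix), 1.0, atol=1e-6)

    def test_quarter_turn_about_z(self):
        m = euler_to_matrix(np.pi / 2, 0.0, 0.0)
        assert np.allclose(m @ np.array([1.0, 0, 0]), [0, 1, 0], atol=1e-6)

    def test_pairwise_distances_preserved(self, ethanol_conformer, rng):
        before = pdist(ethanol_conformer.coordinates)
        for _ in range(5):
            after = pdist(random_rotation(ethanol_conformer, rng).coordinates)
            assert np.abs(after - before).max() < 1e-5


class TestTables:
    def test_registry_roundtrip_and_triple_roundtrip(self, tmp_path):
        registry = {"a": "CCO", "b": "CC(=O)O", "c": "CCN"}
        write_smiles_registry(registry, tmp_path / "reg.csv")
        assert read_smiles_registry(tmp_path / "reg.csv") == registry
        triples = [DDITriple("a", "b", 1), DDITriple("b", "c", 2),
                   DDITriple("a", "c", 3)]
        write_ddi_table(triples, tmp_path / "t.tsv")
        assert read_ddi_table(tmp_path / "t.tsv", registry) == triples

    def test_smi_format_roundtrip(self, tmp_path):
        (tmp_path / "lib.smi").write_text("CCO drug1\nCCN drug2\n")
        registry = read_smiles_registry(tmp_path / "lib.smi")
        assert registry == {"drug1": "CCO", "drug2": "CCN"}
        write_smiles_registry(registry, tmp_path / "out.smi")
        assert read_smiles_registry(tmp_path / "out.smi") == registry

    def test_unknown_drug_id_raises(self, tmp_path):
        registry = {"a": "CCO"}
        write_ddi_table([DDITriple("a", "zzz", 1)], tmp_path / "t.tsv")
        with pytest.raises(InputError, match="zzz"):
            read_ddi_table(tmp_path / "t.tsv", registry)

    def test_missing_columns_and_duplicate_ids_raise(self, tmp_path):
        (tmp_path / "bad.csv").write_text("drug_a,drug_b\nx,y\n")
        with pytest.raises(InputError, match="type"):
            read_ddi_table(tmp_path / "bad.csv")
        (tmp_path / "dup.csv").write_text("id,smiles\nd1,CCO\nd1,CCN\n")
        with pytest.raises(InputError, match="duplicate"):
            read_smiles_registry(tmp_path / "dup.csv")

    def test_sdf_export_roundtrips_coordinates(self, tmp_path):
        from rdkit import Chem
        from stereoddi.chemio import export_sdf
        registry = {"eth": "CCO"}
        conf = generate_conformer("CCO", 3, "eth")
        export_sdf([conf], registry, tmp_path / "out.sdf")
        mol = next(Chem.SDMolSupplier(str(tmp_path / "out.sdf")))
        assert mol.GetProp("_Name") == "eth"
        got = mol.GetConformer().GetPositions()
        assert np.allclose(got, conf.coordinates, atol=1e-4)

    def test_comma_and_tab_both_accepted(self, tmp_path):
        (tmp_path / "a.txt").write_text("drug_a,drug_b,type\nx,y,1\n")
        (tmp_path / "b.txt").write_text("drug_a\tdrug_b\ttype\nx\ty\t2\n")
        assert read_ddi_table(tmp_path / "a.txt")[0].itype == 1
        assert read_ddi_table(tmp_path / "b.txt")[0].itype == 2
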