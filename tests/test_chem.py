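"""Input resolution, SMILES parsing, hydrogenation and 3D embedding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from molforge import chem
from molforge.errors import (
    EmptyFile,
    EmptyInput,
    EmptyToken,
    InvalidSmiles,
)
from molforge.names import TRIVIAL_NAMES


class TestResolveInput:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("ethanol", "CCO"),
            ("Ethanol", "CCO"),
            ("  methanol ", "CO"),
            ("CCO", "CCO"),  # SMILES passes through
            ("N#N", "N#N"),
        ],
    )
    def test_resolution(self, text, expected):
        assert chem.resolve_input(text) == expected

    def test_blank_rejected(self):
        with pytest.raises(EmptyInput):
            chem.resolve_input("   ")


class TestParseSmiles:
    def test_cyclohexane_ring(self):
        # ring-closure bookkeeping: 6 carbons, 6 ring bonds, all single
        g = chem.parse_smiles("C1CCCCC1")
        assert g.n_atoms == 6
        assert g.n_bonds == 6
        assert all(a.element == "C" for a in g.atoms)
        assert all(b.order == "single" for b in g.bonds)

    def test_dimethyl_ether(self):
        g = chem.parse_smiles("COC")
        assert g.elements() == ["C", "O", "C"]
        assert g.n_bonds == 2
        assert all(b.order == "single" for b in g.bonds)

    def test_benzene_kekulized(self):
        g = chem.parse_smiles("c1ccccc1")
        orders = sorted(b.order for b in g.bonds)
        assert orders == ["double"] * 3 + ["single"] * 3

    def test_bond_references_valid_and_unique(self):
        g = chem.parse_smiles("CC(=O)Oc1ccccc1C(=O)O")  # aspirin
        pairs = set()
        for b in g.bonds:
            assert b.atom_a != b.atom_b
            assert 0 <= b.atom_a < g.n_atoms and 0 <= b.atom_b < g.n_atoms
            key = (min(b.atom_a, b.atom_b), max(b.atom_a, b.atom_b))
            assert key not in pairs
            pairs.add(key)

    def test_disconnected_components_accepted(self):
        g = chem.parse_smiles("O.O")
        assert g.n_atoms == 2 and g.n_bonds == 0

    @pytest.mark.parametrize("bad", ["C1CC", "C(C", "Xx", "C#", "1CC"])
    def test_invalid_smiles_echoed(self, bad):
        with pytest.raises(InvalidSmiles) as err:
            chem.parse_smiles(bad)
        assert bad in str(err.value)

    def test_blank_rejected(self):
        with pytest.raises(EmptyInput):
            chem.parse_smiles(" ")


class TestAddHydrogens:
    def test_cyclohexane(self):
        g = chem.add_hydrogens(chem.parse_smiles("C1CCCCC1"))
        assert (g.n_atoms, g.n_bonds) == (18, 18)

    def test_methane(self):
        g = chem.add_hydrogens(chem.parse_smiles("C"))
        assert (g.n_atoms, g.n_bonds) == (5, 4)

    def test_heavy_atoms_first(self):
        g = chem.add_hydrogens(chem.parse_smiles("CCO"))
        assert g.elements()[:3] == ["C", "C", "O"]
        assert all(e == "H" for e in g.elements()[3:])

    def test_idempotent_on_saturated(self):
        g = chem.add_hydrogens(chem.parse_smiles("CO"))
        g2 = chem.add_hydrogens(g)
        assert g2.n_atoms == g.n_atoms and g2.n_bonds == g.n_bonds

    @pytest.mark.parametrize("n", range(1, 21))
    def test_alkane_valence_oracle(self, n):
        # CnH2n+2: 3n+2 atoms and 3n+1 bonds, from the valence closed form
        g = chem.add_hydrogens(chem.parse_smiles("C" * n))
        assert g.n_atoms == 3 * n + 2
        assert g.n_bonds == 3 * n + 1


class TestEmbedConformer:
    def test_deterministic_for_equal_seed(self, cyclohexane):
        graph, conf = cyclohexane
        again = chem.embed_conformer(graph, seed=7)
        assert np.array_equal(conf.coordinates, again.coordinates)

    def test_different_seeds_differ(self, cyclohexane):
        graph, _ = cyclohexane
        c1 = chem.embed_conformer(graph, seed=1)
        c2 = chem.embed_conformer(graph, seed=2)
        assert not np.array_equal(c1.coordinates, c2.coordinates)

    def test_cc_bond_lengths(self, cyclohexane):
        # all six ring C-C distances near the 1.54 A standard length
        graph, conf = cyclohexane
        for b in graph.bonds:
            if graph.atoms[b.atom_a].element == graph.atoms[b.atom_b].element == "C":
                d = np.linalg.norm(conf.coordinates[b.atom_a] - conf.coordinates[b.atom_b])
                assert 1.4 <= d <= 1.7

    def test_centroid_at_origin(self, cyclohexane):
        _, conf = cyclohexane
        assert np.allclose(conf.coordinates.mean(axis=0), 0.0, atol=1e-9)

    def test_distance_invariants(self, cyclohexane):
        graph, conf = cyclohexane
        coords = conf.coordinates
        bonded = {
            (min(b.atom_a, b.atom_b), max(b.atom_a, b.atom_b)) for b in graph.bonds
        }
        for i in range(graph.n_atoms):
            for j in range(i + 1, graph.n_atoms):
                d = np.linalg.norm(coords[i] - coords[j])
                if (i, j) in bonded:
                    assert 0.7 <= d <= 2.2
                else:
                    assert d > 0.5

    def test_trivial_name_dictionary_is_embeddable(self):
        # the full name->SMILES dictionary completes parse+H+embed
        for name, smiles in TRIVIAL_NAMES.items():
            graph = chem.add_hydrogens(chem.parse_smiles(smiles))
            conf = chem.embed_conformer(graph, seed=0)
            assert conf.coordinates.shape == (graph.n_atoms, 3), name

    def test_seed_out_of_range(self, cyclohexane):
        graph, _ = cyclohexane
        with pytest.raises(ValueError):
            chem.embed_conformer(graph, seed=2**31)


class TestBatchInput:
    def test_comma_list(self):
        batch = chem.split_batch_text("CCO, CO")
        assert batch.entries == ("CCO", "CO")
        assert batch.source == "inline"

    def test_single_token(self):
        assert chem.split_batch_text("C").entries == ("C",)

    def test_blank_token_rejected(self):
        with pytest.raises(EmptyToken):
            chem.split_batch_text("CCO,,CO")

    def test_empty_text_rejected(self):
        with pytest.raises(EmptyInput):
            chem.split_batch_text("  ")

    @given(st.lists(st.sampled_from(["C", "CC", "CCO", "c1ccccc1", "COC"]), min_size=1, max_size=20))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_split_preserves_order_and_count(self, tokens):
        batch = chem.split_batch_text(", ".join(tokens))
        assert list(batch.entries) == tokens


class TestReadBatchCsv:
    def test_three_rows(self, tmp_path):
        p = tmp_path / "batch.csv"
        p.write_text("CCO\nCO\nCOC\n")
        assert chem.read_batch_csv(p).entries == ("CCO", "CO", "COC")

    def test_300_rows(self, tmp_path):
        p = tmp_path / "large.csv"
        p.write_text("\n".join("C" * (i % 12 + 1) for i in range(300)))
        batch = chem.read_batch_csv(p)
        assert len(batch) == 300
        assert batch.source == "csv"

    def test_header_skipped(self, tmp_path):
        p = tmp_path / "h.csv"
        p.write_text("smiles\nCCO\n")
        assert chem.read_batch_csv(p, header=True).entries == ("CCO",)

    def test_first_column_used(self, tmp_path):
        p = tmp_path / "multi.csv"
        p.write_text("CCO,ethanol\nCO,methanol\n")
        assert chem.read_batch_csv(p).entries == ("CCO", "CO")

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            chem.read_batch_csv(tmp_path / "nope.csv")

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(EmptyFile):
            chem.read_batch_csv(p)
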