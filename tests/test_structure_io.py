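"""Structure reading/writing, sanitization, chain roles and selections."""

import numpy as np
import pytest

from pmhcdock.errors import (AmbiguousPeptideError, EmptySelectionError,
                             PdbFormatError, RoleAssignmentError,
                             StructureError)
from pmhcdock.structure_io import (AtomRecord, Structure, assign_chain_roles,
                                   parse_selection, read_pdb,
                                   sanitize_structure, select_atom_records,
                                   select_atoms, write_pdb)
from pmhcdock.epitope_builder import thread_peptide


def _atom(serial, name, res, chain, resnum, xyz, element=None, **kw):
    return AtomRecord(serial=serial, name=name,
                      element=element or name[0],
                      residue_name=res, chain_id=chain, residue_number=resnum,
                      coords=np.array(xyz, dtype=float), **kw)


MINIMAL_PDB = (
    "ATOM      1  CA  ALA A   1      11.104   6.134  -6.504  1.00 20.00"
    "           C  \n"
)


def test_read_single_record(tmp_path):
    path = tmp_path / "one.pdb"
    path.write_text(MINIMAL_PDB)
    st = read_pdb(path)
    assert len(st) == 1
    atom = st.atoms[0]
    assert atom.name == "CA" and atom.residue_name == "ALA"
    assert atom.chain_id == "A" and atom.residue_number == 1
    np.testing.assert_allclose(atom.coords, [11.104, 6.134, -6.504])


def test_read_missing_file_raises():
    with pytest.raises(IOError):
        read_pdb("/nonexistent/file.pdb")


def test_read_no_atoms_raises_with_context(tmp_path):
    path = tmp_path / "junk.pdb"
    path.write_text("HEADER junk\nREMARK nothing here\n")
    with pytest.raises(PdbFormatError, match="no ATOM"):
        read_pdb(path)


def test_round_trip_toy_complex(tmp_path, toy9):
    complex_structure, _ = toy9
    path = tmp_path / "toy.pdb"
    write_pdb(complex_structure, path)
    back = read_pdb(path)
    assert len(back) == len(complex_structure)
    np.testing.assert_allclose(back.coords_array(),
                               complex_structure.coords_array(),
                               atol=5.001e-4)  # PDB 3-decimal precision
    assert [a.name for a in back.atoms] == \
        [a.name for a in complex_structure.atoms]
    assert [a.chain_id for a in back.atoms] == \
        [a.chain_id for a in complex_structure.atoms]
    assert [a.residue_name for a in back.atoms] == \
        [a.residue_name for a in complex_structure.atoms]


def test_write_emits_ter_between_chains(tmp_path, toy9):
    complex_structure, _ = toy9
    path = tmp_path / "toy.pdb"
    write_pdb(complex_structure, path)
    lines = path.read_text().splitlines()
    ters = [ln for ln in lines if ln.startswith("TER")]
    assert len(ters) == 3  # one per chain A, B, C
    chain_order = []
    for ln in lines:
        if ln.startswith("ATOM") and (not chain_order or ln[21] != chain_order[-1]):
            chain_order.append(ln[21])
    assert chain_order == ["A", "B", "C"]


def test_write_empty_structure_raises(tmp_path):
    with pytest.raises(StructureError):
        write_pdb(Structure([]), tmp_path / "empty.pdb")


class TestSanitize:
    def test_waters_removed(self):
        atoms = [_atom(1, "CA", "ALA", "A", 1, (0, 0, 0))]
        atoms += [_atom(10 + i, "O", "HOH", "W", i, (i, 0, 0), is_hetero=True)
                  for i in range(5)]
        clean = sanitize_structure(Structure(atoms))
        assert len(clean) == 1
        assert clean.meta["sanitization"]["waters"] == 5

    def test_alt_loc_blank_preferred_then_a_then_occupancy(self):
        base = [
            _atom(1, "CA", "SER", "A", 1, (0, 0, 0)),
            _atom(2, "OG", "SER", "A", 1, (1, 0, 0), alt_loc="A", occupancy=0.6),
            _atom(3, "OG", "SER", "A", 1, (2, 0, 0), alt_loc="B", occupancy=0.4),
        ]
        clean = sanitize_structure(Structure(base))
        ogs = [a for a in clean.atoms if a.name == "OG"]
        assert len(ogs) == 1
        np.testing.assert_allclose(ogs[0].coords, [1, 0, 0])  # 'A' kept

        higher_occ = [
            _atom(1, "CA", "SER", "A", 1, (0, 0, 0)),
            _atom(2, "OG", "SER", "A", 1, (1, 0, 0), alt_loc="B", occupancy=0.3),
            _atom(3, "OG", "SER", "A", 1, (2, 0, 0), alt_loc="C", occupancy=0.7),
        ]
        clean = sanitize_structure(Structure(higher_occ))
        (og,) = [a for a in clean.atoms if a.name == "OG"]
        np.testing.assert_allclose(og.coords, [2, 0, 0])

    def test_hydrogens_removed(self):
        atoms = [_atom(1, "CA", "ALA", "A", 1, (0, 0, 0)),
                 _atom(2, "HA", "ALA", "A", 1, (1, 0, 0), element="H")]
        clean = sanitize_structure(Structure(atoms))
        assert [a.name for a in clean.atoms] == ["CA"]

    def test_selenomethionine_mapped_to_met(self):
        atoms = [_atom(1, "CA", "MSE", "A", 1, (0, 0, 0), is_hetero=True),
                 _atom(2, "CA", "ALA", "A", 2, (3.8, 0, 0))]
        clean = sanitize_structure(Structure(atoms))
        assert clean.atoms[0].residue_name == "MET"
        assert not clean.atoms[0].is_hetero

    def test_unknown_polymer_residue_rejected(self):
        atoms = [_atom(1, "CA", "XYZ", "A", 1, (0, 0, 0))]
        with pytest.raises(StructureError, match="XYZ"):
            sanitize_structure(Structure(atoms))

    def test_explicit_chain_removal(self, toy9):
        complex_structure, _ = toy9
        clean = sanitize_structure(complex_structure, drop_chains=["B"])
        assert set(clean.chains()) == {"A", "C"}

    def test_ternary_complex_reduced_to_pmhc(self, toy9):
        # pMHC plus two receptor-sized chains; listing them for removal
        # leaves the three pMHC chains
        complex_structure, _ = toy9
        five = complex_structure.copy()
        for new_chain in ("D", "E"):
            for a in complex_structure.atoms:
                if a.chain_id == "A":
                    b = a.copy()
                    b.chain_id = new_chain
                    b.coords = b.coords + np.array([0.0, 60.0, 0.0])
                    five.atoms.append(b)
        assert len(five.chains()) == 5
        clean = sanitize_structure(five, drop_chains=["D", "E"])
        assert set(clean.chains()) == {"A", "B", "C"}

    def test_idempotent(self, toy9):
        complex_structure, _ = toy9
        once = sanitize_structure(complex_structure)
        twice = sanitize_structure(once)
        assert len(once) == len(twice)
        np.testing.assert_array_equal(once.coords_array(),
                                      twice.coords_array())


class TestChainRoles:
    def test_toy_fixture_roles(self, toy9):
        complex_structure, _ = toy9
        roles = assign_chain_roles(complex_structure)
        assert roles.heavy_chain == "A"
        assert roles.beta2m == "B"
        assert roles.peptide == "C"

    def test_two_chain_complex_has_no_beta2m(self, toy9):
        complex_structure, _ = toy9
        two = complex_structure.subset(["A", "C"])
        roles = assign_chain_roles(two)
        assert roles.beta2m is None
        assert roles.peptide == "C"

    def test_no_peptide_length_chain_raises(self, toy9):
        complex_structure, _ = toy9
        with pytest.raises(RoleAssignmentError):
            assign_chain_roles(complex_structure.subset(["A", "B"]))

    def test_equal_length_candidates_ambiguous(self, toy9):
        complex_structure, _ = toy9
        dup = complex_structure.copy()
        extra = []
        for a in dup.atoms:
            if a.chain_id == "C":
                b = a.copy()
                b.chain_id = "D"
                b.coords = b.coords + 30.0
                extra.append(b)
        dup.atoms.extend(extra)
        with pytest.raises(AmbiguousPeptideError):
            assign_chain_roles(dup)


class TestSelections:
    def test_ca_count_on_peptide(self, toy9):
        _, template = toy9
        peptide = thread_peptide("ALYNTAAAL", template)
        assert select_atoms(peptide, "CA").shape == (9, 3)

    def test_backbone_count(self, toy9):
        _, template = toy9
        peptide = thread_peptide("ALYNTAAAL", template)
        assert select_atoms(peptide, "backbone").shape == (36, 3)

    def test_heavy_count_poly_ala(self, toy9):
        _, template = toy9
        peptide = thread_peptide("AAAAAAAAA", template)
        # 5 heavy atoms per Ala + the C-terminal OXT copied from the pattern
        records = select_atom_records(peptide, "heavy")
        non_oxt = [a for a in records if a.name != "OXT"]
        assert len(non_oxt) == 45

    def test_empty_selection_raises(self, toy9):
        _, template = toy9
        peptide = thread_peptide("GGGGGGGGG", template)
        with pytest.raises(EmptySelectionError):
            select_atoms(peptide, "side-chain")  # Gly has no side chain

    def test_positional_correspondence_across_structures(self, toy9):
        _, template = toy9
        pep1 = thread_peptide("ALYNTAAAL", template)
        pep2 = thread_peptide("ALYNTAAAL", template)
        # scramble atom order within residues of pep2
        pep2.atoms.sort(key=lambda a: (a.residue_number, a.name))
        rec1 = select_atom_records(pep1, "heavy")
        rec2 = select_atom_records(pep2, "heavy")
        assert [a.name for a in rec1] == [a.name for a in rec2]
        assert [a.residue_number for a in rec1] == \
            [a.residue_number for a in rec2]

    def test_parse_selection_specs(self):
        sel = parse_selection("peptide:CA")
        assert sel.target == "peptide" and sel.atom_class == "CA"
        sel = parse_selection("heavy_chain:1-180:CA")
        assert sel.target == "heavy_chain"
        assert sel.residue_range == (1, 180)
        with pytest.raises(ValueError):
            parse_selection("peptide:sidechainz")

    def test_role_based_selection_on_complex(self, toy9):
        complex_structure, _ = toy9
        ca = select_atoms(complex_structure, "peptide:CA")
        assert ca.shape == (9, 3)
        ranged = select_atoms(complex_structure, "heavy_chain:1-10:CA")
        assert ranged.shape == (10, 3)
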