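import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from contactforge.errors import EmptyStructureError, FormatError, MissingAtomError
from contactforge.structure_model import (
    Atom,
    Residue,
    Structure,
    get_cbeta,
    get_centroid,
    min_heavy_distance,
    parse_structure,
    write_pdb,
)
from contactforge.synthetic_fixtures import make_toy_backbone


def _pdb_line(serial, name, resname, chain, resseq, xyz, altloc=" ", occ=1.00, element=None):
    element = element or name.strip()[0]
    name_field = name if len(name) >= 4 else f" {name:<3s}"
    x, y, z = xyz
    return (
        f"ATOM  {serial:5d} {name_field:<4s}{altloc}{resname:<3s} {chain}"
        f"{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


ALA_GLY = "\n".join([
    _pdb_line(1, "N", "ALA", "A", 1, (0.0, 0.0, 0.0)),
    _pdb_line(2, "CA", "ALA", "A", 1, (1.458, 0.0, 0.0)),
    _pdb_line(3, "C", "ALA", "A", 1, (2.009, 1.42, 0.0)),
    _pdb_line(4, "O", "ALA", "A", 1, (1.251, 2.39, 0.0)),
    _pdb_line(5, "CB", "ALA", "A", 1, (2.0, -0.8, -1.2)),
    _pdb_line(6, "N", "GLY", "A", 2, (3.332, 1.536, 0.0)),
    _pdb_line(7, "CA", "GLY", "A", 2, (4.0, 2.8, 0.2)),
    _pdb_line(8, "C", "GLY", "A", 2, (5.5, 2.7, 0.1)),
    _pdb_line(9, "O", "GLY", "A", 2, (6.1, 1.65, 0.0)),
    "END",
])


class TestParseStructure:
    def test_minimal_ala_gly(self):
        structure = parse_structure(ALA_GLY)
        assert len(structure.residues) == 2
        ala, gly = structure.residues
        assert (ala.aa, gly.aa) == ("A", "G")
        assert gly.get_atom("CB") is None
        assert ala.get_atom("CB") is not None

    def test_altloc_highest_occupancy_kept(self):
        text = "\n".join([
            _pdb_line(1, "N", "SER", "A", 1, (0, 0, 0)),
            _pdb_line(2, "CA", "SER", "A", 1, (1.458, 0, 0)),
            _pdb_line(3, "C", "SER", "A", 1, (2.0, 1.4, 0)),
            _pdb_line(4, "CB", "SER", "A", 1, (1.9, -0.8, -1.2), altloc="A", occ=0.60),
            _pdb_line(5, "CB", "SER", "A", 1, (5.0, 5.0, 5.0), altloc="B", occ=0.40),
            "END",
        ])
        structure = parse_structure(text)
        cbs = [a for a in structure.residues[0].atoms if a.name == "CB"]
        assert len(cbs) == 1
        np.testing.assert_allclose(cbs[0].coords, [1.9, -0.8, -1.2], atol=1e-3)

    def test_altloc_tie_prefers_altloc_identifier_order(self):
        text = "\n".join([
            _pdb_line(1, "N", "SER", "A", 1, (0, 0, 0)),
            _pdb_line(2, "CA", "SER", "A", 1, (1.458, 0, 0)),
            _pdb_line(3, "C", "SER", "A", 1, (2.0, 1.4, 0)),
            _pdb_line(4, "CB", "SER", "A", 1, (9.0, 9.0, 9.0), altloc="B", occ=0.50),
            _pdb_line(5, "CB", "SER", "A", 1, (1.9, -0.8, -1.2), altloc="A", occ=0.50),
            "END",
        ])
        structure = parse_structure(text)
        cb = structure.residues[0].get_atom("CB")
        np.testing.assert_allclose(cb.coords, [1.9, -0.8, -1.2], atol=1e-3)

    def test_waters_and_ligands_dropped(self):
        text = ALA_GLY.replace("END", "\n".join([
            "HETATM   10  O   HOH A 101       8.000   8.000   8.000  1.00  0.00           O",
            "HETATM   11 ZN    ZN A 102       9.000   9.000   9.000  1.00  0.00          ZN",
            "END",
        ]))
        structure = parse_structure(text)
        assert len(structure.residues) == 2

    def test_mse_mapped_to_met(self):
        text = "\n".join([
            "HETATM    1  N   MSE A   1       0.000   0.000   0.000  1.00  0.00           N",
            "HETATM    2  CA  MSE A   1       1.458   0.000   0.000  1.00  0.00           C",
            "HETATM    3  C   MSE A   1       2.009   1.420   0.000  1.00  0.00           C",
            "END",
        ])
        structure = parse_structure(text)
        assert structure.residues[0].aa == "M"

    def test_empty_structure_error(self):
        with pytest.raises((EmptyStructureError, FormatError)):
            parse_structure("END\n")

    def test_unparseable_record_raises_format_error(self):
        bad = ALA_GLY.replace("   1.458", "  xx.458")
        with pytest.raises(FormatError):
            parse_structure(bad)

    def test_multi_model_policies(self):
        multi = "MODEL        1\n" + ALA_GLY.replace("END", "ENDMDL\nMODEL        2\n") \
            + ALA_GLY.replace("END", "ENDMDL\nEND")
        structure = parse_structure(multi, model_policy="first")
        assert len(structure.residues) == 2
        with pytest.raises(FormatError):
            parse_structure(multi, model_policy="error-on-multi")

    def test_hydrogens_flagged_not_heavy(self):
        text = ALA_GLY.replace("END", _pdb_line(10, "HB1", "GLY", "A", 2, (4.1, 2.9, 1.2), element="H") + "\nEND")
        structure = parse_structure(text)
        gly = structure.residues[1]
        assert any(a.is_hydrogen for a in gly.atoms)
        assert all(not a.is_hydrogen for a in gly.heavy_atoms())

    def test_roundtrip_helix(self):
        helix = make_toy_backbone("helix", length=20)
        reparsed = parse_structure(write_pdb(helix), "again")
        assert len(reparsed.residues) == 20
        for r1, r2 in zip(helix.residues, reparsed.residues):
            assert r1.aa == r2.aa
            for atom in r1.atoms:
                np.testing.assert_allclose(
                    atom.coords, r2.get_atom(atom.name).coords, atol=1e-3)


def _single_atom_residue(aa, name, xyz, seq_num=1, extra=()):
    atoms = [Atom(name, name[0], np.asarray(xyz, float))]
    atoms += [Atom(n, n[0], np.asarray(x, float)) for n, x in extra]
    return Residue(chain_id="A", seq_num=seq_num, icode="", aa=aa, atoms=atoms)


class TestGeometricPrimitives:
    def test_cbeta_gly_falls_back_to_ca(self):
        res = _single_atom_residue("G", "CA", (1, 2, 3))
        np.testing.assert_allclose(get_cbeta(res), [1, 2, 3])

    def test_cbeta_identity(self):
        res = _single_atom_residue("A", "CA", (9, 9, 9), extra=[("CB", (0, 0, 0))])
        np.testing.assert_allclose(get_cbeta(res), [0, 0, 0])

    def test_cbeta_missing_raises(self):
        res = _single_atom_residue("S", "CA", (0, 0, 0))
        with pytest.raises(MissingAtomError):
            get_cbeta(res)

    def test_centroid_mean_of_sidechain(self):
        res = _single_atom_residue(
            "S", "CA", (9, 9, 9), extra=[("CB", (0, 0, 0)), ("OG", (2, 0, 0))])
        np.testing.assert_allclose(get_centroid(res), [1, 0, 0])

    def test_centroid_single_atom(self):
        res = _single_atom_residue("A", "CA", (9, 9, 9), extra=[("CB", (1, 2, 3))])
        np.testing.assert_allclose(get_centroid(res), [1, 2, 3])

    def test_centroid_gly_is_ca(self):
        res = _single_atom_residue("G", "CA", (4, 5, 6))
        np.testing.assert_allclose(get_centroid(res), [4, 5, 6])

    def test_min_heavy_distance_self_is_zero(self):
        res = _single_atom_residue("A", "CA", (1, 1, 1))
        assert min_heavy_distance(res, res) == 0.0

    def test_min_heavy_distance_direct(self):
        a = _single_atom_residue("A", "CA", (0, 0, 0))
        b = _single_atom_residue("A", "CA", (7.99, 0, 0), seq_num=2)
        assert min_heavy_distance(a, b) == pytest.approx(7.99)

    def test_min_heavy_distance_matches_brute_force(self):
        rng = np.random.default_rng(5)
        pa = rng.normal(size=(3, 3))
        pb = rng.normal(size=(2, 3)) + 4.0
        a = _single_atom_residue("A", "CA", pa[0], extra=[("CB", pa[1]), ("CG", pa[2])])
        b = _single_atom_residue("A", "CA", pb[0], seq_num=2, extra=[("CB", pb[1])])
        expected = min(np.linalg.norm(x - y) for x in pa for y in pb)
        assert min_heavy_distance(a, b) == pytest.approx(expected, abs=1e-12)


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_min_heavy_distance_symmetric_and_bounded(seed):
    rng = np.random.default_rng(seed)
    pa = rng.normal(scale=2.0, size=(4, 3))
    pb = rng.normal(scale=2.0, size=(3, 3)) + rng.normal(scale=5.0, size=3)
    a = Residue("A", 1, "", "A", [Atom("CA", "C", pa[0])]
                + [Atom(f"C{k}", "C", p) for k, p in enumerate(pa[1:])])
    b = Residue("A", 2, "", "A", [Atom("CA", "C", pb[0])]
                + [Atom(f"C{k}", "C", p) for k, p in enumerate(pb[1:])])
    d_ab = min_heavy_distance(a, b)
    assert d_ab == pytest.approx(min_heavy_distance(b, a), abs=1e-12)
    ca_, cb_ = pa.mean(axis=0), pb.mean(axis=0)
    ra = max(np.linalg.norm(pa - ca_, axis=1))
    rb = max(np.linalg.norm(pb - cb_, axis=1))
    assert d_ab <= np.linalg.norm(ca_ - cb_) + ra + rb + 1e-9


@settings(max_examples=20, deadline=None)
@given(st.tuples(st.floats(-50, 50), st.floats(-50, 50), st.floats(-50, 50)))
def test_centroid_translation_equivariance(shift):
    base = _single_atom_residue(
        "S", "CA", (9, 9, 9), extra=[("CB", (0.3, 0.1, -0.2)), ("OG", (1.5, 0.9, 0.4))])
    shifted = Residue(
        "A", 1, "", "S",
        [Atom(a.name, a.element, a.coords + np.array(shift)) for a in base.atoms],
    )
    np.testing.assert_allclose(
        get_centroid(shifted), get_centroid(base) + np.array(shift), atol=1e-9)
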