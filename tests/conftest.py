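import math

import numpy as np
import pytest

from contactforge.rotamers import build_sidechain
from contactforge.structure_model import Atom, Residue, Structure
from contactforge.synthetic_fixtures import make_mini_rotlib, make_toy_backbone


@pytest.fixture(scope="session")
def mini_lib():
    return make_mini_rotlib(aas="ASVLF", rotamers_per_aa=2, seed=11)


@pytest.fixture(scope="session")
def helix20():
    return make_toy_backbone("helix", length=20)


def make_parallel_pair(offset, aa=("A", "A"), seq_sep=5):
    """Two residues with identical local backbone geometry, the second
    translated by ``offset``; sequence numbers ``seq_sep`` apart."""
    offsets = {
        "N": np.array([-0.52, 1.36, 0.0]),
        "CA": np.zeros(3),
        "C": np.array([1.53, 0.0, 0.0]),
        "O": np.array([2.15, -1.05, 0.0]),
    }
    offset = np.asarray(offset, float)
    residues = []
    for k, (aa_code, shift) in enumerate(zip(aa, [np.zeros(3), offset])):
        atoms = [Atom(name, name[0], xyz + shift) for name, xyz in offsets.items()]
        residues.append(
            Residue(chain_id="A", seq_num=1 + k * seq_sep, icode="", aa=aa_code, atoms=atoms)
        )
    return Structure("pair", {"A": residues})


def brute_force_cd(structure, i, j, lib, interfere_cut=3.0):
    """Independent CD oracle: explicit clash pruning, explicit probability
    normalization, and naive double loops over rotamer pairs and atoms."""

    def allowed(pos):
        res = structure.residues[pos]
        backbone = []
        for k, other in enumerate(structure.residues):
            if k == pos:
                continue
            for atom in other.atoms:
                if atom.is_backbone and not atom.is_hydrogen:
                    backbone.append(atom.coords)
        survivors = []
        for aa in lib.amino_acids:
            for rec in lib.lookup(aa, res.phi, res.psi):
                if rec.prob < 1e-4:
                    continue
                placed = build_sidechain(res, rec)
                clash = any(
                    math.dist(atom_xyz, bb_xyz) < 2.0
                    for atom_xyz in placed.coords
                    for bb_xyz in backbone
                )
                if not clash:
                    survivors.append((placed, lib.aa_weights[aa] * rec.prob))
        total = sum(p for _, p in survivors)
        return [(r, p / total) for r, p in survivors] if total > 0 else []

    cd = 0.0
    for rot_i, p_i in allowed(i):
        for rot_j, p_j in allowed(j):
            interferes = any(
                math.dist(xi, xj) < interfere_cut
                for xi in rot_i.coords
                for xj in rot_j.coords
            )
            if interferes:
                cd += p_i * p_j
    return cd
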