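"""Protein structure model.

Parses PDB text into a light-weight chain/residue/atom model and exposes the
geometric primitives used by the contact definitions: Cβ lookup (Cα for Gly),
side-chain centroids, and minimum heavy-atom distances.

Conventions
-----------
* Only the 20 standard amino acids are retained (MSE is mapped to MET; other
  non-standard residues are dropped with a logged warning).
* Alternate locations are resolved to the highest-occupancy conformer, ties
  broken by altloc identifier order.
* Hydrogens are retained but flagged, and never participate in heavy-atom
  geometry.
* Internally residues are addressed by 0-based indices into their chain;
  author numbering is kept for reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from io import StringIO

import numpy as np

from .errors import EmptyStructureError, FormatError, MissingAtomError
from ._geometry import dihedral

logger = logging.getLogger(__name__)

#: Backbone heavy-atom names (OXT is the C-terminal carboxyl oxygen).
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: Maximum C(i)-N(i+1) distance treated as a peptide bond when computing
#: backbone dihedrals.  Generous so that coordinate-perturbed decoys still
#: get phi/psi values.
PEPTIDE_BOND_CUTOFF = 3.0


def _name_looks_hydrogen(name: str) -> bool:
    stripped = name.strip().lstrip("0123456789")
    return stripped[:1] in ("H", "D")


@dataclass
class Atom:
    """A single atom with PDB name, element and coordinates in Å."""

    name: str
    element: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not self.element:
            self.element = "H" if _name_looks_hydrogen(self.name) else self.name.strip()[:1]

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_ATOMS

    @property
    def is_hydrogen(self) -> bool:
        if self.element in ("H", "D"):
            return True
        return _name_looks_hydrogen(self.name)


@dataclass
class Residue:
    """One amino-acid residue; ``aa`` is the one-letter code (or ``X``)."""

    chain_id: str
    seq_num: int
    icode: str
    aa: str
    atoms: list[Atom] = field(default_factory=list)
    phi: float | None = None
    psi: float | None = None
    chain_pos: int = -1  # 0-based index within the chain, set by Structure

    def get_atom(self, name: str) -> Atom | None:
        for atom in self.atoms:
            if atom.name == name:
                return atom
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def heavy_coords(self) -> np.ndarray:
        atoms = self.heavy_atoms()
        if not atoms:
            raise MissingAtomError(
                f"residue {self.chain_id}{self.seq_num}{self.icode.strip()} has no heavy atoms"
            )
        return np.array([a.coords for a in atoms])

    def backbone_heavy_coords(self) -> np.ndarray:
        coords = [a.coords for a in self.atoms if a.is_backbone and not a.is_hydrogen]
        return np.array(coords) if coords else np.empty((0, 3))

    @property
    def label(self) -> str:
        return f"{self.chain_id}{self.seq_num}{self.icode.strip()}"


class Structure:
    """An ordered collection of chains of residues."""

    def __init__(self, struct_id: str, chains: dict[str, list[Residue]]):
        self.id = struct_id
        self.chains: dict[str, list[Residue]] = {}
        for chain_id, residues in chains.items():
            usable = []
            for res in residues:
                if not any(a.is_backbone and not a.is_hydrogen for a in res.atoms):
                    logger.warning(
                        "structure %s: residue %s has no backbone atoms; dropped",
                        struct_id, res.label,
                    )
                    continue
                usable.append(res)
            if usable:
                self.chains[chain_id] = usable
        seen = set()
        for chain_id, residues in self.chains.items():
            for pos, res in enumerate(residues):
                res.chain_pos = pos
                key = (chain_id, res.seq_num, res.icode)
                if key in seen:
                    raise FormatError(f"duplicate residue key {key} in structure {struct_id}")
                seen.add(key)
        if not self.chains:
            raise EmptyStructureError(f"structure {struct_id} contains no usable residues")
        self._residues = [r for residues in self.chains.values() for r in residues]
        compute_backbone_dihedrals(self)

    @property
    def residues(self) -> list[Residue]:
        """All residues, flattened across chains in chain/file order."""
        return self._residues

    def __len__(self) -> int:
        return len(self._residues)

    def sequence(self, chain_id: str) -> str:
        return "".join(r.aa for r in self.chains[chain_id])


def compute_backbone_dihedrals(structure: Structure) -> None:
    """Fill in phi/psi for every residue (None at chain termini or breaks)."""
    for residues in structure.chains.values():
        for k, res in enumerate(residues):
            n, ca, c = res.get_atom("N"), res.get_atom("CA"), res.get_atom("C")
            if n is None or ca is None or c is None:
                continue
            if k > 0:
                prev_c = residues[k - 1].get_atom("C")
                if prev_c is not None and np.linalg.norm(prev_c.coords - n.coords) < PEPTIDE_BOND_CUTOFF:
                    res.phi = dihedral(prev_c.coords, n.coords, ca.coords, c.coords)
            if k + 1 < len(residues):
                next_n = residues[k + 1].get_atom("N")
                if next_n is not None and np.linalg.norm(c.coords - next_n.coords) < PEPTIDE_BOND_CUTOFF:
                    res.psi = dihedral(n.coords, ca.coords, c.coords, next_n.coords)


def _resolve_altlocs(bio_residue) -> list:
    """Highest-occupancy conformer per atom name; ties by altloc identifier."""
    by_name: dict[str, list] = {}
    for atom in bio_residue.get_unpacked_list():
        by_name.setdefault(atom.get_name(), []).append(atom)
    chosen = []
    for candidates in by_name.values():
        candidates.sort(key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()))
        chosen.append(candidates[0])
    chosen.sort(key=lambda a: a.get_serial_number() or 0)
    return chosen


def parse_structure(pdb_text: str, struct_id: str = "struct", model_policy: str = "first") -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Waters and hetero ligands are dropped, MSE is read as MET, hydrogens are
    retained but flagged.  ``model_policy`` is ``"first"`` (use model 1 of a
    multi-model file) or ``"error-on-multi"``.
    """
    from Bio.PDB import PDBParser  # deferred: Bio import is slow

    if model_policy not in ("first", "error-on-multi"):
        raise ValueError(f"unknown model_policy {model_policy!r}")
    parser = PDBParser(PERMISSIVE=0, QUIET=True)
    try:
        bio_structure = parser.get_structure(struct_id, StringIO(pdb_text))
    except EmptyStructureError:
        raise
    except Exception as exc:  # Bio.PDB reports the offending line number
        raise FormatError(f"unparseable PDB record: {exc}") from exc

    models = list(bio_structure)
    if not models:
        raise EmptyStructureError(f"structure {struct_id}: no models found")
    if len(models) > 1 and model_policy == "error-on-multi":
        raise FormatError(f"structure {struct_id} has {len(models)} models")
    model = models[0]

    chains: dict[str, list[Residue]] = {}
    for bio_chain in model:
        residues: list[Residue] = []
        for bio_res in bio_chain:
            hetflag, seq_num, icode = bio_res.get_id()
            resname = bio_res.get_resname().strip()
            if hetflag == "W":
                continue
            if hetflag != " " and resname != "MSE":
                continue
            if resname == "MSE":
                aa = "M"
            elif resname in THREE_TO_ONE:
                aa = THREE_TO_ONE[resname]
            else:
                logger.warning(
                    "structure %s: non-standard residue %s %s%d dropped",
                    struct_id, resname, bio_chain.get_id(), seq_num,
                )
                continue
            atoms = []
            for bio_atom in _resolve_altlocs(bio_res):
                name = bio_atom.get_name()
                if resname == "MSE" and name == "SE":
                    name = "SD"  # selenium takes the sulfur slot
                atoms.append(
                    Atom(
                        name=name,
                        element=(bio_atom.element or "").strip().upper(),
                        coords=np.asarray(bio_atom.get_coord(), dtype=float),
                    )
                )
            residues.append(
                Residue(
                    chain_id=bio_chain.get_id(),
                    seq_num=seq_num,
                    icode=icode if icode != " " else "",
                    aa=aa,
                    atoms=atoms,
                )
            )
        if residues:
            chains[bio_chain.get_id()] = residues
    return Structure(struct_id, chains)


def write_pdb(structure: Structure) -> str:
    """Serialize a structure to minimal PDB text (ATOM/TER/END records)."""
    lines = []
    serial = 1
    for chain_id, residues in structure.chains.items():
        for res in residues:
            resname = ONE_TO_THREE.get(res.aa, "UNK")
            for atom in res.atoms:
                name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
                x, y, z = atom.coords
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s} {resname:<3s} {chain_id}"
                    f"{res.seq_num:4d}{res.icode or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {atom.element:>2s}"
                )
                serial += 1
        lines.append(f"TER   {serial:5d}")
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def get_cbeta(res: Residue) -> np.ndarray:
    """Cβ coordinates; Cα for glycine. Raises MissingAtomError otherwise."""
    cb = res.get_atom("CB")
    if cb is not None:
        return cb.coords
    if res.aa == "G":
        ca = res.get_atom("CA")
        if ca is not None:
            return ca.coords
    raise MissingAtomError(f"residue {res.label} ({res.aa}): no CB atom")


def get_centroid(res: Residue) -> np.ndarray:
    """Mean of non-hydrogen side-chain atom coordinates (CB included).

    Glycine, and any residue with no side-chain heavy atoms, falls back to Cα.
    """
    side = [a.coords for a in res.heavy_atoms() if not a.is_backbone]
    if side:
        return np.mean(side, axis=0)
    ca = res.get_atom("CA")
    if ca is not None:
        return ca.coords
    raise MissingAtomError(f"residue {res.label}: no side-chain heavy atoms and no CA")


def min_heavy_distance(res_i: Residue, res_j: Residue) -> float:
    """Minimum distance over all non-hydrogen atom pairs, backbone included."""
    ci = res_i.heavy_coords()
    cj = res_j.heavy_coords()
    diff = ci[:, None, :] - cj[None, :, :]
    return float(np.sqrt(np.min(np.einsum("ijk,ijk->ij", diff, diff))))
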