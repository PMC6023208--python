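"""Rotamer libraries and side-chain construction.

Two library dialects are supported:

* ``dunbrack2010`` — the backbone-dependent text tables (one rotamer per
  line: resname, phi, psi, count, r1..r4, probability, chi1..chi4 means,
  chi1..chi4 sigmas).
* ``fixture`` — a small whitespace-separated table used for synthetic
  libraries: ``resname phi psi prob chi1 [chi2 chi3 chi4]``, with ``*`` in
  the phi/psi columns marking a backbone-independent record.

Side chains are built from the bundled ideal-geometry table
(``data/ideal_geometry.txt``) by sequential internal-coordinate placement.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from .errors import FormatError, MissingAtomError
from ._geometry import place_atom
from .structure_model import ONE_TO_THREE, Residue, Structure, THREE_TO_ONE

logger = logging.getLogger(__name__)

#: Number of chi dihedrals per amino acid (one-letter codes).
CHI_COUNTS = {
    "A": 0, "R": 4, "N": 2, "D": 2, "C": 1, "Q": 3, "E": 3, "G": 0,
    "H": 2, "I": 2, "L": 2, "K": 4, "M": 3, "F": 2, "P": 2, "S": 1,
    "T": 1, "W": 2, "Y": 2, "V": 1,
}

#: Default fallback backbone dihedrals for chain termini where phi or psi
#: is undefined (beta-region values; a warning is logged when used).
FALLBACK_PHI = -120.0
FALLBACK_PSI = 120.0


def _one_letter(code: str) -> str:
    code = code.strip().upper()
    if len(code) == 3:
        if code not in THREE_TO_ONE:
            raise FormatError(f"unknown amino-acid code {code!r}")
        return THREE_TO_ONE[code]
    if code in CHI_COUNTS:
        return code
    raise FormatError(f"unknown amino-acid code {code!r}")


@dataclass(frozen=True)
class RotamerRecord:
    """One rotamer: chi angles (degrees), probability mass, optional phi/psi bin."""

    aa: str
    chi: tuple[float, ...]
    prob: float
    phi_bin: float | None = None
    psi_bin: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.prob <= 1.0 + 1e-9:
            raise ValueError(f"rotamer probability {self.prob} outside [0, 1]")
        expected = CHI_COUNTS.get(self.aa)
        if expected is not None and len(self.chi) != expected:
            raise ValueError(
                f"{self.aa}: got {len(self.chi)} chi angles, expected {expected}"
            )


class RotamerLibrary:
    """Rotamer records indexed by amino acid and (optionally) phi/psi bin."""

    def __init__(
        self,
        records: list[RotamerRecord],
        aa_weights: dict[str, float] | None = None,
        renormalize: bool = True,
    ):
        self._index: dict[tuple, list[RotamerRecord]] = {}
        for rec in records:
            key = (rec.aa, rec.phi_bin, rec.psi_bin)
            self._index.setdefault(key, []).append(rec)
        self.backbone_dependent = any(key[1] is not None for key in self._index)
        if renormalize:
            self._renormalize()
        aas = self.amino_acids
        if aa_weights is None:
            aa_weights = {aa: 1.0 / len(aas) for aa in aas}
        total = sum(aa_weights.values())
        self.aa_weights = {aa: w / total for aa, w in aa_weights.items()}

    def _renormalize(self) -> None:
        for key, recs in self._index.items():
            total = sum(r.prob for r in recs)
            if total <= 0:
                raise FormatError(f"rotamer probabilities for {key} sum to 0")
            if abs(total - 1.0) > 1e-6:
                if abs(total - 1.0) > 0.01:
                    logger.warning(
                        "rotamer probabilities for %s sum to %.4f; renormalizing", key, total
                    )
                self._index[key] = [
                    RotamerRecord(r.aa, r.chi, r.prob / total, r.phi_bin, r.psi_bin)
                    for r in recs
                ]

    @property
    def amino_acids(self) -> list[str]:
        return sorted({key[0] for key in self._index})

    @property
    def records(self) -> list[RotamerRecord]:
        return [r for recs in self._index.values() for r in recs]

    def lookup(self, aa: str, phi: float | None, psi: float | None) -> list[RotamerRecord]:
        """Records for ``aa`` at the nearest available phi/psi bin.

        Undefined phi/psi (chain termini) fall back to beta-region values
        with a warning.  For backbone-independent libraries phi/psi are
        ignored.
        """
        aa = _one_letter(aa)
        if not self.backbone_dependent:
            return self._index.get((aa, None, None), [])
        if phi is None or psi is None:
            logger.warning(
                "undefined phi/psi for %s lookup; falling back to (%g, %g)",
                aa, FALLBACK_PHI, FALLBACK_PSI,
            )
            phi = FALLBACK_PHI if phi is None else phi
            psi = FALLBACK_PSI if psi is None else psi
        bins = [key[1:] for key in self._index if key[0] == aa]
        if not bins:
            return []

        def bin_distance(b):
            dphi = abs((phi - b[0] + 180.0) % 360.0 - 180.0)
            dpsi = abs((psi - b[1] + 180.0) % 360.0 - 180.0)
            return dphi * dphi + dpsi * dpsi

        best = min(bins, key=bin_distance)
        return self._index[(aa, *best)]


def load_rotamer_library(
    text: str,
    dialect: str = "fixture",
    aa_weights: dict[str, float] | None = None,
) -> RotamerLibrary:
    """Parse a rotamer library in the ``dunbrack2010`` or ``fixture`` dialect."""
    if dialect not in ("dunbrack2010", "fixture"):
        raise ValueError(f"unknown rotamer-library dialect {dialect!r}")
    records: list[RotamerRecord] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        try:
            if dialect == "fixture":
                aa = _one_letter(tokens[0])
                phi = None if tokens[1] == "*" else float(tokens[1])
                psi = None if tokens[2] == "*" else float(tokens[2])
                prob = float(tokens[3])
                chi = tuple(float(t) for t in tokens[4:4 + CHI_COUNTS[aa]])
                if len(chi) != CHI_COUNTS[aa]:
                    raise ValueError(f"expected {CHI_COUNTS[aa]} chi angles")
                records.append(RotamerRecord(aa, chi, prob, phi, psi))
            else:
                aa = _one_letter(tokens[0])
                phi, psi = float(tokens[1]), float(tokens[2])
                prob = float(tokens[8])
                nchi = CHI_COUNTS[aa]
                chi = tuple(float(t) for t in tokens[9:9 + nchi])
                # the +180/-180 phi (and psi) rows duplicate each other;
                # keep the -180 row only
                if phi == 180.0 or psi == 180.0:
                    continue
                records.append(RotamerRecord(aa, chi, prob, phi, psi))
        except FormatError:
            raise
        except (IndexError, ValueError) as exc:
            raise FormatError(f"malformed rotamer-library line {lineno}: {raw!r} ({exc})") from exc
    if not records:
        raise FormatError("rotamer library contains no records")
    return RotamerLibrary(records, aa_weights=aa_weights)


def write_fixture_library(lib: RotamerLibrary) -> str:
    """Serialize a library in the fixture dialect (lossy for aa_weights)."""
    lines = ["# fixture rotamer library: resname phi psi prob chi1..chi4"]
    for rec in lib.records:
        phi = "*" if rec.phi_bin is None else f"{rec.phi_bin:g}"
        psi = "*" if rec.psi_bin is None else f"{rec.psi_bin:g}"
        chis = " ".join(f"{c:.2f}" for c in rec.chi)
        lines.append(f"{ONE_TO_THREE[rec.aa]} {phi} {psi} {rec.prob:.6f} {chis}".rstrip())
    return "\n".join(lines) + "\n"


# --- ideal geometry -------------------------------------------------------

_TORSION_RE = re.compile(r"^(chi[1-4])([+-]\d+(?:\.\d+)?)?$")


@dataclass(frozen=True)
class _AtomSpec:
    name: str
    parent: str
    grand: str
    ggrand: str
    bond: float
    angle: float
    chi_index: int | None  # 0-based, None for fixed torsions
    offset: float  # fixed torsion value, or offset added to the chi angle


def _parse_geometry(text: str) -> dict[str, list[_AtomSpec]]:
    table: dict[str, list[_AtomSpec]] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) != 8:
            raise FormatError(f"malformed geometry line {lineno}: {raw!r}")
        resname, name, parent, grand, ggrand = tokens[:5]
        bond, angle = float(tokens[5]), float(tokens[6])
        tor = tokens[7]
        match = _TORSION_RE.match(tor)
        if match:
            chi_index = int(match.group(1)[3]) - 1
            offset = float(match.group(2) or 0.0)
        else:
            chi_index = None
            offset = float(tor)
        table.setdefault(_one_letter(resname), []).append(
            _AtomSpec(name, parent, grand, ggrand, bond, angle, chi_index, offset)
        )
    return table


_GEOMETRY: dict[str, list[_AtomSpec]] | None = None


def ideal_geometry() -> dict[str, list[_AtomSpec]]:
    """The bundled per-amino-acid internal-coordinate table (cached)."""
    global _GEOMETRY
    if _GEOMETRY is None:
        text = (resources.files("contactforge") / "data" / "ideal_geometry.txt").read_text()
        _GEOMETRY = _parse_geometry(text)
    return _GEOMETRY


@dataclass
class PlacedRotamer:
    """A rotamer realized in space: heavy side-chain atoms (CB included)."""

    aa: str
    atom_names: list[str]
    coords: np.ndarray  # (n_atoms, 3)
    source: RotamerRecord = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.atom_names)


def build_sidechain(
    res_backbone: Residue,
    rot: RotamerRecord,
    geometry: dict[str, list[_AtomSpec]] | None = None,
) -> PlacedRotamer:
    """Construct heavy side-chain atoms for ``rot`` on the residue's backbone.

    Placement is deterministic: atoms are added one at a time from ideal bond
    lengths/angles and the record's chi dihedrals.  Glycine yields an empty
    placement.
    """
    if geometry is None:
        geometry = ideal_geometry()
    placed: dict[str, np.ndarray] = {}
    for bb in ("N", "CA", "C"):
        atom = res_backbone.get_atom(bb)
        if atom is None:
            raise MissingAtomError(f"residue {res_backbone.label}: backbone atom {bb} missing")
        placed[bb] = atom.coords
    names: list[str] = []
    coords: list[np.ndarray] = []
    for spec in geometry.get(rot.aa, []):
        if spec.chi_index is None:
            torsion = spec.offset
        else:
            torsion = rot.chi[spec.chi_index] + spec.offset
        pos = place_atom(
            placed[spec.ggrand], placed[spec.grand], placed[spec.parent],
            spec.bond, spec.angle, torsion,
        )
        placed[spec.name] = pos
        names.append(spec.name)
        coords.append(pos)
    arr = np.array(coords) if coords else np.empty((0, 3))
    return PlacedRotamer(aa=rot.aa, atom_names=names, coords=arr, source=rot)


def allowed_rotamers(
    structure: Structure,
    pos: int,
    lib: RotamerLibrary,
    backbone_clash_cut: float = 2.0,
    prob_floor: float = 1e-4,
    _backbone_tree: cKDTree | None = None,
) -> list[tuple[PlacedRotamer, float]]:
    """Build and prune rotamers of every library amino acid at position ``pos``.

    A rotamer is removed if any heavy side-chain atom lies within
    ``backbone_clash_cut`` Å of any heavy backbone atom of the structure,
    excluding the position's own backbone.  Surviving probabilities
    (aa weight × within-aa probability) are renormalized to sum to 1.
    ``pos`` indexes ``structure.residues``.
    """
    res = structure.residues[pos]
    if _backbone_tree is None:
        _backbone_tree = backbone_tree_excluding(structure, pos)
    survivors: list[tuple[PlacedRotamer, float]] = []
    for aa in lib.amino_acids:
        weight = lib.aa_weights.get(aa, 0.0)
        if weight <= 0:
            continue
        for rec in lib.lookup(aa, res.phi, res.psi):
            if rec.prob < prob_floor:
                continue
            rotamer = build_sidechain(res, rec)
            if len(rotamer) and _backbone_tree is not None:
                dists, _ = _backbone_tree.query(rotamer.coords, k=1)
                if np.min(dists) < backbone_clash_cut:
                    continue
            survivors.append((rotamer, weight * rec.prob))
    total = sum(p for _, p in survivors)
    if total <= 0:
        return []
    return [(r, p / total) for r, p in survivors]


def backbone_tree_excluding(structure: Structure, pos: int) -> cKDTree | None:
    """KD-tree over all heavy backbone atoms except those of residue ``pos``."""
    coords = [
        r.backbone_heavy_coords()
        for k, r in enumerate(structure.residues)
        if k != pos
    ]
    coords = [c for c in coords if len(c)]
    if not coords:
        return None
    return cKDTree(np.vstack(coords))
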