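"""Contact metrics and contact maps.

Four definitions of residue-residue contact are supported:

======== ============================================================ =========
kind     metric                                                       contact
======== ============================================================ =========
cd       rotamer contact degree in [0, 1]                             value >= c (default 0.1)
any_heavy min distance over all heavy-atom pairs (backbone included)  value < 8 Å
cbeta    Cβ-Cβ distance (Cα for Gly)                                  value < 8 Å
centroid side-chain centroid distance                                 value < 6 Å
======== ============================================================ =========

The contact degree of a position pair is the probability-weighted fraction
of allowed (non backbone-clashing) rotamer pairs whose side-chain heavy
atoms approach within ``interfere_cut`` (default 3 Å).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, MissingAtomError
from .rotamers import RotamerLibrary, allowed_rotamers, backbone_tree_excluding
from .structure_model import Residue, Structure, get_cbeta, get_centroid, min_heavy_distance

KINDS = ("cd", "any_heavy", "cbeta", "centroid")

#: Default thresholds per definition kind.
DEFAULT_THRESHOLDS = {"cd": 0.1, "any_heavy": 8.0, "cbeta": 8.0, "centroid": 6.0}

#: Cα-Cα distance beyond which no rotamer pair can interfere; CD is set to 0
#: without enumeration.  Must exceed twice the maximum side-chain extension
#: plus the interference cutoff (~2*8 + 3 Å), which it does.
CD_REACH_BOUND = 25.0


@dataclass(frozen=True)
class ContactDefinition:
    """A contact definition: metric kind, threshold and separation filter."""

    kind: str
    threshold: float | None = None
    min_separation: int = 1

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown contact kind {self.kind!r}")
        if self.threshold is None:
            object.__setattr__(self, "threshold", DEFAULT_THRESHOLDS[self.kind])
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")

    def is_contact(self, value: float) -> bool:
        """CD uses >= threshold; distance kinds use strict <."""
        if self.kind == "cd":
            return value >= self.threshold
        return value < self.threshold

    def with_min_separation(self, min_separation: int) -> "ContactDefinition":
        return replace(self, min_separation=min_separation)

    @classmethod
    def cd(cls, threshold: float = 0.1, min_separation: int = 1) -> "ContactDefinition":
        return cls("cd", threshold, min_separation)

    @classmethod
    def any_heavy(cls, threshold: float = 8.0, min_separation: int = 1) -> "ContactDefinition":
        return cls("any_heavy", threshold, min_separation)

    @classmethod
    def cbeta(cls, threshold: float = 8.0, min_separation: int = 1) -> "ContactDefinition":
        return cls("cbeta", threshold, min_separation)

    @classmethod
    def centroid(cls, threshold: float = 6.0, min_separation: int = 1) -> "ContactDefinition":
        return cls("centroid", threshold, min_separation)


def sequence_separation(i: int, j: int) -> int:
    """|i - j| in chain residue indices."""
    return abs(i - j)


def compute_cd(
    structure: Structure,
    i: int,
    j: int,
    lib: RotamerLibrary,
    interfere_cut: float = 3.0,
    allowed_i: list | None = None,
    allowed_j: list | None = None,
) -> float:
    """Contact degree between positions ``i`` and ``j`` (indices into
    ``structure.residues``).

    Sums P_i(r_i)·P_j(r_j) over allowed rotamer pairs whose side-chain heavy
    atoms come within ``interfere_cut`` Å.  Returns 0 if either allowed set
    is empty.  Pre-computed ``allowed_rotamers`` outputs may be passed to
    avoid recomputation across pairs.
    """
    if i == j:
        raise ValueError("contact degree requires two distinct positions")
    if allowed_i is None:
        allowed_i = allowed_rotamers(structure, i, lib)
    if allowed_j is None:
        allowed_j = allowed_rotamers(structure, j, lib)
    if not allowed_i or not allowed_j:
        return 0.0
    cut2 = interfere_cut * interfere_cut
    cd = 0.0
    for rot_i, p_i in allowed_i:
        if not len(rot_i):
            continue
        ci = rot_i.coords
        for rot_j, p_j in allowed_j:
            if not len(rot_j):
                continue
            diff = ci[:, None, :] - rot_j.coords[None, :, :]
            if np.min(np.einsum("abk,abk->ab", diff, diff)) < cut2:
                cd += p_i * p_j
    return min(cd, 1.0)


@dataclass
class ContactMap:
    """Per-pair metric values and derived binary contacts for one structure.

    Keys of ``pair_values`` are (i, j) with i < j, indexing the flattened
    ``structure.residues`` list.
    """

    structure_id: str
    definition: ContactDefinition
    pair_values: dict[tuple[int, int], float] = field(default_factory=dict)

    @property
    def contacts(self) -> set[tuple[int, int]]:
        return {
            pair for pair, value in self.pair_values.items()
            if self.definition.is_contact(value)
        }

    def to_tsv(self, structure: Structure | None = None) -> str:
        """TSV serialization: chain_i, resnum_i, chain_j, resnum_j, value, is_contact."""
        lines = [
            f"# structure={self.structure_id} kind={self.definition.kind}"
            f" threshold={self.definition.threshold}"
            f" min_separation={self.definition.min_separation}",
            "chain_i\tresnum_i\tchain_j\tresnum_j\tmetric_value\tis_contact",
        ]
        for (i, j), value in sorted(self.pair_values.items()):
            if structure is not None:
                ri, rj = structure.residues[i], structure.residues[j]
                ci, ni, cj, nj = ri.chain_id, ri.seq_num, rj.chain_id, rj.seq_num
            else:
                ci, ni, cj, nj = "-", i, "-", j
            lines.append(
                f"{ci}\t{ni}\t{cj}\t{nj}\t{value:.6g}\t{int(self.definition.is_contact(value))}"
            )
        return "\n".join(lines) + "\n"


def _pair_value(
    definition: ContactDefinition,
    res_i: Residue,
    res_j: Residue,
) -> float:
    if definition.kind == "any_heavy":
        return min_heavy_distance(res_i, res_j)
    if definition.kind == "cbeta":
        return float(np.linalg.norm(get_cbeta(res_i) - get_cbeta(res_j)))
    if definition.kind == "centroid":
        return float(np.linalg.norm(get_centroid(res_i) - get_centroid(res_j)))
    raise AssertionError(definition.kind)


def compute_contact_map(
    structure: Structure,
    definition: ContactDefinition,
    lib: RotamerLibrary | None = None,
    include_cross_chain: bool = False,
    interfere_cut: float = 3.0,
    reach_bound: float = CD_REACH_BOUND,
) -> ContactMap:
    """Populate metric values for all position pairs passing the separation
    filter (within a chain) and, when ``include_cross_chain``, all
    cross-chain pairs.  Pairs with required atoms missing are skipped.
    """
    if definition.kind == "cd" and lib is None:
        raise ConfigurationError("contact definition 'cd' requires a rotamer library")
    residues = structure.residues
    cmap = ContactMap(structure.id, definition)

    allowed_cache: dict[int, list] = {}

    def allowed(pos: int):
        if pos not in allowed_cache:
            tree = backbone_tree_excluding(structure, pos)
            allowed_cache[pos] = allowed_rotamers(structure, pos, lib, _backbone_tree=tree)
        return allowed_cache[pos]

    for i in range(len(residues)):
        for j in range(i + 1, len(residues)):
            ri, rj = residues[i], residues[j]
            if ri.chain_id == rj.chain_id:
                if sequence_separation(ri.chain_pos, rj.chain_pos) < definition.min_separation:
                    continue
            elif not include_cross_chain:
                continue
            try:
                if definition.kind == "cd":
                    ca_i, ca_j = ri.get_atom("CA"), rj.get_atom("CA")
                    if (
                        ca_i is not None and ca_j is not None
                        and np.linalg.norm(ca_i.coords - ca_j.coords) > reach_bound
                    ):
                        cmap.pair_values[(i, j)] = 0.0
                        continue
                    value = compute_cd(
                        structure, i, j, lib,
                        interfere_cut=interfere_cut,
                        allowed_i=allowed(i), allowed_j=allowed(j),
                    )
                else:
                    value = _pair_value(definition, ri, rj)
            except MissingAtomError:
                continue
            cmap.pair_values[(i, j)] = value
    return cmap
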