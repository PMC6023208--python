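"""Evaluation of contact predictions against structure-derived truth.

Covers sequence-to-structure mapping (best MSA row at >= 95% similarity),
true-contact sets (union over mapped structures or a single target
structure), PPV at top-N / top-(f*L) cutoffs, separation-binned PPV, and
the Shannon-entropy contact-map diversity over a 10x10 grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .contacts import ContactDefinition, compute_contact_map
from .errors import ContactForgeError
from .hybrid import MSA
from .rotamers import RotamerLibrary
from .structure_model import Structure

#: Separation bins (inclusive bounds): short 6-11, medium 12-22, long >= 23.
#: A separation of exactly 23 is classed long-range.
DEFAULT_SEPARATION_BINS = {
    "short": (6, 11),
    "medium": (12, 22),
    "long": (23, math.inf),
}


@dataclass
class StructureMSAMap:
    """Mapping of structure residue positions to MSA columns via one row."""

    row: int
    similarity: float
    pos_to_column: dict[int, int]


def _align_similarity(seq_a: str, seq_b: str) -> tuple[float, list[tuple[int, int]]]:
    """Global identity alignment with affine gaps.

    Returns (similarity, aligned index pairs); similarity is the fraction of
    ``seq_a`` positions aligned to an identical residue.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -0.5
    alignment = aligner.align(seq_a, seq_b)[0]
    pairs: list[tuple[int, int]] = []
    identical = 0
    for (a_start, a_end), (b_start, b_end) in zip(*alignment.aligned):
        for offset in range(a_end - a_start):
            ia, ib = a_start + offset, b_start + offset
            pairs.append((ia, ib))
            if seq_a[ia] == seq_b[ib]:
                identical += 1
    similarity = identical / len(seq_a) if seq_a else 0.0
    return similarity, pairs


def map_structure_to_msa(
    struct_seq: str,
    msa: MSA,
    min_similarity: float = 0.95,
) -> StructureMSAMap:
    """Map structure positions to MSA columns through the best-matching row.

    Each MSA row's ungapped sequence is globally aligned against the
    structure sequence; the best row with similarity >= ``min_similarity``
    is chosen, else the highest-similarity row.  Only identically matching
    aligned positions enter the map.
    """
    if msa.n_rows == 0:
        raise ContactForgeError("empty MSA")
    best: tuple[float, int, list[tuple[int, int]]] | None = None
    for row in range(msa.n_rows):
        similarity, pairs = _align_similarity(struct_seq, msa.ungapped(row))
        if best is None or similarity > best[0]:
            best = (similarity, row, pairs)
    similarity, row, pairs = best
    col_of_pos = msa.column_map(row)
    mapping = {
        struct_pos: col_of_pos[row_pos]
        for struct_pos, row_pos in pairs
        if struct_seq[struct_pos] == msa.ungapped(row)[row_pos]
    }
    return StructureMSAMap(row=row, similarity=similarity, pos_to_column=mapping)


@dataclass
class TrueContactSet:
    """MSA column pairs labeled as contacting, with provenance."""

    pairs: set[tuple[int, int]]
    provenance: dict = field(default_factory=dict)

    def __contains__(self, pair: tuple[int, int]) -> bool:
        return tuple(sorted(pair)) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)


def true_contacts(
    structures: list[Structure],
    maps: list[StructureMSAMap],
    definition: ContactDefinition,
    lib: RotamerLibrary | None = None,
    rule: str = "any-structure",
    min_separation: int = 5,
    structure_index: int = 0,
) -> TrueContactSet:
    """Label MSA column pairs as true contacts from mapped structures.

    ``rule="any-structure"`` takes the union over all structures;
    ``rule="single-structure"`` uses only ``structures[structure_index]``.
    The separation filter is applied in MSA column space.
    """
    if rule not in ("any-structure", "single-structure"):
        raise ValueError(f"unknown rule {rule!r}")
    if len(structures) != len(maps):
        raise ValueError("structures and maps must be parallel lists")
    if rule == "single-structure":
        structures = [structures[structure_index]]
        maps = [maps[structure_index]]
    pairs: set[tuple[int, int]] = set()
    for structure, smap in zip(structures, maps):
        cmap = compute_contact_map(structure, definition, lib=lib)
        for (i, j) in cmap.contacts:
            ci = smap.pos_to_column.get(i)
            cj = smap.pos_to_column.get(j)
            if ci is None or cj is None:
                continue
            lo, hi = min(ci, cj), max(ci, cj)
            if hi - lo < min_separation:
                continue
            pairs.add((lo, hi))
    return TrueContactSet(
        pairs=pairs,
        provenance={
            "rule": rule,
            "definition": definition.kind,
            "min_separation": min_separation,
            "n_structures": len(structures),
        },
    )


def _rank(pairs_with_scores) -> list[tuple[int, int]]:
    """Descending-score order with deterministic (i, j) lexicographic tie-break.

    Accepts either an already-ranked list of pairs or an iterable of
    ((i, j), score) / (i, j, score) items.
    """
    items = list(pairs_with_scores)
    if not items:
        return []
    first = items[0]
    if len(first) == 2 and isinstance(first[0], tuple):
        scored = [(tuple(p), float(s)) for p, s in items]
    elif len(first) == 3:
        scored = [((int(i), int(j)), float(s)) for i, j, s in items]
    else:  # already ranked bare pairs
        return [tuple(p) for p in items]
    scored.sort(key=lambda item: (-item[1], item[0]))
    return [pair for pair, _ in scored]


def ppv_at(
    ranked_pairs,
    truth: TrueContactSet,
    N: int | None = None,
    f: float | None = None,
    L: int | None = None,
) -> float:
    """PPV of the top-k predictions, k = N or round(f*L) (floored at 1).

    ``ranked_pairs`` may be scored items (ranked internally with a
    deterministic tie-break) or an already-ranked pair list.
    """
    if (N is None) == (f is None):
        raise ValueError("give exactly one of N or f")
    if f is not None:
        if L is None:
            raise ValueError("f-mode needs the protein length L")
        if not 0.0 <= f <= 1.0:
            raise ValueError("f must lie in [0, 1]")
        k = max(1, int(math.floor(f * L + 0.5)))  # round half up, floor 1
    else:
        if N < 1:
            raise ValueError("N must be a positive integer")
        k = N
    ranked = _rank(ranked_pairs)
    top = ranked[:k]
    if not top:
        return 0.0
    hits = sum(1 for pair in top if pair in truth)
    return hits / len(top)


def separation_binned_ppv(
    ranked_pairs,
    truth: TrueContactSet,
    N: int | None = None,
    bins: dict[str, tuple[float, float]] = None,
) -> dict[str, float]:
    """PPV per sequence-separation bin; pairs are partitioned by separation
    before ranking within each bin.  ``N=None`` evaluates all pairs per bin."""
    if bins is None:
        bins = DEFAULT_SEPARATION_BINS
    ranked = _rank(ranked_pairs)
    result: dict[str, float] = {}
    for label, (lo, hi) in bins.items():
        in_bin = [(i, j) for (i, j) in ranked if lo <= j - i <= hi]
        if not in_bin:
            continue
        top = in_bin[:N] if N is not None else in_bin
        result[label] = sum(1 for pair in top if pair in truth) / len(top)
    return result


def contact_diversity(
    ranked_pairs,
    L: int,
    n_top: int | None = None,
) -> float:
    """Shannon entropy (bits) of the top-⌊L/2⌋ contacts over a 10x10 grid.

    Each pair (i, j), i < j, falls in cell (⌊10 i / L⌋, ⌊10 j / L⌋); the
    entropy is taken over occupied cells with 0·log 0 = 0.
    """
    if L < 2:
        raise ContactForgeError("diversity needs an alignment length of at least 2")
    if n_top is None:
        n_top = L // 2
    ranked = _rank(ranked_pairs)[:n_top]
    if not ranked:
        return 0.0
    cells: dict[tuple[int, int], int] = {}
    for (i, j) in ranked:
        cell = (min(int(10 * i / L), 9), min(int(10 * j / L), 9))
        cells[cell] = cells.get(cell, 0) + 1
    total = sum(cells.values())
    return float(-sum((n / total) * math.log2(n / total) for n in cells.values()))
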