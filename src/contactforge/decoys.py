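"""Decoy discrimination: scoring structures with a contact potential,
ranking natives among decoys, paired rank statistics, and per-contact
decoy elimination.

Rank-table fixtures for the two published decoy benchmarks (56 I-TASSER
proteins, 59 Rosetta proteins; native ranks under four contact potentials)
ship with the package and load via :func:`load_rank_table_fixture`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from io import StringIO

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .contacts import ContactDefinition, compute_contact_map
from .errors import InsufficientDataError
from .potential import AA_INDEX, ContactPotential
from .rotamers import RotamerLibrary
from .structure_model import Structure

logger = logging.getLogger(__name__)


@dataclass
class DecoySet:
    """A native structure plus decoy conformations of the same sequence."""

    protein_id: str
    native: Structure
    decoys: list[Structure]

    def __post_init__(self):
        if not self.decoys:
            raise ValueError("a decoy set needs at least one decoy")
        n = len(self.native.residues)
        for d in self.decoys:
            if len(d.residues) != n:
                raise ValueError(
                    f"decoy {d.id} length {len(d.residues)} != native length {n}"
                )


class RankTable:
    """Per-protein native ranks under several scoring methods."""

    def __init__(self, frame: pd.DataFrame):
        if (frame < 1).any().any():
            raise ValueError("ranks must be positive integers")
        self.frame = frame

    @property
    def methods(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def proteins(self) -> list[str]:
        return list(self.frame.index)

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_tsv(cls, text: str) -> "RankTable":
        frame = pd.read_csv(StringIO(text), sep="\t", index_col=0, comment="#")
        return cls(frame)

    def to_tsv(self) -> str:
        return self.frame.to_csv(sep="\t")


def load_rank_table_fixture(which: str) -> RankTable:
    """Load a bundled rank-table fixture: ``"itasser"`` (56 proteins) or
    ``"rosetta"`` (59 proteins)."""
    names = {
        "itasser": "table2_itasser_ranks.tsv",
        "rosetta": "table3_rosetta_ranks.tsv",
    }
    if which not in names:
        raise ValueError(f"unknown fixture {which!r}; expected one of {sorted(names)}")
    text = (resources.files("contactforge") / "data" / "fixtures" / names[which]).read_text()
    return RankTable.from_tsv(text)


def score_structure(
    structure: Structure,
    potential: ContactPotential,
    definition: ContactDefinition,
    lib: RotamerLibrary | None = None,
    min_separation: int | None = None,
) -> float:
    """Sum of E(a_i, a_j) over all contacting pairs; lower is more favorable.

    ``min_separation`` defaults to the potential's provenance value (falling
    back to the definition's own filter) so scoring matches derivation.
    """
    if min_separation is None:
        min_separation = potential.provenance.get("min_separation", definition.min_separation)
    definition = definition.with_min_separation(min_separation)
    cmap = compute_contact_map(structure, definition, lib=lib)
    residues = structure.residues
    total = 0.0
    for (i, j) in cmap.contacts:
        ai, aj = residues[i].aa, residues[j].aa
        if ai not in AA_INDEX or aj not in AA_INDEX:
            logger.warning("structure %s: skipping pair with non-standard residue", structure.id)
            continue
        total += potential.energy(ai, aj)
    return total


def rank_native(native_score: float, decoy_scores: list[float]) -> int:
    """Competition (min) rank of the native among ascending scores.

    Decoys tied with the native do not worsen its rank.
    """
    return 1 + sum(1 for s in decoy_scores if s < native_score)


def best_method_counts(table: RankTable) -> dict[str, int]:
    """Per method, the number of proteins where its rank equals the row
    minimum; ties count for every tied method."""
    row_min = table.frame.min(axis=1)
    return {m: int((table.frame[m] == row_min).sum()) for m in table.methods}


def column_median(table: RankTable, method: str) -> float:
    """Sample median of one method's ranks (mean of central pair for even n)."""
    return float(table.frame[method].median())


def friedman_paired(table: RankTable, method_a: str, method_b: str) -> tuple[float, float]:
    """Two-treatment Friedman test over paired per-protein ranks.

    Within-row ties get mid-ranks and the usual tie correction is applied;
    the statistic is referred to a chi-square distribution with 1 df.
    Returns ``(statistic, p_value)``.
    """
    a = table.frame[method_a].to_numpy(dtype=float)
    b = table.frame[method_b].to_numpy(dtype=float)
    n = len(a)
    if n < 3:
        raise InsufficientDataError("Friedman test needs at least 3 rows")
    k = 2
    # within-row mid-ranks
    r_a = np.where(a < b, 1.0, np.where(a > b, 2.0, 1.5))
    r_b = 3.0 - r_a
    rank_sums = np.array([r_a.sum(), r_b.sum()])
    stat = 12.0 / (n * k * (k + 1)) * np.sum(rank_sums**2) - 3.0 * n * (k + 1)
    n_ties = int(np.sum(a == b))  # each tied row contributes t=2, t^3-t=6
    correction = 1.0 - (6.0 * n_ties) / (n * k * (k * k - 1))
    if correction <= 0:
        return 0.0, 1.0
    stat /= correction
    return float(stat), float(chi2.sf(stat, df=k - 1))


def elimination_fraction(
    decoy_set: DecoySet,
    definition: ContactDefinition,
    lib: RotamerLibrary | None = None,
) -> float:
    """Average, over native contacts, of the fraction of decoys in which
    that contact is absent under the same definition."""
    native_contacts = compute_contact_map(decoy_set.native, definition, lib=lib).contacts
    if not native_contacts:
        raise InsufficientDataError(
            f"native {decoy_set.native.id} has no contacts under {definition.kind}"
        )
    decoy_contact_sets = [
        compute_contact_map(d, definition, lib=lib).contacts for d in decoy_set.decoys
    ]
    return elimination_fraction_from_sets(native_contacts, decoy_contact_sets)


def elimination_fraction_from_sets(
    native_contacts: set[tuple[int, int]],
    decoy_contact_sets: list[set[tuple[int, int]]],
) -> float:
    """Elimination fraction from pre-computed contact sets (uniform average
    over native contacts)."""
    if not native_contacts:
        raise InsufficientDataError("no native contacts")
    if not decoy_contact_sets:
        raise InsufficientDataError("no decoys")
    n_decoys = len(decoy_contact_sets)
    fractions = [
        sum(1 for dset in decoy_contact_sets if pair not in dset) / n_decoys
        for pair in native_contacts
    ]
    return float(np.mean(fractions))
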