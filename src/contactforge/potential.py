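"""Statistical contact potentials.

A contact potential is a symmetric 20x20 table of log-odds pseudo-energies

    E(a, b) = -ln[ N_c(a,b) / ((1 + I_ab) f(a) f(b) N_c) ]

where N_c(a,b) counts observed contacts between amino acids a and b, f(a)
is the frequency of a in the database, N_c is the total number of contacts,
and I_ab = 1 for hetero pairs.  With the (1 + I) factor in the denominator
("null-normalized" convention, the default) the potential is exactly zero
when amino acids are randomly redistributed among contacts.  An alternative
"as-printed" convention places (1 + I) in the numerator; the two differ by
exactly 2 ln 2 on hetero cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .contacts import ContactDefinition, compute_contact_map
from .errors import ContactForgeError, FormatError, InconsistencyError
from .rotamers import RotamerLibrary
from .structure_model import Structure

#: Canonical amino-acid ordering used for all 20x20 tables.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: k for k, aa in enumerate(AA_ALPHABET)}

CONVENTIONS = ("null-normalized", "as-printed")


@dataclass
class ContactCounts:
    """Symmetric observed contact counts plus database amino-acid frequencies."""

    nc_ab: np.ndarray  # (20, 20), symmetric
    f_a: np.ndarray  # (20,), sums to 1
    provenance: dict = field(default_factory=dict)

    @property
    def nc_total(self) -> float:
        return float(np.sum(np.triu(self.nc_ab)))

    def count(self, a: str, b: str) -> float:
        return float(self.nc_ab[AA_INDEX[a], AA_INDEX[b]])

    @classmethod
    def from_pairs(
        cls,
        pair_counts: dict[tuple[str, str], float],
        frequencies: dict[str, float],
        provenance: dict | None = None,
    ) -> "ContactCounts":
        """Build counts from {(a, b): n} and {a: f} mappings (tests, fixtures)."""
        nc = np.zeros((20, 20))
        for (a, b), n in pair_counts.items():
            ia, ib = AA_INDEX[a], AA_INDEX[b]
            nc[ia, ib] += n
            if ia != ib:
                nc[ib, ia] += n
        f = np.zeros(20)
        for a, freq in frequencies.items():
            f[AA_INDEX[a]] = freq
        total = f.sum()
        if total <= 0:
            raise InconsistencyError("amino-acid frequencies sum to 0")
        return cls(nc_ab=nc, f_a=f / total, provenance=provenance or {})


def count_contacts(
    structures: list[Structure],
    definition: ContactDefinition,
    lib: RotamerLibrary | None = None,
    min_separation: int = 2,
) -> ContactCounts:
    """Count amino-acid pair contacts and residue frequencies over a
    structure set.  Each contacting pair (i < j) increments N_c(a_i, a_j)
    once; residues with unknown amino acids are excluded from both counts
    and frequencies.
    """
    if not structures:
        raise ContactForgeError("count_contacts requires at least one structure")
    definition = definition.with_min_separation(min_separation)
    nc = np.zeros((20, 20))
    aa_counts = np.zeros(20)
    for structure in structures:
        residues = structure.residues
        for res in residues:
            if res.aa in AA_INDEX:
                aa_counts[AA_INDEX[res.aa]] += 1
        cmap = compute_contact_map(structure, definition, lib=lib)
        for (i, j) in cmap.contacts:
            ai, aj = residues[i].aa, residues[j].aa
            if ai not in AA_INDEX or aj not in AA_INDEX:
                continue
            ia, ib = AA_INDEX[ai], AA_INDEX[aj]
            nc[ia, ib] += 1
            if ia != ib:
                nc[ib, ia] += 1
    total = aa_counts.sum()
    if total <= 0:
        raise ContactForgeError("structures contain no standard amino acids")
    provenance = {
        "definition": definition.kind,
        "threshold": definition.threshold,
        "min_separation": min_separation,
        "n_structures": len(structures),
        "structures": [s.id for s in structures],
    }
    return ContactCounts(nc_ab=nc, f_a=aa_counts / total, provenance=provenance)


@dataclass
class ContactPotential:
    """Symmetric 20x20 pseudo-energy table."""

    e_ab: np.ndarray  # (20, 20)
    convention: str = "null-normalized"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.e_ab = np.asarray(self.e_ab, float)
        if self.e_ab.shape != (20, 20):
            raise ValueError("potential table must be 20x20")
        if not np.allclose(self.e_ab, self.e_ab.T, equal_nan=True):
            raise ValueError("potential table must be symmetric")

    def energy(self, a: str, b: str) -> float:
        return float(self.e_ab[AA_INDEX[a], AA_INDEX[b]])

    def energy_by_index(self, ia: int, ib: int) -> float:
        return float(self.e_ab[ia, ib])


def derive_potential(
    counts: ContactCounts,
    convention: str = "null-normalized",
    zero_count_policy: str = "pseudocount",
    pseudocount: float = 0.5,
) -> ContactPotential:
    """Derive a contact potential from observed counts.

    ``zero_count_policy``:
      * ``"pseudocount"`` — add ``pseudocount`` to every unordered cell
        before normalizing totals (keeps all energies finite);
      * ``"none"`` — use raw counts; zero-count cells become +inf.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    if zero_count_policy not in ("pseudocount", "none"):
        raise ValueError(f"unknown zero_count_policy {zero_count_policy!r}")
    nc = counts.nc_ab.astype(float).copy()
    if zero_count_policy == "pseudocount":
        nc += pseudocount  # adds eps to each unordered cell (both mirror cells)
    total = float(np.sum(np.triu(nc)))
    if total <= 0:
        raise ContactForgeError("no contacts observed; cannot derive a potential")
    f = counts.f_a
    for ia in range(20):
        if f[ia] <= 0 and np.sum(counts.nc_ab[ia]) > 0:
            raise InconsistencyError(
                f"amino acid {AA_ALPHABET[ia]} has contacts but frequency 0"
            )
    e = np.full((20, 20), np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        for ia in range(20):
            for ib in range(20):
                if f[ia] <= 0 or f[ib] <= 0:
                    continue
                one_plus_i = 1.0 if ia == ib else 2.0
                if convention == "null-normalized":
                    ratio = nc[ia, ib] / (one_plus_i * f[ia] * f[ib] * total)
                else:
                    ratio = nc[ia, ib] * one_plus_i / (f[ia] * f[ib] * total)
                e[ia, ib] = math.inf if ratio == 0 else -math.log(ratio)
    provenance = dict(counts.provenance)
    provenance.update({"convention": convention, "zero_count_policy": zero_count_policy})
    if zero_count_policy == "pseudocount":
        provenance["pseudocount"] = pseudocount
    return ContactPotential(e_ab=e, convention=convention, provenance=provenance)


def mean_absolute_energy(potential: ContactPotential) -> float:
    """Mean |E(a, b)| over the 210 unordered amino-acid pairs."""
    iu = np.triu_indices(20)
    return float(np.mean(np.abs(potential.e_ab[iu])))


def write_potential_csv(potential: ContactPotential) -> str:
    """CSV serialization: one ``aa1,aa2,energy`` line per unordered pair."""
    lines = []
    for ia, a in enumerate(AA_ALPHABET):
        for ib in range(ia, 20):
            lines.append(f"{a},{AA_ALPHABET[ib]},{potential.e_ab[ia, ib]:.6f}")
    return "\n".join(lines) + "\n"


def read_potential_csv(text: str, convention: str = "null-normalized") -> ContactPotential:
    """Parse a potential CSV; every unordered pair must be present exactly once."""
    e = np.full((20, 20), np.nan)
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.replace("\t", ",").split(",") if p.strip()]
        if len(parts) != 3:
            raise FormatError(f"malformed potential line {lineno}: {raw!r}")
        a, b, energy = parts[0].upper(), parts[1].upper(), parts[2]
        if a not in AA_INDEX or b not in AA_INDEX:
            raise FormatError(f"unknown amino acid on line {lineno}: {raw!r}")
        try:
            value = float(energy)
        except ValueError as exc:
            raise FormatError(f"bad energy on line {lineno}: {raw!r}") from exc
        ia, ib = AA_INDEX[a], AA_INDEX[b]
        e[ia, ib] = value
        e[ib, ia] = value
    iu = np.triu_indices(20)
    missing = [
        f"{AA_ALPHABET[ia]}-{AA_ALPHABET[ib]}"
        for ia, ib in zip(*iu)
        if np.isnan(e[ia, ib])
    ]
    if missing:
        raise FormatError(f"potential CSV missing {len(missing)} pairs: {', '.join(missing[:8])}...")
    return ContactPotential(e_ab=e, convention=convention)
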