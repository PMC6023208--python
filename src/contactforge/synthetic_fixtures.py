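"""Synthetic inputs for tests and desk-scale benchmarks.

Everything here is generated programmatically from a seed: toy backbones
with known geometry, miniature rotamer libraries, compact structure
databases with planted amino-acid pair enrichment (for potential
recovery), synthetic MSAs with planted contact columns plus matching
co-evolution scores, and coordinate-perturbation decoys.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._geometry import place_atom
from .hybrid import MSA, CoevolutionScores
from .evaluation import TrueContactSet
from .potential import AA_ALPHABET, ContactPotential
from .rotamers import CHI_COUNTS, RotamerLibrary, RotamerRecord
from .structure_model import Atom, Residue, Structure
from .decoys import DecoySet

# Engh-Huber-like backbone internal coordinates.
_BB = {
    "n_ca": 1.458, "ca_c": 1.525, "c_n": 1.329, "c_o": 1.231,
    "n_ca_c": 111.2, "ca_c_n": 116.2, "c_n_ca": 121.7, "ca_c_o": 120.5,
}
_CB = {"bond": 1.530, "angle": 110.6, "torsion": -121.6}

_DIHEDRALS = {"helix": (-57.0, -47.0), "strand": (-139.0, 135.0)}


@dataclass
class SyntheticSpec:
    """Parameters for the synthetic generators; same seed => identical output."""

    seed: int = 0
    n_structures: int = 200
    chain_length: int = 50
    planted_pair_enrichment: dict[tuple[str, str], float] = field(default_factory=dict)
    background_frequencies: dict[str, float] | None = None
    msa_depth: int = 100
    planted_contact_columns: int = 10
    favorable_energy_bias: float = 2.0
    noise: float = 0.3

    def __post_init__(self):
        for pair, mult in self.planted_pair_enrichment.items():
            if mult <= 0:
                raise ValueError(f"enrichment multiplier for {pair} must be > 0")


def _chain_from_backbone(
    coords: list[dict[str, np.ndarray]],
    sequence: str,
    chain_id: str,
) -> list[Residue]:
    residues = []
    for k, atom_coords in enumerate(coords):
        atoms = [Atom(name, name[0], xyz) for name, xyz in atom_coords.items()]
        residues.append(
            Residue(chain_id=chain_id, seq_num=k + 1, icode="", aa=sequence[k], atoms=atoms)
        )
    return residues


def _backbone_trace(length: int, phi: float, psi: float, add_cb: bool) -> list[dict[str, np.ndarray]]:
    """Serially built ideal backbone with fixed (phi, psi), omega = 180."""
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([_BB["n_ca"], 0.0, 0.0])
    ang = math.radians(_BB["n_ca_c"])
    c = ca + _BB["ca_c"] * np.array([-math.cos(ang), math.sin(ang), 0.0])
    coords = []
    for _ in range(length):
        atom_coords = {"N": n, "CA": ca, "C": c}
        next_n = place_atom(n, ca, c, _BB["c_n"], _BB["ca_c_n"], psi)
        atom_coords["O"] = place_atom(n, ca, c, _BB["c_o"], _BB["ca_c_o"], psi + 180.0)
        if add_cb:
            atom_coords["CB"] = place_atom(c, n, ca, _CB["bond"], _CB["angle"], _CB["torsion"])
        coords.append(atom_coords)
        next_ca = place_atom(ca, c, next_n, _BB["n_ca"], _BB["c_n_ca"], 180.0)
        next_c = place_atom(c, next_n, next_ca, _BB["ca_c"], _BB["n_ca_c"], phi)
        n, ca, c = next_n, next_ca, next_c
    return coords


def make_toy_backbone(
    kind: str = "helix",
    length: int = 20,
    spacing: float = 10.0,
    sequence: str | None = None,
    add_cb: bool = True,
    struct_id: str | None = None,
) -> Structure:
    """Deterministic toy structure: ``helix``, ``strand-pair`` (two chains
    ``spacing`` Å apart) or ``collinear`` (residues on a line, ``spacing`` Å
    between consecutive Cα; no pair is in contact at spacing 10)."""
    if sequence is None:
        sequence = "A" * length
    if len(sequence) != length:
        raise ValueError("sequence length must match length")
    struct_id = struct_id or f"toy-{kind}"

    if kind in ("helix", "strand"):
        phi, psi = _DIHEDRALS["helix" if kind == "helix" else "strand"]
        coords = _backbone_trace(length, phi, psi, add_cb)
        return Structure(struct_id, {"A": _chain_from_backbone(coords, sequence, "A")})
    if kind == "strand-pair":
        phi, psi = _DIHEDRALS["strand"]
        coords_a = _backbone_trace(length, phi, psi, add_cb)
        shift = np.array([0.0, 0.0, spacing])
        coords_b = [{name: xyz + shift for name, xyz in ac.items()} for ac in coords_a]
        return Structure(struct_id, {
            "A": _chain_from_backbone(coords_a, sequence, "A"),
            "B": _chain_from_backbone(coords_b, sequence, "B"),
        })
    if kind == "collinear":
        offsets = {
            "N": np.array([-0.52, 1.36, 0.0]),
            "CA": np.zeros(3),
            "C": np.array([1.53, 0.0, 0.0]),
        }
        if add_cb:
            offsets["CB"] = np.array([-0.51, -0.77, -1.22])
        coords = [
            {name: np.array([k * spacing, 0.0, 0.0]) + off for name, off in offsets.items()}
            for k in range(length)
        ]
        return Structure(struct_id, {"A": _chain_from_backbone(coords, sequence, "A")})
    raise ValueError(f"unknown backbone kind {kind!r}")


def make_mini_rotlib(
    aas: str = "ASVLF",
    rotamers_per_aa: int = 2,
    seed: int = 0,
) -> RotamerLibrary:
    """Small backbone-independent library enabling exact brute-force CD
    enumeration.  Chi angles cluster near the gauche/trans minima."""
    rng = np.random.default_rng(seed)
    records = []
    for aa in aas:
        nchi = CHI_COUNTS[aa]
        if nchi == 0:
            records.append(RotamerRecord(aa=aa, chi=(), prob=1.0))
            continue
        raw = rng.random(rotamers_per_aa) + 0.2
        probs = raw / raw.sum()
        for p in probs:
            chi = tuple(
                float(rng.choice([-60.0, 60.0, 180.0]) + rng.uniform(-15.0, 15.0))
                for _ in range(nchi)
            )
            records.append(RotamerRecord(aa=aa, chi=chi, prob=float(p)))
    return RotamerLibrary(records)


def make_random_potential(seed: int = 0, scale: float = 0.5) -> ContactPotential:
    """A symmetric random pseudo-energy table (for synthetic benchmarks)."""
    rng = np.random.default_rng(seed)
    raw = rng.normal(0.0, scale, size=(20, 20))
    e = (raw + raw.T) / math.sqrt(2.0)
    return ContactPotential(e_ab=e, provenance={"synthetic": True, "seed": seed, "scale": scale})


def make_compact_chain(seed: int = 0, length: int = 50, radius_factor: float = 3.0) -> Structure:
    """A compact CA/CB chain (self-avoiding-ish walk confined to a sphere);
    useful as a dense random fixture for contact-count and decoy tests."""
    rng = np.random.default_rng(seed)
    ca = np.zeros((length, 3))
    radius = radius_factor * length ** (1.0 / 3.0)
    for k in range(1, length):
        candidate = ca[k - 1]
        for _ in range(200):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            candidate = ca[k - 1] + 3.8 * direction
            if np.linalg.norm(candidate) > radius:
                continue
            if k > 1 and np.min(np.linalg.norm(ca[: k - 1] - candidate, axis=1)) < 3.0:
                continue
            break
        ca[k] = candidate
    directions = rng.normal(size=(length, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    cb = ca + 1.53 * directions
    residues = [
        Residue(
            chain_id="A", seq_num=k + 1, icode="", aa="A",
            atoms=[Atom("CA", "C", ca[k]), Atom("CB", "C", cb[k])],
        )
        for k in range(length)
    ]
    return Structure(f"compact-{seed}", {"A": residues})


def _background_frequencies(spec: SyntheticSpec) -> np.ndarray:
    f = np.full(20, 1.0 / 20.0)
    if spec.background_frequencies:
        f = np.zeros(20)
        for aa, freq in spec.background_frequencies.items():
            f[AA_ALPHABET.index(aa)] = freq
        f /= f.sum()
    return f


def _enriched_joint(spec: SyntheticSpec, f: np.ndarray) -> np.ndarray:
    """Joint amino-acid pair distribution for contacting pairs.

    Starts from the product measure f f^T and, for each planted hetero pair
    (a, b) with multiplier m, moves probability mass delta = (m-1) f_a f_b
    into each of the (a, b) and (b, a) cells, compensating from the (a, a)
    and (b, b) cells.  This preserves the marginals exactly, so the
    null-normalized potential estimator converges to -ln m for the planted
    cell with no frequency-shift bias.
    """
    joint = np.outer(f, f)
    for (a, b), mult in spec.planted_pair_enrichment.items():
        ia, ib = AA_ALPHABET.index(a), AA_ALPHABET.index(b)
        if ia == ib:
            raise ValueError("planted enrichment pairs must be hetero (a != b)")
        delta = (mult - 1.0) * f[ia] * f[ib]
        if joint[ia, ia] - delta < -1e-12 or joint[ib, ib] - delta < -1e-12:
            raise ValueError(
                f"enrichment {mult} for pair ({a},{b}) infeasible at these frequencies"
            )
        joint[ia, ib] += delta
        joint[ib, ia] += delta
        joint[ia, ia] = max(joint[ia, ia] - delta, 0.0)
        joint[ib, ib] = max(joint[ib, ib] - delta, 0.0)
    return joint


def make_synthetic_database(spec: SyntheticSpec, pair_distance: float = 5.0) -> list[Structure]:
    """Structures whose amino acids are assigned independently of geometry,
    except that designated contacting pairs are drawn from an enriched joint
    distribution: a planted multiplier m drives the derived null-normalized
    potential towards E(a, b) = -ln m.

    Geometry: each chain of length n hosts n//4 isolated contact "islands" --
    residue pairs (t, t + n//2) placed ``pair_distance`` Å apart on a widely
    spaced grid (with jitter), all other residues far from everything.  The
    contact graph under the ``cbeta`` definition (8 Å, separation >= 2) is
    therefore exactly the planted perfect matching, whose pair letters come
    from the enriched joint; remaining residues are iid background draws.
    """
    rng = np.random.default_rng(spec.seed)
    f = _background_frequencies(spec)
    joint = _enriched_joint(spec, f)
    flat = joint.ravel()
    n = spec.chain_length
    n_pairs = n // 4
    if n_pairs < 1 or n < 4:
        raise ValueError("chain_length must be at least 4")
    grid_spacing = 20.0

    structures = []
    for s in range(spec.n_structures):
        seq_idx = rng.choice(20, size=n, p=f)
        draws = rng.choice(400, size=n_pairs, p=flat)
        coords = np.zeros((n, 3))
        # widely separated grid sites; islands never touch each other
        site = 0
        for t in range(n_pairs):
            base = np.array([site * grid_spacing, 0.0, 0.0]) + rng.uniform(-1, 1, 3)
            coords[t] = base
            coords[t + n // 2] = base + np.array([pair_distance, 0.0, 0.0])
            seq_idx[t] = draws[t] // 20
            seq_idx[t + n // 2] = draws[t] % 20
            site += 1
        lonely = [k for k in range(n) if not (k < n_pairs or n // 2 <= k < n // 2 + n_pairs)]
        for k in lonely:
            coords[k] = np.array([site * grid_spacing, grid_spacing, 0.0]) + rng.uniform(-1, 1, 3)
            site += 1
        directions = rng.normal(size=(n, 3))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
        cb = coords + 1.0 * directions
        residues = [
            Residue(
                chain_id="A", seq_num=k + 1, icode="", aa=AA_ALPHABET[seq_idx[k]],
                atoms=[Atom("CA", "C", coords[k]), Atom("CB", "C", cb[k])],
            )
            for k in range(n)
        ]
        structures.append(Structure(f"synth-{spec.seed}-{s}", {"A": residues}))
    return structures


def make_synthetic_msa(
    spec: SyntheticSpec,
    potential: ContactPotential,
    min_separation: int = 5,
) -> tuple[MSA, CoevolutionScores, TrueContactSet]:
    """An alignment with planted contact column pairs, co-evolution scores
    (truth indicator plus clipped Gaussian noise) and the recorded truth.

    Planted columns receive amino-acid pairs drawn with probability
    proportional to exp(-bias * E(a, b)); all other cells are uniform.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.chain_length
    depth = spec.msa_depth

    columns = rng.permutation(L)
    planted: set[tuple[int, int]] = set()
    used: set[int] = set()
    idx = 0
    while len(planted) < spec.planted_contact_columns and idx < L:
        i = int(columns[idx]); idx += 1
        if i in used:
            continue
        partners = [
            int(c) for c in columns[idx:]
            if int(c) not in used and abs(int(c) - i) >= min_separation
        ]
        if not partners:
            continue
        j = partners[0]
        used.update((i, j))
        planted.add((min(i, j), max(i, j)))

    weights = np.exp(-spec.favorable_energy_bias * potential.e_ab)
    weights /= weights.sum()
    flat = weights.ravel()

    matrix = rng.integers(0, 20, size=(depth, L))
    for (i, j) in planted:
        draws = rng.choice(400, size=depth, p=flat)
        matrix[:, i] = draws // 20
        matrix[:, j] = draws % 20
    rows = ["".join(AA_ALPHABET[a] for a in row) for row in matrix]
    msa = MSA(ids=[f"seq{r}" for r in range(depth)], rows=rows)

    pair_scores: dict[tuple[int, int], float] = {}
    for i in range(L):
        for j in range(i + min_separation, L):
            signal = 1.0 if (i, j) in planted else 0.0
            pair_scores[(i, j)] = max(0.0, signal + float(rng.normal(0.0, spec.noise)))
    scores = CoevolutionScores(pair_scores=pair_scores, kind="DI")
    truth = TrueContactSet(
        pairs=planted,
        provenance={"synthetic": True, "seed": spec.seed, "min_separation": min_separation},
    )
    return msa, scores, truth


def make_decoys(
    native: Structure,
    n: int = 10,
    perturbation: float = 1.0,
    seed: int = 0,
) -> DecoySet:
    """Coordinate-perturbed copies of the native (iid Gaussian noise per
    atom coordinate); perturbation magnitude controls contact retention."""
    rng = np.random.default_rng(seed)
    decoys = []
    for d in range(n):
        chains = {}
        for chain_id, residues in native.chains.items():
            chains[chain_id] = [
                Residue(
                    chain_id=res.chain_id, seq_num=res.seq_num, icode=res.icode, aa=res.aa,
                    atoms=[
                        Atom(a.name, a.element, a.coords + rng.normal(0.0, perturbation, 3))
                        for a in res.atoms
                    ],
                )
                for res in residues
            ]
        decoys.append(Structure(f"{native.id}-decoy{d}", chains))
    return DecoySet(protein_id=native.id, native=native, decoys=decoys)
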