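"""Hybrid contact scoring: co-evolution scores corrected by MSA-averaged
contact-potential energies.

For a scored column pair (i, j) with co-evolution score S and average
pairwise contact-potential energy Ê over the alignment rows,

    S' = S * (1 - Ê / S_max)

where S_max is the maximum score among pairs passing the separation filter.
Favorable (negative) energies boost the score; pairs whose Ê is undefined
(all rows gapped) keep S unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from io import StringIO

import numpy as np

from .errors import DegenerateInputError, FormatError
from .potential import AA_INDEX, ContactPotential

logger = logging.getLogger(__name__)

GAP_CHARS = frozenset("-.")


@dataclass
class MSA:
    """A multiple sequence alignment: equal-length rows over columns 0..L-1."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if not self.rows:
            raise ValueError("MSA has no rows")
        length = len(self.rows[0])
        if any(len(r) != length for r in self.rows):
            raise ValueError("MSA rows have unequal lengths")
        self.rows = [r.upper().replace(".", "-") for r in self.rows]

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def ungapped(self, row: int) -> str:
        return self.rows[row].replace("-", "")

    def column_map(self, row: int) -> dict[int, int]:
        """Map from ungapped residue index of ``row`` to alignment column."""
        mapping = {}
        pos = 0
        for col, symbol in enumerate(self.rows[row]):
            if symbol not in GAP_CHARS:
                mapping[pos] = col
                pos += 1
        return mapping

    @classmethod
    def from_text(cls, text: str, fmt: str = "fasta") -> "MSA":
        """Parse an alignment from FASTA or Stockholm text."""
        from Bio import AlignIO

        try:
            alignment = AlignIO.read(StringIO(text), fmt)
        except Exception as exc:
            raise FormatError(f"cannot parse {fmt} alignment: {exc}") from exc
        return cls(
            ids=[rec.id for rec in alignment],
            rows=[str(rec.seq) for rec in alignment],
        )

    def to_fasta(self) -> str:
        return "".join(f">{i}\n{r}\n" for i, r in zip(self.ids, self.rows))


@dataclass
class CoevolutionScores:
    """Per column-pair co-evolution scores; keys are (i, j) with i < j, 0-based."""

    pair_scores: dict[tuple[int, int], float]
    kind: str = "DI"  # "DI" (non-negative) or "precision" (nominally [0, 1])

    @property
    def s_max(self) -> float:
        if not self.pair_scores:
            raise DegenerateInputError("no scored pairs")
        return max(self.pair_scores.values())

    def ranked_pairs(self) -> list[tuple[int, int]]:
        """Pairs in descending score order, ties broken lexicographically."""
        return [
            pair for pair, _ in sorted(
                self.pair_scores.items(), key=lambda item: (-item[1], item[0])
            )
        ]

    def to_text(self) -> str:
        lines = [
            f"{i + 1} {j + 1} {score:.6g}"
            for (i, j), score in sorted(self.pair_scores.items())
        ]
        return "\n".join(lines) + "\n"


def parse_scores(
    text: str,
    kind: str = "DI",
    min_separation: int = 5,
) -> CoevolutionScores:
    """Parse (i, j, score) triples; columns are 1-based in files, 0-based in
    memory.  Pairs closer than ``min_separation`` along the sequence are
    dropped before S_max is taken."""
    if kind not in ("DI", "precision"):
        raise ValueError(f"unknown score kind {kind!r}")
    pair_scores: dict[tuple[int, int], float] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.replace(",", " ").split()
        if len(tokens) < 3:
            raise FormatError(f"malformed score line {lineno}: {raw!r}")
        try:
            i, j, score = int(tokens[0]), int(tokens[1]), float(tokens[2])
        except ValueError as exc:
            raise FormatError(f"malformed score line {lineno}: {raw!r}") from exc
        if i == j:
            raise FormatError(f"self-pair on line {lineno}: {raw!r}")
        if score < 0 and kind == "DI":
            raise FormatError(f"negative DI score on line {lineno}: {raw!r}")
        if score > 1 and kind == "precision":
            logger.warning("precision score %.3f > 1 on line %d; kept as-is", score, lineno)
        pair = (min(i, j) - 1, max(i, j) - 1)
        if pair in pair_scores:
            raise FormatError(f"duplicate pair {pair} on line {lineno}")
        if pair[1] - pair[0] < min_separation:
            continue
        pair_scores[pair] = score
    return CoevolutionScores(pair_scores=pair_scores, kind=kind)


def average_pair_energy(
    msa: MSA,
    i: int,
    j: int,
    potential: ContactPotential,
    mode: str = "msa",
    row: int | None = None,
) -> float | None:
    """Mean contact-potential energy over alignment rows at columns (i, j).

    Rows with a gap or non-standard symbol at either column are skipped.
    ``mode="single"`` evaluates one row only (pass ``row``).  Returns None
    when no usable rows remain (callers fall back to the unadjusted score).
    """
    if mode not in ("msa", "single"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "single":
        if row is None:
            raise ValueError("single mode requires a row index")
        row_indices = [row]
    else:
        row_indices = range(msa.n_rows)
    energies = []
    for r in row_indices:
        a, b = msa.rows[r][i], msa.rows[r][j]
        if a not in AA_INDEX or b not in AA_INDEX:
            continue
        energies.append(potential.energy(a, b))
    if not energies:
        return None
    return float(np.mean(energies))


@dataclass
class HybridScores:
    """Adjusted scores S' and the Ê values used to produce them."""

    pair_scores: dict[tuple[int, int], tuple[float, float | None]]  # (S', Ê)
    s_max: float
    raw: CoevolutionScores = field(repr=False, default=None)

    def ranked_pairs(self) -> list[tuple[int, int]]:
        return [
            pair for pair, _ in sorted(
                self.pair_scores.items(), key=lambda item: (-item[1][0], item[0])
            )
        ]

    def adjusted(self, pair: tuple[int, int]) -> float:
        return self.pair_scores[pair][0]

    def to_tsv(self) -> str:
        lines = ["i\tj\tS\tE_avg\tS_adj"]
        for (i, j), (s_adj, e_avg) in sorted(self.pair_scores.items()):
            s = self.raw.pair_scores[(i, j)] if self.raw else float("nan")
            e_txt = "NA" if e_avg is None else f"{e_avg:.6g}"
            lines.append(f"{i + 1}\t{j + 1}\t{s:.6g}\t{e_txt}\t{s_adj:.6g}")
        return "\n".join(lines) + "\n"


def hybrid_score(
    scores: CoevolutionScores,
    energies: dict[tuple[int, int], float | None],
) -> HybridScores:
    """Apply S' = S (1 - Ê / S_max) to every scored pair.

    ``energies`` maps pairs to Ê (or None for the undefined sentinel, which
    leaves S unchanged).
    """
    s_max = scores.s_max
    if s_max <= 0:
        raise DegenerateInputError(f"S_max = {s_max}; cannot normalize energies")
    adjusted: dict[tuple[int, int], tuple[float, float | None]] = {}
    for pair, s in scores.pair_scores.items():
        e_avg = energies.get(pair)
        if e_avg is None:
            adjusted[pair] = (s, None)
        else:
            adjusted[pair] = (s * (1.0 - e_avg / s_max), e_avg)
    return HybridScores(pair_scores=adjusted, s_max=s_max, raw=scores)


def compute_hybrid(
    msa: MSA,
    scores: CoevolutionScores,
    potential: ContactPotential,
    mode: str = "msa",
    row: int | None = None,
    rng: np.random.Generator | None = None,
) -> HybridScores:
    """Convenience pipeline: Ê for every scored pair, then the adjusted scores.

    In ``single`` mode the row is chosen with ``rng`` when not given
    explicitly (mirrors the randomly-selected-sequence protocol).
    """
    if mode == "single" and row is None:
        if rng is None:
            raise ValueError("single mode needs an explicit row or an rng")
        row = int(rng.integers(msa.n_rows))
    energies = {
        pair: average_pair_energy(msa, pair[0], pair[1], potential, mode=mode, row=row)
        for pair in scores.pair_scores
    }
    return hybrid_score(scores, energies)
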