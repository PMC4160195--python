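"""Rooted-triplet data model, file formats, and distance-based triplet inference.

A rooted triplet ``ij|k`` is the rooted binary tree on three taxa in which the
cherry ``{i, j}`` is separated from the outgroup ``k`` by the root.  Triplets
are the elementary building blocks from which trees and networks are
assembled.  This module also implements TCD (Triplets Construction with
Distance): given a symmetric distance matrix ``D``, the triplet ``ij|k`` is
inferred for a 3-subset ``{i, j, k}`` exactly when ``D_ij < min(D_ik, D_jk)``.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence, TextIO

import numpy as np

__all__ = [
    "Triplet",
    "TripletSet",
    "DistanceMatrix",
    "TripletParseError",
    "parse_triplets",
    "write_triplets",
    "read_phylip_matrix",
    "write_phylip_matrix",
    "tcd_triplets",
]


class TripletParseError(ValueError):
    """Raised on malformed triplet or matrix input; carries the line number."""


@dataclass(frozen=True, order=True)
class Triplet:
    """The rooted triplet ``ab|c``: cherry ``{a, b}``, outgroup ``c``.

    The cherry is unordered; the two members are stored sorted so that
    equality and hashing are invariant under swapping them.
    """

    cherry: tuple[str, str]
    outgroup: str

    def __init__(self, a: str, b: str, c: str):
        if not (a and b and c):
            raise ValueError("triplet labels must be non-empty")
        if len({a, b, c}) != 3:
            raise ValueError(f"triplet labels must be distinct, got {a!r} {b!r} {c!r}")
        lo, hi = sorted((a, b))
        object.__setattr__(self, "cherry", (lo, hi))
        object.__setattr__(self, "outgroup", c)

    @property
    def labels(self) -> frozenset[str]:
        return frozenset((*self.cherry, self.outgroup))

    def __str__(self) -> str:
        return f"{self.cherry[0]}{self.cherry[1]}|{self.outgroup}"

    def __repr__(self) -> str:
        return f"Triplet({self.cherry[0]!r}, {self.cherry[1]!r}, {self.outgroup!r})"


class TripletSet:
    """A deduplicated collection of :class:`Triplet`.

    Conflicting triplets on the same 3-subset (e.g. ``ij|k`` and ``ik|j``) are
    allowed; exact duplicates collapse.  The leaf universe ``L(tau)`` is the
    union of all member labels.
    """

    def __init__(self, triplets: Iterable[Triplet] = ()):
        self._triplets: frozenset[Triplet] = frozenset(triplets)

    @classmethod
    def from_tuples(cls, tuples: Iterable[tuple[str, str, str]]) -> "TripletSet":
        return cls(Triplet(a, b, c) for a, b, c in tuples)

    @property
    def labels(self) -> frozenset[str]:
        """``L(tau)``: the union of labels over all member triplets."""
        out: set[str] = set()
        for t in self._triplets:
            out.update(t.labels)
        return frozenset(out)

    def __iter__(self) -> Iterator[Triplet]:
        return iter(sorted(self._triplets))

    def __len__(self) -> int:
        return len(self._triplets)

    def __contains__(self, t: Triplet) -> bool:
        return t in self._triplets

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TripletSet) and self._triplets == other._triplets

    def __hash__(self) -> int:
        return hash(self._triplets)

    def __repr__(self) -> str:
        return f"TripletSet({{{', '.join(str(t) for t in self)}}})"

    def __or__(self, other: "TripletSet") -> "TripletSet":
        return TripletSet(self._triplets | other._triplets)

    def restrict(self, labels: Iterable[str]) -> "TripletSet":
        """Triplets whose three labels all lie inside ``labels``."""
        keep = frozenset(labels)
        return TripletSet(t for t in self._triplets if t.labels <= keep)

    def without_label(self, label: str) -> "TripletSet":
        """Triplets not mentioning ``label``."""
        return TripletSet(t for t in self._triplets if label not in t.labels)

    def is_dense(self) -> bool:
        """True iff every 3-subset of ``L(tau)`` carries at least one triplet.

        Density is what earlier network-building algorithms require; this
        package does not, but the predicate is needed to characterise inputs.
        """
        labels = sorted(self.labels)
        if len(labels) < 3:
            raise ValueError("density is undefined on fewer than 3 taxa")
        covered = {frozenset(t.labels) for t in self._triplets}
        return all(
            frozenset(c) in covered for c in itertools.combinations(labels, 3)
        )


def parse_triplets(stream: TextIO | str) -> TripletSet:
    """Parse the line-oriented triplet format.

    Each non-blank, non-comment (``#``) line holds three whitespace-separated
    labels ``a b c`` meaning ``ab|c``.  Duplicates collapse; malformed lines
    raise :class:`TripletParseError` naming the line.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = stream.read().splitlines()
    triplets = []
    for num, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        if len(tokens) != 3:
            raise TripletParseError(
                f"line {num}: expected 3 labels, got {len(tokens)}: {raw!r}"
            )
        try:
            triplets.append(Triplet(*tokens))
        except ValueError as exc:
            raise TripletParseError(f"line {num}: {exc}") from exc
    return TripletSet(triplets)


def write_triplets(ts: TripletSet) -> str:
    """Canonical text form: one ``a b c`` line per triplet, sorted.

    ``parse_triplets(write_triplets(ts)) == ts`` for every triplet set.
    """
    lines = sorted(f"{t.cherry[0]} {t.cherry[1]} {t.outgroup}" for t in ts)
    return "\n".join(lines) + ("\n" if lines else "")


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance matrix with zero diagonal."""

    labels: list[str]
    d: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError(f"matrix shape {self.d.shape} does not match {n} labels")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        if not np.array_equal(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate taxon labels")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = pair
        return float(self.d[self.labels.index(i), self.labels.index(j)])


def read_phylip_matrix(stream: TextIO | str) -> DistanceMatrix:
    """Read a PHYLIP square distance matrix (first line ``n``, then rows)."""
    text = stream if isinstance(stream, str) else stream.read()
    tokens = text.split()
    if not tokens:
        raise TripletParseError("empty distance-matrix input")
    try:
        n = int(tokens[0])
    except ValueError as exc:
        raise TripletParseError(f"expected taxon count, got {tokens[0]!r}") from exc
    rest = tokens[1:]
    if len(rest) != n * (n + 1):
        raise TripletParseError(
            f"expected {n} rows of a label plus {n} values ({n * (n + 1)} tokens), "
            f"got {len(rest)}"
        )
    labels: list[str] = []
    rows: list[list[float]] = []
    for r in range(n):
        chunk = rest[r * (n + 1) : (r + 1) * (n + 1)]
        labels.append(chunk[0])
        try:
            rows.append([float(v) for v in chunk[1:]])
        except ValueError as exc:
            raise TripletParseError(f"row {labels[-1]!r}: non-numeric entry") from exc
    return DistanceMatrix(labels, np.array(rows))


def write_phylip_matrix(dm: DistanceMatrix) -> str:
    lines = [str(len(dm.labels))]
    for label, row in zip(dm.labels, dm.d):
        lines.append(label + "  " + "  ".join(f"{v:.6f}" for v in row))
    return "\n".join(lines) + "\n"


def tcd_triplets(
    dm: DistanceMatrix, dense_mode: bool = False, seed: int = 0
) -> TripletSet:
    """Infer triplets from a distance matrix by the TCD rule.

    For every 3-subset ``{i, j, k}`` the triplet ``ij|k`` is emitted iff
    ``D_ij < min(D_ik, D_jk)`` (strict).  With ``dense_mode`` ties are broken
    by a seeded uniform choice among the triplets whose cherry attains the
    minimal distance (two-way tie: one of the two tied cherries; three-way
    tie: any of the three triplets), so the result is dense.  Without
    ``dense_mode`` tied 3-subsets contribute nothing, so the output is
    generally non-dense — which this package accepts as input.

    Tie detection compares the given values exactly; callers worried about
    floating-point noise should round first.
    """
    labels = sorted(dm.labels)
    if len(labels) < 3:
        raise ValueError("TCD needs at least 3 taxa")
    rng = random.Random(seed)
    out: list[Triplet] = []
    for i, j, k in itertools.combinations(labels, 3):
        # candidate (cherry, cherry, outgroup) triplets with their distances
        options = [
            (dm[i, j], (i, j, k)),
            (dm[i, k], (i, k, j)),
            (dm[j, k], (j, k, i)),
        ]
        dmin = min(v for v, _ in options)
        winners = [t for v, t in options if v == dmin]
        if len(winners) == 1:
            out.append(Triplet(*winners[0]))
        elif dense_mode:
            out.append(Triplet(*rng.choice(winners)))
    return TripletSet(out)
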