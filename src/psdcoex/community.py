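"""Interaction graphs of antibiotic-mediated microbial communities.

A community of ``N`` strains interacting via ``M`` antibiotics is an ``N x M``
matrix of discrete phenotypes: each strain is, with respect to each
antibiotic, a producer (``P``), sensitive (``S``), a degrader (``D``), or
intrinsically resistant (``R``).  Communities are identified only up to
relabelling of strains (rows) and antibiotics (columns), so structural
descriptors -- PSD-motif coverage, cyclicity, the extension relation -- must
be invariant under those permutations.

Communities are written in a compact bracket notation, e.g. ``[PD,SP,DS]``
for three strains and two antibiotics: the *j*-th letter of the *i*-th entry
is the phenotype of strain *i* with respect to antibiotic *j*.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np

__all__ = [
    "Phenotype",
    "Community",
    "CommunityParseError",
    "parse_community",
    "format_community",
    "psd_coverage",
    "cyclicity",
    "canonicalize",
    "is_extension",
]

#: Letter order used for canonical (lexicographic) comparison.  The integer
#: codes below follow the same order, so comparing code tuples is comparing
#: letters.
LETTERS = "PSDR"
_CODE = {ch: i for i, ch in enumerate(LETTERS)}


class Phenotype(enum.IntEnum):
    """Discrete phenotype of one strain with respect to one antibiotic."""

    P = 0  # producer
    S = 1  # sensitive
    D = 2  # degrader
    R = 3  # intrinsically resistant

    @property
    def letter(self) -> str:
        return LETTERS[self.value]


class CommunityParseError(ValueError):
    """Raised when a community notation string cannot be parsed."""


@dataclass(frozen=True)
class Community:
    """An ``N x M`` phenotype matrix, stored as a tuple of code-tuple rows.

    Rows index strains, columns index antibiotics; entries are the integer
    codes of :class:`Phenotype`.  Instances are immutable and hashable; two
    instances compare equal only if their matrices are entrywise equal (use
    :meth:`equivalent_to` for equality up to strain/antibiotic relabelling).
    """

    rows: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("community must have at least one strain")
        m = len(self.rows[0])
        if m < 1:
            raise ValueError("community must have at least one antibiotic")
        if any(len(r) != m for r in self.rows):
            raise ValueError("phenotype matrix must be rectangular")
        if any(v not in (0, 1, 2, 3) for r in self.rows for v in r):
            raise ValueError("phenotype codes must be in {0,1,2,3}")

    # -- basic geometry ----------------------------------------------------
    @property
    def n_strains(self) -> int:
        return len(self.rows)

    @property
    def n_antibiotics(self) -> int:
        return len(self.rows[0])

    N = n_strains
    M = n_antibiotics

    def column(self, j: int) -> tuple[int, ...]:
        return tuple(r[j] for r in self.rows)

    @property
    def columns(self) -> tuple[tuple[int, ...], ...]:
        return tuple(self.column(j) for j in range(self.n_antibiotics))

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_letters(cls, rows: list[str] | tuple[str, ...]) -> "Community":
        coded = []
        for r in rows:
            try:
                coded.append(tuple(_CODE[ch] for ch in r))
            except KeyError as exc:
                raise ValueError(f"illegal phenotype letter {exc.args[0]!r}") from None
        return cls(tuple(coded))

    # -- indicator matrices used by the dynamics ---------------------------
    def indicator(self, phenotype: Phenotype) -> np.ndarray:
        """0/1 matrix of shape (N, M) marking cells with ``phenotype``."""
        arr = np.asarray(self.rows, dtype=np.uint8)
        return (arr == int(phenotype)).astype(np.float64)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.rows, dtype=np.uint8)

    # -- notation ----------------------------------------------------------
    @property
    def notation(self) -> str:
        return format_community(self)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.notation

    # -- equivalence -------------------------------------------------------
    def canonical(self) -> "Community":
        return canonicalize(self)

    def equivalent_to(self, other: "Community") -> bool:
        """Equality up to strain and antibiotic permutation."""
        return canonicalize(self).rows == canonicalize(other).rows

    def permuted(self, row_perm, col_perm) -> "Community":
        return Community(
            tuple(
                tuple(self.rows[i][j] for j in col_perm) for i in row_perm
            )
        )


def parse_community(text: str) -> Community:
    """Parse bracket notation like ``[PD,SP,DS]`` into a :class:`Community`.

    Whitespace around rows is permitted (``[PDS, SPD, DSP]``).  Raises
    :class:`CommunityParseError` naming the offending row for ragged rows,
    illegal letters, or an empty list.
    """
    s = text.strip()
    if not (s.startswith("[") and s.endswith("]")):
        raise CommunityParseError(
            f"community notation must be bracketed, got {text!r}"
        )
    body = s[1:-1].strip()
    if not body:
        raise CommunityParseError("community notation contains no strains")
    raw_rows = [r.strip() for r in body.split(",")]
    if any(not r for r in raw_rows):
        raise CommunityParseError(f"empty strain entry in {text!r}")
    m = len(raw_rows[0])
    coded: list[tuple[int, ...]] = []
    for i, r in enumerate(raw_rows):
        if len(r) != m:
            raise CommunityParseError(
                f"ragged rows: strain {i} ({r!r}) has {len(r)} letters, "
                f"expected {m}"
            )
        row = []
        for ch in r:
            if ch not in _CODE:
                raise CommunityParseError(
                    f"illegal phenotype letter {ch!r} in strain {i} ({r!r}); "
                    f"allowed letters are P, S, D, R"
                )
            row.append(_CODE[ch])
        coded.append(tuple(row))
    return Community(tuple(coded))


def format_community(c: Community) -> str:
    """Inverse of :func:`parse_community`: ``[PD,SP,DS]`` style notation."""
    return "[" + ",".join("".join(LETTERS[v] for v in r) for r in c.rows) + "]"


def psd_coverage(c: Community) -> int:
    """Number of antibiotics carrying a full producer-sensitive-degrader motif.

    An antibiotic (column) is covered when at least one strain produces it,
    at least one is sensitive to it, and at least one degrades it.  The PSD
    motif is the higher-order attenuation structure central to coexistence.
    """
    count = 0
    for col in c.columns:
        s = set(col)
        if Phenotype.P in s and Phenotype.S in s and Phenotype.D in s:
            count += 1
    return count


def _rotate_down(col: tuple[int, ...]) -> tuple[int, ...]:
    # one element downward: entry i moves to i+1 (cyclically)
    return (col[-1],) + col[:-1]


def cyclicity(c: Community) -> int:
    """Largest number of columns forming a circulant block.

    A set of k columns is circulant when, for some ordering of the strains
    and some ordering of those columns, each successive column equals the
    previous one cyclically rotated one element downward.  Since communities
    are defined only up to strain permutation, the measure is maximized over
    row orderings.  A single column is vacuously circulant, so the result is
    at least 1 for any community; it is at most M.
    """
    n, m = c.n_strains, c.n_antibiotics
    if m == 1:
        return 1
    best = 1
    for row_perm in permutations(range(n)):
        cols = [tuple(c.rows[i][j] for i in row_perm) for j in range(m)]
        # successor edges: j -> l when rotating column j gives column l
        succ: list[list[int]] = [[] for _ in range(m)]
        for j in range(m):
            rj = _rotate_down(cols[j])
            for l in range(m):
                if l != j and cols[l] == rj:
                    succ[j].append(l)

        def longest_from(j: int, used: set[int]) -> int:
            length = 1
            for l in succ[j]:
                if l not in used:
                    used.add(l)
                    length = max(length, 1 + longest_from(l, used))
                    used.remove(l)
            return length

        for j in range(m):
            best = max(best, longest_from(j, {j}))
            if best == m:
                return best
    return best


def canonicalize(c: Community) -> Community:
    """Lexicographically minimal representative of the relabelling orbit.

    Minimal over all row permutations x column permutations under row-major
    comparison with letter order P < S < D < R.  For a fixed column order the
    minimal row arrangement is simply the sorted rows, so only the M! column
    orders need to be searched.  Idempotent; two communities are equivalent
    iff their canonical forms are identical.
    """
    m = c.n_antibiotics
    best: tuple[tuple[int, ...], ...] | None = None
    for col_perm in permutations(range(m)):
        cand = tuple(sorted(tuple(r[j] for j in col_perm) for r in c.rows))
        if best is None or cand < best:
            best = cand
    assert best is not None
    return Community(best)


def is_extension(child: Community, parent: Community) -> bool:
    """Does ``child`` extend ``parent`` by additional antibiotics?

    True iff the communities have the same number of strains, the child has
    strictly more antibiotics, and deleting some subset of the child's
    antibiotic columns leaves a community equivalent (up to relabelling) to
    the parent.  Extensions add interaction channels without altering the
    parent's interaction graph.
    """
    if child.n_strains != parent.n_strains:
        raise ValueError(
            f"strain-count mismatch: child has {child.n_strains}, "
            f"parent has {parent.n_strains}"
        )
    if child.n_antibiotics <= parent.n_antibiotics:
        return False
    target = canonicalize(parent).rows
    for keep in combinations(range(child.n_antibiotics), parent.n_antibiotics):
        sub = Community(tuple(tuple(r[j] for j in keep) for r in child.rows))
        if canonicalize(sub).rows == target:
            return True
    return False

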