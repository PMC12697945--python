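"""Exhaustive enumeration of unique communities up to relabelling.

Two communities describe the same interaction structure when one can be
turned into the other by renaming strains (permuting rows) and renaming
antibiotics (permuting columns).  This module counts and constructs one
canonical representative per equivalence class, subject to redundancy rules
that discard degenerate matrices:

``distinct_strains``
    no two strains may have identical phenotype rows (otherwise they are the
    same strain listed twice);
``distinct_antibiotics``
    no two antibiotics may have identical phenotype columns (otherwise they
    are a single interaction channel counted twice).

Both rules are applied by default; with them the catalogue sizes are 6 for
(N, M) = (2, 1) and 6864 for (3, 3).  A closed-form count in terms of
unsigned Stirling numbers of the first kind is provided for reference; it is
a cycle-index style approximation, not an exact orbit count, and is reported
alongside -- never used as a check against -- the enumerated catalogue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from itertools import combinations, product
from pathlib import Path

import pandas as pd

from .community import Community, canonicalize, cyclicity, format_community, psd_coverage

__all__ = [
    "stirling_first_unsigned",
    "count_formula",
    "enumerate_communities",
    "CommunityCatalogue",
    "DEFAULT_RULES",
    "KNOWN_RULES",
]

#: Redundancy rules applied by default.
DEFAULT_RULES: frozenset[str] = frozenset({"distinct_strains", "distinct_antibiotics"})
KNOWN_RULES: frozenset[str] = frozenset({"distinct_strains", "distinct_antibiotics"})

_SIZE_GUARD = 5


@lru_cache(maxsize=None)
def _stirling(n: int, k: int) -> int:
    if k > n:
        return 0
    if n == 0:
        return 1 if k == 0 else 0
    if k == 0:
        return 0
    return _stirling(n - 1, k - 1) + (n - 1) * _stirling(n - 1, k)


def stirling_first_unsigned(n: int, k: int) -> int:
    """Unsigned Stirling number of the first kind, c(n, k).

    Counts permutations of ``n`` elements with exactly ``k`` cycles, via the
    recurrence c(n, k) = c(n-1, k-1) + (n-1) * c(n-1, k).
    """
    if n < 0 or k < 0:
        raise ValueError("Stirling numbers need nonnegative arguments")
    if k > n:
        raise ValueError(f"need k <= n, got n={n}, k={k}")
    return _stirling(n, k)


def count_formula(n_strains: int, n_antibiotics: int) -> Fraction:
    """Closed-form community count estimate, as an exact rational.

    Evaluates ``(1 / N! M!) * sum_{i,j} c(N, i) c(M, j) 4^(i*j)`` with
    unsigned Stirling numbers c.  The value is generally not an integer and
    does not equal the enumerated catalogue size; it is returned unrounded.
    """
    if n_strains < 1 or n_antibiotics < 1:
        raise ValueError("need N >= 1 and M >= 1")
    import math

    total = 0
    for i in range(n_strains + 1):
        si = stirling_first_unsigned(n_strains, i)
        if si == 0:
            continue
        for j in range(n_antibiotics + 1):
            sj = stirling_first_unsigned(n_antibiotics, j)
            if sj == 0:
                continue
            total += si * sj * 4 ** (i * j)
    return Fraction(total, math.factorial(n_strains) * math.factorial(n_antibiotics))


@dataclass(frozen=True)
class CommunityCatalogue:
    """Ordered collection of all unique (N, M) communities.

    ``members`` are canonical-form communities sorted lexicographically by
    notation, so catalogue generation is bit-reproducible.  ``rules`` records
    the redundancy rules that were applied.
    """

    n_strains: int
    n_antibiotics: int
    members: tuple[Community, ...]
    rules: frozenset[str] = field(default=DEFAULT_RULES)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __getitem__(self, i: int) -> Community:
        return self.members[i]

    @property
    def notations(self) -> list[str]:
        return [m.notation for m in self.members]

    def to_frame(self) -> pd.DataFrame:
        """Structural summary table (one row per community)."""
        return pd.DataFrame(
            {
                "index": range(len(self.members)),
                "canonical_notation": [m.notation for m in self.members],
                "N": self.n_strains,
                "M": self.n_antibiotics,
                "psd_coverage": [psd_coverage(m) for m in self.members],
                "cyclicity": [cyclicity(m) for m in self.members],
            }
        )

    def export(self, csv_path: str | Path, version: str = "0") -> None:
        """Write the catalogue CSV and a JSON sidecar with provenance."""
        csv_path = Path(csv_path)
        self.to_frame().to_csv(csv_path, index=False)
        sidecar = csv_path.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {
                    "N": self.n_strains,
                    "M": self.n_antibiotics,
                    "rules": sorted(self.rules),
                    "count": len(self.members),
                    "tool_version": version,
                },
                indent=2,
            )
        )


def enumerate_communities(
    n_strains: int,
    n_antibiotics: int,
    rules: frozenset[str] | set[str] | None = None,
) -> CommunityCatalogue:
    """Generate every unique (N, M) community under the given rules.

    Strategy: build strain sets as sorted combinations of the 4^M possible
    phenotype rows (which enforces distinct strains and quotients out row
    permutations for free), filter by the remaining rules, canonicalize over
    column permutations, and deduplicate.  Guarded at N, M <= 5.
    """
    if n_strains < 1 or n_antibiotics < 1:
        raise ValueError("need N >= 1 and M >= 1")
    if n_strains > _SIZE_GUARD or n_antibiotics > _SIZE_GUARD:
        raise ValueError(
            f"exhaustive enumeration is guarded at N, M <= {_SIZE_GUARD}"
        )
    if rules is None:
        rules = DEFAULT_RULES
    rules = frozenset(rules)
    unknown = rules - KNOWN_RULES
    if unknown:
        raise ValueError(f"unknown redundancy rules: {sorted(unknown)}")

    row_alphabet = list(product(range(4), repeat=n_antibiotics))
    check_cols = "distinct_antibiotics" in rules
    distinct_rows = "distinct_strains" in rules

    seen: set[tuple[tuple[int, ...], ...]] = set()
    if distinct_rows:
        candidates = combinations(row_alphabet, n_strains)
    else:
        # combinations_with_replacement quotients out row permutations while
        # allowing repeated strains
        from itertools import combinations_with_replacement

        candidates = combinations_with_replacement(row_alphabet, n_strains)
    for rows in candidates:
        if check_cols:
            cols = {tuple(r[j] for r in rows) for j in range(n_antibiotics)}
            if len(cols) != n_antibiotics:
                continue
        seen.add(canonicalize(Community(rows)).rows)

    members = tuple(
        Community(r)
        for r in sorted(seen, key=lambda r: format_community(Community(r)))
    )
    return CommunityCatalogue(n_strains, n_antibiotics, members, rules)
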