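"""Longest common substring via quadrant-order sorting of CGR coordinates.

Every prefix of either string is a point in the cantor CGR map; sorting
the merged point set in *quadrant order* — sub-squares visited (0,0),
(0,1), (1,1), (1,0), i.e. symbol order A < C < T < G on reversed
prefixes — places prefixes with long shared suffixes next to each other,
exactly as a suffix array does for suffixes.  Each comparison needs one
constant-time longest-common-suffix query plus one symbol look-up, so
the sort costs O((N+M) log(N+M)); the maximal cross-string common suffix
is then attained at some adjacent pair of the sorted list, and one scan
with an LCE per cross-origin adjacency finds it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cmp_to_key

from .encoding import CgrIndex, build_index
from .lce import longest_common_suffix
from .sequences import validate

__all__ = ["OrderedPosition", "LcsResult", "coordinate_order", "longest_common_substring"]

#: Quadrant order of the CGR sub-squares: A(0,0) < C(0,1) < T(1,1) < G(1,0).
QUADRANT_RANK = {"A": 0, "C": 1, "T": 2, "G": 3}


@dataclass(frozen=True)
class OrderedPosition:
    """A prefix (origin string, 1-based prefix length) keyed by its cantor coordinate."""

    origin: int
    position: int
    index: CgrIndex = field(compare=False, repr=False)


@dataclass(frozen=True)
class LcsResult:
    """length of the longest common substring and one witness end per string."""

    length: int
    end1: int
    end2: int


def coordinate_order(a: OrderedPosition, b: OrderedPosition) -> int:
    """-1/0/+1 comparator realizing the quadrant order.

    Equivalent to lexicographic comparison of the reversed prefixes under
    A < C < T < G; ties between identical reversed prefixes are broken by
    (length, origin, position) so the order is total.
    """
    if a.index.variant != "cantor" or b.index.variant != "cantor":
        raise ValueError("coordinate_order requires cantor-variant indexes")
    i, j = a.position, b.position
    shared = longest_common_suffix(a.index, i, b.index, j)
    if shared < min(i, j):
        ra = QUADRANT_RANK[a.index.seq[i - shared - 1]]
        rb = QUADRANT_RANK[b.index.seq[j - shared - 1]]
        return -1 if ra < rb else 1
    for x, y in ((i, j), (a.origin, b.origin), (a.position, b.position)):
        if x != y:
            return -1 if x < y else 1
    return 0


def longest_common_substring(s1: str, s2: str) -> LcsResult:
    """Longest common substring of two sequences, O((N+M) log(N+M))."""
    s1 = validate(s1)
    s2 = validate(s2)
    idx1 = build_index(s1, backend="exact")
    idx2 = build_index(s2, backend="exact")
    points = [OrderedPosition(1, i, idx1) for i in range(1, len(s1) + 1)]
    points += [OrderedPosition(2, j, idx2) for j in range(1, len(s2) + 1)]
    points.sort(key=cmp_to_key(coordinate_order))

    best, e1, e2 = 0, 0, 0
    for a, b in zip(points, points[1:]):
        if a.origin == b.origin:
            continue
        ell = longest_common_suffix(a.index, a.position, b.index, b.position)
        if ell > best:
            best = ell
            if a.origin == 1:
                e1, e2 = a.position, b.position
            else:
                e1, e2 = b.position, a.position
    return LcsResult(length=best, end1=e1, end2=e2)
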