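"""Quadtree (CGR-tree) index over reversed prefixes.

Each CGR coordinate of a prefix S[..p] lives in a nested sequence of
quadrants spelled by the *reversed* prefix, so indexing the points with a
quadtree is the same as building a digital search tree over reversed
prefixes — a suffix-tree-like structure up to text inversion.  Nodes
store one text position each; insertion descends along reverse(S[..p])
and places the new node in the first empty child slot (the naive
quadratic construction, which reproduces the worked bracket notation
node-for-node; children always in A, C, G, T order).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .encoding import IndexBundle, build_bundle
from .lce import longest_common_suffix
from .sequences import ALPHABET, validate

__all__ = ["QuadtreeIndex", "qt_build", "qt_serialize", "qt_parse", "qt_matches", "qt_count"]

_SLOT = {c: k for k, c in enumerate(ALPHABET)}


@dataclass
class _Node:
    position: int
    children: list["_Node | None"] = field(default_factory=lambda: [None, None, None, None])


@dataclass
class QuadtreeIndex:
    seq: str
    children: list[_Node | None] = field(default_factory=lambda: [None, None, None, None])

    def nodes(self):
        """Yield all nodes (preorder, A,C,G,T slot order)."""
        stack = [c for c in reversed(self.children) if c is not None]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(c for c in reversed(node.children) if c is not None)


def qt_build(seq: str) -> QuadtreeIndex:
    """Insert reverse(S[..i]) for i = 1..N, first-empty-slot discipline."""
    seq = validate(seq)
    qt = QuadtreeIndex(seq=seq)
    for i in range(1, len(seq) + 1):
        slots = qt.children
        # descend along S[i], S[i-1], ... until an empty slot
        for p in range(i, 0, -1):
            k = _SLOT[seq[p - 1]]
            if slots[k] is None:
                slots[k] = _Node(position=i)
                break
            slots = slots[k].children
    return qt


def _ser(children: list[_Node | None]) -> str:
    parts = []
    for idx, child in enumerate(children):
        if child is None:
            parts.append("")
        else:
            pad = " " if idx > 0 else ""
            parts.append(f"{pad}{child.position}: {_ser(child.children)}")
    return "[" + ",".join(parts) + "]"


def qt_serialize(qt: QuadtreeIndex) -> str:
    """Bracket notation: children in A,C,G,T order, ``p: [..]`` per node."""
    return _ser(qt.children)


def qt_parse(text: str, seq: str = "") -> QuadtreeIndex:
    """Inverse of :func:`qt_serialize` (round-trip checked in tests)."""
    pos = 0

    def parse_children() -> list[_Node | None]:
        nonlocal pos
        if text[pos] != "[":
            raise ValueError(f"expected '[' at offset {pos}")
        pos += 1
        children: list[_Node | None] = []
        for slot in range(4):
            m = re.match(r"\s*(\d+):\s*", text[pos:])
            if m:
                pos += m.end()
                node = _Node(position=int(m.group(1)))
                node.children = parse_children()
                children.append(node)
            else:
                children.append(None)
            expected = "," if slot < 3 else "]"
            if pos >= len(text) or text[pos] != expected:
                raise ValueError(f"expected {expected!r} at offset {pos}")
            pos += 1
        return children

    children = parse_children()
    if pos != len(text):
        raise ValueError("trailing characters after quadtree")
    return QuadtreeIndex(seq=seq, children=children)


def qt_matches(
    qt: QuadtreeIndex, pattern: str, bundle: IndexBundle | None = None
) -> list[int]:
    """All start positions of ``pattern`` in the indexed text, O(L + occ).

    Descends along reverse(P).  A node met at depth d < L stores a
    position p whose reversed prefix merely *starts* like reverse(P), so
    it is reported only if a constant-time coordinate check (a
    longest-common-suffix query at (p, L) on the direct cantor indexes)
    certifies the full match.  Once depth L is reached, every node of the
    subtree is an occurrence.  Starts are returned sorted ascending.
    """
    pattern = validate(pattern)
    L = len(pattern)
    n = len(qt.seq)
    if L > n:
        return []
    if bundle is None:
        bundle = build_bundle(qt.seq, {"direct"}, backend="exact")
    pb = build_bundle(pattern, {"direct"}, params=bundle.params, backend=bundle.backend)
    ends: list[int] = []

    slots = qt.children
    node = None
    for depth in range(1, L + 1):
        k = _SLOT[pattern[L - depth]]  # reverse(P)[depth]
        node = slots[k]
        if node is None:
            break  # path ends early; hits found on the way still stand
        p = node.position
        if depth < L:
            if p >= L and longest_common_suffix(bundle.direct, p, pb.direct, L) == L:
                ends.append(p)
            slots = node.children
    else:
        # depth L reached: every node of the subtree at `node` matches
        stack = [node]
        while stack:
            nd = stack.pop()
            ends.append(nd.position)
            stack.extend(c for c in nd.children if c is not None)
    return sorted(e - L + 1 for e in ends)


def qt_count(qt: QuadtreeIndex, pattern: str, bundle: IndexBundle | None = None) -> int:
    """Number of occurrences of ``pattern`` in the indexed text."""
    return len(qt_matches(qt, pattern, bundle))
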