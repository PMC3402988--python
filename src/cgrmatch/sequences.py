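"""DNA sequence primitives shared by every module.

Sequences are plain Python strings over the alphabet {A, C, G, T}.  All
public APIs use 1-based, inclusive positions: ``S[i..j]`` denotes the
substring from the i'th to the j'th symbol, both ends included, so
``|S[i..j]| = j - i + 1``.  Helpers for 0-based half-open conversion live
at the I/O boundary (:mod:`cgrmatch.io`).
"""

from __future__ import annotations

ALPHABET = "ACGT"

#: Vertex assignment of the CGR unit square: each base maps to a corner,
#: and complementary bases (A/T, C/G) sit at corners related by flipping
#: both coordinate bits.
VERTICES: dict[str, tuple[int, int]] = {
    "A": (0, 0),
    "C": (0, 1),
    "G": (1, 0),
    "T": (1, 1),
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class SequenceError(ValueError):
    """A sequence (or pattern) violates the ACGT contract."""


class InvalidSymbolError(SequenceError):
    """Non-ACGT symbol; carries the 1-based offending position."""

    def __init__(self, symbol: str, position: int, record: str | None = None):
        self.symbol = symbol
        self.position = position
        self.record = record
        where = f"record {record!r}, " if record else ""
        super().__init__(
            f"invalid symbol {symbol!r} at {where}position {position} "
            "(expected one of A, C, G, T)"
        )


def validate(seq: str, record: str | None = None, allow_empty: bool = False) -> str:
    """Uppercase ``seq`` and reject anything outside {A, C, G, T}.

    Raises :class:`InvalidSymbolError` naming the first offending 1-based
    position, or :class:`SequenceError` for an empty sequence unless
    ``allow_empty`` is set.
    """
    s = seq.upper()
    if not s and not allow_empty:
        raise SequenceError("empty sequence" + (f" in record {record!r}" if record else ""))
    for pos, ch in enumerate(s, start=1):
        if ch not in VERTICES:
            raise InvalidSymbolError(ch, pos, record)
    return s


def reverse(seq: str) -> str:
    """S^r — the sequence read backwards."""
    return seq[::-1]


def complement(seq: str) -> str:
    """S^c — base-pair complement (A<->T, C<->G), same orientation."""
    return seq.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    """S^rc — the Watson-Crick reverse complement."""
    return seq.translate(_COMPLEMENT)[::-1]


def split_ambiguous(seq: str) -> list[tuple[int, str]]:
    """Break a sequence at non-ACGT symbols into maximal clean runs.

    Returns ``(start, run)`` pairs with 1-based starts in the original
    coordinates.  Used by the ``split`` ambiguity policy.
    """
    s = seq.upper()
    runs: list[tuple[int, str]] = []
    start = None
    for pos, ch in enumerate(s, start=1):
        if ch in VERTICES:
            if start is None:
                start = pos
        else:
            if start is not None:
                runs.append((start, s[start - 1 : pos - 1]))
                start = None
    if start is not None:
        runs.append((start, s[start - 1 :]))
    return runs
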