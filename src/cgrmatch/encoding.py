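"""Chaos Game Representation (CGR) encoding of DNA sequences.

The CGR of a sequence S over {A, C, G, T} assigns each base a corner of
the unit square (A=(0,0), C=(0,1), G=(1,0), T=(1,1)) and maps every
prefix S[..i] to a point by the iterated-function-system step

    x_i = x_{i-1} + r * (y_i - x_{i-1}),

starting from an initial point x0.  Two presets matter here:

* ``standard``: r = 1/2, x0 = (1/2, 1/2) — the classical CGR, in which
  prefixes sharing an L-long suffix land within 2^-L of each other
  (a necessary but *not* sufficient condition, due to binary carries);
* ``cantor``:   r = 2/3, x0 = (2/3, 2/3) — the same map squeezed onto
  the Cantor set, so every coordinate has a base-3 expansion using only
  the digits {0, 2}.  Carries can no longer mask mismatches, and
  proximity below 3^-L becomes *equivalent* to sharing an L-suffix,
  which is what makes constant-time longest-common-suffix queries work.

Under the cantor preset the base-3 fractional expansion of an i-symbol
prefix is, most significant digit first,

    2*bit(S[i]), 2*bit(S[i-1]), ..., 2*bit(S[1]), 2, 0, 0, ...

per axis (the trailing "2" is the x0 = 2/3 tail).  The ``exact`` backend
stores those digit sequences as packed integers instead of floats, which
makes every query exact at any sequence length.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .sequences import VERTICES, SequenceError, reverse, complement, reverse_complement, validate

__all__ = [
    "CgrParams",
    "CgrIndex",
    "ExactCoordinate",
    "IndexBundle",
    "UnsupportedConfigError",
    "build_index",
    "build_bundle",
    "closed_form_coordinate",
    "left_delete",
    "left_insert",
    "right_insert",
    "right_delete",
    "decode_sequence",
    "kmer_counts",
]

_SYMBOL_OF_BITS = {v: k for k, v in VERTICES.items()}


class UnsupportedConfigError(ValueError):
    """Backend/parameter combination outside the defined domain."""


@dataclass(frozen=True)
class CgrParams:
    """Contraction ratio r (1/2 <= r < 1) and initial point x0 in [0,1]^2."""

    r: float
    x0: tuple[float, float]

    def __post_init__(self) -> None:
        if not (0.5 <= self.r < 1.0):
            raise ValueError(f"contraction ratio must satisfy 1/2 <= r < 1, got {self.r}")
        if not all(0.0 <= c <= 1.0 for c in self.x0):
            raise ValueError(f"x0 must lie in the unit square, got {self.x0}")

    @classmethod
    def standard(cls) -> "CgrParams":
        return cls(r=0.5, x0=(0.5, 0.5))

    @classmethod
    def cantor(cls) -> "CgrParams":
        return cls(r=2.0 / 3.0, x0=(2.0 / 3.0, 2.0 / 3.0))

    @property
    def variant(self) -> str:
        if self == CgrParams.standard():
            return "standard"
        if self == CgrParams.cantor():
            return "cantor"
        return "custom"


@dataclass(frozen=True)
class ExactCoordinate:
    """Cantor-embedded coordinate as per-axis base-3 digit sequences.

    ``xbits``/``ybits`` hold digit/2 bits packed most-significant-first:
    the binary rendering of ``xbits`` over ``length`` bits is exactly the
    axis-1 digit string (0s and 2s halved).  Digit at fractional position
    m (1-based) is 2 * (axis bit of symbol S[i-m+1]); the implicit tail
    is one digit 2 followed by zeros.
    """

    length: int
    xbits: int
    ybits: int

    @classmethod
    def encode(cls, seq: str) -> "ExactCoordinate":
        seq = validate(seq, allow_empty=True)
        xb = yb = 0
        for p, ch in enumerate(seq):  # bit p-1 (0-based p) holds symbol S[p+1]
            bx, by = VERTICES[ch]
            xb |= bx << p
            yb |= by << p
        return cls(length=len(seq), xbits=xb, ybits=yb)

    @classmethod
    def from_digits(cls, xdigits: str, ydigits: str) -> "ExactCoordinate":
        if len(xdigits) != len(ydigits):
            raise ValueError("axis digit strings must have equal length")
        for s in (xdigits, ydigits):
            bad = set(s) - {"0", "2"}
            if bad:
                raise ValueError(f"malformed digit sequence: digits {sorted(bad)} not in {{0, 2}}")
        n = len(xdigits)
        xb = int(xdigits.replace("2", "1"), 2) if n else 0
        yb = int(ydigits.replace("2", "1"), 2) if n else 0
        return cls(length=n, xbits=xb, ybits=yb)

    def digits(self, axis: int) -> str:
        """Base-3 content digits of the given axis (1 or 2), MSB first."""
        bits = self.xbits if axis == 1 else self.ybits
        if self.length == 0:
            return ""
        return format(bits, f"0{self.length}b").replace("1", "2")

    def value(self) -> tuple[Fraction, Fraction]:
        """Exact numeric value per axis, including the x0 = 2/3 tail."""
        out = []
        p3 = 3 ** self.length
        for bits in (self.xbits, self.ybits):
            num = 0
            scale = 1  # 3^(length-m) for digit position m = length..1
            for p in range(self.length):
                if (bits >> p) & 1:
                    num += 2 * scale
                scale *= 3
            out.append(Fraction(num, p3) + Fraction(2, 3 * p3))
        return (out[0], out[1])

    def as_floats(self) -> tuple[float, float]:
        vx, vy = self.value()
        return (float(vx), float(vy))


class CgrIndex:
    """A sequence plus the CGR coordinates of all its prefixes.

    Entry i (0 <= i <= N) is the coordinate of prefix S[..i]; entry 0 is
    x0.  The float backend keeps an (N+1) x 2 float64 matrix; the exact
    backend (cantor preset only) keeps the two packed digit integers of
    the full sequence, from which any prefix coordinate is a bit slice.
    """

    def __init__(self, seq: str, params: CgrParams | None = None, backend: str = "float"):
        params = params or CgrParams.cantor()
        if backend not in ("float", "exact"):
            raise ValueError(f"unknown backend {backend!r}")
        self.seq = validate(seq)
        self.params = params
        self.backend = backend
        self.variant = params.variant
        self.N = len(self.seq)
        if backend == "exact":
            if self.variant != "cantor":
                raise UnsupportedConfigError(
                    "exact backend requires the cantor preset (r=2/3, x0=(2/3,2/3)); "
                    f"got r={params.r}, x0={params.x0}"
                )
            full = ExactCoordinate.encode(self.seq)
            self._rx, self._ry = full.xbits, full.ybits
            self._coords = None
        else:
            r = params.r
            coords = np.empty((self.N + 1, 2), dtype=np.float64)
            coords[0] = params.x0
            x, y = params.x0
            for i, ch in enumerate(self.seq, start=1):
                vx, vy = VERTICES[ch]
                x += r * (vx - x)
                y += r * (vy - y)
                coords[i, 0] = x
                coords[i, 1] = y
            self._coords = coords

    @property
    def coords(self) -> np.ndarray:
        """(N+1) x 2 coordinate matrix (float backend only)."""
        if self._coords is None:
            raise UnsupportedConfigError("exact backend stores digits, not a float matrix")
        return self._coords

    def coordinate(self, i: int) -> tuple[float, float]:
        """Coordinate of prefix S[..i] as floats, O(1) on the float backend."""
        self._check_pos(i)
        if self._coords is not None:
            return (float(self._coords[i, 0]), float(self._coords[i, 1]))
        return self.exact_coordinate(i).as_floats()

    def exact_coordinate(self, i: int) -> ExactCoordinate:
        self._check_pos(i)
        if self.backend != "exact":
            raise UnsupportedConfigError("exact coordinates require the exact backend")
        mask = (1 << i) - 1
        return ExactCoordinate(length=i, xbits=self._rx & mask, ybits=self._ry & mask)

    def content_bits(self, i: int) -> tuple[int, int]:
        """Packed digit/2 bits of prefix S[..i] (exact backend), no copy of tails."""
        mask = (1 << i) - 1
        return (self._rx & mask, self._ry & mask)

    def _check_pos(self, i: int) -> None:
        if not (0 <= i <= self.N):
            raise IndexError(f"position {i} out of range 0..{self.N}")

    def __len__(self) -> int:
        return self.N


def build_index(seq: str, params: CgrParams | None = None, backend: str = "float") -> CgrIndex:
    """Encode ``seq`` under ``params`` (default: cantor preset)."""
    return CgrIndex(seq, params, backend)


def closed_form_coordinate(seq: str, params: CgrParams, i: int) -> tuple[float, float]:
    """Coordinate of prefix S[..i] by direct summation (non-recursive form).

    x_i = (1-r)^i x0 + r * sum_{k=1..i} (1-r)^(i-k) y_k.  Independent of
    the iterative path; used to cross-check :func:`build_index`.
    """
    seq = validate(seq)
    if not (0 <= i <= len(seq)):
        raise IndexError(f"position {i} out of range 0..{len(seq)}")
    r = params.r
    q = 1.0 - r
    terms_x = [q**i * params.x0[0]]
    terms_y = [q**i * params.x0[1]]
    for k in range(1, i + 1):
        vx, vy = VERTICES[seq[k - 1]]
        w = r * q ** (i - k)
        terms_x.append(w * vx)
        terms_y.append(w * vy)
    return (math.fsum(terms_x), math.fsum(terms_y))


class IndexBundle:
    """Direct / reverse / complement / reverse-complement indexes of one sequence.

    Members are built lazily on first access; all share variant, backend
    and parameters.  The algorithms each declare which members they touch
    (e.g. LCE needs ``reverse``, palindromes need ``direct`` + ``revcomp``).
    """

    _TRANSFORMS = {
        "direct": lambda s: s,
        "reverse": reverse,
        "complement": complement,
        "revcomp": reverse_complement,
    }

    def __init__(
        self,
        seq: str,
        params: CgrParams | None = None,
        backend: str = "float",
        which: set[str] | None = None,
    ):
        self.seq = validate(seq)
        self.params = params or CgrParams.cantor()
        self.backend = backend
        self.variant = self.params.variant
        self._members: dict[str, CgrIndex] = {}
        for name in which or ():
            self._get(name)

    def _get(self, name: str) -> CgrIndex:
        if name not in self._TRANSFORMS:
            raise KeyError(f"unknown index member {name!r}")
        if name not in self._members:
            self._members[name] = CgrIndex(
                self._TRANSFORMS[name](self.seq), self.params, self.backend
            )
        return self._members[name]

    @property
    def direct(self) -> CgrIndex:
        return self._get("direct")

    @property
    def reverse(self) -> CgrIndex:
        return self._get("reverse")

    @property
    def complement(self) -> CgrIndex:
        return self._get("complement")

    @property
    def revcomp(self) -> CgrIndex:
        return self._get("revcomp")

    @property
    def N(self) -> int:
        return len(self.seq)


def build_bundle(
    seq: str,
    which: set[str] | None = None,
    params: CgrParams | None = None,
    backend: str = "float",
) -> IndexBundle:
    return IndexBundle(seq, params=params, backend=backend, which=which)


# ---------------------------------------------------------------------------
# Incremental edit operations (constant-time coordinate updates)
# ---------------------------------------------------------------------------

def _vertex(symbol: str) -> tuple[int, int]:
    symbol = symbol.upper()
    if symbol not in VERTICES:
        raise SequenceError(f"invalid symbol {symbol!r}")
    return VERTICES[symbol]


def left_delete(x, first_symbol: str, N: int | None = None, params: CgrParams | None = None):
    """Coordinate of S with its first symbol removed.

    Float form: x - r(1-r)^(N-1) (y_first - x0).  On the exact backend the
    first symbol owns the least-significant content digit, so deletion is
    a one-bit shift.
    """
    bx, by = _vertex(first_symbol)
    if isinstance(x, ExactCoordinate):
        if x.length == 0:
            raise ValueError("cannot left-delete from the empty string")
        if (x.xbits & 1, x.ybits & 1) != (bx, by):
            raise ValueError(f"first symbol {first_symbol!r} does not match the coordinate")
        return ExactCoordinate(x.length - 1, x.xbits >> 1, x.ybits >> 1)
    if N is None or params is None:
        raise TypeError("float-mode left_delete requires N and params")
    if N < 1:
        raise ValueError("cannot left-delete from the empty string")
    r, q = params.r, 1.0 - params.r
    w = r * q ** (N - 1)
    return (x[0] - w * (bx - params.x0[0]), x[1] - w * (by - params.x0[1]))


def left_insert(x, symbol: str, N: int | None = None, params: CgrParams | None = None):
    """Coordinate of alpha+S given the coordinate of the N-symbol S.

    Float form: x + r(1-r)^N (y_alpha - x0) — the exact inverse of
    :func:`left_delete` (and consistent with the closed-form sum).
    """
    bx, by = _vertex(symbol)
    if isinstance(x, ExactCoordinate):
        return ExactCoordinate(x.length + 1, (x.xbits << 1) | bx, (x.ybits << 1) | by)
    if N is None or params is None:
        raise TypeError("float-mode left_insert requires N and params")
    r, q = params.r, 1.0 - params.r
    w = r * q**N
    return (x[0] + w * (bx - params.x0[0]), x[1] + w * (by - params.x0[1]))


def right_insert(x, symbol: str, params: CgrParams | None = None):
    """One CGR step: append ``symbol`` to the encoded string."""
    bx, by = _vertex(symbol)
    if isinstance(x, ExactCoordinate):
        # appended symbol becomes the new most significant content digit
        return ExactCoordinate(
            x.length + 1, x.xbits | (bx << x.length), x.ybits | (by << x.length)
        )
    if params is None:
        raise TypeError("float-mode right_insert requires params")
    r = params.r
    return (x[0] + r * (bx - x[0]), x[1] + r * (by - x[1]))


def right_delete(x, last_symbol: str, params: CgrParams | None = None):
    """Invert one CGR step: remove the final symbol of the encoded string."""
    bx, by = _vertex(last_symbol)
    if isinstance(x, ExactCoordinate):
        if x.length == 0:
            raise ValueError("cannot right-delete from the empty string")
        top = x.length - 1
        if ((x.xbits >> top) & 1, (x.ybits >> top) & 1) != (bx, by):
            raise ValueError(f"last symbol {last_symbol!r} does not match the coordinate")
        mask = (1 << top) - 1
        return ExactCoordinate(top, x.xbits & mask, x.ybits & mask)
    if params is None:
        raise TypeError("float-mode right_delete requires params")
    r, q = params.r, 1.0 - params.r
    return ((x[0] - r * bx) / q, (x[1] - r * by) / q)


def decode_sequence(x: ExactCoordinate) -> str:
    """Invert the exact cantor encoding: the unique S with encode(S) = x.

    Digit position m of axis b equals 2 * (axis-b bit of S[i-m+1]), so the
    packed bit at position p (0-based, LSB) yields symbol S[p+1] directly.
    """
    if not isinstance(x, ExactCoordinate):
        raise TypeError("decode_sequence expects an ExactCoordinate")
    out = []
    for p in range(x.length):
        out.append(_SYMBOL_OF_BITS[((x.xbits >> p) & 1, (x.ybits >> p) & 1)])
    return "".join(out)


def kmer_counts(index: CgrIndex, m: int) -> dict[str, int]:
    """Count m-mers of S by sub-square occupancy of the standard CGR map.

    The unit square is cut into a 2^m x 2^m grid; the coordinate of every
    prefix S[..i] with i >= m falls in the cell labelled by its m-long
    suffix, so cell occupancies equal sliding-window m-mer counts.
    Prefixes shorter than m are skipped (their cell still carries x0
    contamination).
    """
    if index.variant != "standard":
        raise UnsupportedConfigError("kmer_counts is defined on the standard variant (r=1/2)")
    if not (1 <= m <= index.N):
        raise ValueError(f"word length m={m} out of range 1..{index.N}")
    grid = 1 << m
    pts = index.coords[m:]
    cells = np.floor(pts * grid).astype(np.int64)
    np.clip(cells, 0, grid - 1, out=cells)
    counts: Counter[str] = Counter()
    for ix, iy in cells:
        word = "".join(
            _SYMBOL_OF_BITS[((int(ix) >> (s - 1)) & 1, (int(iy) >> (s - 1)) & 1)]
            for s in range(1, m + 1)
        )
        counts[word] += 1
    return dict(counts)
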