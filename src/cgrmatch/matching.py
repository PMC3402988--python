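"""Exact and approximate pattern matching on CGR indexes.

* :func:`matches_scan` — the standard-index scan: one constant-time LCE
  query per text position, a hit whenever the extension reaches |P|.
* :func:`k_mismatch_matches` — the kangaroo walk: up to k+1 LCE
  extensions per window, hopping over one mismatch after each, O(kN).
* Rolling hash — the CGR recurrence doubles as a Rabin-Karp rolling
  hash: h(S[1..L]) is just the window's last CGR coordinate and sliding
  the window is one left-deletion plus one CGR step.  The ``float`` mode
  keeps fidelity to that coordinate form (drift-prone for long windows);
  the default ``modular`` mode keeps the same base-3 digit polynomial
  per axis reduced modulo the Mersenne prime 2^61 - 1, which is exact at
  any window length.  Hash candidates are always verified (one LCE
  query) before being reported.
"""

from __future__ import annotations

from dataclasses import dataclass

from .encoding import CgrParams, IndexBundle, build_bundle
from .lce import lce
from .sequences import VERTICES, SequenceError, validate

__all__ = [
    "MatchHit",
    "RollingHash",
    "matches_scan",
    "count_scan",
    "k_mismatch_matches",
    "rk_hash_init",
    "rk_roll",
    "rabin_karp_search",
    "rk_index",
    "RabinKarpIndex",
    "MODULUS",
]

MODULUS = (1 << 61) - 1
_INV3 = pow(3, MODULUS - 2, MODULUS)

_stats = {"windows": 0, "max_extensions_per_window": 0}


def reset_stats() -> None:
    _stats["windows"] = 0
    _stats["max_extensions_per_window"] = 0


def get_stats() -> dict[str, int]:
    return dict(_stats)


@dataclass(frozen=True, order=True)
class MatchHit:
    """Occurrence of P in S[start..start+L-1] with its Hamming distance."""

    start: int  # 1-based
    mismatches: int = 0


def _pattern_bundle(bundle: IndexBundle, pattern: str) -> IndexBundle:
    return build_bundle(pattern, {"reverse"}, params=bundle.params, backend=bundle.backend)


def matches_scan(bundle: IndexBundle, pattern: str) -> list[MatchHit]:
    """All exact occurrences of ``pattern``: N - L + 1 LCE queries, O(N)."""
    pattern = validate(pattern)
    L, n = len(pattern), bundle.N
    if L > n:
        return []
    pb = _pattern_bundle(bundle, pattern)
    hits = []
    for i in range(1, n - L + 2):
        if lce(bundle, i, pb, 1) == L:
            hits.append(MatchHit(start=i))
    return hits


def count_scan(bundle: IndexBundle, pattern: str) -> int:
    return len(matches_scan(bundle, pattern))


def k_mismatch_matches(bundle: IndexBundle, pattern: str, k: int) -> list[MatchHit]:
    """Occurrences with at most k substitutions, exact distances reported.

    Each window performs at most k+1 LCE extensions, skipping the single
    mismatching position after each; extensions are maximal, so every
    skipped position is a true mismatch and the accumulated count is the
    window's exact Hamming distance.
    """
    pattern = validate(pattern)
    if k < 0:
        raise ValueError("k must be >= 0")
    L, n = len(pattern), bundle.N
    if L > n:
        return []
    pb = _pattern_bundle(bundle, pattern)
    hits = []
    for i in range(1, n - L + 2):
        pos, mism, extensions = 1, 0, 0
        hit = True
        while pos <= L:
            ext = min(lce(bundle, i + pos - 1, pb, pos), L - pos + 1)
            extensions += 1
            pos += ext
            if pos > L:
                break
            mism += 1  # bundle.seq[i+pos-2] != pattern[pos-1]
            if mism > k:
                hit = False
                break
            pos += 1
        assert extensions <= k + 1
        _stats["windows"] += 1
        if extensions > _stats["max_extensions_per_window"]:
            _stats["max_extensions_per_window"] = extensions
        if hit:
            hits.append(MatchHit(start=i, mismatches=mism))
    return hits


# ---------------------------------------------------------------------------
# CGR rolling hash and Rabin-Karp search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RollingHash:
    """Window fingerprint; ``value`` is a float pair (float mode) or a
    per-axis residue pair modulo 2^61 - 1 (modular mode)."""

    mode: str
    L: int
    params: CgrParams
    start: int  # 1-based start of the current window
    value: tuple
    seq: str | None = None


def _axis_bits(symbol: str) -> tuple[int, int]:
    symbol = symbol.upper()
    if symbol not in VERTICES:
        raise SequenceError(f"invalid symbol {symbol!r}")
    return VERTICES[symbol]


def rk_hash_init(
    seq: str, i: int, L: int, params: CgrParams | None = None, mode: str = "modular"
) -> RollingHash:
    """Fresh hash of the window S[i..i+L-1].

    Float mode iterates the CGR recurrence over the window (the hash *is*
    the window's last coordinate); modular mode evaluates the scaled
    digit polynomial sum_t 2*bit(W[t]) * 3^(t-1) per axis, mod 2^61 - 1.
    """
    seq = validate(seq)
    params = params or CgrParams.cantor()
    if mode not in ("float", "modular"):
        raise ValueError(f"unknown hash mode {mode!r}")
    if L < 1:
        raise ValueError("window length L must be >= 1")
    if not (1 <= i <= len(seq) - L + 1):
        raise IndexError(f"window [{i}..{i + L - 1}] out of range for N={len(seq)}")
    window = seq[i - 1 : i + L - 1]
    if mode == "float":
        r = params.r
        x, y = params.x0
        for ch in window:
            vx, vy = VERTICES[ch]
            x += r * (vx - x)
            y += r * (vy - y)
        value: tuple = (x, y)
    else:
        hx = hy = 0
        p3 = 1
        for ch in window:
            bx, by = VERTICES[ch]
            hx = (hx + 2 * bx * p3) % MODULUS
            hy = (hy + 2 * by * p3) % MODULUS
            p3 = (p3 * 3) % MODULUS
        value = (hx, hy)
    return RollingHash(mode=mode, L=L, params=params, start=i, value=value, seq=seq)


def rk_roll(h: RollingHash, out_symbol: str, in_symbol: str) -> RollingHash:
    """Slide the window one symbol to the right, O(1).

    Float mode: h <- (1-r) h - r (1-r)^L (y_out - x0) + r y_in (left
    deletion folded into one CGR step).  Modular mode: strip the least
    significant digit, rescale by 3^-1, append the new most significant
    digit.
    """
    if h.seq is not None:
        if h.start + h.L > len(h.seq):
            raise IndexError("cannot roll past the end of the text")
        if h.seq[h.start - 1] != out_symbol.upper():
            raise ValueError(
                f"out symbol {out_symbol!r} is not the window's first symbol "
                f"({h.seq[h.start - 1]!r} at position {h.start})"
            )
    ox, oy = _axis_bits(out_symbol)
    ix, iy = _axis_bits(in_symbol)
    if h.mode == "float":
        r = h.params.r
        q = 1.0 - r
        w = r * q**h.L
        x0x, x0y = h.params.x0
        vx = q * h.value[0] - w * (ox - x0x) + r * ix
        vy = q * h.value[1] - w * (oy - x0y) + r * iy
        value: tuple = (vx, vy)
    else:
        p3top = pow(3, h.L - 1, MODULUS)
        hx = ((h.value[0] - 2 * ox) * _INV3 + 2 * ix * p3top) % MODULUS
        hy = ((h.value[1] - 2 * oy) * _INV3 + 2 * iy * p3top) % MODULUS
        value = (hx, hy)
    return RollingHash(
        mode=h.mode, L=h.L, params=h.params, start=h.start + 1, value=value, seq=h.seq
    )


_FLOAT_KEY_DECIMALS = 9


def _bucket_key(h: RollingHash):
    if h.mode == "float":
        return (round(h.value[0], _FLOAT_KEY_DECIMALS), round(h.value[1], _FLOAT_KEY_DECIMALS))
    return h.value


def rabin_karp_search(
    seq: str, pattern: str, mode: str = "modular", params: CgrParams | None = None
) -> list[MatchHit]:
    """Rabin-Karp with the CGR rolling hash; every candidate is verified
    by one LCE query, so the output equals :func:`matches_scan` always."""
    seq = validate(seq)
    pattern = validate(pattern)
    L, n = len(pattern), len(seq)
    if L > n:
        return []
    params = params or CgrParams.cantor()
    hp = _bucket_key(rk_hash_init(pattern, 1, L, params, mode))
    sb = build_bundle(seq, {"reverse"}, backend="exact")
    pb = build_bundle(pattern, {"reverse"}, backend="exact")
    hits = []
    h = rk_hash_init(seq, 1, L, params, mode)
    for i in range(1, n - L + 2):
        if i > 1:
            h = rk_roll(h, seq[i - 2], seq[i + L - 2])
        if _bucket_key(h) == hp and lce(sb, i, pb, 1) == L:
            hits.append(MatchHit(start=i))
    return hits


class RabinKarpIndex:
    """Hash buckets of every L-window of S, built in O(N).

    ``buckets`` maps hash values to ascending window starts; ``query``
    looks up h(P) and verifies each bucketed start with one LCE query,
    expected O(L + occ).
    """

    def __init__(self, seq: str, L: int, mode: str = "modular", params: CgrParams | None = None):
        self.seq = validate(seq)
        self.L = L
        self.mode = mode
        self.params = params or CgrParams.cantor()
        n = len(self.seq)
        if not (1 <= L <= n):
            raise ValueError(f"window length L={L} out of range 1..{n}")
        self.buckets: dict = {}
        h = rk_hash_init(self.seq, 1, L, self.params, mode)
        for i in range(1, n - L + 2):
            if i > 1:
                h = rk_roll(h, self.seq[i - 2], self.seq[i + L - 2])
            self.buckets.setdefault(_bucket_key(h), []).append(i)
        self._bundle = build_bundle(self.seq, {"reverse"}, backend="exact")

    def __getitem__(self, key):
        return self.buckets[key]

    def __len__(self) -> int:
        return len(self.buckets)

    def items(self):
        return self.buckets.items()

    def query(self, pattern: str) -> list[MatchHit]:
        pattern = validate(pattern)
        if len(pattern) != self.L:
            raise ValueError(f"index holds {self.L}-mers, pattern has length {len(pattern)}")
        key = _bucket_key(rk_hash_init(pattern, 1, self.L, self.params, self.mode))
        pb = build_bundle(pattern, {"reverse"}, backend="exact")
        return [
            MatchHit(start=i)
            for i in self.buckets.get(key, [])
            if lce(self._bundle, i, pb, 1) == self.L
        ]


def rk_index(
    seq: str, L: int, mode: str = "modular", params: CgrParams | None = None
) -> RabinKarpIndex:
    return RabinKarpIndex(seq, L, mode, params)
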