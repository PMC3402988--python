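"""Constant-time longest common suffix / extension queries.

The workhorse is :func:`longest_common_suffix` on cantor-variant indexes:
because Cantor-embedded coordinates use only base-3 digits {0, 2}, the
L-infinity distance between two prefix coordinates is below 3^-L exactly
when the prefixes share an L-long suffix.  The query therefore reduces to
counting shared leading base-3 digits — a logarithm on the float backend,
a packed-integer XOR on the exact backend.

Longest common *extension* (prefix match of two suffixes) is the same
query on the reverse indexes, with positions mirrored.

:func:`naive_base2_estimate` retains the standard-CGR (r=1/2) formula
floor(-log2 d) - 1.  It is deliberately unreliable — binary carries make
closeness merely *necessary* for suffix sharing — and is kept to
demonstrate that failure mode (AT vs TA reports 1 where the truth is 0).
"""

from __future__ import annotations

import math

from .encoding import CgrIndex, IndexBundle, build_bundle

__all__ = [
    "longest_common_suffix",
    "naive_base2_estimate",
    "lce",
    "is_suffix",
    "is_prefix",
    "reset_stats",
    "get_stats",
]

#: Base-3 digits beyond this fractional position are lost to double
#: precision; float-backend queries whose answer would reach the cap fall
#: back to exact symbol comparison so results stay correct.
FLOAT_DIGIT_CAP = 30

_stats = {"lcs_queries": 0}


def reset_stats() -> None:
    _stats["lcs_queries"] = 0


def get_stats() -> dict[str, int]:
    return dict(_stats)


def _symbol_fallback(index1: CgrIndex, i: int, index2: CgrIndex, j: int, limit: int) -> int:
    s1, s2 = index1.seq, index2.seq
    n = 0
    while n < limit and s1[i - 1 - n] == s2[j - 1 - n]:
        n += 1
    return n


def longest_common_suffix(index1: CgrIndex, i: int, index2: CgrIndex, j: int) -> int:
    """Length of the longest common suffix of S1[..i] and S2[..j].

    Both indexes must be cantor variant.  Results are clamped to
    min(i, j): beyond that depth the shorter prefix's terminator digit
    can coincide with a content digit of the longer one, so the digit
    count alone would over-report (e.g. "G" vs "GG").  Coincident
    coordinates return the clamped maximum.
    """
    if index1.variant != "cantor" or index2.variant != "cantor":
        raise ValueError("longest_common_suffix requires cantor-variant indexes")
    if index1.backend != index2.backend:
        raise ValueError("indexes must share a backend")
    index1._check_pos(i)
    index2._check_pos(j)
    _stats["lcs_queries"] += 1
    limit = min(i, j)
    if limit == 0:
        return 0

    if index1.backend == "exact":
        ax1, ay1 = index1.content_bits(i)
        ax2, ay2 = index2.content_bits(j)
        # align the leading `limit` digits of both prefixes
        if i > limit:
            ax1 >>= i - limit
            ay1 >>= i - limit
        if j > limit:
            ax2 >>= j - limit
            ay2 >>= j - limit
        best = limit
        for a, b in ((ax1, ax2), (ay1, ay2)):
            diff = a ^ b
            if diff:
                best = min(best, limit - diff.bit_length())
        return best

    x1, y1 = index1.coordinate(i)
    x2, y2 = index2.coordinate(j)
    d = max(abs(x1 - x2), abs(y1 - y2))
    t = min(limit, FLOAT_DIGIT_CAP)
    if d == 0.0 or d < 3.0 ** -t:
        if limit <= FLOAT_DIGIT_CAP:
            return limit
        return _symbol_fallback(index1, i, index2, j, limit)
    est = int(math.floor(-math.log(d) / math.log(3.0)))
    # guard float rounding at power-of-3 boundaries
    while est > 0 and not d < 3.0 ** -est:
        est -= 1
    while d < 3.0 ** -(est + 1):
        est += 1
    return min(est, limit)


def naive_base2_estimate(index1: CgrIndex, i: int, index2: CgrIndex, j: int) -> int:
    """The base-2 logarithm guess on standard (r=1/2) indexes.

    Returns the greatest L with |x_i - x_j|_inf < 2^-L, i.e. -log2(d) - 1
    at exact powers of two.  Sharing an L-suffix *implies* d < 2^-L, so
    this never under-reports a genuine shared suffix — but binary carries
    make it over-report freely (AT vs TA gives 1; the truth is 0).  Kept
    for demonstration, not for use.  Coincident coordinates (log of
    zero) return min(i, j).
    """
    if index1.variant != "standard" or index2.variant != "standard":
        raise ValueError("naive_base2_estimate is defined on standard-variant indexes")
    index1._check_pos(i)
    index2._check_pos(j)
    x1, y1 = index1.coordinate(i)
    x2, y2 = index2.coordinate(j)
    d = max(abs(x1 - x2), abs(y1 - y2))
    if d == 0.0:
        return min(i, j)
    est = int(math.ceil(-math.log2(d))) - 1
    while est > 0 and not d < 2.0 ** -est:
        est -= 1
    while d < 2.0 ** -(est + 1):
        est += 1
    return est


def lce(bundle1: IndexBundle, i: int, bundle2: IndexBundle, j: int) -> int:
    """Longest common extension: |longest common prefix of S1[i..], S2[j..]|.

    Answered as a longest-common-suffix query on the reverse indexes at
    the mirrored positions (N-i+1, M-j+1); O(1) after linear indexing.
    """
    n, m = bundle1.N, bundle2.N
    if not (1 <= i <= n):
        raise IndexError(f"position i={i} out of range 1..{n}")
    if not (1 <= j <= m):
        raise IndexError(f"position j={j} out of range 1..{m}")
    return longest_common_suffix(bundle1.reverse, n - i + 1, bundle2.reverse, m - j + 1)


def is_suffix(pattern: str, text: str) -> bool:
    """True iff ``pattern`` is a suffix of ``text`` (LCE certificate)."""
    L, n = len(pattern), len(text)
    if L == 0 or L > n:
        return L == 0
    ip = build_bundle(pattern, {"direct"}, backend="exact")
    it = build_bundle(text, {"direct"}, backend="exact")
    return longest_common_suffix(ip.direct, L, it.direct, n) == L


def is_prefix(pattern: str, text: str) -> bool:
    """True iff ``pattern`` is a prefix of ``text`` (both reversed, then is_suffix)."""
    return is_suffix(pattern[::-1], text[::-1])
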