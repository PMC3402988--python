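"""Maximal complemented palindromes and tandem repeats via LCE queries.

A *complemented palindrome* of radius rho centred at i (gap g >= 0) is a
segment whose left arm S[i-rho+1..i] equals the reverse complement of
its right arm S[i+g+1..i+g+rho].  The backward arm comparison is a
forward comparison on the reverse complement of S, so one
longest-common-suffix query between the direct index (position i) and
the reverse-complement index (position N-i-g) yields the exact radius;
with a mismatch budget k the query becomes a kangaroo walk of at most
k+1 extensions.  Scanning all centres costs O(N) queries (O(kN) with
mismatches).

A *tandem repeat* of radius rho at start p satisfies S[t] = S[t+rho] for
all t in [p, p+rho-1].  All of them are found by the divide-and-conquer
crossing test: recursively split [1, N], and at each midpoint and each
candidate period rho probe the two anchor pairs (mid, mid+rho) and
(mid-rho, mid) with one backward and one forward LCE; the extensions
delimit a run of t-positions where S[t] = S[t+rho], and every window of
rho consecutive such positions is a tandem start.  Runs rediscovered at
several recursion levels are deduplicated by (start, radius).  O(N log N
+ z) LCE queries exact, O(kN log N + z) with mismatches.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass

from .encoding import IndexBundle, build_bundle
from .lce import longest_common_suffix
from .sequences import validate

__all__ = [
    "PalindromeHit",
    "TandemRepeatHit",
    "palindrome_radius",
    "all_maximal_palindromes",
    "k_mismatch_palindromes",
    "all_tandem_repeats",
    "k_mismatch_tandem_repeats",
    "palindrome_interval",
    "tandem_interval",
]


@dataclass(frozen=True, order=True)
class PalindromeHit:
    """Maximal complemented palindrome spanning S[center-radius+1 .. center+gap+radius]."""

    center: int  # last position of the left arm, 1-based
    radius: int
    gap: int = 0
    mismatches: int = 0


@dataclass(frozen=True, order=True)
class TandemRepeatHit:
    """Tandem repeat spanning S[start .. start+2*radius-1]."""

    start: int  # 1-based
    radius: int
    mismatches: int = 0


def palindrome_interval(hit: PalindromeHit) -> tuple[int, int]:
    """1-based inclusive (start, end) span of a palindrome hit."""
    return (hit.center - hit.radius + 1, hit.center + hit.gap + hit.radius)


def tandem_interval(hit: TandemRepeatHit) -> tuple[int, int]:
    """1-based inclusive (start, end) span of a tandem-repeat hit."""
    return (hit.start, hit.start + 2 * hit.radius - 1)


def palindrome_radius(
    bundle: IndexBundle, center: int, gap: int = 0, k: int = 0
) -> tuple[int, int]:
    """Maximal arm length at ``center`` under mismatch budget ``k``.

    Returns (radius, mismatches); the mismatch count is the exact Hamming
    distance between the left arm and the reverse complement of the
    right arm.  Requires the direct and revcomp members of ``bundle``.
    """
    n = bundle.N
    if not (1 <= center < n):
        raise IndexError(f"center {center} out of range 1..{n - 1}")
    if not (0 <= gap <= n - center - 1):
        raise IndexError(f"gap {gap} out of range 0..{n - center - 1}")
    if k < 0:
        raise ValueError("k must be >= 0")
    limit = min(center, n - center - gap)
    total = mism = 0
    while total < limit:
        ext = longest_common_suffix(
            bundle.direct, center - total, bundle.revcomp, n - center - gap - total
        )
        total += ext
        if total >= limit or mism == k:
            break
        mism += 1
        total += 1
    return (total, mism)


def all_maximal_palindromes(
    seq: str,
    gap: int = 0,
    k: int = 0,
    min_radius: int = 1,
    bundle: IndexBundle | None = None,
) -> list[PalindromeHit]:
    """One hit per centre with maximal radius >= min_radius, centres ascending."""
    seq = validate(seq)
    n = len(seq)
    if bundle is None:
        bundle = build_bundle(seq, {"direct", "revcomp"}, backend="exact")
    hits = []
    for center in range(1, n - gap):
        radius, mism = palindrome_radius(bundle, center, gap=gap, k=k)
        if radius >= min_radius:
            hits.append(PalindromeHit(center=center, radius=radius, gap=gap, mismatches=mism))
    return hits


def k_mismatch_palindromes(
    seq: str, k: int, gap: int = 0, min_radius: int = 1
) -> list[PalindromeHit]:
    return all_maximal_palindromes(seq, gap=gap, k=k, min_radius=min_radius)


# ---------------------------------------------------------------------------
# Tandem repeats
# ---------------------------------------------------------------------------

def _probe(bundle: IndexBundle, h: int, rho: int, k: int) -> tuple[int, int, list[int]]:
    """Characterise S[t] vs S[t+rho] around anchor t = h.

    Walks backward from t = h and forward from t = h+1, each stopping
    after k+1 mismatches or the string boundary.  Returns (low, high,
    mismatch positions) such that every t in [low, high] is classified:
    S[t] = S[t+rho] unless t is listed.
    """
    n = bundle.N
    mis: list[int] = []
    t = h
    while t >= 1 and len(mis) <= k:
        ext = longest_common_suffix(bundle.direct, t, bundle.direct, t + rho)
        t -= ext
        if t < 1:
            break
        mis.append(t)
        t -= 1
    low = t + 1
    mis.reverse()
    t = h + 1
    while t + rho <= n and len(mis) - bisect_left(mis, h + 1) <= k:
        ext = longest_common_suffix(
            bundle.reverse, n - t + 1, bundle.reverse, n - t - rho + 1
        )
        t += ext
        if t + rho > n:
            break
        mis.append(t)
        t += 1
    high = t - 1
    return (low, high, mis)


def _tandem_scan(seq: str, k: int, min_radius: int) -> list[TandemRepeatHit]:
    seq = validate(seq)
    if k < 0:
        raise ValueError("k must be >= 0")
    if min_radius < 1:
        raise ValueError("min_radius must be >= 1")
    n = len(seq)
    bundle = build_bundle(seq, {"direct", "reverse"}, backend="exact")
    found: dict[tuple[int, int], int] = {}

    def emit(h: int, rho: int) -> None:
        low, high, mis = _probe(bundle, h, rho, k)
        p_lo = max(low, h - rho + 1, 1)
        p_hi = min(h, high - rho + 1)
        for p in range(p_lo, p_hi + 1):
            if (p, rho) in found:
                continue
            cnt = bisect_right(mis, p + rho - 1) - bisect_left(mis, p)
            if cnt <= k:
                found[(p, rho)] = cnt

    def rec(lo: int, hi: int) -> None:
        size = hi - lo + 1
        if size < 2:
            return
        mid = (lo + hi) // 2
        for rho in range(min_radius, size // 2 + 1):
            if mid + rho <= n:
                emit(mid, rho)
            if mid - rho >= 1:
                emit(mid - rho, rho)
        rec(lo, mid)
        rec(mid + 1, hi)

    rec(1, n)
    return sorted(
        TandemRepeatHit(start=p, radius=rho, mismatches=c) for (p, rho), c in found.items()
    )


def all_tandem_repeats(seq: str, min_radius: int = 1) -> list[TandemRepeatHit]:
    """Every (start, radius) with S[p..p+rho-1] = S[p+rho..p+2rho-1], sorted."""
    return _tandem_scan(seq, k=0, min_radius=min_radius)


def k_mismatch_tandem_repeats(seq: str, k: int, min_radius: int = 1) -> list[TandemRepeatHit]:
    """Tandem repeats whose halves differ in at most k positions."""
    return _tandem_scan(seq, k=k, min_radius=min_radius)
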