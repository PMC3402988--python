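"""Independent brute-force oracles used to pin down expected values.

Everything here is deliberately naive (character comparisons, slice
equality, quadratic DP) and shares no code path with the CGR
implementations it checks.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def naive_search(text: str, pattern: str) -> list[int]:
    """All 1-based occurrence starts, overlapping included."""
    L = len(pattern)
    return [i + 1 for i in range(len(text) - L + 1) if text[i : i + L] == pattern]


def hamming_hits(text: str, pattern: str, k: int) -> list[tuple[int, int]]:
    """(start, distance) for every window within Hamming distance k."""
    L = len(pattern)
    out = []
    for i in range(len(text) - L + 1):
        d = sum(a != b for a, b in zip(text[i : i + L], pattern))
        if d <= k:
            out.append((i + 1, d))
    return out


def common_suffix_len(s1: str, i: int, s2: str, j: int) -> int:
    """Longest common suffix of s1[..i] and s2[..j] (1-based prefixes)."""
    n = 0
    while n < min(i, j) and s1[i - 1 - n] == s2[j - 1 - n]:
        n += 1
    return n


def palindrome_radius_at(seq: str, center: int, gap: int = 0, k: int = 0) -> tuple[int, int]:
    """Greedy maximal arm under mismatch budget k; returns (radius, mism)."""
    n = len(seq)
    limit = min(center, n - center - gap)
    best = (0, 0)
    mism = 0
    for rho in range(1, limit + 1):
        if seq[center - rho] != seq[center + gap + rho - 1].translate(_COMP):
            mism += 1
            if mism > k:
                break
        best = (rho, mism)
    return best


def all_palindromes(seq: str, gap: int = 0, k: int = 0, min_radius: int = 1):
    """(center, radius, mismatches) per centre with radius >= min_radius."""
    out = []
    for center in range(1, len(seq) - gap):
        rho, m = palindrome_radius_at(seq, center, gap, k)
        if rho >= min_radius:
            out.append((center, rho, m))
    return out


def all_tandems(seq: str, min_radius: int = 1) -> set[tuple[int, int]]:
    """Every (start, radius) with equal adjacent halves (slice equality)."""
    n = len(seq)
    out = set()
    for rho in range(min_radius, n // 2 + 1):
        for p in range(n - 2 * rho + 1):
            if seq[p : p + rho] == seq[p + rho : p + 2 * rho]:
                out.add((p + 1, rho))
    return out


def k_tandems(seq: str, k: int, min_radius: int = 1) -> dict[tuple[int, int], int]:
    """(start, radius) -> Hamming distance, for every window within budget."""
    n = len(seq)
    out = {}
    for rho in range(min_radius, n // 2 + 1):
        for p in range(n - 2 * rho + 1):
            d = sum(a != b for a, b in zip(seq[p : p + rho], seq[p + rho : p + 2 * rho]))
            if d <= k:
                out[(p + 1, rho)] = d
    return out


def lcs_length(s1: str, s2: str) -> int:
    """Longest common substring length by the classic DP, vectorized by row."""
    a = np.frombuffer(s1.encode(), dtype=np.uint8)
    b = np.frombuffer(s2.encode(), dtype=np.uint8)
    prev = np.zeros(len(b) + 1, dtype=np.int32)
    best = 0
    for ca in a:
        cur = np.zeros_like(prev)
        cur[1:] = np.where(b == ca, prev[:-1] + 1, 0)
        m = int(cur.max())
        if m > best:
            best = m
        prev = cur
    return best
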