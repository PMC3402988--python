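"""Seeded synthetic DNA and planted-feature fixtures.

Random sequences are i.i.d. uniform over {A, C, G, T} from a seeded
numpy generator — the background model used for the coordinate-map
demonstrations (e.g. a length-5,000 uniform sequence) and for all
randomized oracle tests.  :func:`make_fixture` overwrites planted
payloads (exact matches, complemented palindromes, tandem repeats) at
stated positions and returns machine-readable ground truth, so recovery
tests never re-derive the truth from the sequence itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequences import ALPHABET, reverse_complement, validate

__all__ = ["Plant", "FixtureSpec", "random_dna", "make_fixture"]


@dataclass(frozen=True)
class Plant:
    kind: str  # match | palindrome | tandem
    payload: str
    position: int  # 1-based start of the payload


@dataclass(frozen=True)
class FixtureSpec:
    length: int
    seed: int
    plants: tuple[Plant, ...] = field(default_factory=tuple)


def random_dna(length: int, seed: int) -> str:
    """Uniform i.i.d. ACGT string; deterministic given (length, seed)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, 4, size=length)
    return "".join(ALPHABET[d] for d in draws)


def make_fixture(spec: FixtureSpec) -> tuple[str, list[dict]]:
    """Background sequence with plants overwritten at their positions.

    Returns (sequence, truth) where each truth entry describes one plant
    in the hit coordinates the finders report: matches by start,
    palindromes by (center, radius, gap=0), tandems by (start, radius).
    """
    seq = list(random_dna(spec.length, spec.seed))
    truth: list[dict] = []
    for plant in spec.plants:
        payload = validate(plant.payload)
        p, n = plant.position, len(payload)
        if p < 1 or p + n - 1 > spec.length:
            raise ValueError(
                f"plant {plant.kind!r} at {p} (length {n}) overlaps the sequence end "
                f"(N={spec.length})"
            )
        if plant.kind == "match":
            truth.append({"kind": "match", "pattern": payload, "start": p})
        elif plant.kind == "palindrome":
            if n % 2 or payload != reverse_complement(payload):
                raise ValueError("palindrome payload must equal its reverse complement")
            truth.append(
                {"kind": "palindrome", "center": p + n // 2 - 1, "radius": n // 2, "gap": 0}
            )
        elif plant.kind == "tandem":
            if n % 2 or payload[: n // 2] != payload[n // 2 :]:
                raise ValueError("tandem payload must be two identical halves")
            truth.append({"kind": "tandem", "start": p, "radius": n // 2})
        else:
            raise ValueError(f"unknown plant kind {plant.kind!r}")
        seq[p - 1 : p + n - 1] = payload
    return ("".join(seq), truth)
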