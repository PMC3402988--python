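import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py

from cgrmatch.simulate import random_dna


@pytest.fixture
def rng():
    return np.random.default_rng(20120502)


def random_seqs(count: int, max_len: int, seed: int, min_len: int = 1) -> list[str]:
    """Deterministic batch of uniform random sequences with varied lengths."""
    rng = np.random.default_rng(seed)
    lengths = rng.integers(min_len, max_len + 1, size=count)
    return [random_dna(int(n), int(rng.integers(0, 2**31))) for n in lengths]


def text_pattern_pairs(count: int, max_text: int, max_pat: int, seed: int):
    """(text, pattern) pairs; half the patterns are sampled from the text
    so exact matches actually occur."""
    rng = np.random.default_rng(seed)
    pairs = []
    for t in range(count):
        n = int(rng.integers(2, max_text + 1))
        text = random_dna(n, int(rng.integers(0, 2**31)))
        L = int(rng.integers(1, min(max_pat, n) + 1))
        if t % 2 == 0:
            start = int(rng.integers(0, n - L + 1))
            pattern = text[start : start + L]
        else:
            pattern = random_dna(L, int(rng.integers(0, 2**31)))
        pairs.append((text, pattern))
    return pairs
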