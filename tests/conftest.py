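"""Shared fixtures and independent oracle helpers.

The oracle functions here are deliberately coded from first principles
(plain dynamic programming / exhaustive scans) and stay independent of the
library code paths they check.
"""

from __future__ import annotations

import random

import numpy as np
import pytest


def random_dna(rng: random.Random, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(length))


def lcs_matches(a: str, b: str) -> int:
    """Unbanded free-gap match maximization (longest common subsequence)."""
    barr = np.frombuffer(b.encode(), dtype=np.uint8)
    prev = np.zeros(len(b) + 1, dtype=np.int32)
    for ch in a.encode():
        t = np.maximum(prev[1:], prev[:-1] + (barr == ch))
        cur = np.empty_like(prev)
        cur[0] = 0
        np.maximum.accumulate(t, out=cur[1:])
        prev = cur
    return int(prev[-1])


def brute_seed_match(candidate: str, target: str, pattern: str) -> bool:
    """Exhaustive scan over all target offsets and candidate anchors."""
    plen = len(pattern)
    care = [i for i, ch in enumerate(pattern) if ch == "1"]
    for anchor in range(len(candidate) - plen + 1):
        for off in range(len(target) - plen + 1):
            if all(candidate[anchor + i] == target[off + i] for i in care):
                return True
    return False


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240917)


@pytest.fixture
def nprng() -> np.random.Generator:
    return np.random.default_rng(20240917)
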