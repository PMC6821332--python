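"""Shared fixtures: small deterministic sequences and string-level oracles."""

from __future__ import annotations

import numpy as np
import pytest

_RC = str.maketrans("ACGT", "TGCA")


def rc(seq: str) -> str:
    """Independent reverse complement used by the test oracles."""
    return seq.translate(_RC)[::-1]


def canon(seq: str) -> str:
    """Independent canonical form (plain string comparison)."""
    r = rc(seq)
    return seq if seq <= r else r


def kmer_set(seq: str, k: int) -> set[str]:
    """Independent canonical k-mer set of a sequence (brute force)."""
    return {canon(seq[i : i + k]) for i in range(len(seq) - k + 1)
            if set(seq[i : i + k]) <= set("ACGT")}


def random_seq(n: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[b] for b in rng.integers(0, 4, n))


@pytest.fixture
def small_genome() -> str:
    return random_seq(2000, seed=11)


@pytest.fixture
def medium_genome() -> str:
    return random_seq(20_000, seed=12)
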