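"""Shared fixtures: tiny references and deterministic sequence helpers."""

from __future__ import annotations

import numpy as np
import pytest

from phylopop._rng import child_rng
from phylopop.assembly import ReferenceAssembly

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_seq(length: int, seed: int, key: str = "seq") -> str:
    rng = child_rng(seed, key)
    return rng.choice(BASES, size=length).tobytes().decode()


def mutate(seq: str, positions, shift: int = 1) -> str:
    """Deterministic substitutions at the given positions (cyclic base shift)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    for p in positions:
        arr[p] = BASES[(int(np.searchsorted(BASES, arr[p])) + shift) % 4]
    return arr.tobytes().decode()


@pytest.fixture
def tiny_ref() -> ReferenceAssembly:
    """Two contigs on one scaffold plus a singleton scaffold (~4.5 kb)."""
    return ReferenceAssembly(
        contigs={
            "A1": random_seq(2000, 11, "A1"),
            "A2": random_seq(1500, 11, "A2"),
            "B1": random_seq(1000, 11, "B1"),
        },
        scaffolds={"S1": ["A1", "A2"], "S2": ["B1"]},
    )
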