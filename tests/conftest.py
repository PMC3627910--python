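from __future__ import annotations

import numpy as np
import pytest

BASES = np.frombuffer(b"ACGT", dtype="S1")
AA = "ACDEFGHIKLMNPQRSTVWY"


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=n, p=p).tobytes().decode()


def random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AA), size=n))


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitution-only divergence at the given per-base rate."""
    out = list(seq)
    for i in np.nonzero(rng.random(len(seq)) < rate)[0]:
        out[i] = "ACGT".replace(out[i], "")[int(rng.integers(0, 3))]
    return "".join(out)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20130401)
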