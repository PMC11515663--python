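from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

from samlite.alphabet import AA_LETTERS
from samlite.index import build_index

#: The three-protein worked example used throughout: reference
#: {MVVAV, VAVNV, VAAVV} indexed with k=2.
FIG_PROTEINS = [("p1", "MVVAV"), ("p2", "VAVNV"), ("p3", "VAAVV")]


@pytest.fixture(scope="session")
def fig_index():
    return build_index(FIG_PROTEINS, k=2)


def random_proteins(rng: np.random.Generator, max_proteins=20, max_len=50, min_len=4):
    """A small random proteome as a list of sequences (names are p0, p1, ...)."""
    n = int(rng.integers(1, max_proteins + 1))
    seqs = []
    for _ in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        seqs.append("".join(rng.choice(list(AA_LETTERS), size=length)))
    return seqs


def named(seqs):
    return [(f"p{i}", s) for i, s in enumerate(seqs)]
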