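"""Shared fixtures: tiny alignments and a small reusable benchmark."""

import numpy as np
import pytest

from coevotree.distances import AMINO_ACIDS, OrthologAlignment
from coevotree.simulate import SimulationConfig, generate_benchmark


def random_alignment(rng, protein_id, species, length=60, gap_rate=0.0):
    """Alignment of independent random sequences (no shared history)."""
    rows = {}
    for sp in species:
        seq = rng.choice(list(AMINO_ACIDS), size=length)
        if gap_rate:
            mask = rng.random(length) < gap_rate
            seq[mask] = "-"
        rows[sp] = "".join(seq)
    return OrthologAlignment(protein_id=protein_id, rows=rows)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_benchmark():
    """A fast 5+5-pair benchmark on 18 species, reused across tests."""
    config = SimulationConfig(
        n_species=18,
        depth=1.0,
        seq_length=120,
        n_interacting=5,
        n_noninteracting=5,
        seed=7,
    )
    return generate_benchmark(config)
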