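import numpy as np
import pytest

from coipopgen.io import Alignment, PopulationMap
from coipopgen.simulate import PAPER_LIKE, SimulationConfig, simulate_coalescent


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def tiny_alignment():
    """Five 12-mers in two populations with one missing-data column."""
    recs = (
        ("a1", "ACGTACGTACGN"),  # N excludes the last column
        ("a2", "ACGTACGTACGA"),
        ("a3", "ACTTACGTACGA"),
        ("b1", "ACTTACGTACGA"),
        ("b2", "ACTTACCTACGA"),
    )
    aln = Alignment(recs)
    pm = PopulationMap({"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B"})
    return aln, pm


@pytest.fixture(scope="session")
def paper_like_dataset():
    """One deterministic draw of the study-shaped synthetic dataset."""
    cfg = SimulationConfig(**{**PAPER_LIKE.__dict__, "seed": 1})
    return simulate_coalescent(cfg)


def random_alignment(rng, n=10, length=50, alphabet="ACGT"):
    seqs = ["".join(rng.choice(list(alphabet), size=length)) for _ in range(n)]
    return Alignment(tuple((f"s{i}", s) for i, s in enumerate(seqs)))
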