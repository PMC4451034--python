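import warnings

import numpy as np
import pytest

from transpoly.seqio import Alignment, CloneRecord
from transpoly import simulate

warnings.filterwarnings("ignore", message="negative NJ branch length")


def make_alignment(seqs, ids=None):
    """Alignment from raw strings with synthetic ids."""
    ids = ids or [f"s{i}" for i in range(len(seqs))]
    return Alignment([CloneRecord(id=i, sequence=s) for i, s in zip(ids, seqs)])


def random_alignment(rng, n, length, n_variable=None, gap_prob=0.0):
    """Random alignment: a shared backbone with random substitutions."""
    base = rng.choice(list("ACGT"), size=length)
    seqs = []
    for _ in range(n):
        s = base.copy()
        k = n_variable if n_variable is not None else rng.integers(0, length // 10 + 1)
        for pos in rng.choice(length, size=k, replace=False):
            s[pos] = rng.choice([b for b in "ACGT" if b != s[pos]])
        if gap_prob:
            mask = rng.random(length) < gap_prob
            s[mask] = "-"
        seqs.append("".join(s))
    return make_alignment(seqs)


@pytest.fixture(scope="session")
def balancing_dataset():
    """One default balancing-preset simulation shared across tests."""
    return simulate.simulate_dataset(simulate.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def neutral_dataset():
    return simulate.neutral_control(simulate.SimulationConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
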