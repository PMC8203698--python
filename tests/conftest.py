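import numpy as np
import pytest

from carepath.core import Action, Dataset, TreatmentSequence


def make_seq(pid, pairs):
    """Build a TreatmentSequence from [(activity, cost), ...]."""
    return TreatmentSequence(pid, tuple(Action(a, float(c)) for a, c in pairs))


@pytest.fixture
def seq_factory():
    return make_seq


@pytest.fixture
def toy_dataset():
    """Two patients with interleavable visit histories."""
    return Dataset(
        [
            make_seq("alice", [("CONS", 80.0), ("LABO", 45.5), ("RADI", 210.0)]),
            make_seq("bob", [("CONS", 75.0), ("QUIR", 2500.0)]),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
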