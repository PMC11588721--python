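import numpy as np
import pytest

from sixma import LabeledDataset, SequenceRecord, SimulationConfig, simulate_dataset


def random_dataset(n_pos: int, n_neg: int, L: int, seed: int = 0) -> LabeledDataset:
    """Uniform-random dataset without a fixed center (for encoder tests)."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    recs = []
    for i in range(n_pos + n_neg):
        seq = "".join(bases[rng.integers(0, 4, L)])
        recs.append(SequenceRecord(id=f"r{i}", seq=seq, label=1 if i < n_pos else 0))
    return LabeledDataset(recs)


@pytest.fixture
def small_dataset() -> LabeledDataset:
    return random_dataset(10, 10, 41, seed=42)


@pytest.fixture
def biased_dataset() -> LabeledDataset:
    """Strong planted signal, handy for pipeline sanity checks."""
    return simulate_dataset(SimulationConfig(n_pos=100, n_neg=100, bias=0.9, seed=7))
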