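import numpy as np
import pytest

from alrscan import CompositionTable


def random_table(I: int, J: int, seed: int, weighted: bool = False) -> CompositionTable:
    """A strictly positive random table; optionally random valid weights."""
    rng = np.random.default_rng(seed)
    values = np.exp(rng.normal(2.0, 1.0, size=(I, J)))
    weights = rng.dirichlet(np.ones(J) * 5.0) if weighted else None
    return CompositionTable(
        values,
        sample_ids=[f"s{i}" for i in range(I)],
        component_labels=[f"c{j}" for j in range(J)],
        weights=weights,
    )


@pytest.fixture
def table_5x4() -> CompositionTable:
    return random_table(5, 4, seed=11)


@pytest.fixture
def table_8x6() -> CompositionTable:
    return random_table(8, 6, seed=23)
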