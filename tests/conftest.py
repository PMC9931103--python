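import numpy as np
import pytest

from symptomnet import (
    Battery,
    Domain,
    Item,
    Orientation,
    ScoreTable,
    SymptomNetwork,
    default_battery,
)


@pytest.fixture(scope="session")
def battery() -> Battery:
    return default_battery()


@pytest.fixture(scope="session")
def two_item_battery() -> Battery:
    items = (
        Item("A", "item A", Domain.NEUROCOGNITIVE, 0, 100,
             Orientation.HIGHER_IS_BETTER),
        Item("B", "item B", Domain.AFFECTIVE, 0, 100,
             Orientation.HIGHER_IS_WORSE),
    )
    return Battery(items=items, name="pair")


@pytest.fixture
def random_score_table(battery):
    """Factory for uniform-in-range score tables on the default battery."""

    def make(n: int, seed: int) -> ScoreTable:
        rng = np.random.default_rng(seed)
        values = np.column_stack([
            rng.uniform(it.score_min, it.score_max, size=n)
            for it in battery.items
        ])
        ids = [f"S{i:04d}" for i in range(n)]
        return ScoreTable(battery=battery, subject_ids=ids, values=values)

    return make


@pytest.fixture
def make_network(battery):
    """Factory wrapping a weight matrix into a SymptomNetwork."""

    def make(weights: np.ndarray) -> SymptomNetwork:
        return SymptomNetwork(battery=battery, weights=weights)

    return make
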