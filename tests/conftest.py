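import numpy as np
import pytest

from reciprsa import behavior, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_agent():
    return simulate.AgentParams()


@pytest.fixture(scope="session")
def small_bundle(default_agent):
    """Shared small behavioral bundle (12 participants, full design)."""
    return simulate.simulate_behavioral_dataset(
        default_agent, n_participants=12, seed=2024
    )


@pytest.fixture(scope="session")
def small_ratings(small_bundle):
    return small_bundle["ratings"]


def make_ratings_frame(rng, n_participants=6, costs=(4, 12, 20)):
    """Unstructured random ratings table (helper, not a fixture)."""
    import pandas as pd

    rows = []
    for p in range(n_participants):
        for bt in ("altruistic", "strategic"):
            for cost in costs:
                vals = rng.uniform(5, 95, size=6)
                rows.append({
                    "participant_id": f"s{p}", "benefactor_type": bt,
                    "cost": cost, "care": vals[0],
                    "second_order_belief": vals[1], "gratitude": vals[2],
                    "guilt": vals[3], "obligation": vals[4],
                    "indebtedness": vals[5],
                })
    return pd.DataFrame(rows)


@pytest.fixture
def random_ratings(rng):
    return make_ratings_frame(rng)


@pytest.fixture
def rm_table(rng):
    """Random complete 8-participant x 3-level repeated-measures table."""
    base = rng.normal(0, 1, size=(8, 1))
    return base + rng.normal(0, 0.5, size=(8, 3)) + np.array([0.0, 0.3, 0.8])


def factor_table(bundle):
    return behavior.delta_factor_table(bundle["factor_scores"].scores)
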