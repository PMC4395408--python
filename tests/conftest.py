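import numpy as np
import pytest

from riskminer.core import NONRA, RA, Transaction, TransactionDB
from riskminer.synthetic import CohortConfig, PlantedPattern, generate_cohort


def make_db(pairs) -> TransactionDB:
    """Build a TransactionDB from (items, label) pairs."""
    return TransactionDB(
        [
            Transaction(f"p{i}", frozenset(items), label)
            for i, (items, label) in enumerate(pairs)
        ]
    )


def random_db(rng: np.random.Generator, n_items=8, n_trans=40) -> TransactionDB:
    """Random small database; every transaction non-empty, both classes used."""
    items = [f"I{j}" for j in range(n_items)]
    pairs = []
    for i in range(n_trans):
        k = int(rng.integers(1, min(n_items, 6) + 1))
        chosen = rng.choice(items, size=k, replace=False)
        label = RA if i < max(2, n_trans // 3) else NONRA
        pairs.append((set(map(str, chosen)), label))
    return make_db(pairs)


@pytest.fixture
def small_separable_db() -> TransactionDB:
    """10 RA all carrying {A1, B2}; 10 nonRA never both."""
    pairs = [({"A1", "B2", "C3"}, RA) for _ in range(10)]
    pairs += [({"C3", "D4"}, NONRA) for _ in range(5)]
    pairs += [({"A1", "D4"}, NONRA) for _ in range(5)]
    return make_db(pairs)


# planted codes are deliberately outside the default background pool so the
# configured carrier fractions are the exact generating rates
PLANTED = (
    PlantedPattern(frozenset({"710.0", "443.0"}), 0.6, 0.05),
    PlantedPattern(frozenset({"245.2", "696.1", "135"}), 0.4, 0.02),
    PlantedPattern(frozenset({"390", "719.0"}), 0.8, 0.10),
)


@pytest.fixture(scope="session")
def planted_config() -> CohortConfig:
    return CohortConfig(n_ra=200, n_nonra=800, planted=PLANTED, seed=11)


@pytest.fixture(scope="session")
def planted_cohort(planted_config):
    return generate_cohort(planted_config)
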