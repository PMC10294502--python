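import numpy as np
import pytest

from mmrules.mining import TransactionSet
from mmrules.reference import load_reference_rules


@pytest.fixture(scope="session")
def toy_transactions() -> TransactionSet:
    """Five participants over items H, D, S; small enough to enumerate by hand."""
    return TransactionSet(
        "toy",
        tuple(map(frozenset, [{"H", "D"}, {"H", "D", "S"}, {"H"}, {"D"}, {"S"}])),
    )


@pytest.fixture(scope="session")
def ag_reference():
    return load_reference_rules("AG")


@pytest.fixture(scope="session")
def ig_reference():
    return load_reference_rules("IG")


def random_transactions(
    rng: np.random.Generator,
    n_items: int,
    n_transactions: int,
    density: float = 0.35,
) -> TransactionSet:
    """Random basket instance over items i0..i{k-1} for oracle comparisons."""
    items = [f"i{j}" for j in range(n_items)]
    flags = rng.random((n_transactions, n_items)) < density
    return TransactionSet(
        "random",
        tuple(
            frozenset(it for it, f in zip(items, row) if f) for row in flags
        ),
    )
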