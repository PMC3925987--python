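import numpy as np
import pytest

from perturbkit import StratifiedPopulation, load_population


@pytest.fixture(scope="session")
def table1_positive():
    return load_population("table1_positive")


@pytest.fixture(scope="session")
def table1_negative():
    return load_population("table1_negative")


@pytest.fixture(scope="session")
def table2_neither():
    return load_population("table2_neither")


@pytest.fixture(scope="session")
def all_populations():
    return {name: load_population(name) for name in (
        "table1_positive", "table1_negative",
        "table2_neither", "table2_noE", "table2_noD",
    )}


def random_population(rng: np.random.Generator, L: int | None = None) -> StratifiedPopulation:
    """A random valid stratified population for property tests."""
    if L is None:
        L = int(rng.integers(2, 7))
    m = rng.uniform(50, 5000, size=L)
    p = rng.uniform(0.05, 0.95, size=L)
    r_u = rng.uniform(0.05, 0.6, size=L)
    rr = rng.uniform(0.3, 1.0 / r_u.max(), size=L)
    return StratifiedPopulation(m=m, p=p, r_u=r_u, rr=rr)
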