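import numpy as np
import pytest

from marshweb import FoodWeb, SyntheticWebConfig, generate_web


@pytest.fixture
def star_web() -> FoodWeb:
    """5-node star: the hub eats all four leaves."""
    A = np.zeros((5, 5), dtype=int)
    A[0, 1:] = 1
    return FoodWeb(("hub", "a", "b", "c", "d"), A, name="star")


@pytest.fixture
def staircase_matrix() -> np.ndarray:
    """Perfectly nested 20x20 staircase: row i eats prey 1..i+1."""
    return np.tril(np.ones((20, 20), dtype=int))


@pytest.fixture
def random_web_factory():
    def make(S: int = 15, fill: float = 0.2, seed: int = 0,
             name: str = "rand") -> FoodWeb:
        rng = np.random.default_rng(seed)
        A = (rng.random((S, S)) < fill).astype(int)
        return FoodWeb(tuple(f"s{i:02d}" for i in range(S)), A, name=name)
    return make


@pytest.fixture
def synthetic_web():
    web, planted = generate_web(SyntheticWebConfig(S=40, seed=11))
    return web, planted
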