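import numpy as np
import pytest
from hypothesis import settings

from debridge.fixtures import (
    FixtureSpec,
    PlantElement,
    make_fixture,
    random_genome,
)
from debridge.repeat_stats import compute_stats

settings.register_profile("suite", deadline=None, max_examples=20, derandomize=True)
settings.load_profile("suite")


def make_trial_genome(rng: np.random.Generator, kind: int):
    """A genome in one of five repeat regimes: plain background, bridgeable
    pair, interleaved pair, nested pair, triple + interleaved."""
    G = int(rng.integers(200, 400))
    seed = int(rng.integers(0, 2**31))
    if kind % 5 == 0:
        g = random_genome(G, seed)
        return g, compute_stats(g)
    elems = {
        1: (PlantElement("pair", (22,)),),
        2: (PlantElement("interleaved_pair", (18, 24)),),
        3: (PlantElement("nested_pair", (18, 24)),),
        4: (
            PlantElement("triple", (16,)),
            PlantElement("interleaved_pair", (18, 22)),
        ),
    }[kind % 5]
    fx = make_fixture(FixtureSpec(G, seed, elems))
    return fx.genome, fx.stats


def harness_point(rng: np.random.Generator, g, stats):
    """(L, N) heavy enough that the theorem hypotheses usually hold."""
    G = len(g)
    L = int(rng.integers(36, 60))
    if stats.l_repeat >= L - 10:
        L = stats.l_repeat + 12
    N = int(1.6 * G * (np.log(G) + 3) / (L - 2))
    return L, N


@pytest.fixture(scope="session")
def interleaved_fixture_small():
    """G=3000 interleaved-dominant genome shared across tests."""
    from debridge.fixtures import interleaved_dominant_fixture

    return interleaved_dominant_fixture(3000, 7)


@pytest.fixture(scope="session")
def confusable_fixture():
    """A genome whose only long repeats are one interleaved pair (30, 34)."""
    return make_fixture(
        FixtureSpec(500, 3, (PlantElement("interleaved_pair", (30, 34)),))
    )
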