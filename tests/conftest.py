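import numpy as np
import pytest

from agreepower import (
    DistanceProfile,
    distance_profile,
    example_fixture,
    marginals,
)


@pytest.fixture
def pair3():
    """Two-rater, three-category observed-proportion table."""
    return example_fixture("two_rater_3cat_pair")


@pytest.fixture
def profile3(pair3):
    """Distance profile of the two-rater example under rater-specific margins."""
    return distance_profile(pair3, marginals(pair3, "cohen"))


@pytest.fixture
def profile5():
    """Published distance profile of the four-rater, five-category example."""
    return example_fixture("four_rater_5cat_profile")


def random_profile(rng: np.random.Generator, n_categories: int) -> DistanceProfile:
    """A random valid distance profile with strictly positive chance masses."""
    c = n_categories
    p = rng.dirichlet(np.full(c, 2.0))
    e = np.empty(c - 1)
    for l in range(1, c):
        idx = np.arange(l, c)
        e[l - 1] = 2.0 * np.sum(p[idx] * p[idx - l])
    obs_all = rng.dirichlet(np.full(c, 1.0))  # diagonal + C-1 distances
    return DistanceProfile(obs_all[1:], e, float(obs_all[0]), 1.0 - float(e.sum()))


def random_pair_counts(rng: np.random.Generator, n_categories: int) -> np.ndarray:
    """Random integer two-rater table with every category used by someone."""
    while True:
        x = rng.integers(0, 8, size=(n_categories, n_categories))
        margins = x.sum(axis=0) + x.sum(axis=1)
        if np.all(margins > 0):
            return x
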