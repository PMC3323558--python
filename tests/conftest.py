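import numpy as np
import pytest

from apmscan.pedigree import Individual, validate_pedigree


@pytest.fixture
def trio():
    """father, mother, child."""
    return validate_pedigree(
        [
            Individual("f", sex="male"),
            Individual("m", sex="female"),
            Individual("c", "f", "m", "female"),
        ]
    )


@pytest.fixture
def four_generations():
    """A 4-generation kindred with sibs, avuncular pairs, and first cousins."""
    m = Individual
    return validate_pedigree(
        [
            m("gg1", sex="male"), m("gg2", sex="female"),
            m("g1", "gg1", "gg2", "male"), m("g2", "gg1", "gg2", "female"),
            m("g1w", sex="female"), m("g2h", sex="male"),
            m("p1", "g1", "g1w", "male"), m("p2", "g1", "g1w", "female"),
            m("q1", "g2h", "g2", "male"),
            m("p1w", sex="female"), m("q1w", sex="female"),
            m("c1", "p1", "p1w", "male"), m("c2", "p1", "p1w", "female"),
            m("d1", "q1", "q1w", "male"),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
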