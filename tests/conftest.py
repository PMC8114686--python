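import pytest

from sbgnq import synthetic_data as syn
from sbgnq.semantics import translate


@pytest.fixture(scope="session")
def toy_clock():
    return syn.make_toy_clock()


@pytest.fixture(scope="session")
def nad_motif():
    return syn.make_nad_motif()


@pytest.fixture(scope="session")
def toy_coupled():
    return syn.make_toy_coupled()


@pytest.fixture(scope="session")
def alternatives_motif():
    return syn.make_alternatives_motif()


@pytest.fixture(scope="session")
def toy_clock_an(toy_clock):
    return translate(toy_clock)


@pytest.fixture(scope="session")
def nad_an(nad_motif):
    return translate(nad_motif)


@pytest.fixture(scope="session")
def coupled_an(toy_coupled):
    return translate(toy_coupled)


def small_random_maps(n, base_seed=0):
    """Seeded random maps whose networks stay within exhaustive-check size."""
    maps = []
    for i in range(n):
        params = syn.GeneratorParams(
            entities=3 + i % 2,
            processes=3 + (i // 2) % 2,
            modulation_density=0.5 + (i % 3) * 0.5,
            necessary_fraction=0.2,
            inhibition_fraction=0.3,
            seed=base_seed + i,
        )
        maps.append(syn.random_map(params))
    return maps
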