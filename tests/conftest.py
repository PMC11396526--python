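import pytest

from zzfullerene import (
    fixture_corannulene,
    fixture_dodecahedron,
    fixture_truncated_icosahedron,
    generate_isomers,
)


@pytest.fixture(scope="session")
def corannulene():
    return fixture_corannulene()


@pytest.fixture(scope="session")
def dodecahedron():
    return fixture_dodecahedron()


@pytest.fixture(scope="session")
def soccer_ball():
    return fixture_truncated_icosahedron()


@pytest.fixture(scope="session")
def small_isomer_sets():
    """All isomers of C20-C30 as {n: [(label, code, graph), ...]}."""
    return {n: list(generate_isomers(n)) for n in (20, 24, 26, 28, 30)}


@pytest.fixture(scope="session")
def mid_isomer_sets(small_isomer_sets):
    """All isomers of C20-C36."""
    sets = dict(small_isomer_sets)
    for n in (32, 34, 36):
        sets[n] = list(generate_isomers(n))
    return sets
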