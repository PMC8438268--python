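import numpy as np
import pytest

import ionmat as im

#: Printed (HU, SPR, solved density) triples used across the validation tests.
ANCHOR_TABLE = {
    "lung": (-325, 0.70, 0.70),
    "fat": (-105, 0.95, 0.92),
    "adipose": (-5, 1.01, 0.98),
    "soft tissue": (45, 1.04, 1.04),
    "muscle": (175, 1.10, 1.10),
    "bone-scapula": (265, 1.13, 1.16),
    "bone-mineral": (715, 1.31, 1.47),
    "tooth": (1585, 1.66, 1.92),
}


@pytest.fixture(scope="session")
def library():
    return im.load_library()


@pytest.fixture(scope="session")
def water_comp():
    return im.water()


@pytest.fixture(scope="session")
def curve():
    return im.fixture_curve()


@pytest.fixture(scope="session")
def scheme():
    return im.default_scheme()


@pytest.fixture(scope="session")
def table_our(curve, scheme, library):
    return im.build_material_table(curve, scheme, library)


@pytest.fixture(scope="session")
def table_water(curve, scheme, library):
    return im.build_material_table(curve, scheme, library, method="water")


@pytest.fixture(scope="session")
def sobp_ref():
    return im.generate_sobp_reference()


def make_random_composition(rng: np.random.Generator, name: str = "random") -> im.TissueComposition:
    symbols = list(im.ELEMENTS)
    n = int(rng.integers(1, len(symbols) + 1))
    chosen = rng.choice(symbols, size=n, replace=False)
    weights = rng.dirichlet(np.ones(n))
    return im.TissueComposition(name, dict(zip(chosen.tolist(), weights.tolist())))
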