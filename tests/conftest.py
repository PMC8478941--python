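import numpy as np
import pytest

import asterforge as af


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_species():
    return (af.ALPHA_ACTININ, af.FASCIN)


def make_random_system(rng, n_filaments=3, n_beads=5, n_xl=6, r_c=4.0,
                       k_c=2.0, bind_some=True):
    """A small random system with a mix of bound and unbound heads."""
    fp = af.FilamentParams(n_beads=n_beads)
    conf = af.ConfinementParams(r_c=r_c, k_c=k_c)
    species = (af.ALPHA_ACTININ, af.FASCIN)
    fils = []
    for _ in range(n_filaments):
        start = rng.uniform(-r_c * 0.6, r_c * 0.6, 2)
        d = rng.standard_normal(2)
        d /= np.linalg.norm(d)
        pts = (start + np.outer(np.arange(n_beads), d)
               + rng.normal(0, 0.1, (n_beads, 2)))
        fils.append(af.Filament(pts))
    xls = []
    for i in range(n_xl):
        c = rng.uniform(-r_c, r_c, 2)
        xls.append(af.Crosslinker(species[i % 2].name,
                                  np.array([c, c + rng.normal(0, 0.3, 2)])))
    state = af.SystemState.from_components(fils, xls, species, fp, conf)
    if bind_some and n_xl >= 4 and n_filaments >= 3:
        af.bind_head(state, 0, 0, 0, 1, 0.3)
        af.bind_head(state, 0, 1, 1, 2, 0.7)
        af.bind_head(state, 1, 0, 2, 0, 0.5)
        af.bind_head(state, 3, 0, 0, 2, 0.2)
        af.bind_head(state, 3, 1, 0, 3, 0.9)
    return state


@pytest.fixture
def random_system(rng):
    return make_random_system(rng)
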