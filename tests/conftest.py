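import numpy as np
import pytest

from deprivmap import SimulationConfig, make_study


@pytest.fixture(scope="session")
def small_study():
    """100-tract study with the default generative conditions."""
    return make_study(SimulationConfig(rows=10, cols=10, seed=42))


@pytest.fixture(scope="session")
def tiny_study():
    """30-tract study for expensive refit-based checks."""
    return make_study(SimulationConfig(rows=6, cols=5, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def toy_study_20():
    """20-tract toy with mild random effects (sigma = 0.2): the regime in
    which the harmonic-mean CPO identity is numerically usable and can be
    validated against exact leave-one-out refits."""
    from deprivmap import make_lattice
    from deprivmap.index import assign_quintiles
    from deprivmap.synthetic import SimulationConfig, _age_structure, \
        simulate_mortality

    g = make_lattice(4, 5)
    cfg = SimulationConfig(rows=5, cols=5, sigma_v=0.2, sigma_S=0.2, seed=17)
    gen = np.random.default_rng(17)
    latent = gen.normal(size=20)
    quint = assign_quintiles(latent).labels
    a45, a65 = _age_structure(20, gen)
    out, _ = simulate_mortality(g, quint, a45, a65, cfg, rng=gen)
    return out, g
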