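import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import isomix as im

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def two_source_one_isotope():
    """K=2, J=1 instance small enough for grid quadrature."""
    sources = im.SourceTable(
        source_names=("low", "high"),
        means=np.array([[0.0], [10.0]]),
        sds=np.array([[1.0], [1.0]]),
    )
    rng = np.random.default_rng(11)
    true_p = 0.35
    mean = true_p * 10.0
    x = rng.normal(mean, 1.0, size=(8, 1))
    data = im.MixtureObservations(x, isotope_names=("d13C",))
    return data, sources


@pytest.fixture
def figure1_dataset():
    return im.make_figure1_example(sigma=0.1, seed=5)


@pytest.fixture
def random_instance():
    """Factory for random (p, sources, tefs, conc, sigma) instances."""

    def make(seed, K=3, J=2, unequal_conc=False):
        rng = np.random.default_rng(seed)
        p = im.ProportionVector(rng.dirichlet(np.ones(K)))
        sources = im.SourceTable(
            source_names=tuple(f"s{k}" for k in range(K)),
            means=rng.normal(0, 10, size=(K, J)),
            sds=np.abs(rng.normal(0, 2, size=(K, J))),
        )
        tefs = im.TEFTable(
            means=rng.normal(0, 1, size=(K, J)),
            sds=np.abs(rng.normal(0, 1, size=(K, J))),
        )
        if unequal_conc:
            conc = im.ConcentrationTable(rng.uniform(0.05, 1.0, size=(K, J)))
        else:
            conc = im.ConcentrationTable.ones(K, J)
        sigma = im.ResidualScale(np.abs(rng.normal(0, 1, size=J)))
        return p, sources, tefs, conc, sigma

    return make
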