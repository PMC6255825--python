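import pytest

from gdpflux.cable import discretize
from gdpflux.morphology import Morphology, Section
from gdpflux.synth import SurrogateMorphologySpec, make_surrogate_morphology


@pytest.fixture
def ball_and_stick() -> Morphology:
    """Soma plus one 100 um x 2 um dendrite."""
    return Morphology([
        Section(id=1, parent_id=-1, length=10.0, diam_prox=10.0,
                diam_dist=10.0, region="soma"),
        Section(id=2, parent_id=1, length=100.0, diam_prox=2.0,
                diam_dist=2.0, region="dendrite"),
    ])


@pytest.fixture
def single_compartment() -> Morphology:
    """A lone spherical-ish soma for sealed-compartment bookkeeping tests."""
    return Morphology([
        Section(id=1, parent_id=-1, length=15.0, diam_prox=15.0,
                diam_dist=15.0, region="soma"),
    ])


@pytest.fixture(scope="session")
def small_surrogate() -> Morphology:
    """A reduced surrogate cell (fewer/shorter dendrites) for fast protocol
    tests; the full-size default is exercised by the acceptance script."""
    spec = SurrogateMorphologySpec(n_primary_dendrites=3,
                                   mean_path_length=300.0,
                                   target_capacitance=40.0, seed=11)
    return make_surrogate_morphology(spec)


@pytest.fixture(scope="session")
def small_model(small_surrogate):
    return discretize(small_surrogate)


@pytest.fixture(scope="session")
def fine_model(small_surrogate):
    """Finer spatial grid so the most proximal synapse site of the
    space-clamp ladder sits within ~10 um of the soma."""
    return discretize(small_surrogate, nseg_rule=0.04)
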