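import numpy as np
import pytest
from shapely.geometry import Polygon

from fosmap.spiketrain import StimulusProtocol
from fosmap.synthetic import SectionParams, make_section, make_spike_trains

# small section geometry used throughout: ~0.16 mm^2, ~270 NeuN cells,
# keeps Monte Carlo loops fast while preserving the crescent shape
SMALL_GEOMETRY = dict(outer_radius=225.0, inner_radius=275.0, inner_offset=375.0)


@pytest.fixture(scope="session")
def protocol():
    return StimulusProtocol(pulse_onset=5.0)


@pytest.fixture(scope="session")
def unit_square():
    return Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])


@pytest.fixture(scope="session")
def small_section():
    return make_section(SectionParams(**SMALL_GEOMETRY), seed=11)


@pytest.fixture(scope="session")
def spike_population(protocol):
    return make_spike_trains(protocol=protocol, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
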