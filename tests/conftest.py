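import pytest

from stretchlab.actuation import MembraneGeometry
from stretchlab.materials import VHB4910


@pytest.fixture
def mat():
    """Published VHB 4910 parameter set."""
    return VHB4910


@pytest.fixture
def geom():
    """Default device geometry: 1 mm film, 3x radial prestretch."""
    return MembraneGeometry()
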