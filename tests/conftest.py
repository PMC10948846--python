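import warnings

import pytest

from cranioflow.geometry import HeadGeometry, generate_mesh
from cranioflow.synthetic import generate_waveform_triplet


@pytest.fixture(autouse=True)
def _quiet_numerics():
    # advisory CFL warnings from deliberately coarse benchmark settings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture(scope="session")
def head_geometry():
    return HeadGeometry()


@pytest.fixture(scope="session")
def coarse_mesh(head_geometry):
    return generate_mesh(head_geometry, "coarse")


@pytest.fixture(scope="session")
def waveforms():
    """Deterministic waveform triplet used across coupled-solver tests."""
    return generate_waveform_triplet(heart_rate=70.0, seed=1)
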