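import numpy as np
import pytest

import bloodspec as bs


@pytest.fixture(scope="session")
def design():
    """The full 540-sample adulteration design with default artifacts."""
    return bs.generate_design(seed=1)


@pytest.fixture(scope="session")
def clean_design():
    """Artifact-free design (all noise terms zero): pure convex mixtures."""
    params = bs.ArtifactParams(
        scatter_slope_sd=0.0, scatter_offset_sd=0.0, tilt_sd=0.0, noise_sd=0.0
    )
    return bs.generate_design(params=params, seed=1)


@pytest.fixture(scope="session")
def endmembers():
    return bs.default_endmembers()


@pytest.fixture(scope="session")
def grid():
    return bs.default_grid()
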