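import numpy as np
import pytest

from frapmorph import BeamProfile, DEFAULT_BEAMS


@pytest.fixture(scope="session")
def beam_small() -> BeamProfile:
    """63x objective: small Gaussian spot, ω = 0.77 μm."""
    return DEFAULT_BEAMS[0]


@pytest.fixture(scope="session")
def beam_large() -> BeamProfile:
    """40x objective: large Gaussian spot, ω = 1.17 μm."""
    return DEFAULT_BEAMS[1]


@pytest.fixture(scope="session")
def beams_with_replicates() -> tuple[BeamProfile, BeamProfile]:
    """Beam profiles carrying n = 59 per-measurement radius replicates."""
    rng = np.random.default_rng(59)
    small = BeamProfile.from_replicates("63x", 0.77 + 0.03 * rng.standard_normal(59))
    large = BeamProfile.from_replicates("40x", 1.17 + 0.05 * rng.standard_normal(59))
    return large, small
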