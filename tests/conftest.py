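import numpy as np
import pytest

from tiltprobe.phase_functions import MomentSet, solve_params_from_moments
from tiltprobe.transport import Medium, ProbeLayout, propagate


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def case1_medium():
    """Typical visible-range tissue: mus' = 2/mm, gamma = 1.5, mua = 0.2/mm."""
    return Medium.from_reduced(2.0, 1.5, 0.2)


@pytest.fixture(scope="session")
def case2_medium():
    """Limiting-case tissue: mus' = 1/mm, gamma = 1.9, mua = 0.2/mm."""
    return Medium.from_reduced(1.0, 1.9, 0.2)


@pytest.fixture(scope="session")
def matched_pair():
    """MHG and MPC solved to the same (g1, g2) = (0.9, 0.85)."""
    target = MomentSet(0.9, 0.85)
    return (
        solve_params_from_moments("mhg", target),
        solve_params_from_moments("mpc", target),
    )


@pytest.fixture(scope="session")
def small_case1_tally(case1_medium):
    """Shared small perpendicular run used by several transport tests."""
    layout = ProbeLayout.linear([0.25, 0.5, 0.75, 1.0])
    return propagate(case1_medium, layout, 200_000, seed=42)
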