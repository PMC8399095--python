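import numpy as np
import pytest

import skijump as sk
from skijump.body import load_segment_model
from skijump.hill import HillProfile


@pytest.fixture(scope="session")
def hill():
    from importlib import resources
    return sk.load_hill(str(resources.files("skijump") / "data" / "default_hill.yaml"))


@pytest.fixture(scope="session")
def model():
    return load_segment_model()


@pytest.fixture(scope="session")
def default_jump(hill):
    """One simulated jump with the default configuration (shared, read-only)."""
    return sk.simulate_jump(sk.SimulationConfig(), hill)


@pytest.fixture(scope="session")
def straight_hill():
    """Near-degenerate hill dominated by a long straight: terminal-velocity
    and constant-slope checks."""
    angle = np.deg2rad(30.0)
    return HillProfile(
        inrun_straight_angle=angle,
        transition_radius=50.0,
        table_angle=np.deg2rad(29.0),
        table_length=1.0,
        inrun_total_arc_length=1200.0,
        landing_knots=((0.0, -1.0, -0.5), (50.0, -26.0, -0.5),
                       (100.0, -51.0, -0.5)),
        gate_ref=1, gate_ref_arc_position=0.0,
    )
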