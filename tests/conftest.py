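import numpy as np
import pytest

from nussplan import geometry


@pytest.fixture(scope="session")
def healthy():
    return geometry.generate_healthy_thorax(n_ribs=8, scale=250.0, seed=1)


@pytest.fixture(scope="session")
def patient():
    """(pex_thorax, healthy_reference) of the packaged synthetic patient."""
    return geometry.synthetic_patient(seed=1)


@pytest.fixture()
def arc_boundary():
    """A dense convex circular-arc reference boundary, left-to-right."""
    th = np.linspace(0.2 * np.pi, 0.8 * np.pi, 200)[::-1]
    return np.column_stack([120 * np.cos(th), 120 * np.sin(th)])
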