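import numpy as np
import pytest

from panorex.bezier import FitConfig
from panorex.panoramic import run_pipeline
from panorex.phantom import PhantomSpec, generate_phantom, preset_spec


@pytest.fixture(scope="session")
def default_phantom():
    """Desk-scale phantom volume with ground truth (seed 0)."""
    return generate_phantom(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def missing_teeth_phantom():
    return generate_phantom(preset_spec("missing-teeth", seed=0))


@pytest.fixture(scope="session")
def default_pipeline(default_phantom):
    """Full pipeline run on the default phantom, shared across tests."""
    volume, truth = default_phantom
    pano, fit, diagnostics = run_pipeline(volume, fit_cfg=FitConfig(n_control_points=11))
    return volume, truth, pano, fit, diagnostics


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
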