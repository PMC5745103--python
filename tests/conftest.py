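import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mdoct import experiments, phantom

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def geometry():
    return phantom.BeamGeometry()


@pytest.fixture(scope="session")
def cp_stack_small():
    """Standard CP phantom at reduced size: (stack, truth, geometry, pattern, layers)."""
    return experiments.standard_phantom(seed=11, ascans=512, bscans=3)


@pytest.fixture(scope="session")
def cp_stack_nospeckle():
    """Speckle- and noise-free CP phantom for analytic oracles."""
    geometry = phantom.BeamGeometry()
    pattern = phantom.ScanPattern.circumpapillary(ascans=256, bscans=1)
    truth = phantom.default_truth(pattern)
    layers = phantom.default_layers()
    stack = phantom.render_multichannel(
        truth, geometry, pattern, layers, seed=0, noise_sigma=0.0, speckle=False
    )
    return stack, truth, geometry, pattern, layers


def single_reflector_truth(pattern, depth=384, base_row=120, step=2):
    """Truth with a single 1-px reflective row (the ELM slab), depth varying
    across A-scans so mean-spectrum subtraction cannot cancel the fringes."""
    n = pattern.ascans_per_bscan
    z = base_row + step * (np.arange(n) % 8)
    rows = {}
    for i, name in enumerate(phantom.LAYER_ORDER):
        offset = i - phantom.LAYER_ORDER.index("ELM")
        rows[name] = (z + offset)[None, :].repeat(pattern.bscans, axis=0)
    return phantom.PhantomTruth(boundaries=rows, depth=depth, vessel_azimuths=[])


REFLECTOR_LAYERS = [phantom.LayerModel("ELM", 900.0)]
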