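import warnings

import numpy as np
import pytest

from hemokymo.containers import PolylineROI
from hemokymo.synthetic import SimVesselSpec, simulate_vessel_video


@pytest.fixture(scope="session")
def parabolic_vessel():
    """Noiseless multifile vessel with an ideal parabolic profile
    (B=2, beta=0, r0=0) and thin tracer cells, shared across tests."""
    spec = SimVesselSpec(
        fov=(56, 96), pixel_size=0.5, duration=0.3, n_rbc=100,
        lumen_radius=10.0, rbc_radius=1.0, vmax=5.0,
        bluntness_B=2.0, beta=0.0, r0=0.0, seed=11,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stack, truth = simulate_vessel_video(spec)
    axis = PolylineROI(np.array([[4.0, 27.5], [91.0, 27.5]]))
    return spec, stack, truth, axis


@pytest.fixture(scope="session")
def pulsatile_sift_vessel():
    """Small pulsatile vessel for the dense-flow (SIFT) tests."""
    spec = SimVesselSpec(
        fov=(24, 40), pixel_size=1.0, frame_rate=500.0, duration=0.044,
        n_rbc=30, lumen_radius=7.0, rbc_radius=2.0, vmax=2.0,
        bluntness_B=2.0, beta=0.3, f0=12.0, modulation_depths=(0.4,),
        seed=31,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stack, truth = simulate_vessel_video(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def pulsatile_sift_fields(pulsatile_sift_vessel):
    """Flow-field series for the pulsatile vessel, computed once."""
    from hemokymo.siftflow import SiftFlowConfig, velocity_map_series

    spec, stack, truth = pulsatile_sift_vessel
    poly = np.array([[1.0, 3.5], [38.0, 3.5], [38.0, 19.5], [1.0, 19.5]])
    cfg = SiftFlowConfig(search_radius=5, upsample_factor=2, bp_iters=20)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fields, mean_field = velocity_map_series(stack, poly, cfg)
    return fields, mean_field
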