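import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from radtme import (
    FenestraSpec,
    RADParams,
    RectDomain,
    build_mesh,
    fiber_radius_for_packing,
    generate_fiber_field,
    solve_rad,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def preset_field():
    """The reference transport geometry: 40 equal fibers at phi=0.30 in 10x5 um."""
    dom = RectDomain(10.0, 5.0)
    r = fiber_radius_for_packing(0.30, dom, 40)
    return generate_fiber_field(dom, 40, r, min_gap=0.02, seed=1, target_phi=0.30)


@pytest.fixture(scope="session")
def preset_mesh(preset_field):
    fen = FenestraSpec(width=0.3, edge="bottom", center_offset=5.0)
    return build_mesh(preset_field, fen, h=0.08)


@pytest.fixture(scope="session")
def preset_run(preset_mesh):
    """Snapshots of the reference RAD run (D=1270 um^2/s, omega_y=34.3 um/s)."""
    t_end, n_steps = 0.2, 2000
    steps = np.unique(np.round(np.geomspace(1, n_steps, 50)).astype(int))
    params = RADParams(
        diffusivity=1270.0,
        omega=(0.0, 34.3),
        inlet_concentration=8.0e13,
        t_end=t_end,
        n_steps=n_steps,
        output_times=steps * (t_end / n_steps),
    )
    return solve_rad(preset_mesh, params)
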