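import numpy as np
import pytest

from ecsnano.synthetic_data import SceneGeometry, simulate_walker
from ecsnano.tracking import Trajectory


def make_channel_geometry(width_nm: float, length_nm: float = 4000.0
                          ) -> SceneGeometry:
    """Straight horizontal channel of the given width (no pools)."""
    return SceneGeometry(
        pools=np.empty((0, 3)),
        channels=np.array(
            [[200.0, 500.0, 200.0 + length_nm, 500.0, width_nm]]
        ),
        domain_size=(length_nm + 400.0, 1000.0),
        resolution_nm=min(5.0, width_nm / 8),
    )


def walker_trajectory(
    geom,
    d_nm2_s,
    n_steps,
    seed,
    dt_s=0.030,
    noise_nm=0.0,
    start_nm=None,
    traj_id=0,
) -> Trajectory:
    """Simulate a walker and wrap it as a Trajectory (optionally noisy)."""
    tt = simulate_walker(geom, d_nm2_s, n_steps, dt_s, seed=seed,
                         start_nm=start_nm)
    xy = tt.positions
    if noise_nm > 0:
        rng = np.random.default_rng(seed + 7_000_003)
        xy = xy + rng.normal(0.0, noise_nm, xy.shape)
    return Trajectory(
        id=traj_id,
        t_index=np.arange(n_steps + 1),
        xy_nm=xy,
        sigma_major_nm=np.zeros(n_steps + 1),
        dt_s=dt_s,
    )


@pytest.fixture(scope="session")
def channel_width_recovery():
    """Median recovered width per true channel width (shared, noise-free).

    Session-scoped because several tests (monotonicity, per-width accuracy)
    consume the same simulations.
    """
    from ecsnano.dimensions import confinement_windows, estimate_local_width

    out = {}
    for width in (50.0, 100.0, 200.0):
        geom = make_channel_geometry(width)
        medians = []
        for seed in range(5):
            traj = walker_trajectory(geom, 1e6, 800, seed=100 + seed,
                                     start_nm=[2200.0, 500.0])
            _pos, widths = estimate_local_width(confinement_windows(traj))
            medians.append(np.median(widths))
        out[width] = float(np.median(medians))
    return out
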