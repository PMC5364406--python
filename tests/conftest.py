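import numpy as np
import pytest

from cytodyn.runs import RunSegment
from cytodyn.synthetic import FilamentShape, MotorParams, simulate_run_trajectory
from cytodyn.trajectory import Trajectory


def make_run(positions, dt=0.05, track_id=0) -> RunSegment:
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    return RunSegment(track_id, np.arange(n), np.arange(n) * dt, positions, dt)


def circle_run(radius=2.0, n=60, arc=np.pi, dt=0.05, track_id=0) -> RunSegment:
    th = np.linspace(0.0, arc, n)
    pts = radius * np.column_stack([np.cos(th), np.sin(th)])
    return make_run(pts, dt=dt, track_id=track_id)


def random_filament(rng, n_vertices=24, step=1.0, turn_sd=0.35,
                    undulation_sd=0.05, undulation_tau=10.0) -> FilamentShape:
    """Gently curved random filament with ~1 µm vertex spacing."""
    heading = rng.uniform(0, 2 * np.pi)
    verts = [np.zeros(2)]
    for _ in range(n_vertices - 1):
        heading += rng.normal(0.0, turn_sd)
        verts.append(verts[-1] + step * np.array([np.cos(heading),
                                                  np.sin(heading)]))
    return FilamentShape(np.array(verts), undulation_sd=undulation_sd,
                         undulation_tau=undulation_tau)


@pytest.fixture
def undulating_runs():
    """Mostly-bound runs along undulating backbones, for decomposition tests."""
    from cytodyn.runs import detect_runs

    runs = []
    for s in range(8):
        rng = np.random.default_rng(100 + s)
        shape = random_filament(rng, turn_sd=0.45, undulation_sd=0.08,
                                undulation_tau=5.0)
        motor = MotorParams(speed_mean=1.0, speed_sd=0.05,
                            run_duration_mean=12.0, off_duration_mean=1.0,
                            d_unbound=0.3, sigma_loc=0.005, dt=0.05)
        tr = simulate_run_trajectory(shape, motor, 240, seed=100 + s)
        runs.extend(detect_runs(tr))
    return runs


def static_track(n=20, x=1.0, y=1.0, dt=0.1, track_id=0) -> Trajectory:
    return Trajectory(track_id, np.arange(n), np.arange(n) * dt,
                      np.full(n, float(x)), np.full(n, float(y)))
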