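import numpy as np
import pytest

from znsh import (
    PotentialSurface,
    RunConfig,
    SurfaceEvaluation,
    Trajectory,
    build_surrogate,
    load_anchor_table,
    run_ensemble,
)


class HarmonicTestSurface(PotentialSurface):
    """V_lower = 0.5 k (x - x0)^2; upper state shifted by a constant gap."""

    ndim = 1

    def __init__(self, k=1.0, x0=0.0, mass=1.0, gap=1.0):
        self.k, self.x0, self.mass, self.gap = k, x0, mass, gap

    def evaluate(self, coordinates):
        x = self._coerce(coordinates)
        e = 0.5 * self.k * (x[0] - self.x0) ** 2
        g = self.k * (x[0] - self.x0)
        return SurfaceEvaluation(
            coordinates=x,
            adiabatic_energies=np.array([e, e + self.gap]),
            adiabatic_gradients=np.array([[g], [g]]),
        )


class FlatTestSurface(PotentialSurface):
    """Zero force everywhere on both states."""

    ndim = 1

    def __init__(self, mass=1.0, gap=1.0):
        self.mass, self.gap = mass, gap

    def evaluate(self, coordinates):
        x = self._coerce(coordinates)
        return SurfaceEvaluation(
            coordinates=x,
            adiabatic_energies=np.array([0.0, self.gap]),
            adiabatic_gradients=np.zeros((2, 1)),
        )


def make_synthetic_trajectory(time_fs, r_angstrom, states, traj_id=0, hops=None):
    """Minimal Trajectory for analysis-level tests."""
    from znsh.units import ANGSTROM_TO_BOHR

    time_fs = np.asarray(time_fs, dtype=float)
    r = np.asarray(r_angstrom, dtype=float)
    states = np.asarray(states, dtype=int)
    n = len(time_fs)
    return Trajectory(
        time_fs=time_fs,
        positions=(r * ANGSTROM_TO_BOHR)[:, None],
        velocities=np.zeros((n, 1)),
        states=states,
        e_lower=np.zeros(n),
        e_upper=np.zeros(n),
        e_kinetic=np.zeros(n),
        hops=hops or [],
        traj_id=traj_id,
    )


@pytest.fixture(scope="session")
def scan_surface():
    return build_surrogate(load_anchor_table("scan"))


@pytest.fixture(scope="session")
def reactive_surface():
    return build_surrogate(load_anchor_table("reactive"))


@pytest.fixture(scope="session")
def default_ensemble():
    """The full default protocol: 40 trajectories x 500 fs, dt 1 fs."""
    return run_ensemble(RunConfig())


@pytest.fixture(scope="session")
def small_ensemble():
    return run_ensemble(RunConfig(n_traj=6, t_max_fs=300.0, seed=11))
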