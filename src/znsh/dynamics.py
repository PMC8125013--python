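"""Nuclear propagation and the surface-hopping loop.

Classical nuclei move on one adiabatic surface by velocity-Verlet
integration.  Whenever the adiabatic gap passes through a strict local
minimum along the trajectory (gap[k-1] > gap[k] < gap[k+1]) below the
gap gate (default 30 kcal/mol), a single hop attempt is made at step k:
the crossing is diabatized from the three bracketing evaluations, the
Zhu-Nakamura probability is computed, a uniform random number decides
the switch, and on acceptance the velocity component along the hopping
direction is rescaled so total energy is conserved exactly.  The
default protocol is 40 trajectories x 500 fs at dt = 1.0 fs, starting
on the upper state from Wigner-sampled open-form initial conditions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional

import numpy as np

from . import zn
from .sampling import mode_from_curvature, wigner_sample
from .surfaces import (
    PotentialSurface,
    SurrogateSurface,
    build_surrogate,
    load_anchor_table,
)
from .units import (
    ANGSTROM_TO_BOHR,
    BOHR_TO_ANGSTROM,
    FS_TO_AU,
    HARTREE_TO_KCALMOL,
    KCALMOL_TO_HARTREE,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "HopEvent",
    "Trajectory",
    "EnsembleResult",
    "verlet_step",
    "run_trajectory",
    "run_ensemble",
    "write_ensemble",
    "read_ensemble",
]

LOWER, UPPER = 0, 1


@dataclass
class RunConfig:
    """Simulation protocol parameters (user units)."""

    dt_fs: float = 1.0
    t_max_fs: float = 500.0
    n_traj: int = 40
    gap_threshold_kcalmol: float = 30.0
    seed: int = 2021
    initial_state: int = UPPER
    r_threshold_angstrom: float = 1.70
    refractory_steps: int = 2
    energy_drift_tol_kcalmol: float = 10.0
    # surrogate-surface construction (used when no surface object is given)
    surface_variant: str = "reactive"
    mass_amu: float = 6.0
    gap_floor_kcalmol: float = 1.0
    open_wall_cm1: float = 300.0
    closed_wall_cm1: float = 1000.0

    def __post_init__(self):
        if self.dt_fs <= 0:
            raise ValueError("dt must be positive")
        n = self.t_max_fs / self.dt_fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("t_max must be an integer multiple of dt")
        if self.n_traj < 1:
            raise ValueError("n_traj must be >= 1")
        if self.initial_state not in (LOWER, UPPER):
            raise ValueError("initial_state must be 0 (lower) or 1 (upper)")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_max_fs / self.dt_fs))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)


@dataclass
class HopEvent:
    """One hop attempt at a local gap minimum."""

    step: int
    time_fs: float
    r_angstrom: float
    gap_kcalmol: float
    a_sq: float
    b_sq: float
    probability: float
    draw: float
    accepted: bool
    frustrated: bool
    from_state: int
    to_state: int


@dataclass
class Trajectory:
    """Time series of one surface-hopping trajectory (atomic units inside)."""

    time_fs: np.ndarray
    positions: np.ndarray  # (n, D) Bohr
    velocities: np.ndarray  # (n, D) Bohr / a.u. time
    states: np.ndarray  # (n,) 0 = lower, 1 = upper
    e_lower: np.ndarray  # Hartree
    e_upper: np.ndarray
    e_kinetic: np.ndarray
    hops: List[HopEvent] = field(default_factory=list)
    failed: bool = False
    fail_reason: str = ""
    final_class: Optional[str] = None
    traj_id: int = 0
    seed_entropy: Optional[int] = None

    @property
    def r_angstrom(self) -> np.ndarray:
        """1-D coordinate track in Angstrom."""
        return self.positions[:, 0] * BOHR_TO_ANGSTROM

    @property
    def e_total(self) -> np.ndarray:
        active = np.where(self.states == LOWER, self.e_lower, self.e_upper)
        return active + self.e_kinetic

    @property
    def accepted_hops(self) -> List[HopEvent]:
        return [h for h in self.hops if h.accepted]

    @property
    def success(self) -> bool:
        return not self.failed


@dataclass
class EnsembleResult:
    """A collection of trajectories plus bookkeeping."""

    trajectories: List[Trajectory]
    config: RunConfig
    surface: Optional[PotentialSurface] = None

    @property
    def successful(self) -> List[Trajectory]:
        return [t for t in self.trajectories if t.success]

    @property
    def n_success(self) -> int:
        return len(self.successful)


def verlet_step(x, v, masses, grad, surface: PotentialSurface, state: int, dt: float):
    """One velocity-Verlet step on the ``state`` adiabatic surface.

    Returns (x_new, v_new, evaluation_at_x_new); exactly one new surface
    evaluation per call.
    """
    a0 = -grad / masses
    x_new = x + v * dt + 0.5 * a0 * dt * dt
    ev_new = surface.evaluate(x_new)
    a1 = -ev_new.adiabatic_gradients[state] / masses
    v_new = v + 0.5 * (a0 + a1) * dt
    return x_new, v_new, ev_new


def _kinetic(v, masses) -> float:
    return float(0.5 * np.sum(masses * v * v))


def run_trajectory(
    surface: PotentialSurface,
    initial,
    config: RunConfig,
    rng,
    masses: Optional[np.ndarray] = None,
    traj_id: int = 0,
) -> Trajectory:
    """Propagate one surface-hopping trajectory.

    ``initial`` is a (position, momentum) pair in atomic units (arrays
    or scalars); the electronic state starts on ``config.initial_state``
    (vertical excitation: nuclei untouched).  All stochastic hop
    decisions draw from ``rng``.
    """
    rng = np.random.default_rng(rng)
    x0 = np.atleast_1d(np.asarray(initial[0], dtype=float))
    p0 = np.atleast_1d(np.asarray(initial[1], dtype=float))
    if masses is None:
        masses = np.full(x0.shape, getattr(surface, "mass"))
    masses = np.asarray(masses, dtype=float)
    v0 = p0 / masses
    dt = config.dt_fs * FS_TO_AU
    n_steps = config.n_steps
    gap_gate = config.gap_threshold_kcalmol * KCALMOL_TO_HARTREE
    drift_tol = config.energy_drift_tol_kcalmol * KCALMOL_TO_HARTREE

    xs, vs, evs, states = [x0], [v0], [surface.evaluate(x0)], [config.initial_state]
    hops: List[HopEvent] = []
    failed, fail_reason = False, ""
    e_ref = evs[0].adiabatic_energies[states[0]] + _kinetic(v0, masses)
    last_hop_step = -10**9

    k = 0  # index of the last completed step
    while k < n_steps:
        try:
            x_new, v_new, ev_new = verlet_step(
                xs[k], vs[k], masses, evs[k].adiabatic_gradients[states[k]],
                surface, states[k], dt,
            )
        except ValueError as exc:
            failed, fail_reason = True, f"surface domain violation: {exc}"
            break
        xs.append(x_new)
        vs.append(v_new)
        evs.append(ev_new)
        states.append(states[k])
        k += 1

        e_tot = ev_new.adiabatic_energies[states[k]] + _kinetic(v_new, masses)
        if abs(e_tot - e_ref) > drift_tol:
            failed = True
            fail_reason = (
                f"energy drift {abs(e_tot - e_ref) * HARTREE_TO_KCALMOL:.2f} "
                "kcal/mol exceeds tolerance"
            )
            break

        # hop attempt at the interior gap minimum j = k - 1
        j = k - 1
        if j < 1 or j - last_hop_step <= config.refractory_steps:
            continue
        g_prev, g_min, g_next = evs[j - 1].gap, evs[j].gap, evs[j + 1].gap
        if not (g_prev > g_min < g_next) or g_min >= gap_gate:
            continue

        F1v, F2v, V12, Ex = zn.diabatize_crossing(evs[j - 1], evs[j], evs[j + 1])
        m_full = masses
        dvec = (F2v - F1v) / np.sqrt(m_full)
        nrm = np.linalg.norm(dvec)
        if nrm == 0.0:
            continue
        dvec = dvec / nrm
        G = zn.mass_scaled_product(F1v, F2v, m_full)
        D_sq = zn.mass_scaled_difference_sq(F1v, F2v, m_full)
        ke_along = zn.kinetic_energy_along(vs[j], m_full, dvec)
        state_j = states[j]
        e_act = float(evs[j].adiabatic_energies[state_j])
        inputs = zn.ZNInputs(
            F1=float(np.sqrt(np.sum(F1v**2 / m_full))),
            F2=float(np.sqrt(np.sum(F2v**2 / m_full))),
            V12=V12,
            Ex=Ex,
            Et=e_act + ke_along,
        )
        result = zn.zn_parameters(inputs, G, D_sq)
        draw = float(rng.random())
        accepted = draw < result.probability
        frustrated = False
        new_state = 1 - state_j
        if accepted:
            deltaE = e_act - float(evs[j].adiabatic_energies[new_state])
            try:
                v_adj = zn.hop_adjust_momentum(vs[j], m_full, dvec, deltaE)
            except zn.FrustratedHop:
                accepted, frustrated = False, True
        hops.append(
            HopEvent(
                step=j,
                time_fs=j * config.dt_fs,
                r_angstrom=float(xs[j][0]) * BOHR_TO_ANGSTROM,
                gap_kcalmol=g_min * HARTREE_TO_KCALMOL,
                a_sq=result.a_sq,
                b_sq=result.b_sq,
                probability=result.probability,
                draw=draw,
                accepted=accepted,
                frustrated=frustrated,
                from_state=state_j,
                to_state=new_state if accepted else state_j,
            )
        )
        if accepted:
            # rewind to step j on the new surface with rescaled velocity
            del xs[j + 1:], vs[j + 1:], evs[j + 1:], states[j + 1:]
            vs[j] = np.asarray(v_adj, dtype=float)
            states[j] = new_state
            k = j
            last_hop_step = j
            e_ref = float(evs[j].adiabatic_energies[new_state]) + _kinetic(vs[j], masses)

    n = len(xs)
    traj = Trajectory(
        time_fs=np.arange(n) * config.dt_fs,
        positions=np.asarray(xs),
        velocities=np.asarray(vs),
        states=np.asarray(states, dtype=int),
        e_lower=np.array([e.adiabatic_energies[0] for e in evs]),
        e_upper=np.array([e.adiabatic_energies[1] for e in evs]),
        e_kinetic=np.array([_kinetic(v, masses) for v in vs]),
        hops=hops,
        failed=failed,
        fail_reason=fail_reason,
        traj_id=traj_id,
    )
    return traj


def default_surface(config: RunConfig) -> SurrogateSurface:
    """Build the surrogate surface described by ``config``."""
    anchors = load_anchor_table(config.surface_variant)
    return build_surrogate(
        anchors,
        gap_floor_kcalmol=config.gap_floor_kcalmol,
        mass_amu=config.mass_amu,
        open_wall_cm1=config.open_wall_cm1,
        closed_wall_cm1=config.closed_wall_cm1,
    )


def run_ensemble(
    config: RunConfig,
    surface: Optional[PotentialSurface] = None,
    initial_conditions: Optional[np.ndarray] = None,
) -> EnsembleResult:
    """Run ``config.n_traj`` independent trajectories.

    Seeding rule: ``SeedSequence(config.seed)`` is spawned into
    ``n_traj + 1`` children -- child 0 drives the Wigner sampling of all
    initial conditions, child i+1 drives the hop decisions of
    trajectory i.  Any single trajectory is therefore reproducible in
    isolation from the master seed and its index.
    """
    if surface is None:
        surface = default_surface(config)
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_traj + 1)
    if initial_conditions is None:
        guess = 3.302 * ANGSTROM_TO_BOHR
        mode = mode_from_curvature(surface, "lower", guess, surface.mass)
        initial_conditions = wigner_sample(mode, config.n_traj, children[0])
    trajectories = []
    for i in range(config.n_traj):
        traj = run_trajectory(
            surface,
            (initial_conditions[i, 0], initial_conditions[i, 1]),
            config,
            np.random.default_rng(children[i + 1]),
            traj_id=i,
        )
        if traj.failed:
            logger.info("trajectory %d failed: %s", i, traj.fail_reason)
        trajectories.append(traj)
    return EnsembleResult(trajectories=trajectories, config=config, surface=surface)


# ---------------------------------------------------------------------------
# Plain-text persistence
# ---------------------------------------------------------------------------

def write_ensemble(ensemble: EnsembleResult, outdir) -> None:
    """Write per-trajectory CSVs, a hop-event CSV and a manifest JSON."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hop_rows = []
    for traj in ensemble.trajectories:
        df = pd.DataFrame(
            {
                "time_fs": traj.time_fs,
                "r_angstrom": traj.r_angstrom,
                "velocity_au": traj.velocities[:, 0],
                "active_state": traj.states,
                "e_s0_kcalmol": traj.e_lower * HARTREE_TO_KCALMOL,
                "e_s1_kcalmol": traj.e_upper * HARTREE_TO_KCALMOL,
                "e_kin_kcalmol": traj.e_kinetic * HARTREE_TO_KCALMOL,
                "e_total_kcalmol": traj.e_total * HARTREE_TO_KCALMOL,
            }
        )
        df.to_csv(
            outdir / f"traj_{traj.traj_id:04d}.csv",
            index=False,
            float_format="%.12g",
        )
        for h in traj.hops:
            hop_rows.append({"traj_id": traj.traj_id, **asdict(h)})
    pd.DataFrame(
        hop_rows,
        columns=["traj_id", "step", "time_fs", "r_angstrom", "gap_kcalmol",
                 "a_sq", "b_sq", "probability", "draw", "accepted",
                 "frustrated", "from_state", "to_state"],
    ).to_csv(outdir / "hops.csv", index=False, float_format="%.12g")
    manifest = {
        "config": ensemble.config.to_dict(),
        "n_traj": len(ensemble.trajectories),
        "success": [t.success for t in ensemble.trajectories],
        "fail_reasons": [t.fail_reason for t in ensemble.trajectories],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def read_ensemble(outdir) -> EnsembleResult:
    """Rebuild an :class:`EnsembleResult` from :func:`write_ensemble` output."""
    import pandas as pd

    outdir = Path(outdir)
    manifest_path = outdir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {outdir}")
    manifest = json.loads(manifest_path.read_text())
    config = RunConfig.from_dict(manifest["config"])
    hops_df = pd.read_csv(outdir / "hops.csv")
    trajectories = []
    for i in range(manifest["n_traj"]):
        df = pd.read_csv(outdir / f"traj_{i:04d}.csv")
        traj_hops = [
            HopEvent(
                step=int(row.step),
                time_fs=float(row.time_fs),
                r_angstrom=float(row.r_angstrom),
                gap_kcalmol=float(row.gap_kcalmol),
                a_sq=float(row.a_sq),
                b_sq=float(row.b_sq),
                probability=float(row.probability),
                draw=float(row.draw),
                accepted=bool(row.accepted),
                frustrated=bool(row.frustrated),
                from_state=int(row.from_state),
                to_state=int(row.to_state),
            )
            for row in hops_df[hops_df.traj_id == i].itertuples()
        ]
        trajectories.append(
            Trajectory(
                time_fs=df["time_fs"].to_numpy(float),
                positions=(df["r_angstrom"].to_numpy(float) * ANGSTROM_TO_BOHR)[:, None],
                velocities=df["velocity_au"].to_numpy(float)[:, None],
                states=df["active_state"].to_numpy(int),
                e_lower=df["e_s0_kcalmol"].to_numpy(float) * KCALMOL_TO_HARTREE,
                e_upper=df["e_s1_kcalmol"].to_numpy(float) * KCALMOL_TO_HARTREE,
                e_kinetic=df["e_kin_kcalmol"].to_numpy(float) * KCALMOL_TO_HARTREE,
                hops=traj_hops,
                failed=not manifest["success"][i],
                fail_reason=manifest["fail_reasons"][i],
                traj_id=i,
            )
        )
    return EnsembleResult(trajectories=trajectories, config=config)
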