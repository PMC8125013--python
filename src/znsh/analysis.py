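"""Ensemble statistics for surface-hopping runs.

Derived quantities: time-dependent state populations, a single
exponential fit of the excited-state decay (y = exp(-x/t)), first-hop
time / geometry / gap statistics, open-vs-closed product classification
by the final ring-closing distance (threshold 1.70 A, strict), the
ring-closing quantum yield with a binomial standard error, and the
ring-closing completion times (first time the distance drops below the
threshold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, List, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .dynamics import EnsembleResult, Trajectory, LOWER, UPPER

__all__ = [
    "DecayFit",
    "populations",
    "fit_decay",
    "hop_statistics",
    "classify_final",
    "quantum_yield",
    "ring_closing_times",
    "summarize",
]


@dataclass(frozen=True)
class DecayFit:
    """Single-exponential decay fit y = exp(-x/t)."""

    time_constant_fs: float
    residual_norm: float

    def __post_init__(self):
        if self.time_constant_fs <= 0:
            raise ValueError("time constant must be positive")


def _common_grid(trajectories: Sequence[Trajectory]) -> np.ndarray:
    if not trajectories:
        raise ValueError("empty ensemble")
    t0 = trajectories[0].time_fs
    for traj in trajectories[1:]:
        if len(traj.time_fs) != len(t0) or not np.allclose(traj.time_fs, t0):
            raise ValueError("trajectories do not share a common time grid")
    return t0


def populations(trajectories: Sequence[Trajectory]):
    """Fraction of trajectories in each state at every time.

    Returns ``(time_fs, P_upper, P_lower)``; P_upper + P_lower = 1
    exactly at every grid point.
    """
    t = _common_grid(trajectories)
    states = np.stack([traj.states for traj in trajectories])
    p_upper = (states == UPPER).mean(axis=0)
    return t, p_upper, 1.0 - p_upper


def fit_decay(time_fs: np.ndarray, p_upper: np.ndarray) -> DecayFit:
    """Least-squares fit of exp(-x/t) to the excited-state population.

    The fit uses the full window, unweighted.  A constant all-ones or
    all-zeros curve carries no decay information and is rejected.
    """
    time_fs = np.asarray(time_fs, dtype=float)
    y = np.asarray(p_upper, dtype=float)
    if np.all(y >= 1.0) or np.all(y <= 0.0):
        raise ValueError("population curve carries no decay information")
    if np.any(np.diff(y) > 0):
        warnings.warn("excited-state population is not monotonically non-increasing")
    # crossing of 1/e as the initial guess; fall back to half the window
    below = np.nonzero(y < np.exp(-1.0))[0]
    t_guess = time_fs[below[0]] if len(below) else 0.5 * (time_fs[-1] - time_fs[0])
    t_guess = max(t_guess, time_fs[1] - time_fs[0])
    popt, _ = curve_fit(
        lambda x, t: np.exp(-x / t), time_fs, y, p0=[t_guess],
        bounds=(1e-12, np.inf), maxfev=10000,
    )
    tau = float(popt[0])
    resid = float(np.linalg.norm(np.exp(-time_fs / tau) - y))
    return DecayFit(time_constant_fs=tau, residual_norm=resid)


def _first_accepted_hops(trajectories: Sequence[Trajectory]) -> List:
    firsts = []
    for traj in trajectories:
        acc = traj.accepted_hops
        if acc:
            firsts.append(acc[0])
    return firsts


def hop_statistics(
    trajectories: Sequence[Trajectory],
    time_bin_fs: float = 20.0,
    geometry_bin_angstrom: float = 0.1,
    gap_bin_kcalmol: float = 0.5,
) -> dict:
    """First-hop time / geometry / gap distributions.

    Each trajectory contributes its first accepted hop; trajectories
    that never hop contribute nothing.  Histograms use the configured
    bin widths, anchored at zero.
    """
    firsts = _first_accepted_hops(trajectories)
    out = {
        "n_hopped": len(firsts),
        "n_no_hop": len(trajectories) - len(firsts),
        "hop_times_fs": np.array([h.time_fs for h in firsts]),
        "hop_geometries_angstrom": np.array([h.r_angstrom for h in firsts]),
        "hop_gaps_kcalmol": np.array([h.gap_kcalmol for h in firsts]),
    }
    for key, width in (
        ("hop_times_fs", time_bin_fs),
        ("hop_geometries_angstrom", geometry_bin_angstrom),
        ("hop_gaps_kcalmol", gap_bin_kcalmol),
    ):
        vals = out[key]
        out["mean_" + key.replace("hop_", "")] = (
            float(vals.mean()) if len(vals) else float("nan")
        )
        if len(vals):
            hi = (np.floor(vals.max() / width) + 1) * width
            edges = np.arange(0.0, hi + 0.5 * width, width)
            counts, edges = np.histogram(vals, bins=edges)
        else:
            counts, edges = np.array([], dtype=int), np.array([0.0])
        out[key + "_hist"] = {"counts": counts, "edges": edges}
    return out


# tolerance guarding the strict tie-break against unit-roundtrip noise
_TIE_EPS_ANGSTROM = 1e-9


def classify_final(trajectory: Trajectory, r_threshold_angstrom: float = 1.70) -> str:
    """Classify the final frame: ``closed`` iff final r < threshold
    (strict inequality -- exactly at threshold counts as open)."""
    r_final = float(trajectory.r_angstrom[-1])
    return "closed" if r_final < r_threshold_angstrom - _TIE_EPS_ANGSTROM else "open"


def quantum_yield(classes: Iterable[str]):
    """Ring-closing quantum yield (#closed / #classified) and its
    normal-approximation binomial standard error."""
    classes = list(classes)
    if not classes:
        raise ValueError("no classified trajectories")
    n = len(classes)
    n_closed = sum(c == "closed" for c in classes)
    y = n_closed / n
    se = float(np.sqrt(y * (1.0 - y) / n))
    return y, se


def ring_closing_times(
    trajectories: Sequence[Trajectory], r_threshold_angstrom: float = 1.70
):
    """First time each closed-product trajectory drops below the
    ring-closing threshold, plus the mean over products.

    A trajectory classified ``closed`` whose distance never goes below
    the threshold is an internal inconsistency and raises.
    """
    times = []
    for traj in trajectories:
        if classify_final(traj, r_threshold_angstrom) != "closed":
            continue
        below = np.nonzero(traj.r_angstrom < r_threshold_angstrom - _TIE_EPS_ANGSTROM)[0]
        if len(below) == 0:
            raise ValueError(
                f"trajectory {traj.traj_id} classified closed but never "
                f"below {r_threshold_angstrom} A"
            )
        times.append(float(traj.time_fs[below[0]]))
    times = np.array(times)
    mean = float(times.mean()) if len(times) else float("nan")
    return times, mean


def summarize(ensemble: EnsembleResult) -> dict:
    """Full ensemble summary (JSON-serializable)."""
    ok = ensemble.successful
    if not ok:
        raise ValueError("no successful trajectories to analyze")
    t, p_up, p_lo = populations(ok)
    r_thr = ensemble.config.r_threshold_angstrom
    classes = [classify_final(traj, r_thr) for traj in ok]
    yield_, yield_se = quantum_yield(classes)
    stats = hop_statistics(ok)
    rc_times, rc_mean = ring_closing_times(ok, r_thr)
    try:
        fit = fit_decay(t, p_up)
        tau, resid = fit.time_constant_fs, fit.residual_norm
    except ValueError:
        tau, resid = None, None
    return {
        "n_total": len(ensemble.trajectories),
        "n_success": len(ok),
        "time_constant_fs": tau,
        "fit_residual_norm": resid,
        "mean_hop_time_fs": stats["mean_times_fs"],
        "mean_hop_geometry_angstrom": stats["mean_geometries_angstrom"],
        "mean_hop_gap_kcalmol": stats["mean_gaps_kcalmol"],
        "n_hopped": stats["n_hopped"],
        "quantum_yield": yield_,
        "quantum_yield_se": yield_se,
        "n_closed": int(round(yield_ * len(ok))),
        "mean_ring_closing_time_fs": rc_mean,
        "ring_closing_times_fs": rc_times.tolist(),
        "hop_times_hist": {
            "counts": stats["hop_times_fs_hist"]["counts"].tolist(),
            "edges": stats["hop_times_fs_hist"]["edges"].tolist(),
        },
        "hop_geometries_hist": {
            "counts": stats["hop_geometries_angstrom_hist"]["counts"].tolist(),
            "edges": stats["hop_geometries_angstrom_hist"]["edges"].tolist(),
        },
        "hop_gaps_hist": {
            "counts": stats["hop_gaps_kcalmol_hist"]["counts"].tolist(),
            "edges": stats["hop_gaps_kcalmol_hist"]["edges"].tolist(),
        },
        "populations": {
            "time_fs": t.tolist(),
            "p_upper": p_up.tolist(),
            "p_lower": p_lo.tolist(),
        },
    }
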