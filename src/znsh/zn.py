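"""Zhu-Nakamura hop machinery.

The single-passage transition probability between two adiabatic states
is evaluated from purely local, coupling-vector-free quantities: two
mass-scaled one-dimensional diabatic forces F1 and F2, the diabatic
coupling V12, the energy Ex at the crossing point, and the total energy
Et (potential plus the kinetic-energy component along the hopping
direction).  Two dimensionless parameters condense these,

    a^2 = hbar^2 sqrt(G) sqrt(D2) / (2 (2 V12)^3)        (effective coupling)
    b^2 = (Et - Ex) sqrt(D2) / (2 V12 sqrt(G))           (collision energy)

with G = sum_i (1/m_i) sum_a F2_ia F1_ia and
D2 = sum_i (1/m_i) sum_a (F2_ia - F1_ia)^2 the mass-scaled force
reductions, and the hop probability is

    p = exp[ -(pi / 4a) sqrt( 2 / (b^2 + sqrt(b^4 + s)) ) ],  s = ±1.

With s = +1 (the curve-crossing branch, used for Landau-Zener-type
topologies with signed b^2) this expression is continuous and monotone
in Et and reduces to the classic Landau-Zener exponential
exp(-2 pi V12^2 / (hbar v |dF|)) in the weak-coupling, high-energy
limit.  The s = -1 branch (nonadiabatic-tunneling topology) clamps
sqrt(b^4 - 1) to zero for b^4 < 1 and yields p = 0 whenever the
resulting root argument is non-positive.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .surfaces import SurfaceEvaluation

logger = logging.getLogger(__name__)
_warned_non_lz = False

__all__ = [
    "ZNInputs",
    "ZNResult",
    "CrossingPoint",
    "mass_scaled_product",
    "mass_scaled_difference_sq",
    "zn_parameters",
    "zn_probability",
    "diabatize_crossing",
    "hop_adjust_momentum",
    "FrustratedHop",
    "zn_single_passage_probability",
]


@dataclass(frozen=True)
class ZNInputs:
    """Scalar inputs of the transition-probability formula (atomic units).

    ``F1`` and ``F2`` are the mass-scaled one-dimensional diabatic
    forces (Hartree/(Bohr sqrt(m_e))); the reduced mass is already
    absorbed into them by the mass-scaled reductions.
    """

    F1: float
    F2: float
    V12: float
    Ex: float
    Et: float
    hbar: float = 1.0

    def __post_init__(self):
        if self.V12 <= 0:
            raise ValueError("diabatic coupling V12 must be positive")


@dataclass(frozen=True)
class ZNResult:
    """Dimensionless ZN parameters and the resulting hop probability."""

    a_sq: float
    b_sq: float
    probability: float
    branch: int  # +1 iff Et >= Ex (classically allowed at the crossing)

    def __post_init__(self):
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError(f"probability {self.probability} outside [0, 1]")
        if self.branch not in (+1, -1):
            raise ValueError("branch must be +1 or -1")


@dataclass(frozen=True)
class CrossingPoint:
    """A local minimum of the adiabatic gap along a trajectory."""

    step: int
    time_fs: float
    coordinates: np.ndarray  # Bohr, at the gap minimum
    gap: float  # Hartree
    before: SurfaceEvaluation
    at: SurfaceEvaluation
    after: SurfaceEvaluation
    direction: np.ndarray  # unit hopping direction


def _force_arrays(F1_vec, F2_vec, masses):
    F1 = np.asarray(F1_vec, dtype=float)
    F2 = np.asarray(F2_vec, dtype=float)
    m = np.asarray(masses, dtype=float)
    if F1.shape != F2.shape:
        raise ValueError(f"force shapes differ: {F1.shape} vs {F2.shape}")
    if np.any(m <= 0):
        raise ValueError("masses must be positive")
    F1 = F1.reshape(len(m), -1)
    if F1.size != F2.size or F1.size % len(m) != 0:
        raise ValueError("force dimension incompatible with number of masses")
    F2 = F2.reshape(len(m), -1)
    return F1, F2, m


def mass_scaled_product(F1_vec, F2_vec, masses) -> float:
    """G = sum_i (1/m_i) sum_alpha F2_ia F1_ia  (for 1-D: F1 F2 / mu)."""
    F1, F2, m = _force_arrays(F1_vec, F2_vec, masses)
    return float(np.sum((F1 * F2).sum(axis=1) / m))


def mass_scaled_difference_sq(F1_vec, F2_vec, masses) -> float:
    """D2 = sum_i (1/m_i) sum_alpha (F2_ia - F1_ia)^2 >= 0."""
    F1, F2, m = _force_arrays(F1_vec, F2_vec, masses)
    return float(np.sum(((F2 - F1) ** 2).sum(axis=1) / m))


def zn_parameters(inputs: ZNInputs, G: float, D_sq: float) -> ZNResult:
    """Evaluate a^2, b^2 (and p) from the mass-scaled force reductions.

    A non-positive G signals a non-Landau-Zener crossing topology
    (diabatic forces of opposite sign); |G| is then used with a logged
    warning, as the geometric mean of the force magnitudes.
    """
    if D_sq < 0:
        raise ValueError("D_sq must be non-negative")
    if G <= 0:
        global _warned_non_lz
        msg = ("non-LZ crossing topology: mass-scaled force product "
               "G = %.3e <= 0; using |G|")
        if not _warned_non_lz:
            logger.warning(msg + " (further occurrences logged at DEBUG)", G)
            _warned_non_lz = True
        else:
            logger.debug(msg, G)
        G = abs(G)
    if D_sq == 0.0 or G == 0.0:
        # degenerate parallel-force crossing: no localized transition region
        branch = +1 if inputs.Et >= inputs.Ex else -1
        return ZNResult(a_sq=0.0, b_sq=0.0, probability=0.0, branch=branch)
    two_v = 2.0 * inputs.V12
    a_sq = inputs.hbar**2 * math.sqrt(G) * math.sqrt(D_sq) / (2.0 * two_v**3)
    b_sq = (inputs.Et - inputs.Ex) * math.sqrt(D_sq) / (two_v * math.sqrt(G))
    branch = +1 if inputs.Et >= inputs.Ex else -1
    p = zn_probability(a_sq, b_sq, +1)
    return ZNResult(a_sq=a_sq, b_sq=b_sq, probability=p, branch=branch)


def zn_probability(a_sq: float, b_sq: float, branch: int = +1) -> float:
    """Single-passage hop probability from the dimensionless parameters.

    ``branch`` selects the sign s under the inner square root:  +1 is
    the curve-crossing form, valid for signed b^2 of either sign; -1 is
    the nonadiabatic-tunneling form, with sqrt(b^4 - 1) clamped to zero
    for b^4 < 1 and p = 0 whenever the root argument is non-positive.
    """
    if a_sq <= 0:
        raise ValueError("a_sq must be positive")
    if branch not in (+1, -1):
        raise ValueError("branch must be +1 or -1")
    if branch == +1:
        inner = math.sqrt(b_sq * b_sq + 1.0)
    else:
        inner = math.sqrt(max(b_sq * b_sq - 1.0, 0.0))
    denom = b_sq + inner
    if denom <= 0.0:
        return 0.0
    a = math.sqrt(a_sq)
    exponent = -(math.pi / (4.0 * a)) * math.sqrt(2.0 / denom)
    return math.exp(exponent)


def diabatize_crossing(
    before: SurfaceEvaluation,
    at: SurfaceEvaluation,
    after: SurfaceEvaluation,
):
    """Estimate diabatic quantities at a local gap minimum.

    The three evaluations must bracket a strict local minimum of the
    adiabatic gap.  Returns ``(F1_vec, F2_vec, V12, Ex)``: V12 is half
    the minimum adiabatic gap, Ex the mean adiabatic energy there, and
    the diabatic force vectors are obtained by inverting the two-state
    model with locally constant coupling.  Writing dH = H22 - H11 for
    the diabatic splitting, the adiabatic gap is
    sqrt(dH^2 + 4 V12^2), so at each bracketing point

        grad(dH) = gap * grad(gap) / sqrt(gap^2 - 4 V12^2),

    with opposite signs of dH on the two sides of the crossing, while
    the trace obeys grad(H11 + H22) = grad(E_lower) + grad(E_upper)
    exactly.  Averaging the two one-sided grad(dH) estimates and
    combining with the trace gives the diabatic gradients, hence the
    forces.  Unlike a naive swap of the adiabatic gradients across the
    crossing, this inversion stays accurate when the bracketing points
    lie inside the coupling zone (|dH| < 2 V12), and it is exact on the
    linear crossing model at any bracket spacing.
    """
    if not (before.gap > at.gap and after.gap > at.gap):
        raise ValueError(
            "evaluations do not bracket a strict local gap minimum "
            f"(gaps: {before.gap:.3e}, {at.gap:.3e}, {after.gap:.3e})"
        )
    V12 = 0.5 * at.gap
    Ex = 0.5 * float(at.adiabatic_energies.sum())
    trace_grad = at.adiabatic_gradients[0] + at.adiabatic_gradients[1]

    def _ddh(ev: SurfaceEvaluation, side: float) -> np.ndarray:
        dgap = ev.adiabatic_gradients[1] - ev.adiabatic_gradients[0]
        denom_sq = ev.gap**2 - 4.0 * V12**2
        # amplification capped when the bracket sits very close to the
        # gap minimum (denominator -> 0 there)
        factor = ev.gap / math.sqrt(max(denom_sq, (ev.gap / 50.0) ** 2))
        return side * factor * dgap

    ddh = 0.5 * (_ddh(before, -1.0) + _ddh(after, +1.0))
    grad_h11 = 0.5 * (trace_grad - ddh)
    grad_h22 = 0.5 * (trace_grad + ddh)
    F1_vec = -grad_h11
    F2_vec = -grad_h22
    return F1_vec, F2_vec, V12, Ex


class FrustratedHop(Exception):
    """Raised when the kinetic energy along the hopping direction cannot
    pay for an upward hop; the caller must leave the state untouched."""


def hop_adjust_momentum(velocities, masses, direction, deltaE: float):
    """Rescale the velocity component along ``direction`` so that total
    energy is conserved across a surface switch.

    ``deltaE`` is the potential energy released by the hop (positive for
    a downward hop, negative for an upward one).  Solves for the update
    v' = v + gamma * d (velocity change along the unit vector d) such
    that the kinetic-energy change equals +deltaE exactly; of the two
    roots the one with smaller |gamma| (minimal perturbation) is taken.
    Raises :class:`FrustratedHop` if no real solution exists.
    """
    v = np.asarray(velocities, dtype=float).ravel()
    d = np.asarray(direction, dtype=float).ravel()
    m = np.asarray(masses, dtype=float)
    if v.ndim != 1 or v.shape != d.shape:
        raise ValueError("velocities and direction must have matching shapes")
    nrm = np.linalg.norm(d)
    if nrm == 0:
        raise ValueError("hopping direction must be a non-zero vector")
    if abs(nrm - 1.0) > 1e-8:
        d = d / nrm
    m_full = np.repeat(m, v.size // m.size) if m.size != v.size else m
    if deltaE == 0.0:
        return v.copy()
    # KE(gamma) - KE(0) = A gamma^2 + B gamma, with
    A = float(np.sum(0.5 * m_full * d * d))
    B = float(np.sum(m_full * v * d))
    disc = B * B + 4.0 * A * deltaE
    if disc < 0.0:
        raise FrustratedHop(
            f"insufficient kinetic energy along hopping direction: need "
            f"{-deltaE:.6e} Hartree, available {B * B / (4.0 * A):.6e}"
        )
    sq = math.sqrt(disc)
    # root of A g^2 + B g - deltaE = 0 with smaller magnitude
    g1 = (-B + sq) / (2.0 * A)
    g2 = (-B - sq) / (2.0 * A)
    gamma = g1 if abs(g1) <= abs(g2) else g2
    return v + gamma * d


def kinetic_energy_along(velocities, masses, direction) -> float:
    """Kinetic-energy component associated with motion along a unit
    direction: the maximum kinetic energy extractable by a velocity
    change along that direction, B^2 / (4A) in the notation of
    :func:`hop_adjust_momentum`."""
    v = np.asarray(velocities, dtype=float).ravel()
    d = np.asarray(direction, dtype=float).ravel()
    m = np.asarray(masses, dtype=float)
    m_full = np.repeat(m, v.size // m.size) if m.size != v.size else m
    d = d / np.linalg.norm(d)
    A = float(np.sum(0.5 * m_full * d * d))
    B = float(np.sum(m_full * v * d))
    return B * B / (4.0 * A)


def zn_single_passage_probability(
    slope_1: float,
    slope_2: float,
    coupling: float,
    mass: float,
    collision_energy: float,
) -> ZNResult:
    """ZN hop probability for one passage of a linear diabatic crossing.

    ``collision_energy`` is the total energy above the diabatic crossing
    point (Et - Ex).  Convenience wrapper used to compare against the
    exact wavepacket and Landau-Zener oracles.
    """
    F1 = np.array([-slope_1])
    F2 = np.array([-slope_2])
    masses = np.array([mass])
    G = mass_scaled_product(F1, F2, masses)
    D_sq = mass_scaled_difference_sq(F1, F2, masses)
    inputs = ZNInputs(
        F1=float(F1[0]) / math.sqrt(mass),
        F2=float(F2[0]) / math.sqrt(mass),
        V12=coupling,
        Ex=0.0,
        Et=collision_energy,
    )
    return zn_parameters(inputs, G, D_sq)
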