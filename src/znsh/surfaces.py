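"""Two-state potential-energy surfaces.

Two families of surfaces are provided:

* :class:`LinearCrossingModel` -- the textbook linear diabatic crossing
  (two linear diabats coupled by a constant V12).  It has closed-form
  adiabatic energies/gradients and an explicit diabatic Hamiltonian, so
  it serves as the exactly solvable test bed for the semiclassical hop
  machinery and for the grid quantum-dynamics oracle.

* :class:`SurrogateSurface` -- a one-dimensional surrogate of the
  photocyclization of a diarylethene photoswitch along the C1-C6
  ring-closing distance.  The two adiabatic curves (S0, S1) are
  shape-preserving cubics pinned exactly to published multireference
  anchor energies, extended outside the anchored range by harmonic
  walls so that the open-form well sits at r = 3.302 A and the
  closed-form well at r = 1.517 A.  This surface stands in for
  on-the-fly excited-state electronic structure in the dynamics.

All ``evaluate`` calls work in atomic units (Bohr, Hartree); anchor
tables and constructors use the conventional A / kcal/mol units.
"""

from __future__ import annotations

import io
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.interpolate import CubicHermiteSpline, PchipInterpolator

from .units import (
    ANGSTROM_TO_BOHR,
    AMU_TO_ME,
    BOHR_TO_ANGSTROM,
    CM1_TO_AU,
    KCALMOL_TO_HARTREE,
    ev_to_nm,
    nm_to_ev,
)

__all__ = [
    "SurfaceEvaluation",
    "PotentialSurface",
    "LinearCrossingModel",
    "AnchorTable",
    "SurrogateSurface",
    "build_surrogate",
    "load_anchor_table",
    "ev_to_nm",
    "nm_to_ev",
]


@dataclass(frozen=True)
class SurfaceEvaluation:
    """Energies and gradients of both adiabatic states at one geometry.

    Attributes
    ----------
    coordinates : (D,) array, Bohr
    adiabatic_energies : (2,) array, Hartree, ``[E_lower, E_upper]``
    adiabatic_gradients : (2, D) array, Hartree/Bohr
    diabatic_hamiltonian : (2, 2) array or None
        Present only for models defined diabatically.
    """

    coordinates: np.ndarray
    adiabatic_energies: np.ndarray
    adiabatic_gradients: np.ndarray
    diabatic_hamiltonian: Optional[np.ndarray] = None

    @property
    def gap(self) -> float:
        """Adiabatic energy gap E_upper - E_lower (Hartree, >= 0)."""
        return float(self.adiabatic_energies[1] - self.adiabatic_energies[0])


class PotentialSurface(ABC):
    """Contract for a two-state adiabatic potential surface."""

    ndim: int = 1

    @abstractmethod
    def evaluate(self, coordinates) -> SurfaceEvaluation:
        """Return both adiabatic energies and gradients at ``coordinates``."""

    def _coerce(self, coordinates) -> np.ndarray:
        x = np.atleast_1d(np.asarray(coordinates, dtype=float))
        if x.shape != (self.ndim,):
            raise ValueError(
                f"expected {self.ndim} coordinate(s), got shape {x.shape}"
            )
        return x


class LinearCrossingModel(PotentialSurface):
    """Linear diabatic crossing: H11 = s1*x, H22 = s2*x, H12 = V12.

    The diabats cross at the origin.  ``slope_1``/``slope_2`` are the
    diabatic slopes dH_ii/dx in Hartree/Bohr, ``coupling`` the constant
    diabatic coupling in Hartree, ``mass`` the particle mass in electron
    masses.  Slopes of the same sign give the Landau-Zener transmission
    topology (both adiabats monotone); opposite signs give the
    nonadiabatic-tunneling topology (lower adiabat barrier / upper well).
    """

    ndim = 1

    def __init__(self, slope_1: float, slope_2: float, coupling: float, mass: float):
        if coupling <= 0:
            raise ValueError("coupling V12 must be positive")
        if slope_1 == slope_2:
            raise ValueError("slopes must differ to define a crossing")
        if mass <= 0:
            raise ValueError("mass must be positive")
        self.slope_1 = float(slope_1)
        self.slope_2 = float(slope_2)
        self.coupling = float(coupling)
        self.mass = float(mass)

    def diabatic_hamiltonian(self, x: float) -> np.ndarray:
        return np.array(
            [
                [self.slope_1 * x, self.coupling],
                [self.coupling, self.slope_2 * x],
            ]
        )

    def evaluate(self, coordinates) -> SurfaceEvaluation:
        xvec = self._coerce(coordinates)
        x = xvec[0]
        h11 = self.slope_1 * x
        h22 = self.slope_2 * x
        mean = 0.5 * (h11 + h22)
        delta = 0.5 * (h11 - h22)
        rad = np.hypot(delta, self.coupling)
        e_lo, e_up = mean - rad, mean + rad
        dmean = 0.5 * (self.slope_1 + self.slope_2)
        ddelta = 0.5 * (self.slope_1 - self.slope_2)
        # d(rad)/dx = delta * ddelta / rad; rad >= coupling > 0 always
        drad = delta * ddelta / rad
        grads = np.array([[dmean - drad], [dmean + drad]])
        return SurfaceEvaluation(
            coordinates=xvec,
            adiabatic_energies=np.array([e_lo, e_up]),
            adiabatic_gradients=grads,
            diabatic_hamiltonian=self.diabatic_hamiltonian(x),
        )


# ---------------------------------------------------------------------------
# Anchor tables and the 1-D surrogate
# ---------------------------------------------------------------------------

_ANCHOR_FILES = {"scan": "anchors_scan.csv", "reactive": "anchors_reactive.csv"}


@dataclass(frozen=True)
class AnchorTable:
    """Calibration anchors for one surrogate variant.

    Each state carries its own list of (r / A, E / kcal/mol) anchor
    points, energies relative to the open-form ground-state minimum
    (defined as zero of energy).  The two states need not share a common
    r grid: the ground-state reaction path is anchored at the
    transition-state distance (1.945 A) while the excited state is
    anchored at the minimum-gap distance (2.103 A).
    """

    r_s0: np.ndarray  # A, strictly decreasing open -> closed
    e_s0: np.ndarray  # kcal/mol
    r_s1: np.ndarray
    e_s1: np.ndarray
    variant: str = "custom"

    def __post_init__(self):
        for name, r, e in (("S0", self.r_s0, self.e_s0), ("S1", self.r_s1, self.e_s1)):
            r = np.asarray(r, dtype=float)
            e = np.asarray(e, dtype=float)
            if r.shape != e.shape or r.ndim != 1:
                raise ValueError(f"{name}: r and E anchor arrays must match 1-D shapes")
            if len(r) < 3:
                raise ValueError(f"{name}: at least 3 anchor points required, got {len(r)}")
            if not np.all(np.diff(r) < 0):
                raise ValueError(f"{name}: r values must be strictly decreasing (open -> closed)")
            object.__setattr__(self, {"S0": "r_s0", "S1": "r_s1"}[name], r)
            object.__setattr__(self, {"S0": "e_s0", "S1": "e_s1"}[name], e)

    # -- tabular I/O -------------------------------------------------------
    @classmethod
    def from_csv(cls, path_or_buffer, variant: str = "custom") -> "AnchorTable":
        """Read anchors from a CSV with columns r_angstrom, e_s0_kcalmol,
        e_s1_kcalmol; empty energy cells mean "no anchor for this state
        at this r"."""
        import pandas as pd

        df = pd.read_csv(path_or_buffer)
        required = {"r_angstrom", "e_s0_kcalmol", "e_s1_kcalmol"}
        if not required.issubset(df.columns):
            raise ValueError(f"anchor CSV must have columns {sorted(required)}")
        m0 = df["e_s0_kcalmol"].notna()
        m1 = df["e_s1_kcalmol"].notna()
        return cls(
            r_s0=df.loc[m0, "r_angstrom"].to_numpy(float),
            e_s0=df.loc[m0, "e_s0_kcalmol"].to_numpy(float),
            r_s1=df.loc[m1, "r_angstrom"].to_numpy(float),
            e_s1=df.loc[m1, "e_s1_kcalmol"].to_numpy(float),
            variant=variant,
        )

    def to_csv(self, path) -> None:
        import pandas as pd

        rs = np.unique(np.concatenate([self.r_s0, self.r_s1]))[::-1]
        s0 = {r: e for r, e in zip(self.r_s0, self.e_s0)}
        s1 = {r: e for r, e in zip(self.r_s1, self.e_s1)}
        df = pd.DataFrame(
            {
                "r_angstrom": rs,
                "e_s0_kcalmol": [s0.get(r, np.nan) for r in rs],
                "e_s1_kcalmol": [s1.get(r, np.nan) for r in rs],
            }
        )
        df.to_csv(path, index=False)


def load_anchor_table(variant: str = "reactive") -> AnchorTable:
    """Load one of the packaged anchor tables (``scan`` or ``reactive``).

    ``scan``: the published relaxed-scan profile along C1-C6 -- S1 falls
    73.0 -> 45.6 kcal/mol reaching the minimum-gap point at 2.103 A
    while S0 rises 34.4 -> 44.0, then S1 52.0 / S0 18.9 at the closed
    form.  ``reactive``: the ground-state reaction path (open form 0.0,
    barrier 40.8 at 1.945 A, closed form -5.6) under the same S1 curve;
    its S0 supports both wells and is the default for full dynamics.
    """
    if variant not in _ANCHOR_FILES:
        raise ValueError(f"unknown anchor variant {variant!r}; choose from {sorted(_ANCHOR_FILES)}")
    text = resources.files("znsh.data").joinpath(_ANCHOR_FILES[variant]).read_text()
    return AnchorTable.from_csv(io.StringIO(text), variant=variant)


class _StateCurve:
    """One adiabatic curve: pinned cubic through anchors + harmonic walls.

    Interior slopes follow the monotone shape-preserving (PCHIP) rule so
    the curve cannot oscillate between anchors; the two end slopes are
    forced to zero so the harmonic extensions place genuine minima at
    the terminal anchors (open well at 3.302 A, closed well at 1.517 A
    for the packaged tables).
    """

    def __init__(self, r_ang: np.ndarray, e_kcal: np.ndarray, k_inner: float, k_outer: float):
        # ascending x in Bohr, energies in Hartree
        x = (r_ang * ANGSTROM_TO_BOHR)[::-1].copy()
        y = (e_kcal * KCALMOL_TO_HARTREE)[::-1].copy()
        slopes = PchipInterpolator(x, y).derivative()(x)
        slopes[0] = 0.0
        slopes[-1] = 0.0
        self.x = x
        self.y = y
        self.spline = CubicHermiteSpline(x, y, slopes)
        self.dspline = self.spline.derivative()
        self.k_inner = k_inner  # wall curvature for r < x[0] (closed side)
        self.k_outer = k_outer  # wall curvature for r > x[-1] (open side)

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        lo, hi = self.x[0], self.x[-1]
        inner = self.y[0] + 0.5 * self.k_inner * (x - lo) ** 2
        outer = self.y[-1] + 0.5 * self.k_outer * (x - hi) ** 2
        mid = self.spline(np.clip(x, lo, hi))
        return np.where(x < lo, inner, np.where(x > hi, outer, mid))

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        lo, hi = self.x[0], self.x[-1]
        inner = self.k_inner * (x - lo)
        outer = self.k_outer * (x - hi)
        mid = self.dspline(np.clip(x, lo, hi))
        return np.where(x < lo, inner, np.where(x > hi, outer, mid))


class SurrogateSurface(PotentialSurface):
    """1-D two-state surrogate built from an :class:`AnchorTable`.

    Use :func:`build_surrogate`; do not construct directly.
    """

    ndim = 1

    def __init__(self, lower: _StateCurve, upper: _StateCurve, gap_floor: float,
                 mass: float, domain: tuple, anchors: AnchorTable):
        self._lower = lower
        self._upper = upper
        self.gap_floor = gap_floor  # Hartree
        self.mass = mass  # electron masses
        self.domain = domain  # (x_min, x_max) Bohr
        self.anchors = anchors

    @property
    def domain_angstrom(self) -> tuple:
        return (self.domain[0] * BOHR_TO_ANGSTROM, self.domain[1] * BOHR_TO_ANGSTROM)

    def evaluate(self, coordinates) -> SurfaceEvaluation:
        xvec = self._coerce(coordinates)
        x = xvec[0]
        if not (self.domain[0] <= x <= self.domain[1]):
            lo, hi = self.domain_angstrom
            raise ValueError(
                f"coordinate r = {x * BOHR_TO_ANGSTROM:.4f} A outside the "
                f"surrogate domain [{lo:.3f}, {hi:.3f}] A"
            )
        e_lo = float(self._lower.energy(x))
        e_up = float(self._upper.energy(x))
        g_lo = float(self._lower.gradient(x))
        g_up = float(self._upper.gradient(x))
        if e_up - e_lo < self.gap_floor:
            # minimum-gap regularization: the upper curve rides the lower
            # one at fixed separation wherever the raw curves pinch closer
            # than gap_floor (never active at an anchor by construction)
            e_up = e_lo + self.gap_floor
            g_up = g_lo
        return SurfaceEvaluation(
            coordinates=xvec,
            adiabatic_energies=np.array([e_lo, e_up]),
            adiabatic_gradients=np.array([[g_lo], [g_up]]),
        )

    def minimum_gap(self, n_scan: int = 4001) -> tuple:
        """Locate the minimum adiabatic gap by dense scan + parabolic refine.

        Returns (r_angstrom, gap_hartree).
        """
        lo = self.anchors.r_s0.min() * ANGSTROM_TO_BOHR
        hi = self.anchors.r_s0.max() * ANGSTROM_TO_BOHR
        xs = np.linspace(lo, hi, n_scan)
        gaps = np.maximum(
            self._upper.energy(xs) - self._lower.energy(xs), self.gap_floor
        )
        k = int(np.argmin(gaps))
        x_best = xs[k]
        if 0 < k < n_scan - 1:
            y0, y1, y2 = gaps[k - 1], gaps[k], gaps[k + 2 - 1]
            denom = y0 - 2 * y1 + y2
            if denom > 0:
                x_best = xs[k] + 0.5 * (y0 - y2) / denom * (xs[1] - xs[0])
        gap = float(self._upper.energy(x_best) - self._lower.energy(x_best))
        gap = max(gap, self.gap_floor)
        return (float(x_best) * BOHR_TO_ANGSTROM, gap)


def build_surrogate(
    anchors: AnchorTable,
    gap_floor_kcalmol: float = 1.0,
    mass_amu: float = 6.0,
    open_wall_cm1: float = 300.0,
    closed_wall_cm1: float = 1000.0,
    domain_padding_angstrom: tuple = (0.9, 3.5),
) -> SurrogateSurface:
    """Construct the 1-D two-state surrogate surface from anchor points.

    Parameters
    ----------
    anchors : AnchorTable
        Calibration anchors; each adiabatic curve passes through its
        anchors exactly.
    gap_floor_kcalmol : float
        Minimum adiabatic S1-S0 separation imposed wherever the
        interpolated curves pinch closer (keeps the adiabatic
        representation non-degenerate near the intersection).
    mass_amu : float
        Effective mass of the 1-D ring-closing coordinate, amu.
    open_wall_cm1, closed_wall_cm1 : float
        Harmonic-wall frequencies (for this mass) beyond the open-side
        and closed-side terminal anchors.  The open-side value sets the
        vibrational frequency of the reactant well used for Wigner
        sampling; the closed-side wall is stiffer, emulating C-C bond
        compression.
    """
    if gap_floor_kcalmol <= 0:
        raise ValueError("gap_floor must be positive")
    if mass_amu <= 0:
        raise ValueError("mass must be positive")
    mass = mass_amu * AMU_TO_ME
    k_outer = mass * (open_wall_cm1 * CM1_TO_AU) ** 2
    k_inner = mass * (closed_wall_cm1 * CM1_TO_AU) ** 2
    lower = _StateCurve(anchors.r_s0, anchors.e_s0, k_inner, k_outer)
    upper = _StateCurve(anchors.r_s1, anchors.e_s1, k_inner, k_outer)
    gap_floor = gap_floor_kcalmol * KCALMOL_TO_HARTREE

    # Regularizability check: the floor may never bind at an anchor of
    # either state, else the exact calibration would be destroyed.
    r_all = np.unique(np.concatenate([anchors.r_s0, anchors.r_s1]))
    x_all = r_all * ANGSTROM_TO_BOHR
    raw_gap = upper.energy(x_all) - lower.energy(x_all)
    bad = raw_gap < gap_floor
    if np.any(bad):
        worst = r_all[bad]
        raise ValueError(
            "interpolated S1-S0 gap falls below gap_floor at anchor "
            f"geometries r = {np.round(worst, 3).tolist()} A; this crossing "
            "cannot be regularized without breaking the anchor calibration -- "
            "lower gap_floor or revise the anchors"
        )

    lo_dom = (min(anchors.r_s0.min(), anchors.r_s1.min()) - domain_padding_angstrom[0])
    hi_dom = (max(anchors.r_s0.max(), anchors.r_s1.max()) + domain_padding_angstrom[1])
    if lo_dom <= 0:
        lo_dom = 0.05
    domain = (lo_dom * ANGSTROM_TO_BOHR, hi_dom * ANGSTROM_TO_BOHR)
    return SurrogateSurface(lower, upper, gap_floor, mass, domain, anchors)
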