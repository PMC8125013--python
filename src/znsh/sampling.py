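"""Wigner sampling of initial conditions.

Initial nuclear coordinates and velocities are drawn from the Wigner
distribution of the ground vibrational state of a harmonic mode,

    W(x, p) ∝ exp(-(x - x0)^2 / (2 sigma_x^2)) exp(-p^2 / (2 sigma_p^2)),

with sigma_x = sqrt(hbar / (2 mu omega)) and sigma_p = sqrt(hbar mu omega / 2),
i.e. a product of independent Gaussians saturating the minimum
uncertainty product sigma_x sigma_p = hbar/2.  The mode parameters are
extracted from the curvature of a potential surface at a local minimum.
Only the 0 K ground-state distribution is implemented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .units import AU_TO_CM1
from .surfaces import PotentialSurface

__all__ = ["HarmonicMode", "mode_from_curvature", "wigner_sample"]


@dataclass(frozen=True)
class HarmonicMode:
    """A 1-D harmonic vibrational mode (atomic units)."""

    equilibrium_position: float  # Bohr
    frequency: float  # angular frequency, a.u.
    mass: float  # electron masses

    def __post_init__(self):
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.mass <= 0:
            raise ValueError("mass must be positive")

    @property
    def frequency_cm1(self) -> float:
        return self.frequency * AU_TO_CM1

    @property
    def sigma_x(self) -> float:
        """Ground-state Wigner position width sqrt(hbar/(2 mu omega))."""
        return float(np.sqrt(0.5 / (self.mass * self.frequency)))

    @property
    def sigma_p(self) -> float:
        """Ground-state Wigner momentum width sqrt(hbar mu omega/2)."""
        return float(np.sqrt(0.5 * self.mass * self.frequency))


def mode_from_curvature(
    surface: PotentialSurface,
    state: str,
    minimum_guess: float,
    mass: float,
    search_half_width: float = 0.8,
    fd_step: float = 1.0e-3,
    grad_tol: float = 1.0e-8,
) -> HarmonicMode:
    """Build a :class:`HarmonicMode` from the curvature of one adiabatic state.

    Locates the local minimum of the chosen state (``"lower"`` or
    ``"upper"``) within ``minimum_guess ± search_half_width`` (Bohr),
    requires the gradient there to vanish below ``grad_tol``
    Hartree/Bohr, and sets omega = sqrt(k/mu) with k the central
    finite-difference second derivative at step ``fd_step`` Bohr.
    """
    idx = {"lower": 0, "upper": 1}.get(state)
    if idx is None:
        raise ValueError("state must be 'lower' or 'upper'")
    if mass <= 0:
        raise ValueError("mass must be positive")

    def energy(x: float) -> float:
        return float(surface.evaluate([x]).adiabatic_energies[idx])

    res = minimize_scalar(
        energy,
        bounds=(minimum_guess - search_half_width, minimum_guess + search_half_width),
        method="bounded",
        options={"xatol": 1e-12},
    )
    x0 = float(res.x)
    grad = float(surface.evaluate([x0]).adiabatic_gradients[idx, 0])
    if abs(grad) > grad_tol:
        raise ValueError(
            f"no stationary point found near {minimum_guess:.4f} Bohr "
            f"(|gradient| = {abs(grad):.2e} Hartree/Bohr at candidate minimum)"
        )
    k = (energy(x0 + fd_step) - 2.0 * energy(x0) + energy(x0 - fd_step)) / fd_step**2
    if k <= 0:
        raise ValueError(
            f"non-positive curvature k = {k:.3e} at x = {x0:.4f} Bohr; "
            "not a harmonic minimum"
        )
    return HarmonicMode(
        equilibrium_position=x0, frequency=float(np.sqrt(k / mass)), mass=mass
    )


def wigner_sample(mode: HarmonicMode, n: int, seed) -> np.ndarray:
    """Draw ``n`` (position, momentum) pairs from the ground-state Wigner
    density of ``mode``.

    Returns an (n, 2) array in atomic units; column 0 positions, column
    1 momenta.  ``seed`` may be an int, a SeedSequence or a Generator;
    the same seed always reproduces the same draws.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    x = rng.normal(mode.equilibrium_position, mode.sigma_x, size=n)
    p = rng.normal(0.0, mode.sigma_p, size=n)
    return np.column_stack([x, p])


def samples_to_csv(samples: np.ndarray, path) -> None:
    """Export an initial-condition set as CSV (index, position_angstrom,
    momentum_au)."""
    import pandas as pd

    from .units import BOHR_TO_ANGSTROM

    df = pd.DataFrame(
        {
            "index": np.arange(len(samples)),
            "position_angstrom": samples[:, 0] * BOHR_TO_ANGSTROM,
            "momentum_au": samples[:, 1],
        }
    )
    df.to_csv(path, index=False)


def samples_from_csv(path) -> np.ndarray:
    """Read back an initial-condition CSV written by :func:`samples_to_csv`."""
    import pandas as pd

    from .units import ANGSTROM_TO_BOHR

    df = pd.read_csv(path)
    return np.column_stack(
        [df["position_angstrom"].to_numpy(float) * ANGSTROM_TO_BOHR,
         df["momentum_au"].to_numpy(float)]
    )
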