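"""Brownian diffusion of labeled molecules in a periodic simulation box.

Hydrodynamic radii map to diffusion coefficients through the Stokes-Einstein
relation D = kB*T / (6*pi*eta*R).  Molecules perform independent 3D random
walks: each coordinate increments by a zero-mean Gaussian of standard
deviation L = sqrt(2*D*dt) per step, which yields MSD(tau) = 6*D*tau in 3D
and MSD(tau) = 6*(f1*D1 + f2*D2)*tau for a molecule switching between two
states with occupancies f1, f2.  The box volume is set by the concentration,
V = N/(c*N_A), with periodic wrapping; the box shares the axial aspect ratio
``a`` of the detection volume so the long axis is along the optical axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import constants

__all__ = [
    "DEFAULT_TEMPERATURE",
    "DEFAULT_VISCOSITY",
    "MoleculeSpec",
    "SimulationBox",
    "diffusion_coefficient",
    "box_from_concentration",
    "step_scale",
    "simulate_positions",
    "wrap_positions",
]

DEFAULT_TEMPERATURE = 293.15  # K
DEFAULT_VISCOSITY = 1.0e-3  # Pa*s, water at ~20 C

LABEL_CONFIGS = ("both", "donor_only", "acceptor_only")


@dataclass(frozen=True)
class MoleculeSpec:
    """Per-state hydrodynamic radii (m) and FRET efficiencies of a species."""

    radius_per_state: tuple[float, float]
    fret_per_state: tuple[float, float] = (0.0, 0.0)
    label_config: str = "both"

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radius_per_state):
            raise ValueError("radii must be positive")
        if any(not 0 <= e <= 1 for e in self.fret_per_state):
            raise ValueError("FRET efficiencies must lie in [0, 1]")
        if self.label_config not in LABEL_CONFIGS:
            raise ValueError(f"label_config must be one of {LABEL_CONFIGS}")

    @property
    def effective_fret(self) -> tuple[float, float]:
        """FRET per state as seen in emission: zero without an acceptor."""
        if self.label_config == "donor_only":
            return (0.0, 0.0)
        return self.fret_per_state


@dataclass(frozen=True)
class SimulationBox:
    """Periodic box holding ``n_molecules`` at a given concentration.

    The volume is V = N/(c*N_A).  Side lengths are rx = ry = r0 and
    rz = a*r0 with r0 = (V/a)^(1/3) (so rx*ry*rz = V exactly), elongated
    along the optical axis like the detection volume; the box is centred on
    the beam, spanning [-r0/2, r0/2) laterally.
    """

    n_molecules: int
    concentration: float  # mol/m^3
    aspect: float
    temperature: float = DEFAULT_TEMPERATURE
    viscosity: float = DEFAULT_VISCOSITY

    @property
    def volume(self) -> float:
        return self.n_molecules / (self.concentration * constants.N_A)

    @property
    def r0(self) -> float:
        return (self.volume / self.aspect) ** (1.0 / 3.0)

    @property
    def half_widths(self) -> np.ndarray:
        r0 = self.r0
        return 0.5 * np.array([r0, r0, self.aspect * r0])

    def sample_positions(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform initial positions, shape (n, 3)."""
        hw = self.half_widths
        return rng.uniform(-hw, hw, size=(n, 3))


def diffusion_coefficient(
    radius: float,
    temperature: float = DEFAULT_TEMPERATURE,
    viscosity: float = DEFAULT_VISCOSITY,
) -> float:
    """Stokes-Einstein diffusion coefficient, m^2/s."""
    if radius <= 0 or temperature <= 0 or viscosity <= 0:
        raise ValueError("radius, temperature and viscosity must be positive")
    return constants.k * temperature / (6.0 * np.pi * viscosity * radius)


def box_from_concentration(
    n_molecules: int,
    concentration: float,
    aspect: float,
    temperature: float = DEFAULT_TEMPERATURE,
    viscosity: float = DEFAULT_VISCOSITY,
) -> SimulationBox:
    """Box with V = N/(c*N_A), r0 = (V/a)^(1/3) and rz = a*r0."""
    if n_molecules < 1:
        raise ValueError("need at least one molecule")
    if concentration <= 0 or aspect <= 0:
        raise ValueError("concentration and aspect must be positive")
    return SimulationBox(n_molecules, concentration, aspect, temperature, viscosity)


def step_scale(D: float, dt: float) -> float:
    """Per-axis standard deviation of a displacement step, L = sqrt(2*D*dt)."""
    if D < 0 or dt < 0:
        raise ValueError("D and dt must be non-negative")
    return float(np.sqrt(2.0 * D * dt))


def wrap_positions(positions: np.ndarray, half_widths: np.ndarray) -> np.ndarray:
    """Periodic wrap of coordinates into [-half_width, half_width)."""
    span = 2.0 * half_widths
    return (positions + half_widths) % span - half_widths


def simulate_positions(
    box: SimulationBox,
    D_per_step: np.ndarray,
    dt: float,
    rng: np.random.Generator,
    initial: np.ndarray | None = None,
    wrap: bool = True,
) -> np.ndarray:
    """Random-walk positions for one molecule, shape (n_steps + 1, 3).

    ``D_per_step`` gives the diffusion coefficient in force at the start of
    each step (state changes within a step use the state at its start).  Set
    ``wrap=False`` to obtain the unwrapped walk for displacement statistics.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    D_per_step = np.asarray(D_per_step, dtype=float)
    n_steps = D_per_step.size
    if initial is None:
        initial = box.sample_positions(1, rng)[0]
    sigma = np.sqrt(2.0 * D_per_step * dt)
    increments = rng.standard_normal((n_steps, 3)) * sigma[:, None]
    positions = np.empty((n_steps + 1, 3))
    positions[0] = initial
    np.cumsum(increments, axis=0, out=positions[1:])
    positions[1:] += initial
    if wrap:
        positions = wrap_positions(positions, box.half_widths)
    return positions
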