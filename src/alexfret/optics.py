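"""Excitation geometry, ALEX timing, and expected per-channel photon rates.

The confocal excitation/detection profile is a 3D Gaussian with lateral waist
omega_xy = lambda/(2*NA) and axial extent omega_z = a*omega_xy, truncated by
the pinhole: fluorescence is rejected when the molecule's lateral distance
from the beam axis exceeds d_pinhole/(2*M).  Alternating laser excitation
(ALEX) switches between the 514 nm donor laser and the 632 nm acceptor laser
with 400 ns pulses separated by 100 ns gaps (1 us period), so each detected
photon can be tagged with both its emission color and its excitation
wavelength.

Expected detection rates per channel for a molecule with FRET efficiency E at
relative PSF intensity g:

* donor laser on:  D514 = I0_D*(1-E)*g;  A514 = I0_D*(E + alpha*(1-E) + delta)*g
  (FRET and direct-excitation terms only when an acceptor label is present;
  the leakage term alpha*(1-E) is donor emission bleeding into the acceptor
  detector, present whenever a donor label is present)
* acceptor laser on:  A632 = I0_A*g (acceptor label present); D632 = 0.

A flat background ``I_bg`` adds to each detection channel while its detector
is gated (photons arriving in the 100 ns gaps are discarded so every photon
carries an unambiguous excitation label).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OpticsConfig",
    "ALEXPattern",
    "CHANNELS",
    "psf_value",
    "alex_state",
    "channel_rates",
    "effective_volume",
]

#: detection channels: (emission, excitation)
CHANNELS = ("D514", "A514", "D632", "A632")

OFF, DONOR_ON, ACCEPTOR_ON = 0, 1, 2


@dataclass(frozen=True)
class ALEXPattern:
    """Donor-first alternating excitation: on for t_on, off for t_gap, twice."""

    t_on: float = 400e-9
    t_gap: float = 100e-9

    @property
    def period(self) -> float:
        return 2.0 * (self.t_on + self.t_gap)

    @property
    def duty(self) -> float:
        """Fraction of time each laser is on."""
        return self.t_on / self.period


@dataclass(frozen=True)
class OpticsConfig:
    """Optical configuration (SI units throughout)."""

    lambda_donor: float = 514e-9
    lambda_acceptor: float = 632e-9
    numerical_aperture: float = 1.2
    aspect: float = 8.0  # axial asymmetry of the PSF
    magnification: float = 60.0
    d_pinhole: float = 50e-6
    I0_donor: float = 150e3  # peak detected rate under donor excitation, Hz
    I0_acceptor: float = 100e3  # peak detected rate under acceptor excitation, Hz
    I_bg: float = 1000.0  # background rate per detection channel, Hz
    alpha: float = 0.0  # donor->acceptor spectral leakage fraction
    beta: float = 1.0  # relative acceptor/donor brightness
    delta_dir: float = 0.0  # direct acceptor excitation by the donor laser
    beam_center_donor: tuple[float, float, float] = (0.0, 0.0, 0.0)
    beam_center_acceptor: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not (0 <= self.alpha < 1 and 0 <= self.delta_dir < 1):
            raise ValueError("alpha and delta_dir must lie in [0, 1)")
        if self.beta <= 0:
            raise ValueError("beta must be positive")

    @property
    def omega_xy(self) -> float:
        """Lateral beam waist lambda/(2*NA) of the donor laser, m."""
        return self.lambda_donor / (2.0 * self.numerical_aperture)

    @property
    def omega_z(self) -> float:
        return self.aspect * self.omega_xy

    @property
    def v_eff(self) -> float:
        return effective_volume(self.omega_xy, self.aspect)

    @property
    def pinhole_radius_sample(self) -> float:
        """Pinhole radius projected into the sample plane, d/(2*M)."""
        return self.d_pinhole / (2.0 * self.magnification)


def effective_volume(omega_xy: float, aspect: float) -> float:
    """Effective detection volume pi^(3/2) * omega_xy^3 * a, m^3."""
    if omega_xy <= 0 or aspect <= 0:
        raise ValueError("omega_xy and aspect must be positive")
    return np.pi ** 1.5 * omega_xy**3 * aspect


def psf_value(
    position: np.ndarray,
    center: np.ndarray | tuple[float, float, float],
    omega_xy: float,
    aspect: float,
    pinhole_radius: float | None = None,
) -> np.ndarray | float:
    """Relative excitation/detection intensity in [0, 1] at ``position``.

    ``position`` has shape (..., 3).  Returns 0 outside the pinhole's lateral
    acceptance radius (if given).
    """
    if omega_xy <= 0:
        raise ValueError("omega_xy must be positive")
    pos = np.asarray(position, dtype=float)
    delta = pos - np.asarray(center, dtype=float)
    r2_lat = delta[..., 0] ** 2 + delta[..., 1] ** 2
    arg = (r2_lat + delta[..., 2] ** 2 / aspect**2) / (2.0 * omega_xy**2)
    g = np.exp(-arg)
    if pinhole_radius is not None:
        g = np.where(r2_lat < pinhole_radius**2, g, 0.0)
    if pos.ndim == 1:
        return float(g)
    return g


def alex_state(t: np.ndarray | float, pattern: ALEXPattern) -> np.ndarray | int:
    """Excitation state at time t: DONOR_ON (1), ACCEPTOR_ON (2) or OFF (0)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    phase = np.mod(t_arr, pattern.period)
    half = pattern.t_on + pattern.t_gap
    state = np.zeros(t_arr.shape, dtype=np.int8)
    state[np.logical_and(phase >= 0, phase < pattern.t_on)] = DONOR_ON
    state[np.logical_and(phase >= half, phase < half + pattern.t_on)] = ACCEPTOR_ON
    if np.isscalar(t) or t_arr.ndim == 0:
        return int(state)
    return state


def channel_rates(
    fret: float,
    label_config: str,
    g: np.ndarray | float,
    excitation: int,
    optics: OpticsConfig,
    include_background: bool = False,
) -> dict[str, np.ndarray | float]:
    """Expected detection rate (Hz) per channel for PSF intensity ``g``.

    ``excitation`` is DONOR_ON, ACCEPTOR_ON or OFF.  Background, when
    requested, is added to the two detection channels gated for the active
    laser.  Rates honor the molecule's labels: a missing acceptor kills FRET,
    direct excitation and 632 nm emission; a missing donor kills all
    donor-channel signal and leakage.
    """
    if label_config not in ("both", "donor_only", "acceptor_only"):
        raise ValueError(f"unknown label_config {label_config!r}")
    has_donor = label_config in ("both", "donor_only")
    has_acceptor = label_config in ("both", "acceptor_only")
    E = fret if has_acceptor else 0.0

    zero = np.zeros_like(np.asarray(g, dtype=float))
    rates = {ch: zero.copy() for ch in CHANNELS}
    if excitation == DONOR_ON:
        if has_donor:
            rates["D514"] = optics.I0_donor * (1.0 - E) * g
            rates["A514"] = optics.I0_donor * (optics.alpha * (1.0 - E)) * g
        if has_acceptor:
            fret_term = optics.I0_donor * E * g if has_donor else 0.0
            rates["A514"] = rates["A514"] + fret_term + (
                optics.I0_donor * optics.delta_dir * g
            )
        if include_background:
            rates["D514"] = rates["D514"] + optics.I_bg
            rates["A514"] = rates["A514"] + optics.I_bg
    elif excitation == ACCEPTOR_ON:
        if has_acceptor:
            rates["A632"] = optics.I0_acceptor * g
        if include_background:
            rates["D632"] = rates["D632"] + optics.I_bg
            rates["A632"] = rates["A632"] + optics.I_bg
    elif excitation != OFF:
        raise ValueError(f"unknown excitation state {excitation!r}")
    if np.isscalar(g):
        rates = {ch: float(v) for ch, v in rates.items()}
    return rates
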