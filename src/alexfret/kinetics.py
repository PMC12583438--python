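"""Two-state Markov model of conformational dynamics.

A molecule hops between two conformational states on a free-energy landscape
described by the energy difference ``delta_G`` (state 1 below state 2) and the
barrier ``delta_G_dagger`` seen from state 2, both in units of kBT.  Arrhenius
kinetics with attempt rate ``ks`` give the transition rates

    k12 = ks * exp(-(delta_G + delta_G_dagger))
    k21 = ks * exp(-delta_G_dagger)

so that the equilibrium constant is K = k21/k12 = exp(delta_G) exactly and the
state lifetimes are tau1 = 1/k12, tau2 = 1/k21.  The kinetic relaxation time
tau_K = 1/(k12 + k21) is the decay time of conformational-exchange
contributions to correlation functions.

Trajectories are stored as transition-event lists (memory-efficient for long
runs) and expanded to regular grids only when needed downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TwoStateModel",
    "StateTrajectory",
    "rates_from_energies",
    "energies_from_lifetimes",
    "lifetimes_and_K",
    "transition_matrix",
    "sample_initial_state",
    "simulate_state_trajectory",
    "default_state_step",
]

#: attempt (pre-exponential) rate, s^-1
DEFAULT_KS = 1.0e6


def rates_from_energies(
    delta_G: float, delta_G_dagger: float, ks: float = DEFAULT_KS
) -> tuple[float, float]:
    """Arrhenius transition rates (k12, k21) in s^-1 from energies in kBT."""
    if not ks > 0:
        raise ValueError("attempt rate ks must be positive")
    if not (math.isfinite(delta_G) and math.isfinite(delta_G_dagger)):
        raise ValueError("energies must be finite")
    k12 = ks * math.exp(-(delta_G + delta_G_dagger))
    k21 = ks * math.exp(-delta_G_dagger)
    return k12, k21


def energies_from_lifetimes(
    tau1: float, tau2: float, ks: float = DEFAULT_KS
) -> tuple[float, float]:
    """Invert the Arrhenius relations: lifetimes (s) -> (G_barrier, delta_G).

    G_barrier = ln(ks*tau1) and delta_G_dagger = ln(ks*tau2), both in kBT;
    delta_G = G_barrier - delta_G_dagger.  Exact inverse of
    :func:`rates_from_energies` composed with :func:`lifetimes_and_K`.
    """
    if tau1 <= 0 or tau2 <= 0:
        raise ValueError("lifetimes must be positive")
    if ks <= 0:
        raise ValueError("attempt rate ks must be positive")
    g_barrier = math.log(ks * tau1)
    delta_g_dagger = math.log(ks * tau2)
    return g_barrier, g_barrier - delta_g_dagger


def lifetimes_and_K(k12: float, k21: float) -> tuple[float, float, float, float]:
    """Return (tau1, tau2, K, tau_K) from the transition rates."""
    if k12 <= 0 or k21 <= 0:
        raise ValueError("transition rates must be positive")
    return 1.0 / k12, 1.0 / k21, k21 / k12, 1.0 / (k12 + k21)


def transition_matrix(
    k12: float, k21: float, dt: float, mode: str = "propagator"
) -> np.ndarray:
    """2x2 state-transition probability matrix over a time step ``dt``.

    ``mode="propagator"`` (default) is the exact two-state propagator, the
    matrix exponential of the rate matrix times dt:

        P12(dt) = k12/(k12+k21) * (1 - exp(-(k12+k21) dt))

    which accounts for any number of intermediate transitions and satisfies
    the semigroup property P(dt) @ P(dt') = P(dt+dt').  ``mode="literal"``
    evaluates P12 = k12*dt*exp(-k12*dt) instead (a first-order form that
    agrees with the propagator when k*dt << 1).
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    if mode == "propagator":
        ksum = k12 + k21
        decay = -math.expm1(-ksum * dt)  # 1 - exp(-ksum*dt)
        p12 = k12 / ksum * decay
        p21 = k21 / ksum * decay
    elif mode == "literal":
        p12 = min(k12 * dt * math.exp(-k12 * dt), 1.0)
        p21 = min(k21 * dt * math.exp(-k21 * dt), 1.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return np.array([[1.0 - p12, p12], [p21, 1.0 - p21]])


def sample_initial_state(k12: float, k21: float, rng: np.random.Generator) -> int:
    """Draw the initial state (1 or 2) from the stationary distribution.

    P(state 1) = k21/(k12+k21) = K/(1+K).
    """
    if k12 <= 0 or k21 <= 0:
        raise ValueError("transition rates must be positive")
    p1 = k21 / (k12 + k21)
    return 1 if rng.random() < p1 else 2


def default_state_step(g_barrier: float) -> float:
    """State-propagation step: 100 ns, relaxed to 10 us for barriers > 3 kBT."""
    return 1.0e-7 if g_barrier <= 3.0 else 1.0e-5


@dataclass(frozen=True)
class TwoStateModel:
    """Free-energy landscape of a two-state molecule (energies in kBT)."""

    delta_G: float
    delta_G_dagger: float
    ks: float = DEFAULT_KS

    def __post_init__(self) -> None:
        rates_from_energies(self.delta_G, self.delta_G_dagger, self.ks)

    @classmethod
    def from_barrier(
        cls, g_barrier: float, delta_G: float, ks: float = DEFAULT_KS
    ) -> "TwoStateModel":
        """Build from total barrier height G_barrier = delta_G + delta_G_dagger."""
        return cls(delta_G, g_barrier - delta_G, ks)

    @classmethod
    def from_lifetimes(
        cls, tau1: float, tau2: float, ks: float = DEFAULT_KS
    ) -> "TwoStateModel":
        g_barrier, delta_g = energies_from_lifetimes(tau1, tau2, ks)
        return cls.from_barrier(g_barrier, delta_g, ks)

    @property
    def G_barrier(self) -> float:
        return self.delta_G + self.delta_G_dagger

    @property
    def k12(self) -> float:
        return rates_from_energies(self.delta_G, self.delta_G_dagger, self.ks)[0]

    @property
    def k21(self) -> float:
        return rates_from_energies(self.delta_G, self.delta_G_dagger, self.ks)[1]

    @property
    def tau1(self) -> float:
        return 1.0 / self.k12

    @property
    def tau2(self) -> float:
        return 1.0 / self.k21

    @property
    def K(self) -> float:
        return self.k21 / self.k12

    @property
    def tau_K(self) -> float:
        return 1.0 / (self.k12 + self.k21)

    @property
    def occupancy1(self) -> float:
        """Stationary occupancy of state 1, K/(1+K)."""
        return self.K / (1.0 + self.K)


@dataclass
class StateTrajectory:
    """Event-list representation of a two-state trajectory on a regular grid.

    ``switch_steps`` holds the step indices at which the state flips (state
    applies from that step onward); states alternate starting from
    ``initial_state``.  The grid has ``n_steps`` steps of ``dt_state`` seconds.
    """

    initial_state: int
    switch_steps: np.ndarray  # int64, strictly increasing, in (0, n_steps)
    n_steps: int
    dt_state: float

    @property
    def duration(self) -> float:
        return self.n_steps * self.dt_state

    def states_per_step(self) -> np.ndarray:
        """Expand to an int8 array of the state (1 or 2) at every step."""
        states = np.empty(self.n_steps, dtype=np.int8)
        bounds = np.concatenate(([0], self.switch_steps, [self.n_steps]))
        s = self.initial_state
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            states[lo:hi] = s
            s = 3 - s
        return states

    def dwell_times(self) -> tuple[np.ndarray, np.ndarray]:
        """Completed dwell times (s) in state 1 and state 2 (edges excluded)."""
        bounds = np.concatenate(([0], self.switch_steps, [self.n_steps]))
        lengths = np.diff(bounds)[1:-1] * self.dt_state  # completed dwells only
        first_complete_state = 3 - self.initial_state
        in_state1 = (
            np.arange(lengths.size) % 2 == (0 if first_complete_state == 1 else 1)
        )
        return lengths[in_state1], lengths[~in_state1]

    def segments(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(start_step, end_step, state) for each constant-state segment."""
        bounds = np.concatenate(([0], self.switch_steps, [self.n_steps]))
        n_seg = bounds.size - 1
        states = np.empty(n_seg, dtype=np.int8)
        states[0::2] = self.initial_state
        states[1::2] = 3 - self.initial_state
        return bounds[:-1], bounds[1:], states


def simulate_state_trajectory(
    model: TwoStateModel,
    duration: float,
    dt_state: float | None = None,
    rng: np.random.Generator | None = None,
    mode: str = "propagator",
) -> StateTrajectory:
    """Simulate a two-state trajectory as per-step Markov transitions.

    Each step the molecule switches with the probability given by
    :func:`transition_matrix` for ``dt_state``; the run of steps spent in a
    state before switching is therefore geometric, which is sampled directly
    so the cost scales with the number of transitions, not steps.  The
    initial state is drawn from the stationary distribution.
    """
    if duration < 0:
        raise ValueError("duration must be non-negative")
    if rng is None:
        rng = np.random.default_rng()
    if dt_state is None:
        dt_state = default_state_step(model.G_barrier)
    if dt_state <= 0:
        raise ValueError("dt_state must be positive")
    n_steps = int(round(duration / dt_state))
    if n_steps == 0:
        return StateTrajectory(0, np.empty(0, dtype=np.int64), 0, dt_state)

    P = transition_matrix(model.k12, model.k21, dt_state, mode=mode)
    p_switch = {1: P[0, 1], 2: P[1, 0]}
    state = sample_initial_state(model.k12, model.k21, rng)
    initial_state = state

    switches: list[np.ndarray] = []
    pos = 0
    # expected switches per batch; geometric draws are cheap in bulk
    while pos < n_steps:
        remaining = n_steps - pos
        exp_dwell = 1.0 / max(p_switch[1], p_switch[2])
        batch = int(min(max(64, 2 * remaining / exp_dwell), 4_000_000))
        # states alternate within a batch, so dwell probabilities alternate
        p = np.empty(batch)
        p[0::2] = p_switch[state]
        p[1::2] = p_switch[3 - state]
        dwells = rng.geometric(p)
        steps = pos + np.cumsum(dwells)
        cut = np.searchsorted(steps, n_steps, side="left")
        switches.append(steps[:cut])
        if cut < batch:
            pos = n_steps
        else:
            pos = int(steps[-1])
            state = state if batch % 2 == 0 else 3 - state
    switch_steps = (
        np.concatenate(switches) if switches else np.empty(0, dtype=np.int64)
    )
    return StateTrajectory(initial_state, switch_steps.astype(np.int64), n_steps, dt_state)
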