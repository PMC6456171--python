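"""Two-state stochastic dynamics of strand sections.

Every strand section is an independent two-state Markov chain observed on a
fixed 1-second grid: an intact section opens with probability
``p_break * length`` per step (longer sections break more often) and a
broken section reseals with probability ``p_seal`` per step.  Probabilities
are used directly as per-step transition probabilities, matching the fixed
update cadence; they are not converted to continuous rates.

The stationary distribution of the chain,

    p_broken = p_break * l / (p_break * l + p_seal),

is used to draw initial states so simulations start in statistical
equilibrium of the structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import StrandNetwork


@dataclass(frozen=True)
class DynamicsParams:
    """Strand break/seal dynamics.

    p_break : break-forming probability per strand length per step (m^-1 s^-1)
    p_seal  : resealing probability per step (s^-1); default 0.033 gives a
              mean open duration of ~30 s
    dt_state : state-update interval (s); the model is defined on a 1-s grid
    """

    p_break: float
    p_seal: float = 0.033
    dt_state: float = 1.0

    def __post_init__(self) -> None:
        if self.p_break < 0:
            raise ValueError("p_break must be >= 0")
        if not (0 < self.p_seal <= 1):
            raise ValueError("p_seal must be in (0, 1]")
        if self.dt_state != 1.0:
            raise ValueError("the state process is defined on a 1-s grid")

    def with_p_break(self, p_break: float) -> "DynamicsParams":
        return DynamicsParams(p_break, self.p_seal, self.dt_state)


def stationary_broken_probability(dyn: DynamicsParams, length: float) -> float:
    """Stationary probability that a section of given length is broken."""
    if length < 0:
        raise ValueError("length must be >= 0")
    pb = dyn.p_break * length
    if pb > 1:
        raise ValueError("p_break * length must be <= 1 (it is a probability)")
    denom = pb + dyn.p_seal
    return pb / denom if denom > 0 else 0.0


def section_break_probabilities(network: StrandNetwork,
                                dyn: DynamicsParams) -> np.ndarray:
    """Per-step break probability ``p_break * l`` for every section."""
    pb = dyn.p_break * network.section_lengths
    if np.any(pb > 1):
        raise ValueError("p_break * length exceeds 1 for some section")
    return pb


def stationary_probabilities(network: StrandNetwork,
                             dyn: DynamicsParams) -> np.ndarray:
    """Stationary broken probability for every section."""
    pb = section_break_probabilities(network, dyn)
    denom = pb + dyn.p_seal
    out = np.zeros_like(pb)
    np.divide(pb, denom, out=out, where=denom > 0)
    return out


def sample_initial_states(network: StrandNetwork, dyn: DynamicsParams,
                          rng: np.random.Generator) -> np.ndarray:
    """Draw the t=0 state of every section from its stationary distribution.

    Returns a boolean array (True = broken).
    """
    return rng.random(len(network.sections)) < stationary_probabilities(network, dyn)


def step_states(states: np.ndarray, network: StrandNetwork,
                dyn: DynamicsParams, rng: np.random.Generator) -> np.ndarray:
    """Advance all section states by one 1-s step (synchronous update)."""
    pb = section_break_probabilities(network, dyn)
    u = rng.random(len(states))
    # broken stays broken unless u < p_seal; intact breaks if u < p_break*l
    return np.where(states, u >= dyn.p_seal, u < pb)


@dataclass
class StrandStateTrajectory:
    """Sampled binary trajectory of all sections on the 1-s grid.

    ``states[t, s]`` is True when section ``s`` is broken during the
    interval ``[t, t+1)`` seconds.
    """

    states: np.ndarray          # (n_steps + 1, n_sections) bool
    p_broken: np.ndarray        # stationary broken probability per section

    def broken_fraction(self) -> np.ndarray:
        """Time-averaged broken occupancy per section."""
        return self.states.mean(axis=0)

    def to_table(self) -> np.ndarray:
        """(section id, t, state) rows for debugging dumps."""
        T, S = self.states.shape
        t, s = np.meshgrid(np.arange(T), np.arange(S), indexing="ij")
        return np.column_stack([s.ravel(), t.ravel(),
                                self.states.ravel().astype(int)])


def simulate_states(network: StrandNetwork, dyn: DynamicsParams,
                    n_steps: int, seed: int = 0) -> StrandStateTrajectory:
    """Simulate the full state trajectory (diagnostic helper)."""
    rng = np.random.default_rng(seed)
    states = np.empty((n_steps + 1, len(network.sections)), dtype=bool)
    states[0] = sample_initial_states(network, dyn, rng)
    for t in range(n_steps):
        states[t + 1] = step_states(states[t], network, dyn, rng)
    return StrandStateTrajectory(states, stationary_probabilities(network, dyn))
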