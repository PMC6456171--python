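"""Static mean-field comparator models ("steady-state" models).

These replace the stochastic strand dynamics with the *expected* number of
permanently open breaks per strand (from the stationary distribution of
the two-state chain) and collapse each compartment row into a single
well-mixed layer.  The permeability model becomes a series of n_strand
static layers; the resistance model a series of n_strand identical strands
each carrying its expected breaks in parallel with the intact strand.

Expected break counts are used fractionally (no rounding): the comparator
is a mean-field construct and rounding would introduce artificial steps.
These models bracket the dynamic ones: they overestimate permeability and
underestimate resistance because they ignore the rarity of simultaneous
openings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import StrandNetwork
from .dynamics import DynamicsParams, stationary_broken_probability
from .permeability import Molecule, break_permeability_coefficient
from .ter import ElectricalParams, break_resistance


@dataclass(frozen=True)
class SteadyStateConfig:
    """Shared inputs of the two comparator models."""

    network: StrandNetwork
    dyn: DynamicsParams


def expected_breaks_per_strand(network: StrandNetwork,
                               dyn: DynamicsParams) -> np.ndarray:
    """Expected number of simultaneously open breaks on each horizontal strand."""
    out = np.empty(network.geom.n_strand)
    for s in range(1, network.geom.n_strand + 1):
        ids = network.strand_section_ids(s)
        out[s - 1] = sum(
            stationary_broken_probability(dyn, network.sections[i].length)
            for i in ids)
    return out


def ss_permeability(config: SteadyStateConfig, molecule: Molecule,
                    l_cb: float) -> float:
    """Static-layer permeability (m/s): series of n_strand layers, each with
    conductance (expected breaks) * l_break * P_break / w_model."""
    network, dyn = config.network, config.dyn
    geom = network.geom
    p_break_coeff = break_permeability_coefficient(geom, molecule, l_cb)
    m = expected_breaks_per_strand(network, dyn)
    if np.any(m == 0):
        return 0.0
    layer_p = m * geom.l_break * p_break_coeff / geom.w_model
    return 1.0 / np.sum(1.0 / layer_p)


def ss_resistance(config: SteadyStateConfig, elec: ElectricalParams,
                  l_cb: float) -> float:
    """Static-strand area resistance (Ohm m^2): series of n_strand strands,
    each the intact strand (minus broken length) in parallel with its
    expected breaks."""
    network, dyn = config.network, config.dyn
    geom = network.geom
    r_break = break_resistance(geom, elec)
    strand_length = geom.width_compartments * geom.w_comp
    m = expected_breaks_per_strand(network, dyn)
    g = (strand_length - m * geom.l_break) / elec.r_strand + m / r_break
    r2d = np.sum(1.0 / g)
    return r2d * geom.w_model / l_cb
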