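"""Transepithelial electrical resistance from the dynamic resistor network.

Each strand section is a resistor between the two paracellular regions it
separates: intact sections conduct through the strand material
(R = R_strand / l_ij, so longer sections conduct better), broken sections
add the break in parallel with the remaining strand,

    R_ij = ((l_ij - l_break) / R_strand + 1 / R_break)^-1.

At every 1-s state snapshot the planar circuit is solved by mesh (loop)
analysis: one loop per bounded face of the conduction graph plus the outer
loop that carries the voltage source, giving the 2D resistance
R = V_s / I_outer, scaled to an epithelial area resistance by
w_model / l_cb.  The static tricellular pore resistance is combined in
parallel, and the TER trace is time-averaged.

Strand capacitance is ignored; results are independent of V_s (pure
scaling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import GeometryParams, StrandNetwork
from .dynamics import DynamicsParams, sample_initial_states, step_states
from .permeability import TricellularParams


@dataclass(frozen=True)
class ElectricalParams:
    """Electrical constants of the resistor network.

    ``r_strand`` is the intact strand resistance per length (Ohm m).
    ``r_break_override`` pins the break resistance to a fixed value
    (default 0.2 GOhm, the value consistent with the fitted strand
    resistances); set to ``None`` to use the geometric estimate
    rho_em * h_strand / (2 w_TJ l_break).
    """

    r_strand: float
    rho_em: float = 0.537          # extracellular medium resistivity (Ohm m)
    v_s: float = 1.0               # source voltage (V); pure scaling
    r_break_override: float | None = 0.2e9

    def __post_init__(self) -> None:
        if self.r_strand <= 0 or self.rho_em <= 0 or self.v_s <= 0:
            raise ValueError("electrical parameters must be positive")
        if self.r_break_override is not None and self.r_break_override <= 0:
            raise ValueError("r_break_override must be positive")


def break_resistance(geom: GeometryParams, elec: ElectricalParams) -> float:
    """Resistance of a single break (Ohm).

    The geometric estimate treats the break as a slab of extracellular
    medium of height h_strand and cross-section A_break = 2 w_TJ l_break;
    the override (default 0.2 GOhm) takes precedence when set.
    """
    if elec.r_break_override is not None:
        return elec.r_break_override
    a_break = 2.0 * geom.w_tj * geom.l_break
    return elec.rho_em * geom.h_strand / a_break


def section_resistance(broken: bool, l_ij: float, l_break: float,
                       r_strand: float, r_break: float) -> float:
    """Resistance of one strand section (Ohm, per unit depth).

    Intact: the full section of strand conducts, R = R_strand / l_ij.
    Broken: the remaining strand of length l_ij - l_break is in parallel
    with the break.
    """
    if l_ij <= l_break and broken:
        raise ValueError("section shorter than the break size")
    if not broken:
        return r_strand / l_ij
    return 1.0 / ((l_ij - l_break) / r_strand + 1.0 / r_break)


def section_resistances(network: StrandNetwork, states: np.ndarray,
                        elec: ElectricalParams) -> np.ndarray:
    """Vector of section resistances for a boolean break-state vector."""
    geom = network.geom
    r_break = break_resistance(geom, elec)
    l = network.section_lengths
    r_intact = elec.r_strand / l
    r_broken = 1.0 / ((l - geom.l_break) / elec.r_strand + 1.0 / r_break)
    return np.where(states, r_broken, r_intact)


def ttj_resistance(ttj: TricellularParams, elec: ElectricalParams) -> float:
    """Area-specific resistance of the tricellular pores (Ohm m^2),
    R_tTJ = rho_em h_tTJ / (pi r_tTJ^2 rho_tTJ); infinite without pores."""
    if ttj.rho_ttj == 0:
        return np.inf
    return elec.rho_em * ttj.h_ttj / (np.pi * ttj.r_ttj ** 2 * ttj.rho_ttj)


# ---------------------------------------------------------------------------
# Mesh (loop-current) solver
# ---------------------------------------------------------------------------

class MeshSystem:
    """Precomputed loop structure of the network circuit.

    Rows of the (implicit) loop-resistance matrix are the inner faces of
    the planar conduction graph plus the outer loop containing the source
    branch.  Each section is shared by at most two loops; its resistance
    contributes ``+r`` to both diagonal entries and ``-+ r`` (sign from the
    relative traversal direction) to the off-diagonal pair.
    """

    def __init__(self, network: StrandNetwork):
        self.network = network
        n_inner = len(network.loop_nodes)
        self.n_loops = n_inner + 1
        self.outer_index = n_inner

        cycles = [(nodes, True) for nodes in network.loop_nodes]
        cycles.append((network.outer_loop_nodes, False))  # open: closes via source

        sec_loops: dict[int, list[tuple[int, int]]] = {}
        for li, (nodes, closed) in enumerate(cycles):
            n = len(nodes)
            pairs = range(n) if closed else range(n - 1)
            for i in pairs:
                a, b = nodes[i], nodes[(i + 1) % n]
                sid = network.section_id(a, b)
                sign = 1 if network.sections[sid].u == a else -1
                sec_loops.setdefault(sid, []).append((li, sign))

        rows, cols, signs, secs = [], [], [], []
        for sid, loops in sec_loops.items():
            if len(loops) > 2:  # pragma: no cover - planarity guarantee
                raise RuntimeError("section shared by more than two loops")
            for la, sa in loops:
                rows.append(la)
                cols.append(la)
                signs.append(1.0)
                secs.append(sid)
            if len(loops) == 2:
                (la, sa), (lb, sb) = loops
                ss = float(sa * sb)
                rows.append(la); cols.append(lb); signs.append(ss); secs.append(sid)
                rows.append(lb); cols.append(la); signs.append(ss); secs.append(sid)
        self._rows = np.asarray(rows)
        self._cols = np.asarray(cols)
        self._signs = np.asarray(signs)
        self._secs = np.asarray(secs)

    def solve(self, r_sections: np.ndarray, v_s: float = 1.0):
        """Solve the mesh equations; returns (loop currents, R_2D)."""
        if np.any(r_sections <= 0) or not np.all(np.isfinite(r_sections)):
            raise ValueError("section resistances must be finite and positive")
        data = self._signs * r_sections[self._secs]
        m = sp.coo_matrix((data, (self._rows, self._cols)),
                          shape=(self.n_loops, self.n_loops)).tocsc()
        b = np.zeros(self.n_loops)
        b[self.outer_index] = v_s
        currents = spla.spsolve(m, b)
        i_outer = currents[self.outer_index]
        return currents, v_s / abs(i_outer)


def solve_network(network: StrandNetwork, r_sections: np.ndarray,
                  v_s: float = 1.0, mesh: MeshSystem | None = None):
    """Mesh analysis of the circuit; returns (loop currents, R_2D)."""
    if mesh is None:
        mesh = MeshSystem(network)
    return mesh.solve(r_sections, v_s)


# ---------------------------------------------------------------------------
# Dynamic TER simulation
# ---------------------------------------------------------------------------

@dataclass
class TERResult:
    """TER trace and time averages (SI: Ohm m^2; report as Ohm cm^2)."""

    t: np.ndarray
    ter: np.ndarray                # combined TER(t), Ohm m^2
    r_btj: np.ndarray              # bTJ area resistance trace, Ohm m^2
    r_ttj: float | None            # static tTJ area resistance, Ohm m^2
    ter_mean: float
    r_btj_mean: float

    @property
    def share_ttj(self) -> float:
        """Fraction of the total conductance carried by the tTJ pores."""
        if self.r_ttj is None:
            return 0.0
        return self.ter_mean / self.r_ttj


def simulate_ter(network: StrandNetwork, dyn: DynamicsParams,
                 elec: ElectricalParams, l_cb: float,
                 ttj: TricellularParams | None = None,
                 horizon: float = 1e5, seed: int = 0) -> TERResult:
    """Simulate the dynamic resistor network over ``horizon`` seconds.

    At each 1-s snapshot the mesh system is solved for the bTJ area
    resistance; the static tTJ resistance is combined in parallel and the
    trace is time-averaged.  Snapshots with an unchanged break pattern
    reuse the previous solution.
    """
    mesh = MeshSystem(network)
    rng = np.random.default_rng(seed)
    geom = network.geom
    r_break = break_resistance(geom, elec)
    l = network.section_lengths
    r_intact = elec.r_strand / l
    r_broken = 1.0 / ((l - geom.l_break) / elec.r_strand + 1.0 / r_break)
    r_ttj = None if ttj is None else ttj_resistance(ttj, elec)

    n_steps = int(round(horizon))
    states = sample_initial_states(network, dyn, rng)
    prev = None
    r_btj = np.empty(n_steps)
    scale = network.w_model / l_cb
    r2d = None
    for t in range(n_steps):
        if prev is None or not np.array_equal(states, prev):
            r = np.where(states, r_broken, r_intact)
            _, r2d = mesh.solve(r, elec.v_s)
            prev = states
        r_btj[t] = r2d * scale
        states = step_states(states, network, dyn, rng)

    if r_ttj is None:
        ter = r_btj.copy()
    else:
        ter = 1.0 / (1.0 / r_btj + 1.0 / r_ttj)
    return TERResult(t=np.arange(n_steps, dtype=float), ter=ter,
                     r_btj=r_btj, r_ttj=r_ttj,
                     ter_mean=float(ter.mean()),
                     r_btj_mean=float(r_btj.mean()))
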