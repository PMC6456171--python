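"""Molecular permeability through the dynamic tight-junction barrier.

The bicellular (bTJ) pathway is a stochastic compartment model: molecules
hop between brick-lattice compartments only through transiently broken
strand sections, with rate constants

    k_ij(t) = l_break * r_ij(t) * P_break / A_i,

where ``r_ij`` is the binary section state and ``P_break`` the hindered
slit permeability coefficient of a break, already scaled to the whole
epithelium through the relative junction area ``eps_TJ = 2 w_TJ l_cb``.
The basal reservoir is clamped and the apical compartment is absorbing
(backflow neglected); the bTJ permeability is the slope of the mean apical
accumulation divided by ``w_model * c_basal``.

The tricellular (tTJ) pathway is a static ensemble of cylindrical pores
treated analytically and added in parallel:  P_TJ = P_bTJ + P_tTJ.

The default permeant is a 547-Da PEG oligomer; its radius and aqueous
diffusivity follow the standard PEG mass-size and mass-diffusivity power
laws, and confinement is described by the Dechadilok-Deen hindrance
polynomials for a slit (breaks) and a cylindrical pore (tTJ tube).

Amounts are 2D (per unit depth, units m^-1); conversions to nm/s happen
only at reporting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .geometry import (APICAL, BASAL, GeometryParams, StrandNetwork,
                       StrandSection, build_network)
from .dynamics import (DynamicsParams, section_break_probabilities,
                       stationary_probabilities)

#: Avogadro constant (mol^-1)
N_A = 6.022e23

#: Default basal concentration, mol m^-3 (= 1 mM); pure scaling parameter.
C_BASAL_DEFAULT = 1.0


# ---------------------------------------------------------------------------
# Permeant molecule
# ---------------------------------------------------------------------------

def peg_radius(mass_da: float) -> float:
    """PEG oligomer radius (m) from its mass via r = 0.29 M^0.454 Angstrom."""
    if mass_da <= 0:
        raise ValueError("molecular mass must be > 0")
    return 0.29 * mass_da ** 0.454 * 1e-10


def peg_diffusivity(mass_da: float) -> float:
    """Aqueous diffusion coefficient (m^2 s^-1), D0 = 9.9e-9 M^-0.453."""
    if mass_da <= 0:
        raise ValueError("molecular mass must be > 0")
    return 9.9e-9 * mass_da ** -0.453


@dataclass(frozen=True)
class Molecule:
    """Permeant with mass-derived radius and aqueous diffusivity."""

    mass_da: float = 547.0

    @property
    def radius(self) -> float:
        return peg_radius(self.mass_da)

    @property
    def diffusivity(self) -> float:
        return peg_diffusivity(self.mass_da)


PEG_547 = Molecule(547.0)


# ---------------------------------------------------------------------------
# Hindrance factors (Dechadilok & Deen polynomials)
# ---------------------------------------------------------------------------

def slit_hindrance(lam: float) -> float:
    """Hindrance factor H_s for diffusion in a slit, lam = r_m / w_TJ."""
    if lam < 0 or lam >= 1:
        raise ValueError("slit hindrance requires 0 <= lambda < 1")
    if lam == 0:
        return 1.0
    return (1.0 + 9.0 / 16.0 * lam * math.log(lam) - 1.19358 * lam
            + 0.4285 * lam ** 3 - 0.3192 * lam ** 4 + 0.08428 * lam ** 5)


def pore_hindrance(lam: float) -> float:
    """Hindrance factor H_p for diffusion in a cylindrical pore, lam = r_m/r_pore."""
    if lam < 0 or lam > 1:
        raise ValueError("pore hindrance requires 0 <= lambda <= 1")
    if lam == 0:
        return 1.0
    return (1.0 + 9.0 / 8.0 * lam * math.log(lam) - 1.56034 * lam
            + 0.528155 * lam ** 2 + 1.91521 * lam ** 3 - 2.81903 * lam ** 4
            + 0.270788 * lam ** 5 + 1.10115 * lam ** 6 - 0.435933 * lam ** 7)


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TricellularParams:
    """Static tricellular pore pathway: radius, tube height, areal density."""

    rho_ttj: float                 # pores per area (m^-2)
    r_ttj: float = 5e-9            # pore radius (m)
    h_ttj: float = 1e-6            # pore (central tube) height (m)

    def __post_init__(self) -> None:
        if self.rho_ttj < 0 or self.r_ttj <= 0 or self.h_ttj <= 0:
            raise ValueError("tricellular parameters must be positive")


@dataclass(frozen=True)
class EpitheliumParams:
    """Per-epithelium measurements and fitted dynamics (SI units).

    ``l_cb`` is the cell-boundary length per epithelial area (m^-1),
    ``rho_ttj`` the tricellular pore density (m^-2).  ``p_break`` (m^-1 s^-1)
    and ``r_strand`` (Ohm m) are the fitted structural-dynamics parameters.
    """

    name: str
    l_cb: float
    rho_ttj: float
    p_exp: float | None = None       # measured permeability (m/s)
    ter_exp: float | None = None     # measured TER (Ohm m^2)
    p_break: float | None = None     # m^-1 s^-1
    r_strand: float | None = None    # Ohm m

    def __post_init__(self) -> None:
        if self.l_cb <= 0 or self.rho_ttj < 0:
            raise ValueError("l_cb must be > 0 and rho_ttj >= 0")

    @classmethod
    def from_paper_units(cls, name: str, *, P_exp_nm_s: float | None = None,
                         TER_ohm_cm2: float | None = None,
                         l_cb_per_um: float, rho_ttj_per_um2: float,
                         p_break_per_um_s: float | None = None,
                         R_strand_gohm_um: float | None = None) -> "EpitheliumParams":
        """Build from the customary reporting units (nm/s, Ohm cm^2, um^-1, ...)."""
        return cls(
            name=name,
            l_cb=l_cb_per_um * 1e6,
            rho_ttj=rho_ttj_per_um2 * 1e12,
            p_exp=None if P_exp_nm_s is None else P_exp_nm_s * 1e-9,
            ter_exp=None if TER_ohm_cm2 is None else TER_ohm_cm2 * 1e-4,
            p_break=None if p_break_per_um_s is None else p_break_per_um_s * 1e6,
            r_strand=None if R_strand_gohm_um is None else R_strand_gohm_um * 1e3,
        )

    @property
    def ttj(self) -> TricellularParams:
        return TricellularParams(rho_ttj=self.rho_ttj)

    def dynamics(self, p_seal: float = 0.033) -> DynamicsParams:
        if self.p_break is None:
            raise ValueError(f"{self.name}: p_break is not set")
        return DynamicsParams(self.p_break, p_seal)


# ---------------------------------------------------------------------------
# Analytic pathway coefficients
# ---------------------------------------------------------------------------

def break_permeability_coefficient(geom: GeometryParams, molecule: Molecule,
                                   l_cb: float) -> float:
    """Epithelium-scaled permeability coefficient of a strand break (m/s).

    P_break = eps_TJ * D0 * H_s(r_m / w_TJ) / h_strand with
    eps_TJ = 2 w_TJ l_cb the relative TJ area of the epithelium.
    """
    if l_cb < 0:
        raise ValueError("l_cb must be >= 0")
    eps_tj = 2.0 * geom.w_tj * l_cb
    lam = molecule.radius / geom.w_tj
    return eps_tj * molecule.diffusivity * slit_hindrance(lam) / geom.h_strand


def ttj_permeability(ttj: TricellularParams, molecule: Molecule) -> float:
    """Tricellular pore pathway permeability (m/s), parallel static pores."""
    lam = molecule.radius / ttj.r_ttj
    if lam > 1:
        raise ValueError("molecule larger than the tricellular pore")
    eps_ttj = math.pi * ttj.r_ttj ** 2 * ttj.rho_ttj
    return eps_ttj * molecule.diffusivity * pore_hindrance(lam) / ttj.h_ttj


def rate_constant(section: StrandSection, broken: bool, geom: GeometryParams,
                  p_break_coeff: float, area_i: float) -> float:
    """Permeation rate constant out of compartment i through one section (s^-1).

    Intact sections pass no molecules; for a broken section
    k_ij = l_break * P_break / A_i (donor-side area).
    """
    if not broken:
        return 0.0
    return geom.l_break * p_break_coeff / area_i


def total_permeability(p_btj: float, p_ttj: float) -> float:
    """Parallel combination of the two leak-pathway components (simple sum)."""
    if p_btj < 0 or p_ttj < 0:
        raise ValueError("permeabilities must be >= 0")
    return p_btj + p_ttj


# ---------------------------------------------------------------------------
# Dynamic bTJ simulation
# ---------------------------------------------------------------------------

@dataclass
class PermeabilityResult:
    """Simulation output of the dynamic bTJ model (+ analytic tTJ term)."""

    t: np.ndarray                  # times (s) of the mean apical trace
    q_apical_mean: np.ndarray      # mean apical amount (m^-1)
    p_btj: float                   # m/s
    p_ttj: float                   # m/s
    eps_tj: float
    eps_ttj: float
    c_basal: float                 # mol m^-3
    q_basal: float                 # m^-1
    reps: int
    lag_time: float | None = None  # s
    q_apical_reps: np.ndarray | None = None
    mass_balance_error: float = 0.0

    @property
    def p_tj(self) -> float:
        return total_permeability(self.p_btj, self.p_ttj)


def _sim_arrays(network: StrandNetwork, dyn: DynamicsParams,
                molecule: Molecule, l_cb: float, c_basal: float):
    geom = network.geom
    p_break_coeff = break_permeability_coefficient(geom, molecule, l_cb)
    k_coef = geom.l_break * p_break_coeff            # m^2 s^-1
    a_basal = geom.w_model * geom.h_basal
    c_number = c_basal * N_A                         # molecules m^-3
    q_basal = c_number * a_basal                     # m^-1
    return {
        "sec_u": network.section_u,
        "sec_v": network.section_v,
        "sec_pb": section_break_probabilities(network, dyn),
        "sec_pstat": stationary_probabilities(network, dyn),
        "p_seal": dyn.p_seal,
        "area": network.areas,
        "a_basal": a_basal,
        "q_basal": q_basal,
        "k_coef": k_coef,
        "c_number": c_number,
    }


def _run_reps(network, dyn, molecule, l_cb, c_basal, q0, horizon, reps, seed,
              accum_from=None, keep_reps=False):
    arr = _sim_arrays(network, dyn, molecule, l_cb, c_basal)
    n_steps = int(round(horizon))
    if accum_from is None:
        accum_from = n_steps // 2
    traces = np.empty((reps, n_steps + 1)) if keep_reps else None
    mean_trace = np.zeros(n_steps + 1)
    q_mean_rows = np.zeros(network.n_rows)
    balance = 0.0
    for r in range(reps):
        trace, q, q_mean, q_ap, in_bas, out_bas = _kernel.run_replicate(
            arr["sec_u"], arr["sec_v"], arr["sec_pb"], arr["sec_pstat"],
            arr["p_seal"], arr["area"], arr["a_basal"], arr["q_basal"],
            arr["k_coef"], q0, n_steps, 1.0, int(seed) + r, accum_from)
        if not np.isfinite(trace[-1]) or not np.all(np.isfinite(q)):
            raise FloatingPointError(
                "non-finite state encountered in permeability simulation")
        mean_trace += trace
        if keep_reps:
            traces[r] = trace
        for row in range(network.n_rows):
            ids = network.row_compartments(row + 1)
            q_mean_rows[row] += q_mean[ids].sum()
        # closure of the piecewise-exact bookkeeping
        total_in = in_bas
        total_out = out_bas + q_ap
        dq = q.sum() - q0.sum()
        scale = max(abs(total_in), abs(total_out), abs(dq), 1e-300)
        balance = max(balance, abs(total_in - total_out - dq) / scale)
    mean_trace /= reps
    q_mean_rows /= reps
    return mean_trace, q_mean_rows, balance, traces, arr


def equilibrium_initialize(network: StrandNetwork, dyn: DynamicsParams,
                           molecule: Molecule, l_cb: float,
                           c_basal: float = C_BASAL_DEFAULT,
                           reps: int = 16, horizon: float = 3600,
                           seed: int = 0) -> np.ndarray:
    """Per-row equilibrium concentrations relative to the basal compartment.

    Runs zero-initial-condition pre-runs and averages each compartment row
    over the linear phase (second half of the horizon).  The relative
    profile depends only on the lattice, not on the magnitude of the
    dynamics, so it can be cached per geometry.  Warns when the apical
    accumulation has not yet become linear within the pre-run horizon.
    """
    q0 = np.zeros(network.n_compartments)
    mean_trace, q_rows, _, _, arr = _run_reps(
        network, dyn, molecule, l_cb, c_basal, q0, horizon, reps, seed)
    n = len(mean_trace) - 1
    # linearity check: slope of 3rd vs 4th quarter of the mean apical trace
    s3 = np.polyfit(np.arange(n // 2, 3 * n // 4),
                    mean_trace[n // 2:3 * n // 4], 1)[0]
    s4 = np.polyfit(np.arange(3 * n // 4, n + 1),
                    mean_trace[3 * n // 4:], 1)[0]
    if s4 > 0 and abs(s3 - s4) > 0.25 * s4:
        warnings.warn("linear phase may not be reached within the pre-run "
                      "horizon; equilibrium profile could be biased",
                      stacklevel=2)
    row_areas = np.array([network.areas[network.row_compartments(r + 1)].sum()
                          for r in range(network.n_rows)])
    conc_rows = q_rows / row_areas                  # molecules per m^3
    return conc_rows / arr["c_number"]              # relative to basal


def initial_amounts_from_profile(network: StrandNetwork, profile: np.ndarray,
                                 c_basal: float = C_BASAL_DEFAULT) -> np.ndarray:
    """Convert a per-row relative concentration profile to initial amounts."""
    c_number = c_basal * N_A
    q0 = np.empty(network.n_compartments)
    for row in range(network.n_rows):
        for cid in network.row_compartments(row + 1):
            q0[cid] = profile[row] * c_number * network.areas[cid]
    return q0


def _slope_fit(t: np.ndarray, y: np.ndarray, window: float):
    i0 = int(len(t) * (1.0 - window))
    return np.polyfit(t[i0:], y[i0:], 1)


def simulate_btj_permeability(network: StrandNetwork, dyn: DynamicsParams,
                              molecule: Molecule, epi: EpitheliumParams,
                              horizon: float = 7200, reps: int = 512,
                              seed: int = 0,
                              q0: np.ndarray | None = None,
                              equilibrium_profile: np.ndarray | None = None,
                              c_basal: float = C_BASAL_DEFAULT,
                              fit_window: float = 0.5,
                              keep_reps: bool = False) -> PermeabilityResult:
    """Simulate the dynamic bTJ pathway and report P_bTJ (+ analytic P_tTJ).

    The linear ODE system is propagated exactly over each 1-s state
    interval; the mean apical accumulation over replicates is fitted with a
    first-degree polynomial over the trailing ``fit_window`` fraction of the
    horizon and converted to a permeability via
    P_bTJ = slope / (w_model * c_basal).

    Initial amounts: ``q0`` explicitly, else from ``equilibrium_profile``
    (per-row relative concentrations), else zero.
    """
    if q0 is None:
        if equilibrium_profile is not None:
            q0 = initial_amounts_from_profile(network, equilibrium_profile,
                                              c_basal)
        else:
            q0 = np.zeros(network.n_compartments)
    mean_trace, _, balance, traces, arr = _run_reps(
        network, dyn, molecule, epi.l_cb, c_basal, q0, horizon, reps, seed,
        keep_reps=keep_reps)
    t = np.arange(len(mean_trace), dtype=float)
    slope, _ = _slope_fit(t, mean_trace, fit_window)
    p_btj = slope / (network.w_model * arr["c_number"])
    p_ttj = ttj_permeability(epi.ttj, molecule)
    geom = network.geom
    return PermeabilityResult(
        t=t, q_apical_mean=mean_trace,
        p_btj=max(p_btj, 0.0), p_ttj=p_ttj,
        eps_tj=2 * geom.w_tj * epi.l_cb,
        eps_ttj=math.pi * epi.ttj.r_ttj ** 2 * epi.rho_ttj,
        c_basal=c_basal, q_basal=arr["q_basal"], reps=reps,
        q_apical_reps=traces, mass_balance_error=balance)


def lag_time(network: StrandNetwork, dyn: DynamicsParams, molecule: Molecule,
             epi: EpitheliumParams, horizon: float = 7200, reps: int = 512,
             seed: int = 0, fit_window: float = 0.5,
             c_basal: float = C_BASAL_DEFAULT,
             method: str = "mean") -> float:
    """Diffusional lag time (s): back-extrapolated zero of the linear phase.

    Starts from empty compartments, fits the linear phase of apical
    accumulation and returns its intersection with the time axis.

    ``method="mean"`` (default) extrapolates the replicate-averaged
    trace.  Note that with stationary initial strand states the averaged
    trace is close to linear from t = 0 in break-dominated regimes (rare
    instantaneous spanning openings carry flux immediately), so this
    estimator measures a small ensemble-level delay and is noisy: its
    intercept inherits the heavy-tailed full-opening fluctuations.
    ``method="median"`` extrapolates the linear phase of *each replicate*
    and returns the median intercept, a robust measure of the typical
    single-realization transit delay.  Tight barriers need horizons well
    beyond the lag itself.
    """
    q0 = np.zeros(network.n_compartments)
    mean_trace, _, _, traces, _ = _run_reps(
        network, dyn, molecule, epi.l_cb, c_basal, q0, horizon, reps, seed,
        keep_reps=(method == "median"))
    t = np.arange(len(mean_trace), dtype=float)
    if method == "mean":
        slope, intercept = _slope_fit(t, mean_trace, fit_window)
        if slope <= 0:
            raise RuntimeError("no linear phase detected (non-positive "
                               "slope); increase the horizon or replicates")
        return -intercept / slope
    if method != "median":
        raise ValueError("method must be 'median' or 'mean'")
    lags = []
    for trace in traces:
        slope, intercept = _slope_fit(t, trace, fit_window)
        if slope > 0:
            lags.append(-intercept / slope)
    if len(lags) < reps / 2:
        raise RuntimeError("no linear phase in most replicates; "
                           "increase the horizon")
    return float(np.median(lags))
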