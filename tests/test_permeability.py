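"""Permeability pathway: molecule laws, hindrance, rates, and the dynamic
compartment simulation against static oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tjbarrier as tj
from tjbarrier.dynamics import DynamicsParams
from tjbarrier.geometry import APICAL, BASAL
from tjbarrier.permeability import (C_BASAL_DEFAULT, N_A, PEG_547,
                                    EpitheliumParams, Molecule,
                                    TricellularParams,
                                    break_permeability_coefficient,
                                    equilibrium_initialize, pore_hindrance,
                                    peg_diffusivity, peg_radius,
                                    rate_constant, simulate_btj_permeability,
                                    slit_hindrance, total_permeability,
                                    ttj_permeability)


class TestMoleculeLaws:
    def test_peg547_radius(self):
        assert peg_radius(547) * 1e9 == pytest.approx(0.51, abs=0.005)

    def test_radius_prefactor(self):
        assert peg_radius(1.0) == pytest.approx(0.029e-9)

    def test_diffusivity_prefactor(self):
        assert peg_diffusivity(1.0) == pytest.approx(9.9e-9)

    def test_diffusivity_power_law_oracle(self):
        # independent re-evaluation through logs
        m = 547.0
        expect = 9.9e-9 * math.exp(-0.453 * math.log(m))
        assert peg_diffusivity(m) == pytest.approx(expect, rel=1e-12)

    @given(m=st.floats(10, 5000))
    @settings(max_examples=30, deadline=None)
    def test_monotonicity(self, m):
        assert peg_radius(m * 1.1) > peg_radius(m)
        assert peg_diffusivity(m * 1.1) < peg_diffusivity(m)


class TestHindrance:
    def test_free_limits(self):
        assert slit_hindrance(0.0) == 1.0
        assert pore_hindrance(0.0) == 1.0

    def test_pore_closes_at_unity(self):
        assert abs(pore_hindrance(1.0)) < 1e-12

    def test_slit_term_by_term(self):
        lam = PEG_547.radius / 4e-9  # 547-Da PEG in the default 4-nm slit
        terms = [1.0, 9 / 16 * lam * math.log(lam), -1.19358 * lam,
                 0.4285 * lam ** 3, -0.3192 * lam ** 4, 0.08428 * lam ** 5]
        assert slit_hindrance(lam) == pytest.approx(math.fsum(terms), rel=1e-12)

    def test_pore_term_by_term(self):
        lam = PEG_547.radius / 5e-9  # 547-Da PEG in the 5-nm tTJ pore
        terms = [1.0, 9 / 8 * lam * math.log(lam), -1.56034 * lam,
                 0.528155 * lam ** 2, 1.91521 * lam ** 3, -2.81903 * lam ** 4,
                 0.270788 * lam ** 5, 1.10115 * lam ** 6,
                 -0.435933 * lam ** 7]
        assert pore_hindrance(lam) == pytest.approx(math.fsum(terms), rel=1e-12)

    def test_slit_decreasing_on_grid(self):
        grid = np.linspace(0, 0.5, 51)
        vals = [slit_hindrance(x) for x in grid]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            slit_hindrance(1.0)
        with pytest.raises(ValueError):
            pore_hindrance(1.2)


class TestPathwayCoefficients:
    def test_break_coefficient_zero_boundary_length(self):
        geom = tj.GeometryParams()
        assert break_permeability_coefficient(geom, PEG_547, 0.0) == 0.0

    def test_break_coefficient_linear_in_l_cb(self):
        geom = tj.GeometryParams()
        one = break_permeability_coefficient(geom, PEG_547, 0.525e6)
        two = break_permeability_coefficient(geom, PEG_547, 1.05e6)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_break_coefficient_chained_oracle(self):
        geom = tj.GeometryParams()
        r = 0.29 * 547 ** 0.454 * 1e-10
        d0 = 9.9e-9 * 547 ** -0.453
        hs = slit_hindrance(r / 4e-9)
        expect = (2 * 4e-9 * 0.525e6) * d0 * hs / 6e-9
        got = break_permeability_coefficient(geom, PEG_547, 0.525e6)
        assert got == pytest.approx(expect, rel=1e-12)

    def test_ttj_zero_density(self):
        assert ttj_permeability(TricellularParams(rho_ttj=0.0), PEG_547) == 0.0

    def test_ttj_linear_in_density(self):
        a = ttj_permeability(TricellularParams(rho_ttj=0.05e12), PEG_547)
        b = ttj_permeability(TricellularParams(rho_ttj=0.10e12), PEG_547)
        assert b == pytest.approx(2 * a, rel=1e-12)

    def test_ttj_pores_alone_cover_tight_epithelium(self, presets):
        """For MDCK C7 the pore pathway alone exceeds the measured value."""
        c7 = presets["MDCK C7"]
        p = ttj_permeability(c7.ttj, PEG_547)
        d0 = 9.9e-9 * 547 ** -0.453
        expect = (math.pi * 25e-18 * 0.078e12) * d0 * \
            pore_hindrance(peg_radius(547) / 5e-9) / 1e-6
        assert p == pytest.approx(expect, rel=1e-12)
        assert p >= c7.p_exp

    def test_ttj_rejects_oversized_molecule(self):
        with pytest.raises(ValueError):
            ttj_permeability(TricellularParams(rho_ttj=1e11), Molecule(1e6))

    def test_total_permeability_additive(self):
        assert total_permeability(0.0, 3.0) == 3.0
        assert total_permeability(3.0, 0.0) == 3.0
        assert total_permeability(1.5, 2.5) == total_permeability(2.5, 1.5)


class TestRateConstant:
    def test_intact_passes_nothing(self, fig_network):
        s = fig_network.sections[0]
        assert rate_constant(s, False, fig_network.geom, 1e-4, 1e-14) == 0.0

    def test_symmetry_equal_areas(self, fig_network):
        geom = fig_network.geom
        s = fig_network.sections[0]
        k_ij = rate_constant(s, True, geom, 2.8e-4, 1e-14)
        k_ji = rate_constant(s, True, geom, 2.8e-4, 1e-14)
        assert k_ij == k_ji

    def test_flux_balance_unequal_areas(self, fig_network):
        """k_ij A_i == k_ji A_j: equal-and-opposite equilibrium fluxes."""
        geom = fig_network.geom
        s = fig_network.sections[0]
        a_i, a_j = 1e-14, 5e-15
        k_ij = rate_constant(s, True, geom, 2.8e-4, a_i)
        k_ji = rate_constant(s, True, geom, 2.8e-4, a_j)
        assert k_ij * a_i == pytest.approx(k_ji * a_j, rel=1e-12)


def _tiny_epi(l_cb=0.3e6, rho=0.03e12):
    return EpitheliumParams("test", l_cb=l_cb, rho_ttj=rho, p_exp=5e-9)


class TestDynamicSimulation:
    def test_sealed_network_passes_nothing(self, small_network):
        res = simulate_btj_permeability(
            small_network, DynamicsParams(0.0), PEG_547, _tiny_epi(),
            horizon=50, reps=2, seed=0)
        assert res.p_btj == 0.0
        assert np.all(res.q_apical_mean == 0.0)

    def test_mass_conservation_closure(self, small_network):
        res = simulate_btj_permeability(
            small_network, DynamicsParams(0.05e6), PEG_547, _tiny_epi(),
            horizon=400, reps=4, seed=1)
        assert res.mass_balance_error < 1e-9

    def test_apical_trace_nondecreasing(self, small_network):
        res = simulate_btj_permeability(
            small_network, DynamicsParams(0.05e6), PEG_547, _tiny_epi(),
            horizon=400, reps=3, seed=2, keep_reps=True)
        assert np.all(np.diff(res.q_apical_reps, axis=1) >= -1e-9)

    def test_static_all_broken_matches_linear_solve(self):
        """Permanently broken single-row network reproduces the steady-state
        flux of the static rate-constant system."""
        geom = tj.GeometryParams(n_strand=2, width_compartments=8)
        net = tj.build_network(geom)
        epi = _tiny_epi()
        # p_break * l == 1 for full sections and a vanishing seal rate keep
        # every section open for the whole run
        dyn = DynamicsParams(p_break=1.0 / 100e-9, p_seal=1e-12)
        res = simulate_btj_permeability(net, dyn, PEG_547, epi,
                                        horizon=300, reps=2, seed=3)
        # independent static steady state: A q = -b
        pbc = break_permeability_coefficient(geom, PEG_547, epi.l_cb)
        kc = geom.l_break * pbc
        n = net.n_compartments
        a_basal = geom.w_model * geom.h_basal
        c_n = C_BASAL_DEFAULT * N_A
        q_basal = c_n * a_basal
        A = np.zeros((n, n))
        b = np.zeros(n)
        for s in net.sections:
            u, v = s.u, s.v
            if u >= 0 and v >= 0:
                A[u, u] -= kc / net.areas[u]
                A[v, v] -= kc / net.areas[v]
                A[u, v] += kc / net.areas[v]
                A[v, u] += kc / net.areas[u]
            else:
                c = u if u >= 0 else v
                bnd = v if u >= 0 else u
                A[c, c] -= kc / net.areas[c]
                if bnd == BASAL:
                    b[c] += kc / a_basal * q_basal
        q_ss = np.linalg.solve(A, -b)
        flux = sum(kc / net.areas[c] * q_ss[c]
                   for s in net.sections if APICAL in (s.u, s.v)
                   for c in [s.u if s.u >= 0 else s.v])
        p_expect = flux / (net.w_model * c_n)
        assert res.p_btj == pytest.approx(p_expect, rel=1e-6)

    def test_scaling_parameters_do_not_matter(self, small_network):
        """P_bTJ is independent of the basal concentration (pure scaling)."""
        epi = _tiny_epi()
        kw = dict(horizon=300, reps=2, seed=4)
        a = simulate_btj_permeability(small_network, DynamicsParams(0.05e6),
                                      PEG_547, epi, c_basal=1.0, **kw)
        b = simulate_btj_permeability(small_network, DynamicsParams(0.05e6),
                                      PEG_547, epi, c_basal=123.0, **kw)
        assert a.p_btj == pytest.approx(b.p_btj, rel=1e-12)

    def test_seeded_reproducibility(self, small_network):
        epi = _tiny_epi()
        kw = dict(horizon=200, reps=3, seed=9)
        a = simulate_btj_permeability(small_network, DynamicsParams(0.05e6),
                                      PEG_547, epi, **kw)
        b = simulate_btj_permeability(small_network, DynamicsParams(0.05e6),
                                      PEG_547, epi, **kw)
        assert np.array_equal(a.q_apical_mean, b.q_apical_mean)


class TestEquilibriumProfile:
    def test_profile_shape(self):
        """Concentrations decrease from the basal to the apical side and are
        roughly linear across interior rows."""
        net = tj.build_network(tj.GeometryParams(n_strand=4,
                                                 width_compartments=10))
        prof = equilibrium_initialize(net, DynamicsParams(0.1e6), PEG_547,
                                      0.3e6, reps=24, horizon=1200, seed=5)
        assert np.all(np.diff(prof) < 0)
        assert 0 < prof[-1] < prof[0] < 1
        # interior profile close to a straight line in row index
        x = np.arange(len(prof))
        resid = prof - np.polyval(np.polyfit(x, prof, 1), x)
        assert np.max(np.abs(resid)) < 0.1

    def test_single_row_bounded(self):
        net = tj.build_network(tj.GeometryParams(n_strand=2,
                                                 width_compartments=10))
        prof = equilibrium_initialize(net, DynamicsParams(0.1e6), PEG_547,
                                      0.3e6, reps=16, horizon=600, seed=6)
        assert prof.shape == (1,)
        assert 0 < prof[0] < 1

    def test_profile_invariant_to_dynamics_magnitude(self):
        """The relative row profile does not depend on p_break."""
        net = tj.build_network(tj.GeometryParams(n_strand=3,
                                                 width_compartments=10))
        slow = equilibrium_initialize(net, DynamicsParams(0.05e6), PEG_547,
                                      0.3e6, reps=32, horizon=1500, seed=7)
        fast = equilibrium_initialize(net, DynamicsParams(0.15e6), PEG_547,
                                      0.3e6, reps=32, horizon=1500, seed=8)
        assert np.allclose(slow, fast, atol=0.06)
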