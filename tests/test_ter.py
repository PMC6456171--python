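"""Resistor-network model: section resistances, mesh solver vs nodal
oracle, closed-form limits and the dynamic TER simulation."""

import numpy as np
import pytest

import tjbarrier as tj
from tjbarrier.dynamics import DynamicsParams
from tjbarrier.geometry import APICAL, BASAL
from tjbarrier.permeability import TricellularParams
from tjbarrier.ter import (ElectricalParams, MeshSystem, break_resistance,
                           section_resistance, section_resistances,
                           simulate_ter, solve_network, ttj_resistance)


def nodal_r2d(net, r, v_s=1.0):
    """Independent node-potential (Laplacian) solve of the same circuit."""
    n = net.n_compartments
    idx = {**{i: i for i in range(n)}, BASAL: n, APICAL: n + 1}
    G = np.zeros((n + 2, n + 2))
    for s in net.sections:
        g = 1.0 / r[s.id]
        a, b = idx[s.u], idx[s.v]
        G[a, a] += g
        G[b, b] += g
        G[a, b] -= g
        G[b, a] -= g
    v = np.linalg.solve(G[:n, :n], -G[:n, n] * v_s)
    vfull = np.concatenate([v, [v_s, 0.0]])
    current = abs(G[n] @ vfull)
    return v_s / current


class TestBreakResistance:
    def test_geometric_formula(self):
        geom = tj.GeometryParams()
        elec = ElectricalParams(r_strand=7.65e3, r_break_override=None)
        expect = 0.537 * 6e-9 / (2 * 4e-9 * 20e-9)
        assert break_resistance(geom, elec) == pytest.approx(expect, rel=1e-12)

    def test_halving_with_break_area(self):
        g1 = tj.GeometryParams(l_break=20e-9)
        g2 = tj.GeometryParams(l_break=40e-9)
        elec = ElectricalParams(r_strand=7.65e3, r_break_override=None)
        assert break_resistance(g1, elec) == pytest.approx(
            2 * break_resistance(g2, elec), rel=1e-12)

    def test_override_default(self):
        geom = tj.GeometryParams()
        elec = ElectricalParams(r_strand=7.65e3)
        assert break_resistance(geom, elec) == 0.2e9

    def test_strand_to_break_ratios(self):
        """Per-break-length strand resistances dwarf the break resistance:
        ~90x for average MDCK II and ~2655x for MDCK C7."""
        r_break = 0.2e9
        ratio_mdck2 = (0.36e3 / 20e-9) / r_break
        ratio_c7 = (10.62e3 / 20e-9) / r_break
        assert ratio_mdck2 == pytest.approx(90, rel=0.01)
        assert ratio_c7 == pytest.approx(2655, rel=0.01)


class TestSectionResistance:
    def test_intact_value(self):
        assert section_resistance(False, 0.05e-6, 20e-9, 7.65e3, 0.2e9) == \
            pytest.approx(153e9, rel=1e-12)

    def test_broken_with_infinite_strand(self):
        r = section_resistance(True, 0.05e-6, 20e-9, np.inf, 0.2e9)
        assert r == pytest.approx(0.2e9, rel=1e-12)

    def test_break_always_lowers_resistance(self):
        for l in (50e-9, 100e-9):
            intact = section_resistance(False, l, 20e-9, 7.65e3, 0.2e9)
            broken = section_resistance(True, l, 20e-9, 7.65e3, 0.2e9)
            assert broken < intact


class TestMeshSolver:
    def test_intact_series_closed_form(self):
        """All-intact network: R_bTJ = n_strand * R_strand / l_cb exactly."""
        for n, w in [(2, 5), (3, 3), (4, 50), (5, 7)]:
            net = tj.build_network(
                tj.GeometryParams(n_strand=n, width_compartments=w))
            elec = ElectricalParams(r_strand=7.65e3)
            r = section_resistances(net, np.zeros(len(net.sections), bool),
                                    elec)
            _, r2d = solve_network(net, r)
            l_cb = 0.525e6
            assert r2d * net.w_model / l_cb == pytest.approx(
                n * elec.r_strand / l_cb, rel=1e-9)

    def test_mesh_equals_nodal_on_random_patterns(self, fig_network):
        elec = ElectricalParams(r_strand=7.65e3)
        mesh = MeshSystem(fig_network)
        rng = np.random.default_rng(2024)
        for _ in range(100):
            states = rng.random(len(fig_network.sections)) < rng.uniform(0.05, 0.6)
            r = section_resistances(fig_network, states, elec)
            _, r2d = mesh.solve(r)
            assert r2d == pytest.approx(nodal_r2d(fig_network, r), rel=1e-9)

    def test_voltage_linearity(self, fig_network):
        elec = ElectricalParams(r_strand=7.65e3)
        states = np.zeros(len(fig_network.sections), bool)
        states[::3] = True
        r = section_resistances(fig_network, states, elec)
        mesh = MeshSystem(fig_network)
        i1, r1 = mesh.solve(r, 1.0)
        i2, r2 = mesh.solve(r, 2.0)
        assert np.allclose(i2, 2 * i1)
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_rejects_bad_resistance(self, fig_network):
        mesh = MeshSystem(fig_network)
        r = np.ones(len(fig_network.sections))
        r[0] = -1.0
        with pytest.raises(ValueError):
            mesh.solve(r)


class TestTricellularResistance:
    def test_inverse_in_density(self):
        elec = ElectricalParams(r_strand=1e3)
        a = ttj_resistance(TricellularParams(rho_ttj=0.106e12), elec)
        b = ttj_resistance(TricellularParams(rho_ttj=0.053e12), elec)
        assert b == pytest.approx(2 * a, rel=1e-12)

    def test_mdck_iia_value_and_share(self):
        """R_tTJ for MDCK IIa in Ohm cm^2 and its small conductance share."""
        elec = ElectricalParams(r_strand=1e3)
        r = ttj_resistance(TricellularParams(rho_ttj=0.106e12), elec)
        expect = 0.537 * 1e-6 / (np.pi * 25e-18 * 0.106e12)
        assert r == pytest.approx(expect, rel=1e-12)
        share = 28e-4 / r  # measured TER over tTJ resistance
        assert 0.01 < share < 0.10


class TestDynamicTER:
    def test_static_limit_without_breaks(self, small_network):
        epi = tj.get_preset("Caco-2")
        elec = ElectricalParams(r_strand=epi.r_strand)
        res = simulate_ter(small_network, DynamicsParams(0.0), elec,
                           epi.l_cb, ttj=epi.ttj, horizon=30, seed=0)
        n = small_network.geom.n_strand
        r_btj = n * elec.r_strand / epi.l_cb
        r_ttj = ttj_resistance(epi.ttj, elec)
        expect = 1.0 / (1.0 / r_btj + 1.0 / r_ttj)
        assert np.allclose(res.ter, expect, rtol=1e-9)

    def test_trace_bounded_by_static_solutions(self, small_network):
        epi = tj.get_preset("Caco-2")
        elec = ElectricalParams(r_strand=epi.r_strand)
        dyn = DynamicsParams(epi.p_break)
        res = simulate_ter(small_network, dyn, elec, epi.l_cb,
                           horizon=400, seed=1)
        nsec = len(small_network.sections)
        mesh = MeshSystem(small_network)
        scale = small_network.w_model / epi.l_cb
        _, lo2d = mesh.solve(section_resistances(
            small_network, np.ones(nsec, bool), elec))
        _, hi2d = mesh.solve(section_resistances(
            small_network, np.zeros(nsec, bool), elec))
        assert res.r_btj.min() >= lo2d * scale - 1e-9
        assert res.r_btj.max() <= hi2d * scale + 1e-9

    def test_seeded_reproducibility(self, small_network):
        epi = tj.get_preset("Caco-2")
        elec = ElectricalParams(r_strand=epi.r_strand)
        dyn = DynamicsParams(epi.p_break)
        a = simulate_ter(small_network, dyn, elec, epi.l_cb, horizon=100,
                         seed=5)
        b = simulate_ter(small_network, dyn, elec, epi.l_cb, horizon=100,
                         seed=5)
        assert np.array_equal(a.ter, b.ter)
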