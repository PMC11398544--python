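"""Unit and oracle tests for the lumped-parameter circuit module."""

import numpy as np
import pytest

from corouq.units import dyncm2
from corouq.zerod import (
    Branch,
    Capacitor,
    CircuitSystem,
    HeartChamber,
    PressureSource,
    Resistor,
    StructuralError,
    SteadyTreeModel,
    build_network_from_anatomy,
    chamber_pressure,
    murray_resistance_split,
    run_periodic,
    segments_from_tree,
    stenosis_pressure_loss,
)
from corouq.zerod.vessels import (
    VesselSegment,
    poiseuille_resistance,
    stenosis_coefficient,
)


class TestVesselSegments:
    def test_identical_branches_equal_parameters(self):
        a = VesselSegment.from_geometry("a", length=2.0, diameter=0.3)
        b = VesselSegment.from_geometry("b", length=2.0, diameter=0.3)
        assert a.resistance == b.resistance
        assert a.capacitance == b.capacitance
        assert a.inductance == b.inductance

    def test_poiseuille_diameter_scaling(self):
        # halving diameter at fixed length raises R by 2^4 = 16
        r1 = poiseuille_resistance(2.0, 0.4)
        r2 = poiseuille_resistance(2.0, 0.2)
        assert r2 / r1 == pytest.approx(16.0, rel=1e-12)

    def test_zero_severity_zero_coefficient(self):
        assert stenosis_coefficient(0.3, 0.0) == 0.0

    def test_severity_monotone(self):
        s = [stenosis_coefficient(0.3, sev) for sev in (0.1, 0.3, 0.5, 0.7)]
        assert all(np.diff(s) > 0)

    def test_nonpositive_geometry_rejected(self):
        with pytest.raises(ValueError):
            VesselSegment.from_geometry("bad", length=-1.0, diameter=0.3)
        with pytest.raises(ValueError):
            VesselSegment.from_geometry("bad", length=1.0, diameter=0.0)


class TestStenosisLaw:
    def test_forward(self):
        assert stenosis_pressure_loss(100.0, 2.0) == 400.0

    def test_odd_symmetry(self):
        assert stenosis_pressure_loss(100.0, -2.0) == -400.0

    def test_zero_coefficient(self):
        assert stenosis_pressure_loss(0.0, 123.4) == 0.0

    def test_negative_coefficient_rejected(self):
        with pytest.raises(ValueError):
            stenosis_pressure_loss(-1.0, 1.0)


class TestChamberPressure:
    def chamber(self, emax=2000.0, emin=500.0):
        return HeartChamber("c", emax, emin, activation_onset=0.1,
                            activation_duration=0.3, unstressed_volume=10.0,
                            period=0.8)

    def test_outside_activation_window(self):
        ch = self.chamber()
        assert chamber_pressure(ch, 60.0, 0.05) == pytest.approx(500.0 * 50.0)
        assert chamber_pressure(ch, 60.0, 0.7) == pytest.approx(500.0 * 50.0)

    def test_constant_elastance(self):
        ch = self.chamber(emax=800.0, emin=800.0)
        ts = np.linspace(0, 0.8, 17)
        ps = [chamber_pressure(ch, 60.0, t) for t in ts]
        assert np.allclose(ps, 800.0 * 50.0)

    def test_zero_at_unstressed_volume(self):
        ch = self.chamber()
        for t in np.linspace(0, 0.8, 9):
            assert chamber_pressure(ch, 10.0, t) == 0.0

    def test_time_reduced_modulo_period(self):
        ch = self.chamber()
        assert chamber_pressure(ch, 60.0, 0.25) == pytest.approx(
            chamber_pressure(ch, 60.0, 0.25 + 0.8))

    def test_invalid_elastance(self):
        with pytest.raises(ValueError):
            HeartChamber("c", 100.0, 200.0, 0.0, 0.3)


class TestMurraySplit:
    def test_equal_diameters(self):
        r = murray_resistance_split(100.0, [0.3, 0.3])
        assert np.allclose(r, [200.0, 200.0])

    def test_exponent_ratio(self):
        # d1 = 2 d2 -> conductance ratio 2^2.6
        r = murray_resistance_split(100.0, [0.4, 0.2])
        assert r[1] / r[0] == pytest.approx(2**2.6, rel=1e-12)

    def test_single_outlet(self):
        assert murray_resistance_split(123.0, [0.3])[0] == pytest.approx(123.0)

    def test_parallel_total_preserved(self, rng):
        d = rng.uniform(0.1, 0.5, size=7)
        r = murray_resistance_split(321.0, d)
        assert 1.0 / np.sum(1.0 / r) == pytest.approx(321.0, rel=1e-12)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            murray_resistance_split(100.0, [])


class TestHyperemia:
    def test_identity_factor(self, small_tree):
        net = build_network_from_anatomy(small_tree)
        same = net.with_hyperemia(1.0)
        for oid in net.coronary_bcs:
            assert same.coronary_bcs[oid].Ra == pytest.approx(net.coronary_bcs[oid].Ra)

    def test_factor_024_scales_all_resistances(self, small_tree):
        net = build_network_from_anatomy(small_tree)
        hyper = net.with_hyperemia(0.24)
        for oid, bc in net.coronary_bcs.items():
            hbc = hyper.coronary_bcs[oid]
            assert hbc.Ra == pytest.approx(0.24 * bc.Ra)
            assert hbc.Ramicro == pytest.approx(0.24 * bc.Ramicro)
            assert hbc.Rv == pytest.approx(0.24 * bc.Rv)
            # other parameters untouched
            assert hbc.Ca == bc.Ca and hbc.Cim == bc.Cim

    def test_halving_resistance_increases_flow(self, small_tree):
        net = build_network_from_anatomy(small_tree)
        model = SteadyTreeModel(net, inlet_pressure=dyncm2(93.0))
        r_full = {o: bc.total_resistance for o, bc in net.coronary_bcs.items()}
        r_half = {o: 0.5 * v for o, v in r_full.items()}
        q_full = SteadyTreeModel(net, dyncm2(93.0)).solve(r_full).inflow
        q_half = model.solve(r_half).inflow
        assert q_half > q_full


class TestBuildNetwork:
    def test_segments_match_branches(self, small_tree):
        net = build_network_from_anatomy(small_tree)
        assert len(net.segments) == len(small_tree)

    def test_stenosed_mains_have_positive_coefficient(self, small_tree):
        net = build_network_from_anatomy(small_tree)
        for main in ("LAD", "LCx", "RCA"):
            assert net.segments[main].stenosis_coefficient > 0

    def test_disconnected_tree_rejected(self, small_tree):
        bad = small_tree.copy()
        bad.loc[1, "parent_id"] = "nonexistent"
        with pytest.raises(StructuralError):
            build_network_from_anatomy(bad)

    def test_nonpositive_geometry_rejected(self, small_tree):
        bad = small_tree.copy()
        bad.loc[0, "diameter_cm"] = 0.0
        with pytest.raises(ValueError):
            segments_from_tree(bad)


class TestCircuitOracles:
    def test_series_resistor_ohms_law(self):
        # constant pressure source across two series resistors to ground
        sysm = CircuitSystem(
            ["src", "mid"],
            [PressureSource(node="src", p=lambda t: 1000.0),
             Resistor(name="r1", a="src", b="mid", R=300.0),
             Resistor(name="r2", a="mid", b="__ground__", R=200.0)])
        y = sysm.step(sysm.initial_state(), 0.0, 0.01, theta=1.0)
        p_mid = y[sysm.node_index("mid")]
        assert p_mid == pytest.approx(1000.0 * 200.0 / 500.0, rel=1e-9)

    def test_windkessel_discharge_time_constant(self):
        # isolated C discharging through Rd: P(t) = P0 exp(-t / (Rd C))
        Rd, C, P0 = 1200.0, 1e-3, 1000.0
        sysm = CircuitSystem(
            ["n"],
            [Capacitor(name="c", a="n", b="__ground__", C=C),
             Resistor(name="rd", a="n", b="__ground__", R=Rd)])
        y0 = sysm.initial_state(pressures={"n": P0})
        tau = Rd * C
        times, states = sysm.integrate(y0, t_end=tau, dt=tau / 400, n_startup_be=0)
        p_end = states[-1, sysm.node_index("n")]
        assert p_end == pytest.approx(P0 * np.exp(-1.0), rel=1e-3)

    def test_linear_limit_matches_algebraic_network(self, small_tree):
        # S = 0, C = 0, L = 0, constant driving pressure: transient solve
        # equals the algebraic resistor-network solution to 6 significant digits
        net = build_network_from_anatomy(small_tree)
        p_in = dyncm2(90.0)
        elements = [PressureSource(node="inlet", p=lambda t: p_in)]
        nodes = ["inlet"]
        r_out = {}
        for sid, seg in net.segments.items():
            prox = "inlet" if seg.parent is None else f"n_{seg.parent}"
            nodes.append(f"n_{sid}")
            elements.append(Branch(name=f"seg_{sid}", a=prox, b=f"n_{sid}",
                                   R=seg.resistance, L=0.0, S=0.0))
            if seg.is_outlet:
                r_out[sid] = net.coronary_bcs[sid].total_resistance
                elements.append(Resistor(name=f"out_{sid}", a=f"n_{sid}",
                                         b="__ground__", R=r_out[sid]))
        sysm = CircuitSystem(nodes, elements)
        y = sysm.step(sysm.initial_state(), 0.0, 1.0, theta=1.0)
        # independent oracle: steady nonlinear solver with S removed
        for seg in net.segments.values():
            seg.stenosis_coefficient = 0.0
        ref = SteadyTreeModel(net, inlet_pressure=p_in).solve(r_out)
        for sid in net.segments:
            q_sim = y[sysm.n_nodes + sysm.flow_names.index(f"seg_{sid}")]
            assert q_sim == pytest.approx(ref.segment_flows[sid], rel=1e-6)

    def test_steady_solver_stenosis_pressure_drop(self, small_tree):
        net = build_network_from_anatomy(small_tree)
        model = SteadyTreeModel(net, inlet_pressure=dyncm2(93.0))
        sol = model.solve({o: bc.total_resistance
                           for o, bc in net.coronary_bcs.items()})
        lad = net.segments["LAD"]
        q = sol.segment_flows["LAD"]
        dp = model.p_in - sol.node_pressures["LAD"]
        expected = lad.resistance * q + lad.stenosis_coefficient * abs(q) * q
        assert dp == pytest.approx(expected, rel=1e-8)


@pytest.fixture(scope="module")
def closed_loop_result(small_tree):
    net = build_network_from_anatomy(small_tree)
    return net, net.simulate(n_cycles=5, steps_per_cycle=300)


class TestClosedLoop:
    def test_mass_conservation(self, closed_loop_result):
        net, res = closed_loop_result
        q_in = sum(res.flows[f"seg_{r}"] for r in net.roots()).mean()
        q_out = sum(res.flows[f"seg_{o}"] for o in net.outlets()).mean()
        assert abs(q_in - q_out) / abs(q_in) < 0.005

    def test_waveform_lengths_and_finiteness(self, closed_loop_result):
        _, res = closed_loop_result
        for p in res.pressures.values():
            assert len(p) == 301
            assert np.all(np.isfinite(p))
        for q in res.flows.values():
            assert np.all(np.isfinite(q))

    def test_cycle_convergence_reported(self, closed_loop_result):
        _, res = closed_loop_result
        assert np.isfinite(res.cycle_convergence)
        assert res.cycle_convergence < 0.05

    def test_physiologic_pressure_range(self, closed_loop_result):
        from corouq.units import mmhg
        _, res = closed_loop_result
        pa = res.pressures["aorta"]
        assert 40 < mmhg(pa.min()) < mmhg(pa.max()) < 220

    def test_grid_convergence(self, small_tree):
        # halving the time step changes mean outlet flows by < 1%
        net = build_network_from_anatomy(small_tree)
        res1 = net.simulate(n_cycles=4, steps_per_cycle=150)
        res2 = net.simulate(n_cycles=4, steps_per_cycle=300)
        for o in net.outlets():
            q1 = res1.flows[f"seg_{o}"].mean()
            q2 = res2.flows[f"seg_{o}"].mean()
            assert abs(q1 - q2) / abs(q2) < 0.01


class TestMonotonicity:
    def test_outlet_resistance_monotonicity(self, small_tree):
        net = build_network_from_anatomy(small_tree)
        model = SteadyTreeModel(net, inlet_pressure=dyncm2(93.0))
        base_r = {o: bc.total_resistance for o, bc in net.coronary_bcs.items()}
        base = model.solve(base_r)
        target = net.outlets()[0]
        bumped = dict(base_r)
        bumped[target] *= 1.5
        sol = model.solve(bumped)
        k = model.outlet_ids.index(target)
        assert sol.outlet_flows[k] < base.outlet_flows[k]
        for j, o in enumerate(model.outlet_ids):
            if o != target:
                assert sol.outlet_flows[j] >= base.outlet_flows[j] - 1e-12
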