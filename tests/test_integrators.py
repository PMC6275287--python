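"""Fixed-step solvers: exponential Euler, clamp mode, RK4, Crank-Nicolson."""

import math

import numpy as np
import pytest

import somasim as ss
from somasim.errors import ConfigError
from somasim.fixtures import make_fixture
from somasim.integrators import SimConfig, axial_conductances, integrate


class TestConfig:
    def test_bad_dt_and_out_dt(self):
        with pytest.raises(ConfigError):
            SimConfig(t_end=10.0, dt=0.0)
        with pytest.raises(ConfigError):
            SimConfig(t_end=10.0, dt=0.1, out_dt=0.15)

    def test_clamp_and_inject_conflict(self, leak_tree):
        cfg = SimConfig(t_end=10.0, I_ext={"cell": 0.1},
                        V_clamp={"cell": -40.0})
        with pytest.raises(ConfigError):
            integrate(leak_tree, cfg)

    def test_empty_model_rejected(self):
        with pytest.raises(ConfigError):
            integrate(ss.ModelTree(), SimConfig(t_end=10.0))


class TestExpEuler:
    def test_leak_single_step_closed_form(self, leak_tree):
        # tau = Cm/g = 10 ms; after one dt=10 step: -50 - 10*exp(-1)
        tr = integrate(leak_tree, SimConfig(t_end=10.0, dt=10.0))
        assert tr.V["cell"][0] == pytest.approx(-50.0 - 10.0 * math.exp(-1.0),
                                                abs=1e-12)

    def test_leak_asymptote_with_injection(self, leak_tree):
        # V_inf = (g*E + I/A)/g = -50 + 10 = -40 mV
        tr = integrate(leak_tree, SimConfig(t_end=200.0, I_ext={"cell": 0.1}))
        assert tr.V["cell"][-1] == pytest.approx(-40.0, abs=1e-6)

    def test_hh_quiescent_then_spiking(self):
        tree = make_fixture("hh_neuron")
        tr0 = integrate(tree, SimConfig(t_end=2000.0, I_ext={"HH": 0.0}))
        assert ss.spike_times(tr0.t, tr0.V["HH"]).size == 0
        tree = make_fixture("hh_neuron")
        tr1 = integrate(tree, SimConfig(t_end=2000.0, I_ext={"HH": 0.2}))
        assert ss.spike_times(tr1.t, tr1.V["HH"]).size > 10

    def test_determinism_bit_exact(self):
        def run():
            tree = make_fixture("bursting_neuron")
            return integrate(tree, SimConfig(t_end=1000.0)).V["AB"]

        assert np.array_equal(run(), run())

    def test_gating_states_stay_in_unit_interval(self):
        tree = make_fixture("bursting_neuron")
        integrate(tree, SimConfig(t_end=2000.0))
        for chan in tree.compartments["AB"].conductances.values():
            assert 0.0 <= chan.m <= 1.0
            assert 0.0 <= chan.h <= 1.0

    def test_trace_length_and_sampling(self, leak_tree):
        tr = integrate(leak_tree, SimConfig(t_end=10.0, dt=0.1, out_dt=0.5))
        assert tr.t.size == 20
        assert tr.t[0] == pytest.approx(0.5)
        assert tr.t[-1] == pytest.approx(10.0)

    def test_snapshot_reset_reproduces_continuation(self):
        tree = make_fixture("bursting_neuron")
        integrate(tree, SimConfig(t_end=500.0))
        tree.snapshot("A")
        first = integrate(tree, SimConfig(t_end=500.0)).V["AB"]
        tree.reset("A")
        second = integrate(tree, SimConfig(t_end=500.0)).V["AB"]
        assert np.array_equal(first, second)


class TestClamp:
    def test_leak_clamp_current(self, leak_tree):
        # g*A*(V-E) = 1 * 0.01 * 10 = 0.1 nA
        tr = integrate(leak_tree, SimConfig(t_end=100.0,
                                            V_clamp={"cell": -40.0}))
        assert tr.I_clamp["cell"][-1] == pytest.approx(0.1, rel=1e-9)

    def test_clamp_at_reversal_zero_current(self, leak_tree):
        tr = integrate(leak_tree, SimConfig(t_end=100.0,
                                            V_clamp={"cell": -50.0}))
        assert abs(tr.I_clamp["cell"][-1]) < 1e-12

    def test_kd_asymptotic_current_nonlinear_in_v(self):
        asym = []
        for v in (-40.0, 0.0, 40.0):
            tree = ss.ModelTree()
            tree.add_compartment("c", A=0.01)
            tree.add_channel("c", "Kd", gbar=1000.0, E=-80.0)
            ss.initialize(tree, V0=-80.0)
            tr = integrate(tree, SimConfig(t_end=500.0, V_clamp={"c": v}))
            asym.append(tr.I_clamp["c"][-1])
        # increments grow: conductance activates with depolarization
        assert asym[2] - asym[1] > asym[1] - asym[0] > 0

    def test_clamp_at_rest_matches_free_run(self):
        tree = make_fixture("hh_neuron")
        integrate(tree, SimConfig(t_end=3000.0))  # settle to rest
        v_rest = tree.compartments["HH"].V
        tr = integrate(tree, SimConfig(t_end=200.0, V_clamp={"HH": v_rest}))
        assert abs(tr.I_clamp["HH"][-1]) < 1e-3

    def test_gating_evolves_under_clamp(self):
        tree = ss.ModelTree()
        tree.add_compartment("c", A=0.01)
        tree.add_channel("c", "Kd", gbar=1000.0, E=-80.0)
        ss.initialize(tree, V0=-80.0)
        m0 = tree.compartments["c"].conductances["Kd"].m
        integrate(tree, SimConfig(t_end=200.0, V_clamp={"c": 0.0}))
        assert tree.compartments["c"].conductances["Kd"].m > m0 + 0.5


class TestRK4:
    def test_leak_matches_exact_exponential(self, leak_tree):
        tr = integrate(leak_tree, SimConfig(t_end=20.0, dt=0.5, solver="rk4"))
        exact = -50.0 - 10.0 * np.exp(-tr.t / 10.0)
        assert np.max(np.abs(tr.V["cell"] - exact)) < 1e-6

    def test_converges_to_exp_euler(self):
        diffs = []
        for dt in (0.05, 0.025, 0.0125):
            te = make_fixture("hh_neuron")
            ve = integrate(te, SimConfig(t_end=200.0, dt=dt, out_dt=0.1,
                                         I_ext={"HH": 0.2})).V["HH"]
            t4 = make_fixture("hh_neuron")
            v4 = integrate(t4, SimConfig(t_end=200.0, dt=dt, out_dt=0.1,
                                         I_ext={"HH": 0.2},
                                         solver="rk4")).V["HH"]
            diffs.append(np.max(np.abs(ve - v4)))
        assert diffs[0] > diffs[1] > diffs[2]

    def test_multi_compartment_rejected(self):
        tree = ss.ModelTree()
        tree.add_compartment("a")
        tree.add_compartment("b")
        with pytest.raises(ConfigError):
            integrate(tree, SimConfig(t_end=10.0, solver="rk4"))


class TestCrankNicolson:
    def test_steady_state_matches_cosh_attenuation(self):
        tree = make_fixture("passive_cable")
        tr = integrate(tree, SimConfig(t_end=2000.0, dt=0.05, out_dt=1.0,
                                       solver="crank_nicolson",
                                       I_ext={"c000": 0.5}))
        labels = list(tree.compartments)
        v = np.array([tr.V[lab][-1] for lab in labels]) + 50.0
        n, ell = len(labels), 0.632
        lam = math.sqrt((1 / 0.1) * 0.05 / (2 * 1e-5 * 100.0))
        x = (np.arange(n) + 0.5) * ell
        total = n * ell
        analytic = np.cosh((total - x) / lam)
        rel = v / v[0]
        expected = analytic / analytic[0]
        assert np.max(np.abs(rel - expected) / expected) < 0.02

    def test_zero_coupling_matches_single_compartment(self):
        tree = make_fixture("passive_cable", n_comps=3)
        tree.axial_resistivity = 1e15
        tr = integrate(tree, SimConfig(t_end=50.0, dt=0.05,
                                       solver="crank_nicolson",
                                       I_ext={"c001": 0.2}))
        single = ss.ModelTree()
        area = 2 * math.pi * 0.05 * 0.632
        single.add_compartment("c", A=area, Cm=10.0)
        single.add_channel("c", "Leak", gbar=0.1, E=-50.0)
        ss.initialize(single)
        trs = integrate(single, SimConfig(t_end=50.0, dt=0.05,
                                          I_ext={"c": 0.2}))
        assert np.max(np.abs(tr.V["c001"] - trs.V["c"])) < 1e-5

    def test_second_order_convergence(self):
        def v_end(dt):
            tree = make_fixture("passive_cable", n_comps=10)
            tr = integrate(tree, SimConfig(t_end=20.0, dt=dt, out_dt=4.0,
                                           solver="crank_nicolson",
                                           I_ext={"c000": 0.5}))
            return np.array([tr.V[lab] for lab in tree.compartments])

        ref = v_end(0.005)
        e1 = np.max(np.abs(v_end(0.08) - ref))
        e2 = np.max(np.abs(v_end(0.04) - ref))
        assert e1 / e2 > 2.0  # at least halves; ~4x expected at 2nd order

    def test_missing_geometry_rejected(self, leak_tree):
        leak_tree.add_compartment("second")
        leak_tree.add_channel("second", "Leak")
        with pytest.raises(ConfigError):
            integrate(leak_tree, SimConfig(t_end=10.0,
                                           solver="crank_nicolson"))

    def test_axial_conductance_value(self):
        # two identical cylinders: R = 2 * 1e-5*Ra*(l/2)/(pi r^2)
        tree = ss.ModelTree(axial_resistivity=100.0)
        for lab in ("a", "b"):
            tree.add_compartment(lab, A=0.1, radius=0.05, length=0.5)
            tree.add_channel(lab, "Leak")
        g = axial_conductances(tree)
        r_expected = 2 * (1e-5 * 100.0 * 0.25 / (math.pi * 0.05**2))
        assert g[0] == pytest.approx(1.0 / r_expected)
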