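"""Protocol layer: spikes, f-I, activation recovery, trace costs, sweeps."""

import numpy as np
import pytest

import somasim as ss
from somasim.errors import PathError, ValidationError
from somasim.protocols import (
    detect_bursts,
    dominant_current_labels,
    fi_curve,
    firing_rate,
    lemasson_error,
    recover_activation,
    spike_times,
    sweep,
)


class TestSpikeDetection:
    def test_flat_trace_no_spikes(self):
        t = np.arange(0.0, 1000.0, 0.1)
        assert spike_times(t, np.full_like(t, -60.0)).size == 0

    def test_sawtooth_rate(self):
        # 5 upward crossings of 0 mV in one second
        t = np.arange(0.0, 1000.0, 0.1)
        v = 20.0 * np.sin(2 * np.pi * 5 * (t + 10.0) / 1000.0)
        assert spike_times(t, v).size == 5
        assert firing_rate(t, v) == pytest.approx(5.0, rel=0.01)

    def test_refractory_merges_chatter(self):
        t = np.arange(0.0, 10.0, 0.01)
        v = np.where((t * 100).astype(int) % 2 == 0, 5.0, -5.0)  # 0.02 ms flicker
        assert spike_times(t, v, refractory=1.0).size <= 10

    def test_burst_grouping(self):
        spikes = np.array([0.0, 10.0, 20.0, 400.0, 410.0, 900.0])
        bursts = detect_bursts(spikes, max_isi=100.0)
        assert len(bursts) == 3
        assert bursts[0] == (0.0, 20.0)


class TestFICurve:
    def test_zero_current_zero_rate(self):
        tree = ss.make_fixture("hh_neuron")
        fi = fi_curve(tree, [0.0], t_end=1500.0, t_transient=500.0)
        assert fi.rate[0] == 0.0

    def test_rates_nondecreasing_suprathreshold(self):
        tree = ss.make_fixture("hh_neuron")
        fi = fi_curve(tree, [0.1, 0.2, 0.3, 0.4], t_end=1500.0,
                      t_transient=500.0)
        assert np.all(np.diff(fi.rate) >= 0)
        assert fi.rate[-1] > 0

    def test_single_value_matches_direct_run(self):
        tree = ss.make_fixture("hh_neuron")
        fi = fi_curve(tree, [0.2], t_end=1500.0, t_transient=500.0)
        tree2 = ss.make_fixture("hh_neuron")
        tr = ss.integrate(tree2, ss.SimConfig(t_end=1500.0,
                                              I_ext={"HH": 0.2}))
        sel = tr.t >= 500.0
        direct = 1000.0 * spike_times(tr.t[sel], tr.V["HH"][sel]).size / 1000.0
        assert fi.rate[0] == pytest.approx(direct)

    def test_model_restored_after_curve(self):
        tree = ss.make_fixture("hh_neuron")
        before, _ = tree.serialize()
        fi_curve(tree, [0.0, 0.3], t_end=600.0, t_transient=100.0)
        after, _ = tree.serialize()
        assert np.array_equal(before, after)


class TestActivationRecovery:
    def test_kd_selects_exponent_four(self):
        fit = recover_activation("Kd", np.arange(-80.0, 51.0, 10.0),
                                 E_rev=-80.0)
        assert fit.n_best == 4

    @pytest.mark.parametrize("p", [1, 2, 3, 4])
    def test_synthetic_round_trip(self, p):
        def minf(v):
            return 1.0 / (1.0 + np.exp((-30.0 - v) / 9.0))

        def taum(v):
            return 5.0 + 0.0 * v

        name = f"SynthP{p}"
        ss.register_channel(name,
                            ss.GatingSpec(p=p, q=0, m_inf=minf, tau_m=taum),
                            default_E=-80.0, overwrite=True)
        fit = recover_activation(name, np.arange(-80.0, 41.0, 10.0),
                                 E_rev=-80.0)
        assert fit.n_best == p
        assert fit.V_half_fit == pytest.approx(-30.0, rel=0.01)
        assert fit.k_fit == pytest.approx(9.0, rel=0.01)

    def test_asymptote_matches_gating_spec(self):
        # clamp current at each step ~ gbar * m_inf(V)^4 * (V - E) * A
        v_steps = np.array([-40.0, -20.0, 0.0, 20.0])
        fit = recover_activation("Kd", v_steps, E_rev=-80.0)
        from somasim.channels import steady_state_curves

        minf = steady_state_curves("Kd", v_steps)["m_inf"]
        expected = minf**4 / np.max(minf**4)
        assert np.allclose(fit.g_norm, expected, rtol=0.01)


class TestDominantCurrent:
    def test_single_channel_always_wins(self, leak_tree):
        tr = ss.integrate(leak_tree, ss.SimConfig(
            t_end=50.0, record_currents=True, I_ext={"cell": 0.1}))
        assert set(dominant_current_labels(tr)) == {"Leak"}

    def test_hh_upstroke_sodium_downstroke_potassium(self):
        tree = ss.make_fixture("hh_neuron")
        tr = ss.integrate(tree, ss.SimConfig(
            t_end=500.0, I_ext={"HH": 0.2}, record_currents=True))
        labels = np.array(dominant_current_labels(tr))
        v = tr.V["HH"]
        dv = np.diff(v, prepend=v[0])
        upstroke = (v > -20.0) & (dv > 0.5)
        downstroke = (v > -20.0) & (dv < -0.5)
        assert upstroke.sum() and (labels[upstroke] == "NaV").mean() > 0.9
        assert downstroke.sum() and (labels[downstroke] == "Kd").mean() > 0.9

    def test_missing_currents_rejected(self, leak_tree):
        tr = ss.integrate(leak_tree, ss.SimConfig(t_end=10.0))
        with pytest.raises(ValidationError):
            dominant_current_labels(tr)


class TestLeMasson:
    def test_identical_traces_zero(self):
        v = -60.0 + 10.0 * np.sin(np.linspace(0, 20, 500))
        assert lemasson_error(v, v) == 0.0

    def test_disjoint_embeddings_two(self):
        t = np.linspace(0, 20, 500)
        a = -70.0 + 1.0 * np.sin(t)
        b = 40.0 + 1.0 * np.sin(t)
        assert lemasson_error(a, b) == pytest.approx(2.0)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(42)
        a = -60 + 20 * rng.standard_normal(400).cumsum() * 0.01
        b = -55 + 20 * rng.standard_normal(400).cumsum() * 0.01
        c_ab = lemasson_error(a, b)
        # histogram grids differ (dV range from first trace) but values agree
        assert 0.0 <= c_ab <= 2.0

    def test_finer_step_scores_lower(self):
        def v_at(dt):
            tree = ss.make_fixture("hh_neuron")
            return ss.integrate(tree, ss.SimConfig(
                t_end=2000.0, dt=dt, out_dt=0.2, I_ext={"HH": 0.2})).V["HH"]

        ref = v_at(0.0125)
        assert lemasson_error(ref, v_at(0.1), dt=0.2) < \
            lemasson_error(ref, v_at(0.2), dt=0.2)


class TestSweep:
    def test_baseline_restored(self):
        tree = ss.make_fixture("hh_neuron")
        before, _ = tree.serialize()

        def proto(tr):
            return tr.compartments["HH"].conductances["Kd"].gbar

        out = sweep(tree, "HH/Kd/gbar", [150.0, 300.0, 600.0], proto)
        assert out == [150.0, 300.0, 600.0]
        after, _ = tree.serialize()
        assert np.array_equal(before, after)

    def test_empty_values(self):
        tree = ss.make_fixture("hh_neuron")
        assert sweep(tree, "HH/Kd/gbar", [], lambda t: None) == []

    def test_ambiguous_path_rejected(self):
        tree = ss.make_fixture("hh_neuron")
        with pytest.raises(PathError):
            sweep(tree, "*/gbar", [1.0], lambda t: None)

    def test_calcium_target_sweep_changes_dynamics(self):
        tree = ss.make_fixture("homeostatic_neuron")

        def final_gbar(tr):
            ss.integrate(tr, ss.SimConfig(t_end=10000.0))
            return tr.compartments["AB"].conductances["NaV"].gbar

        out = sweep(tree, "AB/NaV/IntegralController/Ca_target",
                    [40.0, 120.0], final_gbar)
        assert abs(out[0] - out[1]) > 1.0
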