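"""Model container: construction, paths, serialization, snapshots, hashing."""

import numpy as np
import pytest

import somasim as ss
from somasim.errors import (
    LookupError_,
    NamingError,
    PathError,
    RegistryError,
    ShapeError,
    ValidationError,
)


def build_hh(order):
    tree = ss.ModelTree()
    tree.add_compartment("HH", A=0.01, Cm=10.0)
    for name in order:
        gbar = {"NaV": 1000.0, "Kd": 300.0, "Leak": 1.0}[name]
        tree.add_channel("HH", name, gbar=gbar)
    return tree


class TestConstruction:
    def test_add_compartment_and_channels(self):
        tree = build_hh(["NaV", "Kd", "Leak"])
        assert len(tree.compartments) == 1
        assert len(tree.compartments["HH"].conductances) == 3

    def test_add_to_missing_parent_fails(self):
        tree = ss.ModelTree()
        with pytest.raises(LookupError_):
            tree.add_component("nope", "conductance", "NaV", {})

    def test_duplicate_names_rejected(self):
        tree = build_hh(["NaV"])
        with pytest.raises(NamingError):
            tree.add_channel("HH", "NaV")
        with pytest.raises(NamingError):
            tree.add_compartment("HH")

    def test_unknown_kind_and_type(self):
        tree = ss.ModelTree()
        tree.add_compartment("A")
        with pytest.raises(RegistryError):
            tree.add_component("", "gizmo", "x", {})
        with pytest.raises(RegistryError):
            tree.add_channel("A", "NotAChannel")

    def test_bad_param_name_rejected(self):
        tree = ss.ModelTree()
        tree.add_compartment("A")
        with pytest.raises(ValidationError):
            tree.add_channel("A", "Leak", conductance=5.0)

    def test_generic_add_component(self):
        tree = ss.ModelTree()
        tree.add_component("", "compartment", "AB", {"A": 0.0628})
        tree.add_component("AB", "conductance", "Kd", {"gbar": 500.0})
        tree.add_component("AB", "mechanism", "CalciumMech", {"tau_Ca": 150.0})
        tree.add_component("AB/Kd", "mechanism", "IntegralController",
                           {"tau_m": 1e4, "Ca_target": 10.0})
        assert tree.compartments["AB"].calcium_mech.tau_Ca == 150.0
        assert tree.compartments["AB"].conductances["Kd"].controller is not None


class TestConnect:
    def test_connect_sets_gbar(self, pyloric_tree):
        tree = ss.ModelTree()
        tree.add_compartment("LP")
        tree.add_compartment("PY")
        syn = tree.connect("LP", "PY", "Glutamatergic", gbar=30.0)
        assert syn.gbar == 30.0
        assert syn.E_syn == -70.0

    def test_self_synapse_rejected(self):
        tree = ss.ModelTree()
        tree.add_compartment("A")
        with pytest.raises(ValidationError):
            tree.connect("A", "A", "Glutamatergic")

    def test_unknown_type_and_compartment(self):
        tree = ss.ModelTree()
        tree.add_compartment("A")
        tree.add_compartment("B")
        with pytest.raises(RegistryError):
            tree.connect("A", "B", "GABAergic")
        with pytest.raises(LookupError_):
            tree.connect("A", "C", "Glutamatergic")

    def test_parallel_synapses_allowed(self):
        tree = ss.ModelTree()
        tree.add_compartment("A")
        tree.add_compartment("B")
        tree.connect("A", "B", "Glutamatergic", gbar=10.0)
        tree.connect("A", "B", "Glutamatergic", gbar=20.0)
        assert len(tree.synapses) == 2

    def test_pyloric_has_seven_synapses(self, pyloric_tree):
        assert len(pyloric_tree.synapses) == 7


class TestResolve:
    def test_unique_path(self, hh_tree):
        matches = hh_tree.resolve("HH/NaV/gbar")
        assert len(matches) == 1 and matches[0].get() == 1000.0

    def test_wildcard_gbar(self, hh_tree):
        assert len(hh_tree.resolve("*/gbar")) == 3

    def test_empty_on_no_match(self):
        assert ss.ModelTree().resolve("AB/*") == []

    def test_malformed_path(self, hh_tree):
        with pytest.raises(PathError):
            hh_tree.resolve("")
        with pytest.raises(PathError):
            hh_tree.resolve("a//b")


class TestReplicate:
    def test_hh_times_10_gives_50_states(self, hh_tree):
        # NaV (m, h) + Kd (m) + V + Ca = 5 states per compartment
        hh_tree.replicate("HH", 10)
        assert hh_tree.n_states() == 50

    def test_identity(self, hh_tree):
        n0 = hh_tree.n_states()
        hh_tree.replicate("HH", 1)
        assert hh_tree.n_states() == n0

    def test_errors(self, hh_tree):
        with pytest.raises(LookupError_):
            hh_tree.replicate("nope", 3)
        with pytest.raises(ValidationError):
            hh_tree.replicate("HH", 0)

    def test_copies_are_uncoupled(self, hh_tree):
        hh_tree.replicate("HH", 4)
        assert len(hh_tree.synapses) == 0
        assert set(hh_tree.compartments) == {"HH", "HH_2", "HH_3", "HH_4"}


class TestSerialization:
    def test_round_trip_identity(self, pyloric_tree):
        vec, layout = pyloric_tree.serialize()
        pyloric_tree.deserialize(vec)
        vec2, layout2 = pyloric_tree.serialize()
        assert layout == layout2
        assert np.array_equal(vec, vec2)

    def test_insertion_order_irrelevant(self):
        a = build_hh(["NaV", "Kd", "Leak"])
        b = build_hh(["Leak", "NaV", "Kd"])
        va, la = a.serialize()
        vb, lb = b.serialize()
        assert la == lb
        assert np.array_equal(va, vb)

    def test_single_entry_change(self, hh_tree):
        vec, layout = hh_tree.serialize()
        i = layout.index("HH/Kd/gbar")
        vec[i] = 123.0
        hh_tree.deserialize(vec)
        assert hh_tree.compartments["HH"].conductances["Kd"].gbar == 123.0
        vec2, _ = hh_tree.serialize()
        assert np.array_equal(vec, vec2)

    def test_wrong_length_rejected(self, hh_tree):
        vec, _ = hh_tree.serialize()
        with pytest.raises(ShapeError):
            hh_tree.deserialize(vec[:-1])

    def test_vector_covers_expected_slots(self, hh_tree):
        # tree param + 4 compartment scalars + per channel gbar,E (+gates)
        _, layout = hh_tree.serialize()
        expected = {"@tree/axial_resistivity", "HH/V", "HH/Ca", "HH/A",
                    "HH/Cm", "HH/NaV/gbar", "HH/NaV/E", "HH/NaV/m",
                    "HH/NaV/h", "HH/Kd/gbar", "HH/Kd/E", "HH/Kd/m",
                    "HH/Leak/gbar", "HH/Leak/E"}
        assert set(layout) == expected


class TestSnapshots:
    def test_snapshot_reset_restores_perturbation(self, hh_tree):
        hh_tree.snapshot("initial")
        vec0, _ = hh_tree.serialize()
        hh_tree.compartments["HH"].conductances["Kd"].gbar = 77.0
        hh_tree.reset("initial")
        vec1, _ = hh_tree.serialize()
        assert np.array_equal(vec0, vec1)

    def test_noop_snapshot_reset(self, hh_tree):
        vec0, _ = hh_tree.serialize()
        hh_tree.snapshot("s")
        hh_tree.reset("s")
        vec1, _ = hh_tree.serialize()
        assert np.array_equal(vec0, vec1)

    def test_unknown_snapshot(self, hh_tree):
        with pytest.raises(LookupError_):
            hh_tree.reset("missing")


class TestHashing:
    def test_structural_hash_order_invariant(self):
        a = build_hh(["NaV", "Kd", "Leak"])
        b = build_hh(["Kd", "Leak", "NaV"])
        assert a.structural_hash() == b.structural_hash()
        assert a.full_hash() == b.full_hash()

    def test_gbar_changes_full_not_structural(self, hh_tree):
        s0, f0 = hh_tree.structural_hash(), hh_tree.full_hash()
        hh_tree.compartments["HH"].conductances["Kd"].gbar *= 2
        assert hh_tree.structural_hash() == s0
        assert hh_tree.full_hash() != f0

    def test_structure_changes_structural(self, hh_tree):
        s0 = hh_tree.structural_hash()
        hh_tree.add_channel("HH", "H")
        assert hh_tree.structural_hash() != s0

    def test_modified_equation_source_changes_hash(self, hh_tree):
        # a copy of Kd with a perturbed time constant is a different type
        def kd2_minf(v):
            return 1.0 / (1.0 + np.exp((-12.3 - v) / 11.8))

        def kd2_taum(v):
            return 15.0 - 12.8 / (1.0 + np.exp(-(v + 28.3) / 19.2))

        ss.register_channel(
            "Kd_mod", ss.GatingSpec(p=4, q=0, m_inf=kd2_minf, tau_m=kd2_taum),
            default_gbar=300.0, default_E=-80.0, overwrite=True)
        other = ss.ModelTree()
        other.add_compartment("HH", A=0.01, Cm=10.0)
        other.add_channel("HH", "NaV", gbar=1000.0)
        other.add_channel("HH", "Kd_mod", name="Kd", gbar=300.0)
        other.add_channel("HH", "Leak", gbar=1.0)
        assert other.structural_hash() != hh_tree.structural_hash()

    def test_hash_format(self, hh_tree):
        h = hh_tree.structural_hash()
        assert len(h) == 32 and h == h.lower()
        int(h, 16)

    def test_full_hash_distinct_across_fixtures(self):
        hashes = {ss.make_fixture(n).full_hash()
                  for n in ("hh_neuron", "bursting_neuron",
                            "homeostatic_neuron", "pyloric_network")}
        assert len(hashes) == 4
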