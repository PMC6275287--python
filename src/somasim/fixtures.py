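"""Built-in example models.

All fixtures are generated programmatically, deterministic, and need no
external data:

* ``hh_neuron`` — single compartment, squid-axon-like spiker (NaV, Kd, Leak
  with Liu-type STG kinetics): quiescent at rest, tonically spiking with
  0.2 nA injected.
* ``bursting_neuron`` — the 8-channel STG burster (NaV, CaT, CaS, A, KCa,
  Kd, H, Leak); with its calcium mechanism it bursts with calcium
  oscillations locked to the bursts, without it it spikes tonically with
  constant calcium.
* ``homeostatic_neuron`` — the burster with an integral controller on every
  conductance and small initial densities; the calcium error signal drives
  the densities up until activity reaches the calcium target.
* ``pyloric_network`` — the triphasic pyloric triad (AB, LP, PY; 7 graded
  synapses of 2 kinetic types) after the classic stomatogastric circuit
  models.
* ``passive_cable`` — an unbranched leak-only cable for the implicit
  solver, with analytic steady-state attenuation available as an oracle.

Maximal conductance densities are in uS/mm^2 (1 mS/cm^2 = 10 uS/mm^2);
those of the burster and network cells follow the published STG models the
channel kinetics come from.
"""

from __future__ import annotations

import numpy as np

from .component_tree import ModelTree
from .errors import ValidationError
from .integrators import initialize

__all__ = ["make_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("hh_neuron", "bursting_neuron", "homeostatic_neuron",
                 "pyloric_network", "passive_cable")

# 8-channel STG burster (pacemaker-like cell), uS/mm^2
BURSTER_GBAR = {
    "NaV": 1000.0, "CaT": 25.0, "CaS": 60.0, "A": 500.0,
    "KCa": 50.0, "Kd": 1000.0, "H": 0.1, "Leak": 0.0,
}
BURSTER_AREA = 0.0628  # mm^2

# homeostatic fixture constants: the mRNA timescale of each controller is
# inversely proportional to the channel's target density, which fixes the
# steady-state conductance ratios (O'Leary et al. 2014)
HOMEOSTASIS_CA_TARGET = 79.0     # uM (time-average of the reference burster)
HOMEOSTASIS_TAU_G = 500.0        # ms
HOMEOSTASIS_TAU_M_SCALE = 5.0e5  # ms * uS/mm^2 ; tau_m_i = scale / gbar_target_i
HOMEOSTASIS_G0 = 0.05            # initial density as a fraction of target

# pyloric cell conductances, uS/mm^2
PYLORIC_GBAR = {
    "AB": {"NaV": 1000.0, "CaT": 25.0, "CaS": 60.0, "A": 500.0,
           "KCa": 50.0, "Kd": 1000.0, "H": 0.1, "Leak": 0.0},
    "LP": {"NaV": 1000.0, "CaS": 40.0, "A": 200.0,
           "KCa": 0.0, "Kd": 250.0, "H": 0.5, "Leak": 0.3},
    "PY": {"NaV": 1000.0, "CaT": 25.0, "CaS": 20.0, "A": 500.0,
           "Kd": 1250.0, "H": 0.5, "Leak": 0.1},
}

# (pre, post, type, gbar nS): the triad's seven synapses; the pacemaker AB
# compartment stands in for the electrically coupled AB/PD pair and so is
# the source of both fast glutamatergic and slow cholinergic inhibition
PYLORIC_SYNAPSES = (
    ("AB", "LP", "Glutamatergic", 30.0),
    ("AB", "LP", "Cholinergic", 30.0),
    ("AB", "PY", "Glutamatergic", 30.0),
    ("AB", "PY", "Cholinergic", 10.0),
    ("LP", "AB", "Glutamatergic", 3.0),
    ("LP", "PY", "Glutamatergic", 5.0),
    ("PY", "LP", "Glutamatergic", 10.0),
)


def _hh_neuron(**overrides) -> ModelTree:
    tree = ModelTree()
    tree.add_compartment("HH", A=0.01, Cm=10.0)
    tree.add_channel("HH", "NaV", gbar=1000.0, E=50.0)
    tree.add_channel("HH", "Kd", gbar=300.0, E=-80.0)
    tree.add_channel("HH", "Leak", gbar=1.0, E=-50.0)
    return tree


def _bursting_neuron(with_calcium: bool = True, **overrides) -> ModelTree:
    tree = ModelTree()
    tree.add_compartment("AB", A=BURSTER_AREA, Cm=10.0)
    gbars = dict(BURSTER_GBAR)
    gbars.update(overrides.pop("gbar", {}))
    for name, g in gbars.items():
        tree.add_channel("AB", name, gbar=g)
    if with_calcium:
        tree.add_calcium_mech("AB")
    return tree


def _homeostatic_neuron(**overrides) -> ModelTree:
    tree = _bursting_neuron(with_calcium=True)
    comp = tree.compartments["AB"]
    ca_target = overrides.pop("Ca_target", HOMEOSTASIS_CA_TARGET)
    for name, chan in comp.conductances.items():
        target = BURSTER_GBAR[name]
        if target <= 0:
            continue
        chan.gbar = HOMEOSTASIS_G0 * target
        tree.add_controller("AB", name,
                            tau_m=HOMEOSTASIS_TAU_M_SCALE / target,
                            tau_g=HOMEOSTASIS_TAU_G,
                            Ca_target=ca_target,
                            mRNA=chan.gbar)
    return tree


def _pyloric_network(**overrides) -> ModelTree:
    tree = ModelTree()
    for lab, gbars in PYLORIC_GBAR.items():
        tree.add_compartment(lab, A=BURSTER_AREA, Cm=10.0)
        for name, g in gbars.items():
            tree.add_channel(lab, name, gbar=g)
        tree.add_calcium_mech(lab)
    for pre, post, typ, g in PYLORIC_SYNAPSES:
        tree.connect(pre, post, typ, gbar=g)
    return tree


def _passive_cable(n_comps: int = 50, radius: float = 0.05,
                   length: float = 0.632, g_leak: float = 0.1,
                   E_leak: float = -50.0, Ra: float = 100.0,
                   **overrides) -> ModelTree:
    """Leak-only unbranched cable; default geometry gives lambda ~ 15.8 mm."""
    tree = ModelTree(axial_resistivity=Ra)
    for i in range(n_comps):
        lab = f"c{i:03d}"
        area = 2 * np.pi * radius * length
        tree.add_compartment(lab, A=area, Cm=10.0, radius=radius,
                             length=length)
        tree.add_channel(lab, "Leak", gbar=g_leak, E=E_leak)
    return tree


_BUILDERS = {
    "hh_neuron": _hh_neuron,
    "bursting_neuron": _bursting_neuron,
    "homeostatic_neuron": _homeostatic_neuron,
    "pyloric_network": _pyloric_network,
    "passive_cable": _passive_cable,
}


def make_fixture(name: str, *, V0: float = -60.0, **overrides) -> ModelTree:
    """Build a named fixture, initialized to a transient-free state at ``V0``."""
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise ValidationError(
            f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}") from None
    tree = builder(**overrides)
    initialize(tree, V0=V0)
    return tree
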