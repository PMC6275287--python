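"""Graded chemical synapses and electrical (gap-junction) coupling.

The graded synapse follows the pyloric-network formulation (Prinz et al.
2004): the activation variable s tracks a sigmoid function of the
presynaptic voltage,

    s_inf(Vpre) = 1 / (1 + exp((V_half - Vpre)/Delta))
    tau_s       = (1 - s_inf) / k_minus          (floored at dt)
    I_syn       = gbar * s * (V_post - E_syn) * 1e-3   [nS*mV -> nA]

Two kinetic variants are built in: Glutamatergic (E_syn = -70 mV,
k_minus = 1/40 ms^-1) and Cholinergic (E_syn = -80 mV, k_minus = 1/100
ms^-1).  Electrical synapses pass ohmic current g*(V_b - V_a) symmetrically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .registry import SYNAPSE_REGISTRY, get_synapse_type, register_synapse

__all__ = [
    "GradedSynapse",
    "ElectricalSynapse",
    "synapse_state_step",
    "synapse_current",
    "electrical_current",
]


@dataclass
class GradedSynapse:
    """A directed graded chemical synapse between two named compartments."""

    type_name: str
    pre: str
    post: str
    gbar: float          # nS
    E_syn: float         # mV
    V_half: float = -35.0
    Delta: float = 5.0
    k_minus: float = 0.025  # 1/ms
    s: float = 0.0

    @classmethod
    def from_type(cls, type_name: str, pre: str, post: str,
                  **overrides) -> "GradedSynapse":
        st = get_synapse_type(type_name)
        kw = dict(gbar=st.default_gbar, E_syn=st.E_syn, V_half=st.V_half,
                  Delta=st.Delta, k_minus=st.k_minus)
        kw.update(overrides)
        return cls(type_name=type_name, pre=pre, post=post, **kw)


@dataclass
class ElectricalSynapse:
    """Symmetric ohmic coupling between compartments a and b."""

    a: str
    b: str
    g: float  # nS


def synapse_state_step(syn: GradedSynapse, V_pre: float, dt: float) -> float:
    """Advance the activation variable one exponential-Euler step.

    tau_s is floored at dt so the update stays stable as s_inf -> 1.
    """
    s_inf = 1.0 / (1.0 + math.exp((syn.V_half - V_pre) / syn.Delta))
    tau_s = max((1.0 - s_inf) / syn.k_minus, dt)
    return s_inf + (syn.s - s_inf) * math.exp(-dt / tau_s)


def synapse_current(syn: GradedSynapse, V_post: float) -> float:
    """Postsynaptic current in nA (positive = outward from the postsynaptic cell)."""
    return syn.gbar * syn.s * (V_post - syn.E_syn) * 1e-3


def electrical_current(syn: ElectricalSynapse, V_a: float, V_b: float) -> tuple[float, float]:
    """Currents injected into a and b (nA); they sum to zero exactly."""
    i_a = syn.g * (V_b - V_a) * 1e-3
    return i_a, -i_a


def _register_builtins() -> None:
    register_synapse("Glutamatergic", E_syn=-70.0, V_half=-35.0, Delta=5.0,
                     k_minus=1.0 / 40.0)
    register_synapse("Cholinergic", E_syn=-80.0, V_half=-35.0, Delta=5.0,
                     k_minus=1.0 / 100.0)


if "Glutamatergic" not in SYNAPSE_REGISTRY:
    _register_builtins()
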