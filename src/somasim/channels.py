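"""Hodgkin-Huxley-style channel formalism and the built-in channel library.

A channel population carries a current

    I = gbar * m^p * h^q * (V - E) * A        [nA]

with gbar in uS/mm^2, V and E in mV, and A (membrane area) in mm^2.  The
gating variables m and h relax toward voltage-dependent steady states
m_inf(V), h_inf(V) with time constants tau_m(V), tau_h(V) in ms.

The built-in library transcribes the stomatogastric-ganglion channel models
of Prinz et al. (2003), a variant of the Liu et al. (1998) parameterizations
fitted to lobster STG recordings: a fast sodium channel (NaV), two calcium
channels (CaT, CaS), a transient potassium channel (A), a calcium-gated
potassium channel (KCa), a delayed rectifier (Kd), a hyperpolarization-
activated mixed-cation channel (H), and a passive Leak.  These eight types
cover the squid-axon-like spiker (NaV, Kd, Leak) and the STG burster used
throughout the test fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .registry import (
    CHANNEL_REGISTRY,
    GatingSpec,
    get_channel_type,
    register_channel,
)

__all__ = [
    "ConductanceInstance",
    "channel_current",
    "steady_state_curves",
]


@dataclass
class ConductanceInstance:
    """One ion-channel population inside a compartment.

    ``gbar`` is the maximal conductance density (uS/mm^2), ``E`` the reversal
    potential (mV).  For calcium channels ``E`` is recomputed every step from
    the Nernst equation when the owning compartment has a calcium mechanism;
    the stored value is a placeholder until then.
    """

    type_name: str
    gbar: float
    E: float
    m: float = 0.0
    h: float = 1.0
    controller: "object | None" = None  # IntegralController, set via add

    @property
    def spec(self) -> GatingSpec:
        return get_channel_type(self.type_name).spec


def channel_current(c: ConductanceInstance, V: float, A: float) -> float:
    """Instantaneous current through the population, in nA (positive = outward)."""
    s = c.spec
    return c.gbar * c.m**s.p * c.h**s.q * (V - c.E) * A


def steady_state_curves(type_name: str, V_grid, Ca: float = 0.05) -> dict:
    """Evaluate m_inf, h_inf, tau_m, tau_h on a voltage grid.

    Non-inactivating channels report ``h_inf`` identically 1 and ``tau_h``
    as NaN; gate-less channels (Leak) report all four as NaN.  ``Ca`` (uM)
    only matters for calcium-gated activations (KCa).
    """
    ct = get_channel_type(type_name)
    v = np.asarray(V_grid, dtype=float)
    nan = np.full_like(v, np.nan)
    out = {"m_inf": nan.copy(), "h_inf": nan.copy(),
           "tau_m": nan.copy(), "tau_h": nan.copy()}
    s = ct.spec
    if s.p > 0:
        out["m_inf"] = (s.m_inf(v, Ca) if s.ca_dependent else s.m_inf(v)).astype(float)
        out["tau_m"] = np.asarray(s.tau_m(v), dtype=float)
    if s.q > 0:
        out["h_inf"] = np.asarray(s.h_inf(v), dtype=float)
        out["tau_h"] = np.asarray(s.tau_h(v), dtype=float)
    elif s.p > 0:
        out["h_inf"] = np.ones_like(v)
    return out


# ---------------------------------------------------------------------------
# Built-in STG channel library (Prinz et al. 2003 kinetics).
# V in mV, tau in ms, Ca in uM.
# ---------------------------------------------------------------------------


def _sig(v, vhalf, k):
    # 1/(1+exp((vhalf - v)/k)); k > 0 rises with V, k < 0 falls with V
    return 1.0 / (1.0 + np.exp((vhalf - v) / k))


def nav_minf(v):
    return _sig(v, -25.5, 5.29)


def nav_hinf(v):
    return _sig(v, -48.9, -5.18)


def nav_taum(v):
    return 1.32 - 1.26 / (1.0 + np.exp(-(v + 120.0) / 25.0))


def nav_tauh(v):
    return (0.67 / (1.0 + np.exp(-(v + 62.9) / 10.0))) * (
        1.5 + 1.0 / (1.0 + np.exp((v + 34.9) / 3.6))
    )


def cat_minf(v):
    return _sig(v, -27.1, 7.2)


def cat_hinf(v):
    return _sig(v, -32.1, -5.5)


def cat_taum(v):
    return 43.4 - 42.6 / (1.0 + np.exp(-(v + 68.1) / 20.5))


def cat_tauh(v):
    return 210.0 - 179.6 / (1.0 + np.exp(-(v + 55.0) / 16.9))


def cas_minf(v):
    return _sig(v, -33.0, 8.1)


def cas_hinf(v):
    return _sig(v, -60.0, -6.2)


def cas_taum(v):
    return 2.8 + 14.0 / (np.exp((v + 27.0) / 10.0) + np.exp(-(v + 70.0) / 13.0))


def cas_tauh(v):
    return 120.0 + 300.0 / (np.exp((v + 55.0) / 9.0) + np.exp(-(v + 65.0) / 16.0))


def a_minf(v):
    return _sig(v, -27.2, 8.7)


def a_hinf(v):
    return _sig(v, -56.9, -4.9)


def a_taum(v):
    return 23.2 - 20.8 / (1.0 + np.exp(-(v + 32.9) / 15.2))


def a_tauh(v):
    return 77.2 - 58.4 / (1.0 + np.exp(-(v + 38.9) / 26.5))


def kca_minf(v, ca):
    return (ca / (ca + 3.0)) * _sig(v, -28.3, 12.6)


def kca_taum(v):
    return 180.6 - 150.2 / (1.0 + np.exp(-(v + 46.0) / 22.7))


def kd_minf(v):
    return _sig(v, -12.3, 11.8)


def kd_taum(v):
    return 14.4 - 12.8 / (1.0 + np.exp(-(v + 28.3) / 19.2))


def h_minf(v):
    return _sig(v, -75.0, -5.5)


def h_taum(v):
    return 2.0 / (np.exp(-(v + 169.7) / 11.6) + np.exp((v - 26.7) / 14.3))


def _register_builtins() -> None:
    register_channel("NaV", GatingSpec(p=3, q=1, m_inf=nav_minf, tau_m=nav_taum,
                                       h_inf=nav_hinf, tau_h=nav_tauh),
                     default_gbar=1000.0, default_E=50.0)
    register_channel("CaT", GatingSpec(p=3, q=1, m_inf=cat_minf, tau_m=cat_taum,
                                       h_inf=cat_hinf, tau_h=cat_tauh,
                                       is_calcium=True),
                     default_gbar=25.0, default_E=30.0)
    register_channel("CaS", GatingSpec(p=3, q=1, m_inf=cas_minf, tau_m=cas_taum,
                                       h_inf=cas_hinf, tau_h=cas_tauh,
                                       is_calcium=True),
                     default_gbar=60.0, default_E=30.0)
    register_channel("A", GatingSpec(p=3, q=1, m_inf=a_minf, tau_m=a_taum,
                                     h_inf=a_hinf, tau_h=a_tauh),
                     default_gbar=500.0, default_E=-80.0)
    register_channel("KCa", GatingSpec(p=4, q=0, m_inf=kca_minf, tau_m=kca_taum,
                                       ca_dependent=True, ca_half=3.0),
                     default_gbar=50.0, default_E=-80.0)
    register_channel("Kd", GatingSpec(p=4, q=0, m_inf=kd_minf, tau_m=kd_taum),
                     default_gbar=1000.0, default_E=-80.0)
    register_channel("H", GatingSpec(p=1, q=0, m_inf=h_minf, tau_m=h_taum),
                     default_gbar=0.1, default_E=-20.0)
    register_channel("Leak", GatingSpec(p=0, q=0),
                     default_gbar=1.0, default_E=-50.0)


if "NaV" not in CHANNEL_REGISTRY:
    _register_builtins()
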