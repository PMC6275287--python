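"""Component type registries.

Channel and synapse types are registered once, by name, together with the
source text of their rate equations.  The source text participates in the
structural hash of any model that uses the type, so editing a channel's
kinetics changes the identity of every model built from it.
"""

from __future__ import annotations

import inspect
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import RegistryError, ValidationError

# grid used to validate registered gating curves
_VALIDATION_GRID = np.arange(-100.0, 100.0 + 0.5, 1.0)


@dataclass(frozen=True)
class GatingSpec:
    """Voltage (and optionally calcium) dependence of one channel type.

    ``m_inf``/``h_inf`` are steady-state open fractions in [0, 1];
    ``tau_m``/``tau_h`` are relaxation time constants in ms, strictly
    positive.  ``p`` and ``q`` are the integer exponents of the activation
    and inactivation gates (q == 0 means non-inactivating; no h state is
    allocated).  A calcium-dependent activation (KCa-style) is expressed as
    a voltage curve multiplied by Ca/(Ca + ca_half).
    """

    p: int
    q: int
    m_inf: Callable[[np.ndarray], np.ndarray] | None = None
    tau_m: Callable[[np.ndarray], np.ndarray] | None = None
    h_inf: Callable[[np.ndarray], np.ndarray] | None = None
    tau_h: Callable[[np.ndarray], np.ndarray] | None = None
    is_calcium: bool = False
    ca_dependent: bool = False
    ca_half: float = 3.0  # uM, half-activation of the Ca/(Ca+K) factor


@dataclass(frozen=True)
class ChannelType:
    name: str
    spec: GatingSpec
    default_gbar: float  # uS/mm^2
    default_E: float     # mV
    source: str          # canonical equation text, enters structural_hash


@dataclass(frozen=True)
class SynapseType:
    """A graded chemical synapse type (sigmoid steady state, first-order s)."""

    name: str
    E_syn: float    # mV
    V_half: float   # mV, presynaptic half-activation
    Delta: float    # mV, sigmoid slope
    k_minus: float  # 1/ms, closing rate
    default_gbar: float = 0.0  # nS
    source: str = ""


CHANNEL_REGISTRY: dict[str, ChannelType] = {}
SYNAPSE_REGISTRY: dict[str, SynapseType] = {}


def _fn_source(fn) -> str:
    if fn is None:
        return "None"
    try:
        return inspect.getsource(fn)
    except (OSError, TypeError):  # e.g. lambdas in a REPL
        return repr(fn)


def _validate_spec(name: str, spec: GatingSpec) -> None:
    if spec.p < 0 or spec.q < 0:
        raise ValidationError(f"{name}: gate exponents must be >= 0")
    if int(spec.p) != spec.p or int(spec.q) != spec.q:
        raise ValidationError(f"{name}: fractional gate exponents rejected")
    v = _VALIDATION_GRID
    if spec.p > 0:
        if spec.m_inf is None or spec.tau_m is None:
            raise ValidationError(f"{name}: p > 0 requires m_inf and tau_m")
        if spec.ca_dependent:
            m = np.asarray(spec.m_inf(v, 0.05), dtype=float)
        else:
            m = np.asarray(spec.m_inf(v), dtype=float)
        if not np.all((m >= 0) & (m <= 1)):
            raise ValidationError(f"{name}: m_inf outside [0, 1] on validation grid")
        tm = np.asarray(spec.tau_m(v), dtype=float)
        if not np.all(tm > 0):
            raise ValidationError(f"{name}: tau_m not strictly positive on validation grid")
    if spec.q > 0:
        if spec.h_inf is None or spec.tau_h is None:
            raise ValidationError(f"{name}: q > 0 requires h_inf and tau_h")
        h = np.asarray(spec.h_inf(v), dtype=float)
        if not np.all((h >= 0) & (h <= 1)):
            raise ValidationError(f"{name}: h_inf outside [0, 1] on validation grid")
        th = np.asarray(spec.tau_h(v), dtype=float)
        if not np.all(th > 0):
            raise ValidationError(f"{name}: tau_h not strictly positive on validation grid")


def register_channel(
    name: str,
    spec: GatingSpec,
    *,
    default_gbar: float = 0.0,
    default_E: float = 0.0,
    overwrite: bool = False,
) -> ChannelType:
    """Register a channel type, validating its curves on V in [-100, 100] mV."""
    if not overwrite and name in CHANNEL_REGISTRY:
        raise RegistryError(f"channel type {name!r} already registered")
    _validate_spec(name, spec)
    source = "\n".join(
        [
            f"p={spec.p} q={spec.q} is_calcium={spec.is_calcium} "
            f"ca_dependent={spec.ca_dependent} ca_half={spec.ca_half!r}",
            _fn_source(spec.m_inf),
            _fn_source(spec.tau_m),
            _fn_source(spec.h_inf),
            _fn_source(spec.tau_h),
        ]
    )
    ct = ChannelType(name=name, spec=spec, default_gbar=default_gbar,
                     default_E=default_E, source=source)
    CHANNEL_REGISTRY[name] = ct
    return ct


def get_channel_type(name: str) -> ChannelType:
    try:
        return CHANNEL_REGISTRY[name]
    except KeyError:
        raise RegistryError(f"unknown channel type {name!r}") from None


def register_synapse(
    name: str,
    *,
    E_syn: float,
    V_half: float = -35.0,
    Delta: float = 5.0,
    k_minus: float = 0.025,
    default_gbar: float = 0.0,
    overwrite: bool = False,
) -> SynapseType:
    if not overwrite and name in SYNAPSE_REGISTRY:
        raise RegistryError(f"synapse type {name!r} already registered")
    if Delta <= 0:
        raise ValidationError(f"{name}: Delta must be > 0")
    if k_minus <= 0:
        raise ValidationError(f"{name}: k_minus must be > 0")
    source = (f"graded: s_inf=1/(1+exp((V_half-Vpre)/Delta)); tau_s=(1-s_inf)/k_minus; "
              f"E_syn={E_syn!r} V_half={V_half!r} Delta={Delta!r} k_minus={k_minus!r}")
    st = SynapseType(name=name, E_syn=E_syn, V_half=V_half, Delta=Delta,
                     k_minus=k_minus, default_gbar=default_gbar, source=source)
    SYNAPSE_REGISTRY[name] = st
    return st


def get_synapse_type(name: str) -> SynapseType:
    try:
        return SYNAPSE_REGISTRY[name]
    except KeyError:
        raise RegistryError(f"unknown synapse type {name!r}") from None
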