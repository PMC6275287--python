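"""Fixed-step time evolution of a model tree.

Three solvers are provided:

* ``exp_euler`` (default) — exponential Euler for gating, synapse and
  calcium states and for the membrane potential, following the classic
  scheme for equations of the relaxation form dx/dt = (x_inf - x)/tau
  (Dayan & Abbott).  Unconditionally keeps gating variables in [0, 1] and
  works for arbitrary networks.  Voltage clamp runs through the same loop
  with the clamped compartments' V pinned and the total membrane current
  reported as the clamp current.
* ``rk4`` — classical 4th-order Runge-Kutta on the joint (V, m, h, Ca)
  system of a single compartment.
* ``crank_nicolson`` — second-order implicit scheme for unbranched
  multi-compartment cables, solving the tridiagonal axial+membrane voltage
  system each step with gating staggered by exponential Euler.

All solvers use a fixed step ``dt``; outputs are sampled every ``out_dt``
(a multiple of ``dt``).  Integration continues from the model's current
state and writes the evolved state back into the tree, so snapshot/reset
bracketing reproduces continuations bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from ._sim_core import TAB_DV, TAB_GRID, TAB_V0, compile_model, run_exp_euler, write_back
from .component_tree import ModelTree
from .errors import ConfigError, IntegrationError
from .mechanisms import calcium_step, controller_step
from .registry import get_channel_type
from .synapses import ElectricalSynapse, GradedSynapse

__all__ = ["SimConfig", "Trace", "integrate", "initialize"]


@dataclass
class SimConfig:
    """Integration settings and external drive.

    ``I_ext`` maps compartment label to injected current (nA), a scalar or a
    per-step series; a bare scalar is accepted for single-compartment
    models.  ``V_clamp`` maps label to a clamp command (mV, scalar or
    series); a compartment cannot be both clamped and injected.
    """

    t_end: float
    dt: float = 0.05
    out_dt: float | None = None
    solver: str = "exp_euler"
    I_ext: object = None
    V_clamp: dict | None = None
    record_currents: bool = False
    record_synapses: bool = False
    record_gbar: bool = False

    def __post_init__(self):
        if self.dt <= 0:
            raise ConfigError("dt must be > 0")
        if self.out_dt is None:
            self.out_dt = self.dt
        k = self.out_dt / self.dt
        if self.out_dt < self.dt or abs(k - round(k)) > 1e-9:
            raise ConfigError("out_dt must be a positive multiple of dt")
        if self.t_end < self.dt:
            raise ConfigError("t_end must be at least dt")
        if self.solver not in ("exp_euler", "rk4", "crank_nicolson"):
            raise ConfigError(f"unknown solver {self.solver!r}")

    @property
    def n_steps(self) -> int:
        return int(np.floor(self.t_end / self.dt + 1e-9))

    @property
    def out_every(self) -> int:
        return int(round(self.out_dt / self.dt))


@dataclass
class Trace:
    """Time-indexed record of an integration."""

    t: np.ndarray
    V: dict[str, np.ndarray]
    Ca: dict[str, np.ndarray]
    I_clamp: dict[str, np.ndarray] = field(default_factory=dict)
    channel_currents: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    synapse_states: dict[str, np.ndarray] = field(default_factory=dict)
    gbar: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def as_dataframe(self):
        """Tidy long-format DataFrame: t, compartment, variable, value."""
        import pandas as pd

        frames = []
        for lab, arr in self.V.items():
            frames.append(pd.DataFrame(
                {"t": self.t, "compartment": lab, "variable": "V", "value": arr}))
        for lab, arr in self.Ca.items():
            frames.append(pd.DataFrame(
                {"t": self.t, "compartment": lab, "variable": "Ca", "value": arr}))
        for lab, arr in self.I_clamp.items():
            frames.append(pd.DataFrame(
                {"t": self.t, "compartment": lab, "variable": "I_clamp",
                 "value": arr}))
        for lab, chans in self.channel_currents.items():
            for name, arr in chans.items():
                frames.append(pd.DataFrame(
                    {"t": self.t, "compartment": lab, "variable": f"I_{name}",
                     "value": arr}))
        for key, arr in self.synapse_states.items():
            frames.append(pd.DataFrame(
                {"t": self.t, "compartment": key, "variable": "s", "value": arr}))
        for lab, chans in self.gbar.items():
            for name, arr in chans.items():
                frames.append(pd.DataFrame(
                    {"t": self.t, "compartment": lab,
                     "variable": f"gbar_{name}", "value": arr}))
        return pd.concat(frames, ignore_index=True)


def initialize(tree: ModelTree, V0: float = -60.0) -> None:
    """Set a startup-transient-free initial condition.

    Every compartment is set to ``V0``, calcium to the mechanism baseline,
    gating variables to their steady states at ``V0`` and synapse
    activations to their steady states at the presynaptic voltage.
    """
    for comp in tree.compartments.values():
        comp.V = V0
        mech = comp.calcium_mech
        comp.Ca = mech.Ca_0 if mech is not None else comp.Ca
        for chan in comp.conductances.values():
            spec = chan.spec
            if spec.p > 0:
                if spec.ca_dependent:
                    chan.m = float(spec.m_inf(np.float64(V0), comp.Ca))
                else:
                    chan.m = float(spec.m_inf(np.float64(V0)))
            if spec.q > 0:
                chan.h = float(spec.h_inf(np.float64(V0)))
    for syn in tree.synapses:
        if isinstance(syn, GradedSynapse):
            vpre = tree.compartments[syn.pre].V
            syn.s = float(1.0 / (1.0 + np.exp((syn.V_half - vpre) / syn.Delta)))


def _dense_drive(value, labels, n_steps, what) -> np.ndarray:
    """Expand per-compartment scalar/series drive into an (ncomp, nsteps) array."""
    out = np.zeros((len(labels), n_steps))
    if value is None:
        return out
    if np.isscalar(value):
        if len(labels) != 1:
            raise ConfigError(
                f"scalar {what} is ambiguous for multi-compartment models; "
                "pass a dict keyed by compartment label")
        value = {labels[0]: value}
    for lab, v in value.items():
        if lab not in labels:
            raise ConfigError(f"{what} refers to unknown compartment {lab!r}")
        i = labels.index(lab)
        v = np.asarray(v, dtype=float)
        if v.ndim == 0:
            out[i, :] = float(v)
        elif v.shape == (n_steps,):
            out[i, :] = v
        else:
            raise ConfigError(
                f"{what}[{lab!r}] must be scalar or length-{n_steps} series")
    return out


def integrate(tree: ModelTree, cfg: SimConfig) -> Trace:
    """Advance the model by ``cfg.t_end`` and return the sampled trace.

    Raises :class:`IntegrationError` with the offending step index if any
    state goes non-finite.
    """
    if not tree.compartments:
        raise ConfigError("cannot integrate an empty model")
    if cfg.solver == "rk4":
        return _integrate_rk4(tree, cfg)
    if cfg.solver == "crank_nicolson":
        return _integrate_cable_cn(tree, cfg)
    return _integrate_exp_euler(tree, cfg)


def _clamp_arrays(tree, cfg, labels, n_steps):
    clamped = np.zeros(len(labels), dtype=np.bool_)
    if not cfg.V_clamp:
        return clamped, np.zeros((len(labels), 1))
    clampV = np.zeros((len(labels), n_steps))
    for lab, v in cfg.V_clamp.items():
        if lab not in labels:
            raise ConfigError(f"V_clamp refers to unknown compartment {lab!r}")
        i = labels.index(lab)
        clamped[i] = True
        v = np.asarray(v, dtype=float)
        clampV[i, :] = float(v) if v.ndim == 0 else v
    return clamped, clampV


def _integrate_exp_euler(tree: ModelTree, cfg: SimConfig) -> Trace:
    full_hash = tree.full_hash()
    cm = compile_model(tree)
    labels = cm.labels
    n_steps = cfg.n_steps
    out_every = cfg.out_every
    n_out = n_steps // out_every

    Iext = _dense_drive(cfg.I_ext, labels, n_steps, "I_ext")
    clamped, clampV = _clamp_arrays(tree, cfg, labels, n_steps)
    if cfg.V_clamp:
        for lab in cfg.V_clamp:
            if np.any(Iext[labels.index(lab)] != 0.0):
                raise ConfigError(
                    f"compartment {lab!r} cannot be clamped and injected")

    ncomp, nchan, nsyn = len(labels), len(cm.chan_refs), len(cm.syn_refs)
    V_out = np.empty((ncomp, n_out))
    Ca_out = np.empty((ncomp, n_out))
    Iclamp_out = np.zeros((ncomp, n_out))
    IC_out = np.zeros((nchan if cfg.record_currents else 1, n_out))
    S_out = np.zeros((nsyn if cfg.record_synapses else 1, n_out))
    G_out = np.zeros((nchan if cfg.record_gbar else 1, n_out))

    fail = run_exp_euler(
        n_steps, cfg.dt, out_every,
        cm.V, cm.Ca, cm.Cm, cm.A,
        clamped, clampV, Iext,
        cm.has_ca, cm.tau_ca, cm.f_ca, cm.ca0, cm.ca_out, cm.nfac,
        cm.ch_comp, cm.ch_gbar, cm.ch_E, cm.ch_p, cm.ch_q, cm.ch_isca,
        cm.ch_cadep, cm.ch_cahalf, cm.ch_tab, cm.ch_m, cm.ch_h,
        cm.tab_minf, cm.tab_taum, cm.tab_hinf, cm.tab_tauh,
        TAB_V0, 1.0 / TAB_DV,
        cm.sy_pre, cm.sy_post, cm.sy_gbar, cm.sy_E, cm.sy_vh, cm.sy_delta,
        cm.sy_km, cm.sy_s,
        cm.el_a, cm.el_b, cm.el_g,
        cm.ct_chan, cm.ct_taum, cm.ct_taug, cm.ct_target, cm.ct_mrna,
        V_out, Ca_out, Iclamp_out,
        cfg.record_currents, IC_out,
        cfg.record_synapses, S_out,
        cfg.record_gbar, G_out,
    )
    if fail >= 0:
        raise IntegrationError(
            f"non-finite state at step {fail} (t = {fail * cfg.dt:.4f} ms)",
            step=int(fail))
    write_back(tree, cm)

    t = cfg.out_dt * np.arange(1, n_out + 1)
    trace = Trace(
        t=t,
        V={lab: V_out[i].copy() for i, lab in enumerate(labels)},
        Ca={lab: Ca_out[i].copy() for i, lab in enumerate(labels)},
        meta={"dt": cfg.dt, "out_dt": cfg.out_dt, "t_end": cfg.t_end,
              "solver": "exp_euler", "full_hash": full_hash},
    )
    for i, lab in enumerate(labels):
        if clamped[i]:
            trace.I_clamp[lab] = Iclamp_out[i].copy()
    if cfg.record_currents:
        for i, (lab, name, _) in enumerate(cm.chan_refs):
            trace.channel_currents.setdefault(lab, {})[name] = IC_out[i].copy()
    if cfg.record_synapses:
        for j, syn in enumerate(cm.syn_refs):
            key = f"{syn.pre}->{syn.post}/{syn.type_name}/{j}"
            trace.synapse_states[key] = S_out[j].copy()
    if cfg.record_gbar:
        for i, (lab, name, _) in enumerate(cm.chan_refs):
            trace.gbar.setdefault(lab, {})[name] = G_out[i].copy()
    return trace


# ---------------------------------------------------------------------------
# RK4 (single compartment)
# ---------------------------------------------------------------------------


def _curves(chan, v, ca):
    """(m_inf, tau_m, h_inf, tau_h) via the same tables the main kernel uses."""
    spec = chan.spec
    row = _curves.rows[chan.type_name]
    minf = np.interp(v, TAB_GRID, row[0])
    if spec.ca_dependent:
        minf *= ca / (ca + spec.ca_half)
    return minf, np.interp(v, TAB_GRID, row[1]), \
        np.interp(v, TAB_GRID, row[2]), np.interp(v, TAB_GRID, row[3])


_curves.rows = {}


def _table_rows_for(tree):
    cm = compile_model(tree)
    rows = {}
    for i, (_, _, chan) in enumerate(cm.chan_refs):
        r = cm.ch_tab[i]
        rows[chan.type_name] = (cm.tab_minf[r], cm.tab_taum[r],
                                cm.tab_hinf[r], cm.tab_tauh[r])
    return rows


def _integrate_rk4(tree: ModelTree, cfg: SimConfig) -> Trace:
    if len(tree.compartments) != 1:
        raise ConfigError("rk4 supports exactly one compartment")
    if tree.synapses:
        raise ConfigError("rk4 does not support synapses")
    if cfg.V_clamp:
        raise ConfigError("rk4 does not support voltage clamp")
    full_hash = tree.full_hash()
    (lab, comp), = tree.compartments.items()
    chans = sorted(comp.conductances.items())
    mech = comp.calcium_mech
    _curves.rows = _table_rows_for(tree)

    n_steps = cfg.n_steps
    out_every = cfg.out_every
    n_out = n_steps // out_every
    Iext = _dense_drive(cfg.I_ext, [lab], n_steps, "I_ext")[0]

    # state vector: [V, Ca, m..., h...]
    names = []
    y = [comp.V, comp.Ca]
    for name, c in chans:
        if c.spec.p > 0:
            y.append(c.m)
            names.append((name, "m"))
        if c.spec.q > 0:
            y.append(c.h)
            names.append((name, "h"))
    y = np.array(y, dtype=float)
    A, Cm = comp.A, comp.Cm

    def rhs(y, inj):
        v, ca = y[0], y[1]
        dy = np.zeros_like(y)
        k = 2
        gsum = 0.0
        gEsum = 0.0
        i_ca = 0.0
        for name, c in chans:
            spec = c.spec
            minf, taum, hinf, tauh = _curves(c, v, ca)
            g = c.gbar
            if spec.p > 0:
                m = y[k]
                dy[k] = (minf - m) / taum
                g *= m ** spec.p
                k += 1
            if spec.q > 0:
                h = y[k]
                dy[k] = (hinf - h) / tauh
                g *= h ** spec.q
                k += 1
            if spec.is_calcium and mech is not None:
                e = mech.nernst_factor * np.log(mech.Ca_out / max(ca, 1e-12))
            else:
                e = c.E
            gsum += g
            gEsum += g * e
            if spec.is_calcium:
                i_ca += g * (v - e) * A
        dy[0] = (gEsum - gsum * v + inj / A) / Cm
        if mech is not None:
            dy[1] = (mech.Ca_0 - mech.f * i_ca - ca) / mech.tau_Ca
        return dy

    dt = cfg.dt
    V_out = np.empty(n_out)
    Ca_out = np.empty(n_out)
    for t in range(n_steps):
        inj = Iext[t]
        k1 = rhs(y, inj)
        k2 = rhs(y + 0.5 * dt * k1, inj)
        k3 = rhs(y + 0.5 * dt * k2, inj)
        k4 = rhs(y + dt * k3, inj)
        y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(y)):
            raise IntegrationError(f"non-finite state at step {t}", step=t)
        for _, c in chans:
            if c.controller is not None:
                # controllers are slow; a forward-Euler sub-step suffices
                c.controller.mRNA, c.gbar = controller_step(
                    c.controller, y[1], c.gbar, dt)
        if (t + 1) % out_every == 0:
            o = (t + 1) // out_every - 1
            V_out[o] = y[0]
            Ca_out[o] = y[1]

    comp.V = float(y[0])
    comp.Ca = float(y[1])
    k = 2
    for name, c in chans:
        if c.spec.p > 0:
            c.m = float(np.clip(y[k], 0.0, 1.0))
            k += 1
        if c.spec.q > 0:
            c.h = float(np.clip(y[k], 0.0, 1.0))
            k += 1

    t_arr = cfg.out_dt * np.arange(1, n_out + 1)
    return Trace(t=t_arr, V={lab: V_out}, Ca={lab: Ca_out},
                 meta={"dt": cfg.dt, "out_dt": cfg.out_dt, "t_end": cfg.t_end,
                       "solver": "rk4", "full_hash": full_hash})


# ---------------------------------------------------------------------------
# Crank-Nicolson cable (unbranched chain, insertion order)
# ---------------------------------------------------------------------------


def axial_conductances(tree: ModelTree) -> np.ndarray:
    """Axial coupling conductances (uS) between successive compartments.

    Compartments are taken as an unbranched chain in insertion order; each
    needs cylinder geometry (radius, length in mm).  The series resistance
    between centres i and i+1 is Ra*(l_i/2)/(pi r_i^2) + Ra*(l_j/2)/(pi r_j^2)
    with Ra the tree's axial resistivity (ohm*cm).
    """
    comps = list(tree.compartments.values())
    ra = tree.axial_resistivity  # ohm*cm
    g = np.zeros(len(comps) - 1)
    for i in range(len(comps) - 1):
        a, b = comps[i], comps[i + 1]
        for c in (a, b):
            if c.radius is None or c.length is None:
                raise ConfigError(
                    f"compartment {c.label!r} lacks cable geometry "
                    "(radius/length)")
        # 1 ohm*cm * mm/mm^2 = 10 ohm -> R in Mohm = 1e-5 * Ra * l / area
        r_half = (1e-5 * ra * (a.length / 2) / (np.pi * a.radius**2)
                  + 1e-5 * ra * (b.length / 2) / (np.pi * b.radius**2))
        g[i] = 1.0 / r_half  # uS (since mV/Mohm = nA)
    return g


def _integrate_cable_cn(tree: ModelTree, cfg: SimConfig) -> Trace:
    if len(tree.compartments) < 2:
        raise ConfigError("crank_nicolson needs at least two compartments")
    if tree.synapses:
        raise ConfigError("crank_nicolson supports chains without synapses")
    if cfg.V_clamp:
        raise ConfigError("voltage clamp is not supported for cables")
    full_hash = tree.full_hash()
    labels = list(tree.compartments)
    comps = [tree.compartments[lab] for lab in labels]
    n = len(comps)
    g_ax = axial_conductances(tree)  # uS
    _curves.rows = _table_rows_for(tree)

    n_steps = cfg.n_steps
    out_every = cfg.out_every
    n_out = n_steps // out_every
    Iext = _dense_drive(cfg.I_ext, labels, n_steps, "I_ext")

    V = np.array([c.V for c in comps])
    Ca = np.array([c.Ca for c in comps])
    CmA = np.array([c.Cm * c.A for c in comps])  # nF
    A = np.array([c.A for c in comps])
    dt = cfg.dt

    V_out = np.empty((n, n_out))
    Ca_out = np.empty((n, n_out))
    ab = np.zeros((3, n))

    for t in range(n_steps):
        gsum = np.zeros(n)
        gEsum = np.zeros(n)
        ica = np.zeros(n)
        for i, comp in enumerate(comps):
            mech = comp.calcium_mech
            for name, c in sorted(comp.conductances.items()):
                spec = c.spec
                if spec.p > 0 or spec.q > 0:
                    minf, taum, hinf, tauh = _curves(c, V[i], Ca[i])
                    if spec.p > 0:
                        c.m = minf + (c.m - minf) * np.exp(-dt / taum)
                    if spec.q > 0:
                        c.h = hinf + (c.h - hinf) * np.exp(-dt / tauh)
                g = c.gbar * c.m ** spec.p * c.h ** spec.q
                if spec.is_calcium and mech is not None:
                    e = mech.nernst_factor * np.log(
                        mech.Ca_out / max(Ca[i], 1e-12))
                else:
                    e = c.E
                gsum[i] += g
                gEsum[i] += g * e
                if spec.is_calcium:
                    ica[i] += g * (V[i] - e) * A[i]

        # tridiagonal CN system: (C/dt - L/2) V+ = (C/dt + L/2) V + b
        # L in uS: diagonal -(A*gsum + axial), off-diagonals +g_ax; b in nA
        diag = -(A * gsum)
        diag[:-1] -= g_ax
        diag[1:] -= g_ax
        b = A * gEsum + Iext[:, t]
        lhs_diag = CmA / dt - diag / 2
        rhs = (CmA / dt + diag / 2) * V + b
        rhs[:-1] += (g_ax / 2) * V[1:]
        rhs[1:] += (g_ax / 2) * V[:-1]
        ab[0, 1:] = -g_ax / 2
        ab[1, :] = lhs_diag
        ab[2, :-1] = -g_ax / 2
        V = scipy.linalg.solve_banded((1, 1), ab, rhs)
        if not np.all(np.isfinite(V)):
            raise IntegrationError(f"non-finite voltage at step {t}", step=t)

        for i, comp in enumerate(comps):
            mech = comp.calcium_mech
            if mech is not None:
                Ca[i] = calcium_step(mech, Ca[i], ica[i], dt)
            for c in comp.conductances.values():
                if c.controller is not None:
                    c.controller.mRNA, c.gbar = controller_step(
                        c.controller, Ca[i], c.gbar, dt)

        if (t + 1) % out_every == 0:
            o = (t + 1) // out_every - 1
            V_out[:, o] = V
            Ca_out[:, o] = Ca

    for i, comp in enumerate(comps):
        comp.V = float(V[i])
        comp.Ca = float(Ca[i])

    t_arr = cfg.out_dt * np.arange(1, n_out + 1)
    return Trace(
        t=t_arr,
        V={lab: V_out[i].copy() for i, lab in enumerate(labels)},
        Ca={lab: Ca_out[i].copy() for i, lab in enumerate(labels)},
        meta={"dt": cfg.dt, "out_dt": cfg.out_dt, "t_end": cfg.t_end,
              "solver": "crank_nicolson", "full_hash": full_hash})
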