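"""Internal simulation core: flattened model arrays and the jit inner loop.

The exponential-Euler integrator runs over a flat structure-of-arrays view
of the model: one slot per channel instance across all compartments, with
gating curves pre-tabulated on a fine voltage grid (0.02 mV, linear
interpolation) so that arbitrary registered channel types all run through
the same compiled kernel.  Calcium-gated activations are stored as their
voltage factor; the Ca/(Ca + K) factor is applied in the kernel.

Update order within one step (synchronous: all reads use the previous
step's values across compartments):
synapse states -> calcium reversal -> gating states -> voltage -> calcium
mechanism -> integral controllers -> output sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .component_tree import ModelTree
from .registry import get_channel_type
from .synapses import ElectricalSynapse, GradedSynapse

# gating-curve tabulation grid
TAB_V0 = -150.0
TAB_V1 = 100.0
TAB_DV = 0.02
TAB_GRID = np.arange(TAB_V0, TAB_V1 + TAB_DV / 2, TAB_DV)


@dataclass
class CompiledModel:
    """Flattened arrays for the kernel plus back-references for write-back."""

    labels: list
    V: np.ndarray
    Ca: np.ndarray
    Cm: np.ndarray
    A: np.ndarray
    has_ca: np.ndarray
    tau_ca: np.ndarray
    f_ca: np.ndarray
    ca0: np.ndarray
    ca_out: np.ndarray
    nfac: np.ndarray
    ch_comp: np.ndarray
    ch_gbar: np.ndarray
    ch_E: np.ndarray
    ch_p: np.ndarray
    ch_q: np.ndarray
    ch_isca: np.ndarray
    ch_cadep: np.ndarray
    ch_cahalf: np.ndarray
    ch_tab: np.ndarray
    ch_m: np.ndarray
    ch_h: np.ndarray
    tab_minf: np.ndarray
    tab_taum: np.ndarray
    tab_hinf: np.ndarray
    tab_tauh: np.ndarray
    sy_pre: np.ndarray
    sy_post: np.ndarray
    sy_gbar: np.ndarray
    sy_E: np.ndarray
    sy_vh: np.ndarray
    sy_delta: np.ndarray
    sy_km: np.ndarray
    sy_s: np.ndarray
    el_a: np.ndarray
    el_b: np.ndarray
    el_g: np.ndarray
    ct_chan: np.ndarray
    ct_taum: np.ndarray
    ct_taug: np.ndarray
    ct_target: np.ndarray
    ct_mrna: np.ndarray
    chan_refs: list = field(default_factory=list)  # (comp_label, chan_name, instance)
    syn_refs: list = field(default_factory=list)
    ctrl_refs: list = field(default_factory=list)


def compile_model(tree: ModelTree) -> CompiledModel:
    # canonical (sorted) ordering: accumulation order, and hence the trace,
    # is independent of the order in which the model was built
    labels = sorted(tree.compartments)
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    comps = [tree.compartments[lab] for lab in labels]

    V = np.array([c.V for c in comps])
    Ca = np.array([c.Ca for c in comps])
    Cm = np.array([c.Cm for c in comps])
    A = np.array([c.A for c in comps])
    has_ca = np.zeros(n, dtype=np.bool_)
    tau_ca = np.ones(n)
    f_ca = np.zeros(n)
    ca0 = np.zeros(n)
    ca_out = np.ones(n)
    nfac = np.zeros(n)
    for i, c in enumerate(comps):
        mech = c.calcium_mech
        if mech is not None:
            has_ca[i] = True
            tau_ca[i] = mech.tau_Ca
            f_ca[i] = mech.f
            ca0[i] = mech.Ca_0
            ca_out[i] = mech.Ca_out
            nfac[i] = mech.nernst_factor

    # channels: one flat slot per instance; tables keyed per type
    type_rows: dict[str, int] = {}
    tab_rows: list[tuple] = []

    def table_row(type_name: str) -> int:
        if type_name in type_rows:
            return type_rows[type_name]
        spec = get_channel_type(type_name).spec
        v = TAB_GRID
        zero = np.zeros_like(v)
        one = np.ones_like(v)
        if spec.p > 0:
            if spec.ca_dependent:
                # separable Ca-gated activation: voltage factor recovered at
                # Ca == ca_half where Ca/(Ca+K) == 1/2
                minf = 2.0 * np.asarray(spec.m_inf(v, spec.ca_half), dtype=float)
            else:
                minf = np.asarray(spec.m_inf(v), dtype=float)
            taum = np.asarray(spec.tau_m(v), dtype=float)
        else:
            minf, taum = zero, one
        if spec.q > 0:
            hinf = np.asarray(spec.h_inf(v), dtype=float)
            tauh = np.asarray(spec.tau_h(v), dtype=float)
        else:
            hinf, tauh = one, one
        type_rows[type_name] = len(tab_rows)
        tab_rows.append((minf, taum, hinf, tauh))
        return type_rows[type_name]

    chan_refs = []
    ctrl_refs = []
    for lab, comp in zip(labels, comps):
        for name in sorted(comp.conductances):
            chan = comp.conductances[name]
            chan_refs.append((lab, name, chan))
            if chan.controller is not None:
                ctrl_refs.append((len(chan_refs) - 1, chan.controller))

    nch = len(chan_refs)
    ch_comp = np.zeros(nch, dtype=np.int64)
    ch_gbar = np.zeros(nch)
    ch_E = np.zeros(nch)
    ch_p = np.zeros(nch, dtype=np.int64)
    ch_q = np.zeros(nch, dtype=np.int64)
    ch_isca = np.zeros(nch, dtype=np.bool_)
    ch_cadep = np.zeros(nch, dtype=np.bool_)
    ch_cahalf = np.full(nch, 3.0)
    ch_tab = np.zeros(nch, dtype=np.int64)
    ch_m = np.zeros(nch)
    ch_h = np.ones(nch)
    for i, (lab, name, chan) in enumerate(chan_refs):
        spec = chan.spec
        ch_comp[i] = idx[lab]
        ch_gbar[i] = chan.gbar
        ch_E[i] = chan.E
        ch_p[i] = spec.p
        ch_q[i] = spec.q
        ch_isca[i] = spec.is_calcium
        ch_cadep[i] = spec.ca_dependent
        ch_cahalf[i] = spec.ca_half
        ch_tab[i] = table_row(chan.type_name)
        ch_m[i] = chan.m
        ch_h[i] = chan.h

    ntab = max(len(tab_rows), 1)
    ngrid = TAB_GRID.size
    tab_minf = np.zeros((ntab, ngrid))
    tab_taum = np.ones((ntab, ngrid))
    tab_hinf = np.ones((ntab, ngrid))
    tab_tauh = np.ones((ntab, ngrid))
    for r, (mi, tm, hi, th) in enumerate(tab_rows):
        tab_minf[r] = mi
        tab_taum[r] = tm
        tab_hinf[r] = hi
        tab_tauh[r] = th

    graded = sorted(
        (s for s in tree.synapses if isinstance(s, GradedSynapse)),
        key=lambda s: (s.pre, s.post, s.type_name))
    electr = sorted(
        (s for s in tree.synapses if isinstance(s, ElectricalSynapse)),
        key=lambda s: (s.a, s.b))
    nsy = len(graded)
    sy_pre = np.array([idx[s.pre] for s in graded], dtype=np.int64)
    sy_post = np.array([idx[s.post] for s in graded], dtype=np.int64)
    sy_gbar = np.array([s.gbar for s in graded], dtype=np.float64)
    sy_E = np.array([s.E_syn for s in graded], dtype=np.float64)
    sy_vh = np.array([s.V_half for s in graded], dtype=np.float64)
    sy_delta = np.array([s.Delta for s in graded], dtype=np.float64)
    sy_km = np.array([s.k_minus for s in graded], dtype=np.float64)
    sy_s = np.array([s.s for s in graded], dtype=np.float64)
    el_a = np.array([idx[s.a] for s in electr], dtype=np.int64)
    el_b = np.array([idx[s.b] for s in electr], dtype=np.int64)
    el_g = np.array([s.g for s in electr], dtype=np.float64)

    nct = len(ctrl_refs)
    ct_chan = np.array([i for i, _ in ctrl_refs], dtype=np.int64)
    ct_taum = np.array([c.tau_m for _, c in ctrl_refs], dtype=np.float64)
    ct_taug = np.array([c.tau_g for _, c in ctrl_refs], dtype=np.float64)
    ct_target = np.array([c.Ca_target for _, c in ctrl_refs], dtype=np.float64)
    ct_mrna = np.array([c.mRNA for _, c in ctrl_refs], dtype=np.float64)

    return CompiledModel(
        labels=labels, V=V, Ca=Ca, Cm=Cm, A=A,
        has_ca=has_ca, tau_ca=tau_ca, f_ca=f_ca, ca0=ca0, ca_out=ca_out,
        nfac=nfac,
        ch_comp=ch_comp, ch_gbar=ch_gbar, ch_E=ch_E, ch_p=ch_p, ch_q=ch_q,
        ch_isca=ch_isca, ch_cadep=ch_cadep, ch_cahalf=ch_cahalf,
        ch_tab=ch_tab, ch_m=ch_m, ch_h=ch_h,
        tab_minf=tab_minf, tab_taum=tab_taum, tab_hinf=tab_hinf,
        tab_tauh=tab_tauh,
        sy_pre=sy_pre, sy_post=sy_post, sy_gbar=sy_gbar, sy_E=sy_E,
        sy_vh=sy_vh, sy_delta=sy_delta, sy_km=sy_km, sy_s=sy_s,
        el_a=el_a, el_b=el_b, el_g=el_g,
        ct_chan=ct_chan, ct_taum=ct_taum, ct_taug=ct_taug,
        ct_target=ct_target, ct_mrna=ct_mrna,
        chan_refs=chan_refs, syn_refs=graded, ctrl_refs=ctrl_refs,
    )


def write_back(tree: ModelTree, cm: CompiledModel) -> None:
    """Copy evolved state from the flat arrays back into the object tree."""
    for i, lab in enumerate(cm.labels):
        comp = tree.compartments[lab]
        comp.V = float(cm.V[i])
        comp.Ca = float(cm.Ca[i])
    for i, (_, _, chan) in enumerate(cm.chan_refs):
        chan.m = float(cm.ch_m[i])
        chan.h = float(cm.ch_h[i])
        chan.gbar = float(cm.ch_gbar[i])
    for j, syn in enumerate(cm.syn_refs):
        syn.s = float(cm.sy_s[j])
    for k, (_, ctrl) in enumerate(cm.ctrl_refs):
        ctrl.mRNA = float(cm.ct_mrna[k])


@njit(cache=True)
def _interp(tab, row, x):
    # x is the fractional grid coordinate, clamped to the table edges
    n = tab.shape[1]
    if x <= 0.0:
        return tab[row, 0]
    if x >= n - 1:
        return tab[row, n - 1]
    i = int(x)
    f = x - i
    return tab[row, i] * (1.0 - f) + tab[row, i + 1] * f


@njit(cache=True)
def run_exp_euler(
    nsteps, dt, out_every,
    V, Ca, Cm, A,
    clamped, clampV, Iext,
    has_ca, tau_ca, f_ca, ca0, ca_out, nfac,
    ch_comp, ch_gbar, ch_E, ch_p, ch_q, ch_isca, ch_cadep, ch_cahalf,
    ch_tab, ch_m, ch_h,
    tab_minf, tab_taum, tab_hinf, tab_tauh, tab_v0, tab_dv_inv,
    sy_pre, sy_post, sy_gbar, sy_E, sy_vh, sy_delta, sy_km, sy_s,
    el_a, el_b, el_g,
    ct_chan, ct_taum, ct_taug, ct_target, ct_mrna,
    V_out, Ca_out, Iclamp_out,
    rec_curr, IC_out, rec_syn, S_out, rec_gbar, G_out,
):
    ncomp = V.shape[0]
    nchan = ch_comp.shape[0]
    nsyn = sy_pre.shape[0]
    nel = el_a.shape[0]
    nctrl = ct_chan.shape[0]

    Vprev = np.empty(ncomp)
    gsum = np.empty(ncomp)
    gEsum = np.empty(ncomp)
    ica = np.empty(ncomp)
    e_use = np.empty(nchan)
    geff = np.empty(nchan)
    any_clamp = False
    for c in range(ncomp):
        if clamped[c]:
            any_clamp = True

    for t in range(nsteps):
        for c in range(ncomp):
            Vprev[c] = V[c]
            gsum[c] = 0.0
            gEsum[c] = 0.0
            ica[c] = 0.0

        # graded synapse activation (reads presynaptic V from previous step)
        for j in range(nsyn):
            vpre = Vprev[sy_pre[j]]
            sinf = 1.0 / (1.0 + math.exp((sy_vh[j] - vpre) / sy_delta[j]))
            tau = (1.0 - sinf) / sy_km[j]
            if tau < dt:
                tau = dt
            sy_s[j] = sinf + (sy_s[j] - sinf) * math.exp(-dt / tau)

        # reversal potentials (Nernst for calcium channels with a mechanism)
        for i in range(nchan):
            c = ch_comp[i]
            if ch_isca[i] and has_ca[c]:
                cav = Ca[c]
                if cav < 1e-12:
                    cav = 1e-12
                e_use[i] = nfac[c] * math.log(ca_out[c] / cav)
            else:
                e_use[i] = ch_E[i]

        # gating (exponential Euler toward tabulated steady states)
        for i in range(nchan):
            c = ch_comp[i]
            x = (Vprev[c] - tab_v0) * tab_dv_inv
            r = ch_tab[i]
            if ch_p[i] > 0:
                minf = _interp(tab_minf, r, x)
                if ch_cadep[i]:
                    minf *= Ca[c] / (Ca[c] + ch_cahalf[i])
                taum = _interp(tab_taum, r, x)
                ch_m[i] = minf + (ch_m[i] - minf) * math.exp(-dt / taum)
            if ch_q[i] > 0:
                hinf = _interp(tab_hinf, r, x)
                tauh = _interp(tab_tauh, r, x)
                ch_h[i] = hinf + (ch_h[i] - hinf) * math.exp(-dt / tauh)

        # effective conductance densities and calcium current (pre-update V)
        for i in range(nchan):
            g = ch_gbar[i]
            for _ in range(ch_p[i]):
                g *= ch_m[i]
            for _ in range(ch_q[i]):
                g *= ch_h[i]
            geff[i] = g
            c = ch_comp[i]
            gsum[c] += g
            gEsum[c] += g * e_use[i]
            if ch_isca[i]:
                ica[c] += g * (Vprev[c] - e_use[i]) * A[c]

        # synaptic conductances folded into the voltage update
        for j in range(nsyn):
            c = sy_post[j]
            gs = sy_gbar[j] * sy_s[j] * 1e-3 / A[c]
            gsum[c] += gs
            gEsum[c] += gs * sy_E[j]
        for j in range(nel):
            a = el_a[j]
            b = el_b[j]
            g = el_g[j] * 1e-3
            gsum[a] += g / A[a]
            gEsum[a] += (g / A[a]) * Vprev[b]
            gsum[b] += g / A[b]
            gEsum[b] += (g / A[b]) * Vprev[a]

        # membrane potential
        for c in range(ncomp):
            if clamped[c]:
                V[c] = clampV[c, t]
            else:
                inj = Iext[c, t] / A[c]
                if gsum[c] > 0.0:
                    vinf = (gEsum[c] + inj) / gsum[c]
                    V[c] = vinf + (V[c] - vinf) * math.exp(-dt * gsum[c] / Cm[c])
                else:
                    V[c] += dt * inj / Cm[c]
            if not math.isfinite(V[c]):
                return t

        # calcium buffering (mechanisms run after the voltage step)
        for c in range(ncomp):
            if has_ca[c]:
                ca_inf = ca0[c] - f_ca[c] * ica[c]
                canew = ca_inf + (Ca[c] - ca_inf) * math.exp(-dt / tau_ca[c])
                if canew < 0.0:
                    canew = 0.0
                Ca[c] = canew
            if not math.isfinite(Ca[c]):
                return t

        # integral controllers (see the calcium value updated this step)
        for k in range(nctrl):
            i = ct_chan[k]
            c = ch_comp[i]
            g = ch_gbar[i]
            gnew = g + dt * (ct_mrna[k] - g) / ct_taug[k]
            if gnew < 0.0:
                gnew = 0.0
            ct_mrna[k] += dt * (ct_target[k] - Ca[c]) / ct_taum[k]
            ch_gbar[i] = gnew

        # output sampling
        if (t + 1) % out_every == 0:
            o = (t + 1) // out_every - 1
            for c in range(ncomp):
                V_out[c, o] = V[c]
                Ca_out[c, o] = Ca[c]
            if any_clamp or rec_curr:
                for c in range(ncomp):
                    Iclamp_out[c, o] = 0.0
                for i in range(nchan):
                    c = ch_comp[i]
                    cur = geff[i] * (V[c] - e_use[i]) * A[c]
                    Iclamp_out[c, o] += cur
                    if rec_curr:
                        IC_out[i, o] = cur
                for j in range(nsyn):
                    c = sy_post[j]
                    Iclamp_out[c, o] += sy_gbar[j] * sy_s[j] * (V[c] - sy_E[j]) * 1e-3
                for j in range(nel):
                    a = el_a[j]
                    b = el_b[j]
                    cur = el_g[j] * (V[b] - V[a]) * 1e-3
                    Iclamp_out[a, o] -= cur
                    Iclamp_out[b, o] += cur
            if rec_syn:
                for j in range(nsyn):
                    S_out[j, o] = sy_s[j]
            if rec_gbar:
                for i in range(nchan):
                    G_out[i, o] = ch_gbar[i]
    return -1
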