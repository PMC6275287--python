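"""Model configuration files and trace persistence.

Models are stored as YAML: human-auditable, diff-able, with a strict schema
(unknown keys are rejected with the offending path) and a canonical writer
(sorted keys) so that save(load(f)) is byte-identical for canonical files.
Traces go to HDF5 (default) or tidy CSV, chosen by file extension; both
embed the generating model's full hash for provenance.
"""

from __future__ import annotations

import io as _io
import os

import numpy as np
import yaml

from .component_tree import Compartment, ModelTree
from .errors import ValidationError
from .integrators import Trace
from .mechanisms import CalciumMech, IntegralController
from .registry import get_channel_type, get_synapse_type
from .synapses import ElectricalSynapse, GradedSynapse

__all__ = ["load_model", "save_model", "loads_model", "dumps_model",
           "write_trace", "read_trace", "validate_trace"]

_COMP_PARAMS = ("V", "Ca", "A", "Cm", "radius", "length")
_CHAN_PARAMS = ("gbar", "E", "m", "h")
_CTRL_PARAMS = ("tau_m", "tau_g", "Ca_target", "mRNA")
_CAMECH_PARAMS = ("tau_Ca", "f", "Ca_0", "Ca_out", "T")
_GRADED_PARAMS = ("gbar", "E_syn", "V_half", "Delta", "k_minus", "s")
_SIM_KEYS = ("dt", "out_dt", "t_end", "solver")


def _reject_unknown(mapping: dict, allowed, where: str) -> None:
    unknown = set(mapping) - set(allowed)
    if unknown:
        raise ValidationError(
            f"unknown key(s) {sorted(unknown)} at {where}")


def _require_map(obj, where: str) -> dict:
    if not isinstance(obj, dict):
        raise ValidationError(f"expected a mapping at {where}")
    return obj


def loads_model(text: str) -> ModelTree:
    doc = yaml.safe_load(text)
    doc = _require_map(doc, "top level")
    _reject_unknown(doc, ("compartments", "synapses", "simulation",
                          "axial_resistivity"), "top level")
    tree = ModelTree(axial_resistivity=float(doc.get("axial_resistivity", 100.0)))
    comps = _require_map(doc.get("compartments", {}), "compartments")
    for lab, entry in comps.items():
        entry = _require_map(entry or {}, f"compartments/{lab}")
        _reject_unknown(entry, ("params", "channels", "mechanisms"),
                        f"compartments/{lab}")
        params = _require_map(entry.get("params", {}) or {},
                              f"compartments/{lab}/params")
        _reject_unknown(params, _COMP_PARAMS, f"compartments/{lab}/params")
        tree.add_compartment(lab, **{k: float(v) for k, v in params.items()})
        chans = _require_map(entry.get("channels", {}) or {},
                             f"compartments/{lab}/channels")
        for name, centry in chans.items():
            where = f"compartments/{lab}/channels/{name}"
            centry = _require_map(centry or {}, where)
            _reject_unknown(centry, ("type", "params", "controller"), where)
            type_name = centry.get("type", name)
            get_channel_type(type_name)  # error names the type
            cparams = _require_map(centry.get("params", {}) or {},
                                   f"{where}/params")
            _reject_unknown(cparams, _CHAN_PARAMS, f"{where}/params")
            tree.add_channel(lab, type_name, name=name,
                             **{k: float(v) for k, v in cparams.items()})
            if "controller" in centry:
                ctrl = _require_map(centry["controller"] or {},
                                    f"{where}/controller")
                _reject_unknown(ctrl, _CTRL_PARAMS, f"{where}/controller")
                tree.add_controller(lab, name,
                                    **{k: float(v) for k, v in ctrl.items()})
        mechs = entry.get("mechanisms", []) or []
        if not isinstance(mechs, list):
            raise ValidationError(
                f"expected a list at compartments/{lab}/mechanisms")
        for i, mentry in enumerate(mechs):
            where = f"compartments/{lab}/mechanisms[{i}]"
            mentry = _require_map(mentry or {}, where)
            _reject_unknown(mentry, ("type", "params"), where)
            if mentry.get("type") != "CalciumMech":
                raise ValidationError(
                    f"unknown mechanism type {mentry.get('type')!r} at {where}")
            mparams = _require_map(mentry.get("params", {}) or {},
                                   f"{where}/params")
            _reject_unknown(mparams, _CAMECH_PARAMS, f"{where}/params")
            tree.add_calcium_mech(lab, **{k: float(v)
                                          for k, v in mparams.items()})
    syns = doc.get("synapses", []) or []
    if not isinstance(syns, list):
        raise ValidationError("expected a list at synapses")
    for i, sentry in enumerate(syns):
        where = f"synapses[{i}]"
        sentry = dict(_require_map(sentry or {}, where))
        typ = sentry.pop("type", None)
        if typ == "Electrical":
            _reject_unknown(sentry, ("a", "b", "g"), where)
            tree.connect(sentry["a"], sentry["b"], "Electrical",
                         g=float(sentry.get("g", 0.0)))
        else:
            get_synapse_type(typ)
            _reject_unknown(sentry, ("pre", "post") + _GRADED_PARAMS, where)
            pre, post = sentry.pop("pre"), sentry.pop("post")
            tree.connect(pre, post, typ,
                         **{k: float(v) for k, v in sentry.items()})
    sim = doc.get("simulation")
    if sim is not None:
        sim = _require_map(sim, "simulation")
        _reject_unknown(sim, _SIM_KEYS, "simulation")
        tree.sim_defaults = dict(sim)
    return tree


def dumps_model(tree: ModelTree) -> str:
    """Canonical YAML text: sorted labels and keys, full explicit state."""
    comps = {}
    for lab in sorted(tree.compartments):
        comp = tree.compartments[lab]
        params = {"A": comp.A, "Ca": comp.Ca, "Cm": comp.Cm, "V": comp.V}
        if comp.radius is not None:
            params["radius"] = comp.radius
        if comp.length is not None:
            params["length"] = comp.length
        entry: dict = {"params": dict(sorted(params.items()))}
        if comp.conductances:
            chans = {}
            for name in sorted(comp.conductances):
                chan = comp.conductances[name]
                spec = chan.spec
                cparams = {"E": chan.E, "gbar": chan.gbar}
                if spec.p > 0:
                    cparams["m"] = chan.m
                if spec.q > 0:
                    cparams["h"] = chan.h
                centry = {"type": chan.type_name,
                          "params": dict(sorted(cparams.items()))}
                if chan.controller is not None:
                    c = chan.controller
                    centry["controller"] = {
                        "Ca_target": c.Ca_target, "mRNA": c.mRNA,
                        "tau_g": c.tau_g, "tau_m": c.tau_m}
                chans[name] = centry
            entry["channels"] = chans
        mech = comp.calcium_mech
        if mech is not None:
            entry["mechanisms"] = [{
                "type": "CalciumMech",
                "params": {"Ca_0": mech.Ca_0, "Ca_out": mech.Ca_out,
                           "T": mech.T, "f": mech.f, "tau_Ca": mech.tau_Ca}}]
        comps[lab] = entry
    doc: dict = {"axial_resistivity": tree.axial_resistivity,
                 "compartments": comps}
    if tree.synapses:
        entries = []
        for syn in tree.synapses:
            if isinstance(syn, ElectricalSynapse):
                entries.append({"type": "Electrical", "a": syn.a, "b": syn.b,
                                "g": syn.g})
            else:
                entries.append({
                    "type": syn.type_name, "pre": syn.pre, "post": syn.post,
                    "Delta": syn.Delta, "E_syn": syn.E_syn,
                    "V_half": syn.V_half, "gbar": syn.gbar,
                    "k_minus": syn.k_minus, "s": syn.s})
        entries.sort(key=lambda e: (e.get("pre", e.get("a", "")),
                                    e.get("post", e.get("b", "")),
                                    e["type"]))
        doc["synapses"] = entries
    if getattr(tree, "sim_defaults", None):
        doc["simulation"] = dict(sorted(tree.sim_defaults.items()))

    def _py(x):
        if isinstance(x, dict):
            return {k: _py(v) for k, v in x.items()}
        if isinstance(x, list):
            return [_py(v) for v in x]
        if isinstance(x, (np.floating, np.integer)):
            return x.item()
        return x

    return yaml.safe_dump(_py(doc), sort_keys=False, default_flow_style=False)


def load_model(path: str | os.PathLike) -> ModelTree:
    with open(path) as fh:
        return loads_model(fh.read())


def save_model(tree: ModelTree, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(dumps_model(tree))


# ---------------------------------------------------------------------------
# trace persistence
# ---------------------------------------------------------------------------


def write_trace(trace: Trace, path: str | os.PathLike) -> None:
    """Write a trace to HDF5 (.h5/.hdf5) or tidy CSV (.csv)."""
    path = os.fspath(path)
    if path.endswith(".csv"):
        _write_trace_csv(trace, path)
    else:
        _write_trace_h5(trace, path)


def read_trace(path: str | os.PathLike) -> Trace:
    path = os.fspath(path)
    if path.endswith(".csv"):
        return _read_trace_csv(path)
    return _read_trace_h5(path)


def validate_trace(trace: Trace, tree: ModelTree) -> bool:
    """True iff the trace was produced by a model with this full hash."""
    return trace.meta.get("full_hash") == tree.full_hash()


def _write_trace_h5(trace: Trace, path: str) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        for k, v in trace.meta.items():
            f.attrs[k] = v
        f.create_dataset("t", data=trace.t)
        for group, data in (("V", trace.V), ("Ca", trace.Ca),
                            ("I_clamp", trace.I_clamp),
                            ("synapse_states", trace.synapse_states)):
            g = f.create_group(group)
            for lab, arr in data.items():
                g.create_dataset(lab, data=arr)
        for group, data in (("channel_currents", trace.channel_currents),
                            ("gbar", trace.gbar)):
            g = f.create_group(group)
            for lab, chans in data.items():
                gg = g.create_group(lab)
                for name, arr in chans.items():
                    gg.create_dataset(name, data=arr)


def _read_trace_h5(path: str) -> Trace:
    import h5py

    with h5py.File(path, "r") as f:
        meta = {k: (v.item() if isinstance(v, np.generic) else v)
                for k, v in f.attrs.items()}
        tr = Trace(t=f["t"][:], V={}, Ca={}, meta=meta)
        for group, target in (("V", tr.V), ("Ca", tr.Ca),
                              ("I_clamp", tr.I_clamp),
                              ("synapse_states", tr.synapse_states)):
            for lab in f.get(group, {}):
                target[lab] = f[group][lab][:]
        for group, target in (("channel_currents", tr.channel_currents),
                              ("gbar", tr.gbar)):
            for lab in f.get(group, {}):
                target[lab] = {name: f[group][lab][name][:]
                               for name in f[group][lab]}
    return tr


def _write_trace_csv(trace: Trace, path: str) -> None:
    buf = _io.StringIO()
    for k, v in sorted(trace.meta.items()):
        buf.write(f"# {k}: {v!r}\n")
    buf.write("t,compartment,variable,value\n")

    def emit(lab, var, arr):
        for t, v in zip(trace.t, arr):
            buf.write(f"{float(t)!r},{lab},{var},{float(v)!r}\n")

    for lab, arr in trace.V.items():
        emit(lab, "V", arr)
    for lab, arr in trace.Ca.items():
        emit(lab, "Ca", arr)
    for lab, arr in trace.I_clamp.items():
        emit(lab, "I_clamp", arr)
    for key, arr in trace.synapse_states.items():
        emit(key, "s", arr)
    for lab, chans in trace.channel_currents.items():
        for name, arr in chans.items():
            emit(lab, f"I_{name}", arr)
    for lab, chans in trace.gbar.items():
        for name, arr in chans.items():
            emit(lab, f"gbar_{name}", arr)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def _read_trace_csv(path: str) -> Trace:
    import ast

    meta = {}
    rows: dict[tuple[str, str], list[float]] = {}
    t_ref: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# "):
                k, _, v = line[2:].partition(": ")
                meta[k] = ast.literal_eval(v)
                continue
            if line.startswith("t,") or not line:
                continue
            t_s, lab, var, val = line.split(",", 3)
            key = (lab, var)
            if key not in rows:
                rows[key] = []
            rows[key].append(float(val))
            if key == next(iter(rows)):
                t_ref.append(float(t_s))
    tr = Trace(t=np.array(t_ref), V={}, Ca={}, meta=meta)
    for (lab, var), vals in rows.items():
        arr = np.array(vals)
        if var == "V":
            tr.V[lab] = arr
        elif var == "Ca":
            tr.Ca[lab] = arr
        elif var == "I_clamp":
            tr.I_clamp[lab] = arr
        elif var == "s":
            tr.synapse_states[lab] = arr
        elif var.startswith("I_"):
            tr.channel_currents.setdefault(lab, {})[var[2:]] = arr
        elif var.startswith("gbar_"):
            tr.gbar.setdefault(lab, {})[var[5:]] = arr
    return tr
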