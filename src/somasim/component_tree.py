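"""Hierarchical model container.

A :class:`ModelTree` holds named compartments, each with its ion-channel
populations and intracellular mechanisms, plus the synapses wiring
compartments together.  The tree is the unit of serialization (a flat,
canonically ordered vector of every parameter and dynamic variable),
snapshotting (named bookmarks of that vector) and hashing (a structural MD5
over component types and their equation sources, and a full MD5 that also
covers the serialized values).

Component paths are slash-separated label sequences such as
``"AB/NaV/gbar"``; a ``*`` token matches any (possibly multi-segment)
substring, so ``"*/gbar"`` matches every maximal-conductance parameter in
the tree.  Canonical ordering is lexicographic by full path string, which
makes serialization and hashing independent of construction order.
"""

from __future__ import annotations

import copy
import hashlib
import inspect
import re
from dataclasses import dataclass, field
from typing import Callable, Iterator

import numpy as np

from .channels import ConductanceInstance
from .errors import (
    LookupError_,
    NamingError,
    PathError,
    RegistryError,
    ShapeError,
    ValidationError,
)
from .mechanisms import CalciumMech, IntegralController
from .registry import get_channel_type, get_synapse_type
from .synapses import ElectricalSynapse, GradedSynapse

__all__ = ["Compartment", "ModelTree", "Match"]


_CAMECH_FIELDS = ("tau_Ca", "f", "Ca_0", "Ca_out", "T")
_CTRL_FIELDS = ("tau_m", "tau_g", "Ca_target", "mRNA")
_GRADED_FIELDS = ("gbar", "E_syn", "V_half", "Delta", "k_minus", "s")


@dataclass
class Compartment:
    """One isopotential membrane section.

    ``Cm`` is specific capacitance (nF/mm^2), ``A`` surface area (mm^2); the
    total capacitance entering the voltage equation is Cm*A.  ``radius`` and
    ``length`` (mm) are only needed for cable models with axial coupling.
    """

    label: str
    V: float = -60.0
    Ca: float = 0.05
    Cm: float = 10.0
    A: float = 0.01
    radius: float | None = None
    length: float | None = None
    conductances: dict[str, ConductanceInstance] = field(default_factory=dict)
    mechanisms: list[CalciumMech] = field(default_factory=list)

    def __post_init__(self):
        if not self.label or not isinstance(self.label, str):
            raise NamingError("compartment label must be a non-empty string")
        if "/" in self.label or "*" in self.label:
            raise NamingError(f"label {self.label!r} may not contain '/' or '*'")
        if self.A <= 0 or self.Cm <= 0:
            raise ValidationError(f"{self.label}: A and Cm must be > 0")
        if self.Ca < 0:
            raise ValidationError(f"{self.label}: Ca must be >= 0")

    @property
    def calcium_mech(self) -> CalciumMech | None:
        return self.mechanisms[0] if self.mechanisms else None

    def n_states(self) -> int:
        """Dynamic state variables in this compartment (V, Ca, gates, mRNA)."""
        n = 2  # V, Ca
        for c in self.conductances.values():
            s = c.spec
            n += (1 if s.p > 0 else 0) + (1 if s.q > 0 else 0)
            if c.controller is not None:
                n += 1
        return n


@dataclass
class Match:
    """One result of a path query: a component or a scalar parameter."""

    path: str
    kind: str  # compartment | conductance | mechanism | synapse | parameter
    obj: object
    get: Callable[[], float] | None = None
    set: Callable[[float], None] | None = None


class ModelTree:
    """Named, hierarchical container of compartments, synapses and mechanisms."""

    def __init__(self, axial_resistivity: float = 100.0):
        self.compartments: dict[str, Compartment] = {}
        self.synapses: list[GradedSynapse | ElectricalSynapse] = []
        self.snapshots: dict[str, tuple[np.ndarray, tuple[str, ...]]] = {}
        #: axial resistivity for cable models, in ohm*cm
        self.axial_resistivity = float(axial_resistivity)

    # -- construction -------------------------------------------------------

    def add_compartment(self, label: str, **params) -> Compartment:
        if label in self.compartments:
            raise NamingError(f"compartment {label!r} already exists")
        comp = Compartment(label=label, **params)
        self.compartments[label] = comp
        return comp

    def add_channel(self, comp_label: str, type_name: str, *,
                    name: str | None = None, **params) -> ConductanceInstance:
        comp = self._get_compartment(comp_label)
        name = name or type_name
        if name in comp.conductances:
            raise NamingError(f"conductance {name!r} already in {comp_label!r}")
        ct = get_channel_type(type_name)
        allowed = {"gbar", "E", "m", "h"}
        bad = set(params) - allowed
        if bad:
            raise ValidationError(f"unknown channel parameters: {sorted(bad)}")
        inst = ConductanceInstance(
            type_name=type_name,
            gbar=float(params.get("gbar", ct.default_gbar)),
            E=float(params.get("E", ct.default_E)),
            m=float(params.get("m", 0.0)),
            h=float(params.get("h", 1.0)),
        )
        if inst.gbar < 0:
            raise ValidationError(f"{comp_label}/{name}: gbar must be >= 0")
        comp.conductances[name] = inst
        return inst

    def add_calcium_mech(self, comp_label: str, **params) -> CalciumMech:
        comp = self._get_compartment(comp_label)
        if comp.mechanisms:
            raise NamingError(f"{comp_label!r} already has a calcium mechanism")
        allowed = {f.name for f in CalciumMech.__dataclass_fields__.values()}
        bad = set(params) - set(_CAMECH_FIELDS)
        if bad:
            raise ValidationError(f"unknown CalciumMech parameters: {sorted(bad)}")
        mech = CalciumMech(**params)
        comp.mechanisms.append(mech)
        return mech

    def add_controller(self, comp_label: str, channel_name: str,
                       **params) -> IntegralController:
        comp = self._get_compartment(comp_label)
        try:
            chan = comp.conductances[channel_name]
        except KeyError:
            raise LookupError_(
                f"no conductance {channel_name!r} in {comp_label!r}") from None
        if chan.controller is not None:
            raise NamingError(
                f"{comp_label}/{channel_name} already has a controller")
        bad = set(params) - set(_CTRL_FIELDS)
        if bad:
            raise ValidationError(f"unknown controller parameters: {sorted(bad)}")
        ctrl = IntegralController(**params)
        chan.controller = ctrl
        return ctrl

    def add_component(self, parent_path: str, kind: str, name: str,
                      params: dict | None = None) -> None:
        """Generic component insertion by parent path.

        ``kind`` is one of ``compartment`` (parent is the root, ``""``),
        ``conductance`` (parent is a compartment) or ``mechanism`` (parent is
        a compartment for calcium mechanisms, a conductance for integral
        controllers).  Unspecified parameters take registered defaults.
        """
        params = dict(params or {})
        if kind == "compartment":
            if parent_path not in ("", "/"):
                raise PathError("compartments can only be added at the root")
            self.add_compartment(name, **params)
        elif kind == "conductance":
            if parent_path not in self.compartments:
                raise LookupError_(f"no compartment {parent_path!r}")
            type_name = params.pop("type", name)
            self.add_channel(parent_path, type_name, name=name, **params)
        elif kind == "mechanism":
            parts = parent_path.split("/") if parent_path else []
            if len(parts) == 1:
                self._get_compartment(parts[0])
                params.pop("type", None)
                self.add_calcium_mech(parts[0], **params)
            elif len(parts) == 2:
                params.pop("type", None)
                self.add_controller(parts[0], parts[1], **params)
            else:
                raise PathError(
                    f"cannot attach a mechanism at {parent_path!r}")
        else:
            raise RegistryError(f"unknown component kind {kind!r}")

    def connect(self, pre: str, post: str, synapse_type: str,
                **params) -> GradedSynapse | ElectricalSynapse:
        """Add a directed chemical synapse (or symmetric electrical coupling).

        Self-synapses are rejected; multiple parallel synapses between the
        same pair are allowed.
        """
        self._get_compartment(pre)
        self._get_compartment(post)
        if pre == post:
            raise ValidationError("self-synapses are not allowed")
        if synapse_type == "Electrical":
            syn = ElectricalSynapse(a=pre, b=post, g=float(params.pop("g", 0.0)))
            if params:
                raise ValidationError(
                    f"unknown electrical-synapse parameters: {sorted(params)}")
        else:
            get_synapse_type(synapse_type)  # raises RegistryError if unknown
            bad = set(params) - set(_GRADED_FIELDS)
            if bad:
                raise ValidationError(f"unknown synapse parameters: {sorted(bad)}")
            syn = GradedSynapse.from_type(synapse_type, pre, post, **params)
        self.synapses.append(syn)
        return syn

    def replicate(self, label: str, n_copies: int) -> None:
        """Append n_copies-1 uncoupled deep copies of a compartment.

        Copies are labelled ``label_2`` .. ``label_<n>``; no synapses are
        added, so the total state count is n_copies times the source's.
        """
        src = self._get_compartment(label)
        if n_copies < 1:
            raise ValidationError("n_copies must be >= 1")
        for k in range(2, n_copies + 1):
            new_label = f"{label}_{k}"
            if new_label in self.compartments:
                raise NamingError(f"replicate collision: {new_label!r} exists")
            dup = copy.deepcopy(src)
            dup.label = new_label
            self.compartments[new_label] = dup

    # -- lookup -------------------------------------------------------------

    def _get_compartment(self, label: str) -> Compartment:
        try:
            return self.compartments[label]
        except KeyError:
            raise LookupError_(f"no compartment {label!r}") from None

    def resolve(self, path: str) -> list[Match]:
        """All components and parameters whose canonical path matches ``path``.

        ``*`` matches any substring (including across ``/``).  Matches come
        back sorted by path; an empty list means no match.
        """
        if not isinstance(path, str) or not path or "//" in path or path.isspace():
            raise PathError(f"malformed path {path!r}")
        pattern = re.compile(
            "^" + ".*".join(re.escape(tok) for tok in path.split("*")) + "$")
        out = [m for m in self._iter_matches() if pattern.match(m.path)]
        out.sort(key=lambda m: m.path)
        return out

    def _iter_matches(self) -> Iterator[Match]:
        for lab, comp in self.compartments.items():
            yield Match(lab, "compartment", comp)
            for name, chan in comp.conductances.items():
                yield Match(f"{lab}/{name}", "conductance", chan)
                if chan.controller is not None:
                    yield Match(f"{lab}/{name}/IntegralController",
                                "mechanism", chan.controller)
            if comp.calcium_mech is not None:
                yield Match(f"{lab}/CalciumMech", "mechanism", comp.calcium_mech)
        for i, syn in enumerate(self.synapses):
            yield Match(self._synapse_prefix(syn, i), "synapse", syn)
        for path, get, set_ in self._iter_scalars():
            yield Match(path, "parameter", None, get, set_)

    # -- flat serialization -------------------------------------------------

    def _synapse_prefix(self, syn, index: int) -> str:
        # disambiguating index among synapses with identical (pre, post, type)
        if isinstance(syn, ElectricalSynapse):
            key = (syn.a, syn.b, "Electrical")
            k = sum(1 for s in self.synapses[:index]
                    if isinstance(s, ElectricalSynapse)
                    and (s.a, s.b, "Electrical") == key)
            return f"@syn/{syn.a}<->{syn.b}/Electrical/{k}"
        key = (syn.pre, syn.post, syn.type_name)
        k = sum(1 for s in self.synapses[:index]
                if isinstance(s, GradedSynapse)
                and (s.pre, s.post, s.type_name) == key)
        return f"@syn/{syn.pre}->{syn.post}/{syn.type_name}/{k}"

    def _iter_scalars(self):
        """Yield (path, getter, setter) for every parameter and state."""

        def attr(obj, name):
            return (lambda: float(getattr(obj, name)),
                    lambda v, o=obj, n=name: setattr(o, n, float(v)))

        yield ("@tree/axial_resistivity", *attr(self, "axial_resistivity"))
        for lab, comp in self.compartments.items():
            for p in ("V", "Ca", "A", "Cm"):
                yield (f"{lab}/{p}", *attr(comp, p))
            if comp.radius is not None:
                yield (f"{lab}/radius", *attr(comp, "radius"))
            if comp.length is not None:
                yield (f"{lab}/length", *attr(comp, "length"))
            for name, chan in comp.conductances.items():
                spec = chan.spec
                yield (f"{lab}/{name}/gbar", *attr(chan, "gbar"))
                yield (f"{lab}/{name}/E", *attr(chan, "E"))
                if spec.p > 0:
                    yield (f"{lab}/{name}/m", *attr(chan, "m"))
                if spec.q > 0:
                    yield (f"{lab}/{name}/h", *attr(chan, "h"))
                if chan.controller is not None:
                    for p in _CTRL_FIELDS:
                        yield (f"{lab}/{name}/IntegralController/{p}",
                               *attr(chan.controller, p))
            if comp.calcium_mech is not None:
                for p in _CAMECH_FIELDS:
                    yield (f"{lab}/CalciumMech/{p}", *attr(comp.calcium_mech, p))
        for i, syn in enumerate(self.synapses):
            prefix = self._synapse_prefix(syn, i)
            if isinstance(syn, ElectricalSynapse):
                yield (f"{prefix}/g", *attr(syn, "g"))
            else:
                for p in _GRADED_FIELDS:
                    yield (f"{prefix}/{p}", *attr(syn, p))

    def layout(self) -> tuple[str, ...]:
        """Canonical (path-sorted) serialization layout."""
        return tuple(sorted(p for p, _, _ in self._iter_scalars()))

    def serialize(self) -> tuple[np.ndarray, tuple[str, ...]]:
        """Flatten every parameter and dynamic variable into one vector.

        The ordering is lexicographic by full path, so two trees with the
        same content serialize identically regardless of construction order.
        """
        entries = sorted(self._iter_scalars(), key=lambda e: e[0])
        vec = np.array([get() for _, get, _ in entries], dtype=np.float64)
        return vec, tuple(p for p, _, _ in entries)

    def deserialize(self, vector) -> None:
        """Write a serialized vector back in canonical layout order."""
        entries = sorted(self._iter_scalars(), key=lambda e: e[0])
        vec = np.asarray(vector, dtype=np.float64)
        if vec.ndim != 1 or len(vec) != len(entries):
            raise ShapeError(
                f"vector length {vec.size} != layout length {len(entries)}")
        for v, (_, _, set_) in zip(vec, entries):
            set_(v)

    # -- snapshots ----------------------------------------------------------

    def snapshot(self, name: str) -> None:
        """Bookmark the full serialized state under a (case-sensitive) name."""
        vec, layout = self.serialize()
        self.snapshots[name] = (vec.copy(), layout)

    def reset(self, name: str) -> None:
        """Restore a named snapshot; re-integration afterwards is bit-exact."""
        try:
            vec, layout = self.snapshots[name]
        except KeyError:
            raise LookupError_(f"no snapshot named {name!r}") from None
        if layout != self.layout():
            raise ShapeError(
                f"snapshot {name!r} layout no longer matches the tree")
        self.deserialize(vec)

    # -- hashing ------------------------------------------------------------

    def structural_hash(self) -> str:
        """MD5 over component types and their equation sources (not values).

        Invariant under insertion order and parameter values; changes when a
        component is added/removed or a registered equation source changes.
        """
        lines: list[str] = []
        for lab in sorted(self.compartments):
            comp = self.compartments[lab]
            lines.append(f"compartment {lab}")
            for name in sorted(comp.conductances):
                chan = comp.conductances[name]
                ct = get_channel_type(chan.type_name)
                lines.append(f"conductance {lab}/{name} type={ct.name}")
                lines.append(ct.source)
                if chan.controller is not None:
                    lines.append(f"mechanism {lab}/{name}/IntegralController")
                    lines.append(inspect.getsource(IntegralController))
            if comp.calcium_mech is not None:
                lines.append(f"mechanism {lab}/CalciumMech")
                lines.append(inspect.getsource(CalciumMech))
        for i, syn in enumerate(self.synapses):
            prefix = self._synapse_prefix(syn, i)
            if isinstance(syn, ElectricalSynapse):
                lines.append(f"synapse {prefix}")
            else:
                st = get_synapse_type(syn.type_name)
                lines.append(f"synapse {prefix}")
                lines.append(st.source)
        lines.sort()
        return hashlib.md5("\n".join(lines).encode()).hexdigest()

    def full_hash(self) -> str:
        """MD5 over the structural hash plus the serialized value vector."""
        vec, layout = self.serialize()
        h = hashlib.md5(self.structural_hash().encode())
        h.update("\n".join(layout).encode())
        h.update(vec.tobytes())
        return h.hexdigest()

    # -- misc ---------------------------------------------------------------

    def n_states(self) -> int:
        """Total count of dynamic state variables in the tree."""
        n = sum(c.n_states() for c in self.compartments.values())
        n += sum(1 for s in self.synapses if isinstance(s, GradedSynapse))
        return n

    def __repr__(self) -> str:
        return (f"<ModelTree: {len(self.compartments)} compartments, "
                f"{len(self.synapses)} synapses, {self.n_states()} states>")
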