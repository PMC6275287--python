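"""Experiment protocols built on the integrators.

This layer reproduces the standard in-silico electrophysiology workflows:
spike detection and f-I curves, voltage-clamp characterization of a channel
with recovery of its activation function by sigmoid^n least-squares fitting,
dominant-current labelling of a voltage trace, the LeMasson trace-similarity
cost, burst detection, and programmatic parameter sweeps.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .component_tree import ModelTree
from .errors import PathError, ValidationError
from .integrators import SimConfig, Trace, initialize, integrate
from .registry import get_channel_type

__all__ = [
    "spike_times", "firing_rate", "fi_curve", "FICurve",
    "recover_activation", "ActivationFit", "dominant_current_labels",
    "lemasson_error", "sweep", "detect_bursts",
]

#: default spike threshold (mV) and refractory window (ms)
SPIKE_THRESHOLD = 0.0
SPIKE_REFRACTORY = 1.0


def spike_times(t: np.ndarray, V: np.ndarray,
                threshold: float = SPIKE_THRESHOLD,
                refractory: float = SPIKE_REFRACTORY) -> np.ndarray:
    """Times (ms) of upward threshold crossings, with a refractory window."""
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValidationError("spike detection requires a finite trace")
    up = np.flatnonzero((V[:-1] < threshold) & (V[1:] >= threshold))
    if up.size == 0:
        return np.empty(0)
    times = np.asarray(t)[up + 1]
    keep = [times[0]]
    for x in times[1:]:
        if x - keep[-1] >= refractory:
            keep.append(x)
    return np.array(keep)


def firing_rate(t: np.ndarray, V: np.ndarray,
                threshold: float = SPIKE_THRESHOLD) -> float:
    """Mean firing rate in Hz over the trace duration."""
    n = spike_times(t, V, threshold).size
    duration_ms = t[-1] - t[0] + (t[1] - t[0] if len(t) > 1 else 0.0)
    return 1000.0 * n / duration_ms


@dataclass
class FICurve:
    I_values: np.ndarray  # nA
    rate: np.ndarray      # Hz


def fi_curve(tree: ModelTree, I_values, *, compartment: str | None = None,
             t_end: float = 2000.0, t_transient: float = 500.0,
             dt: float = 0.05) -> FICurve:
    """Firing rate vs injected current, restoring the model between runs.

    Each amplitude starts from the same bookmarked state; the transient
    ``t_transient`` ms is discarded before counting spikes.
    """
    if compartment is None:
        if len(tree.compartments) != 1:
            raise ValidationError("specify `compartment` for network models")
        compartment = next(iter(tree.compartments))
    I_values = np.asarray(I_values, dtype=float)
    base, _ = tree.serialize()
    rates = np.empty(I_values.size)
    for k, amp in enumerate(I_values):
        tree.deserialize(base)
        trace = integrate(tree, SimConfig(
            t_end=t_end, dt=dt, I_ext={compartment: float(amp)}))
        sel = trace.t >= t_transient
        n = spike_times(trace.t[sel], trace.V[compartment][sel]).size
        rates[k] = 1000.0 * n / (t_end - t_transient)
    tree.deserialize(base)
    return FICurve(I_values=I_values, rate=rates)


@dataclass
class ActivationFit:
    """Result of recovering an activation curve from clamp currents."""

    V_grid: np.ndarray
    g_norm: np.ndarray
    n_best: int
    V_half_fit: float
    k_fit: float
    residuals: dict[int, float] = field(default_factory=dict)
    params: dict[int, tuple[float, float]] = field(default_factory=dict)


def _sigmoid_n(v, a, vhalf, k, n):
    return a * (1.0 / (1.0 + np.exp((vhalf - v) / k))) ** n


def recover_activation(channel_type: str, V_steps, E_rev: float,
                       n_candidates=range(1, 9), *,
                       gbar: float = 1000.0, A: float = 0.01,
                       step_duration: float = 500.0, dt: float = 0.05,
                       V_hold: float = -80.0) -> ActivationFit:
    """In-silico voltage-clamp characterization of one channel type.

    A single compartment containing only the channel is clamped to each
    voltage step for ``step_duration`` ms starting from rest at ``V_hold``;
    the asymptotic clamp current (mean of the last 10% of the step) divided
    by the driving force gives the conductance-voltage curve, which is
    normalized and fitted with a*[1/(1+exp((V_half-V)/k))]^n by least
    squares for each candidate exponent.  The free amplitude ``a`` absorbs
    the bias of normalizing by the largest measured point (the activation
    curve does not quite saturate at the top clamp step); without it the
    exponent comparison is dominated by that bias rather than by curve
    shape.  The exponent with the smallest residual sum of squares wins.
    """
    get_channel_type(channel_type)
    V_steps = np.asarray(V_steps, dtype=float)
    keep = np.abs(V_steps - E_rev) > 1e-9
    if not np.all(keep):
        import warnings

        warnings.warn("dropping clamp steps at the reversal potential")
    V_steps = V_steps[keep]

    g = np.empty(V_steps.size)
    for k, v_step in enumerate(V_steps):
        tree = ModelTree()
        tree.add_compartment("cell", A=A)
        tree.add_channel("cell", channel_type, gbar=gbar, E=E_rev)
        initialize(tree, V0=V_hold)
        trace = integrate(tree, SimConfig(
            t_end=step_duration, dt=dt, V_clamp={"cell": float(v_step)}))
        i_asym = float(np.mean(trace.I_clamp["cell"][-max(
            1, trace.t.size // 10):]))
        g[k] = i_asym / (v_step - E_rev)
    g_norm = g / np.max(g)

    residuals: dict[int, float] = {}
    params: dict[int, tuple[float, float]] = {}
    for n in n_candidates:
        best = (np.inf, (np.nan, np.nan))
        for vh0 in (-60.0, -40.0, -20.0, 0.0):
            for k0 in (5.0, 15.0):
                try:
                    popt, _ = curve_fit(
                        lambda v, a, vh, kk: _sigmoid_n(v, a, vh, kk, n),
                        V_steps, g_norm, p0=(1.0, vh0, k0), maxfev=5000)
                except RuntimeError:
                    continue
                rss = float(np.sum(
                    (_sigmoid_n(V_steps, *popt, n) - g_norm) ** 2))
                if rss < best[0]:
                    best = (rss, (float(popt[1]), float(popt[2])))
        residuals[int(n)] = best[0]
        params[int(n)] = best[1]
    n_best = min(residuals, key=lambda n: residuals[n])
    return ActivationFit(V_grid=V_steps, g_norm=g_norm, n_best=n_best,
                         V_half_fit=params[n_best][0],
                         k_fit=params[n_best][1],
                         residuals=residuals, params=params)


def dominant_current_labels(trace: Trace, compartment: str | None = None) -> list[str]:
    """Per-sample label of the dominant membrane current.

    Where the voltage is rising the strongest inward (most negative) current
    wins; where it is falling the strongest outward (most positive) one.
    Ties go to the first recorded channel.
    """
    if not trace.channel_currents:
        raise ValidationError("trace was recorded without channel currents")
    if compartment is None:
        compartment = next(iter(trace.channel_currents))
    chans = trace.channel_currents[compartment]
    names = list(chans)
    I = np.vstack([chans[n] for n in names])  # (nchan, nt)
    V = trace.V[compartment]
    dV = np.diff(V, prepend=V[0])
    rising = dV >= 0
    lab_in = np.argmin(I, axis=0)   # most negative = strongest inward
    lab_out = np.argmax(I, axis=0)  # most positive = strongest outward
    pick = np.where(rising, lab_in, lab_out)
    return [names[i] for i in pick]


def lemasson_error(V_a: np.ndarray, V_b: np.ndarray, *, dt: float = 1.0,
                   bins: int = 100, V_range=(-80.0, 50.0)) -> float:
    """Trace-similarity cost in [0, 2] from (V, dV/dt) occupancy histograms.

    Both traces are embedded as points (V, dV/dt), histogrammed on a shared
    fixed grid (``bins`` x ``bins`` over ``V_range`` and a symmetric dV/dt
    range taken from the first trace), normalized by their point counts, and
    compared by the summed absolute difference.  Identical traces score 0;
    non-overlapping embeddings score 2.
    """
    V_a = np.asarray(V_a, dtype=float)
    V_b = np.asarray(V_b, dtype=float)
    if V_a.size < 2 or V_b.size < 2:
        raise ValidationError("lemasson_error needs traces with >= 2 samples")
    dva = np.diff(V_a) / dt
    dvb = np.diff(V_b) / dt
    dv_max = np.max(np.abs(dva))
    if dv_max == 0:
        dv_max = 1.0
    edges_v = np.linspace(V_range[0], V_range[1], bins + 1)
    edges_dv = np.linspace(-dv_max, dv_max, bins + 1)
    ha, _, _ = np.histogram2d(V_a[1:], dva, bins=(edges_v, edges_dv))
    hb, _, _ = np.histogram2d(V_b[1:], dvb, bins=(edges_v, edges_dv))
    pa = ha / dva.size
    pb = hb / dvb.size
    return float(np.abs(pa - pb).sum())


def sweep(tree: ModelTree, path: str, values, protocol) -> list:
    """Run ``protocol(tree)`` for each value of one parameter.

    ``path`` must resolve to exactly one numeric parameter.  The model is
    restored to its pre-sweep state between runs and afterwards.
    """
    matches = [m for m in tree.resolve(path) if m.kind == "parameter"]
    if len(matches) == 0:
        raise PathError(f"{path!r} matches no parameter")
    if len(matches) > 1:
        raise PathError(
            f"{path!r} is ambiguous ({len(matches)} parameters); "
            "disambiguate the path")
    base, _ = tree.serialize()
    out = []
    try:
        for v in values:
            tree.deserialize(base)
            # re-resolve: deserialize rebuilt values, setters remain valid
            m = [mm for mm in tree.resolve(path) if mm.kind == "parameter"][0]
            m.set(float(v))
            out.append(protocol(tree))
    finally:
        tree.deserialize(base)
    return out


def detect_bursts(spike_t: np.ndarray, max_isi: float = 100.0) -> list[tuple[float, float]]:
    """Group spikes with inter-spike interval < ``max_isi`` ms into bursts.

    Returns (first_spike, last_spike) windows; single spikes count as
    one-spike bursts.
    """
    spike_t = np.asarray(spike_t, dtype=float)
    if spike_t.size == 0:
        return []
    bursts = []
    start = prev = spike_t[0]
    for x in spike_t[1:]:
        if x - prev >= max_isi:
            bursts.append((start, prev))
            start = x
        prev = x
    bursts.append((start, prev))
    return bursts
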