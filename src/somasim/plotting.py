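"""Matplotlib helpers for the standard displays.

These mirror the classic simulator figures: a voltage trace colored by the
dominant instantaneous current, the four gating curves of a channel type,
an f-I curve, and the sigmoid^n activation-fit panel.
"""

from __future__ import annotations

import numpy as np

from .channels import steady_state_curves
from .protocols import ActivationFit, FICurve, _sigmoid_n, dominant_current_labels


def plot_trace(trace, compartment=None, ax=None):
    """Voltage trace; colored by dominant current when currents were recorded."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    if compartment is None:
        compartment = next(iter(trace.V))
    t, v = trace.t, trace.V[compartment]
    if trace.channel_currents:
        labels = dominant_current_labels(trace, compartment)
        names = sorted(set(labels))
        cmap = dict(zip(names, plt.cm.tab10.colors))
        colors = [cmap[l] for l in labels]
        ax.scatter(t, v, c=colors, s=1, rasterized=True)
        for n in names:
            ax.plot([], [], color=cmap[n], label=n)
        ax.legend(loc="upper right", fontsize=8)
    else:
        ax.plot(t, v, lw=0.7, color="k")
    ax.set_xlabel("time (ms)")
    ax.set_ylabel(f"V [{compartment}] (mV)")
    return ax


def plot_activation_curves(type_name, V_grid=None, axes=None):
    """m_inf/h_inf and tau_m/tau_h over the voltage grid."""
    import matplotlib.pyplot as plt

    if V_grid is None:
        V_grid = np.arange(-100.0, 101.0, 1.0)
    curves = steady_state_curves(type_name, V_grid)
    if axes is None:
        _, axes = plt.subplots(1, 2, figsize=(8, 3))
    axes[0].plot(V_grid, curves["m_inf"], label="m_inf")
    axes[0].plot(V_grid, curves["h_inf"], label="h_inf")
    axes[0].set_ylabel("steady state")
    axes[1].plot(V_grid, curves["tau_m"], label="tau_m")
    axes[1].plot(V_grid, curves["tau_h"], label="tau_h")
    axes[1].set_ylabel("tau (ms)")
    for ax in axes:
        ax.set_xlabel("V (mV)")
        ax.legend(fontsize=8)
        ax.set_title(type_name)
    return axes


def plot_fi(fi: FICurve, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ax.plot(fi.I_values, fi.rate, "o-")
    ax.set_xlabel("I (nA)")
    ax.set_ylabel("firing rate (Hz)")
    return ax


def plot_activation_fit(fit: ActivationFit, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ax.plot(fit.V_grid, fit.g_norm, "ko", label="g/g_max")
    vv = np.linspace(fit.V_grid.min(), fit.V_grid.max(), 200)
    for n, (vh, k) in sorted(fit.params.items()):
        if not np.isfinite(vh):
            continue
        style = "-" if n == fit.n_best else ":"
        ax.plot(vv, _sigmoid_n(vv, 1.0, vh, k, n), style,
                label=f"n={n}" + (" (best)" if n == fit.n_best else ""))
    ax.set_xlabel("V (mV)")
    ax.set_ylabel("normalized conductance")
    ax.legend(fontsize=7)
    return ax
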