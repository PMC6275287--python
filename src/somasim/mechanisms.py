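"""Intracellular mechanisms: calcium buffering and homeostatic integral control.

Calcium dynamics follow the single-pool buffering model standard in
stomatogastric-ganglion work (Liu et al. 1998; Prinz et al. 2003):

    tau_Ca * d[Ca]/dt = -f * I_Ca - [Ca] + Ca_0

where I_Ca (nA) is the summed current through calcium channels (inward
currents are negative, so influx raises [Ca]) and f (uM/nA) converts current
to concentration for the cell's volume.  The calcium reversal potential is
recomputed from the Nernst equation each step.

The integral controller implements calcium-dependent homeostatic regulation
of channel densities (O'Leary et al. 2014): a per-channel "mRNA" variable
integrates the error between intracellular calcium and a target, and the
channel's maximal conductance relaxes toward the mRNA level:

    tau_m * d(mRNA)/dt = Ca_target - [Ca]
    tau_g * d(gbar)/dt = mRNA - gbar      (gbar floored at 0)

mRNA may go negative (as in the cited formulation); only gbar is floored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ValidationError

# physical constants
_R = 8.314462618       # J/(mol K)
_F = 96485.33212       # C/mol


@dataclass
class CalciumMech:
    """Calcium influx/buffering for one compartment.

    Defaults follow the Prinz-model convention for a 0.0628 mm^2 compartment;
    ``f`` scales inversely with compartment volume and should be adjusted
    along with the area.
    """

    tau_Ca: float = 200.0    # ms
    f: float = 14.96         # uM/nA
    Ca_0: float = 0.05       # uM, baseline
    Ca_out: float = 3000.0   # uM, extracellular
    T: float = 11.0          # deg C

    def __post_init__(self):
        if self.tau_Ca <= 0 or self.f <= 0 or self.Ca_out <= 0:
            raise ValidationError("CalciumMech requires tau_Ca, f, Ca_out > 0")

    @property
    def nernst_factor(self) -> float:
        """RT/2F in mV at the mechanism's temperature."""
        return 1000.0 * _R * (self.T + 273.15) / (2.0 * _F)


def calcium_step(mech: CalciumMech, Ca: float, I_Ca_total: float, dt: float) -> float:
    """One exponential-Euler step of the buffering ODE; result clipped at 0.

    The instantaneous fixed point is Ca_inf = Ca_0 - f*I_Ca (inward calcium
    current is negative, raising the fixed point above baseline).
    """
    ca_inf = mech.Ca_0 - mech.f * I_Ca_total
    ca_new = ca_inf + (Ca - ca_inf) * math.exp(-dt / mech.tau_Ca)
    return max(ca_new, 0.0)


def nernst_reversal(mech: CalciumMech, Ca_in: float) -> float:
    """Calcium reversal potential (mV) for divalent Ca, E = (RT/2F) ln(Ca_out/Ca_in)."""
    if Ca_in <= 0:
        raise ValidationError("nernst_reversal requires Ca_in > 0")
    return mech.nernst_factor * math.log(mech.Ca_out / Ca_in)


@dataclass
class IntegralController:
    """Homeostatic integral control of one channel's maximal conductance."""

    tau_m: float             # ms, mRNA (transcription) timescale
    tau_g: float = 5000.0    # ms, translation timescale
    Ca_target: float = 7.0   # uM
    mRNA: float = 0.0        # dynamic state; may go negative

    def __post_init__(self):
        if self.tau_m <= 0 or self.tau_g <= 0:
            raise ValidationError("IntegralController requires tau_m, tau_g > 0")
        if self.Ca_target <= 0:
            raise ValidationError("IntegralController requires Ca_target > 0")


def controller_step(ctrl: IntegralController, Ca: float, g: float,
                    dt: float) -> tuple[float, float]:
    """One forward-Euler controller step; returns (mRNA', gbar').

    The conductance update reads the pre-update mRNA (synchronous update);
    gbar is floored at 0.
    """
    g_new = g + dt * (ctrl.mRNA - g) / ctrl.tau_g
    g_new = max(g_new, 0.0)
    mrna_new = ctrl.mRNA + dt * (ctrl.Ca_target - Ca) / ctrl.tau_m
    return mrna_new, g_new
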