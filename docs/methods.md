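# Methods

## Model formalism

A model is a tree of named compartments; each compartment carries a
membrane potential V (mV), an intracellular calcium concentration [Ca]
(µM), a specific capacitance C_m (nF/mm², default 10) and a surface area A
(mm²). Ion-channel populations contribute density currents
ḡ·m^p·h^q·(V−E) (ḡ in µS/mm²); whole-cell currents (injected, synaptic,
electrical) are divided by A before entering the voltage equation. With
these units (mV, ms, µS/mm², nF/mm², nA, µM) all equations close without
conversion factors except the nS→µS factor of 10⁻³ on synaptic
conductances.

Channel kinetics are the Prinz et al. (2003) variant of the Liu et al.
(1998) STG library. Both variants share the same steady-state curves for
the channels used here; we pin the Prinz time constants and use the same
set for every fixture. The KCa activation is separable,
m_∞(V, Ca) = [Ca/(Ca+3 µM)]·σ(V), and is the only calcium-gated curve.
Calcium-channel reversals are Nernstian, E_Ca = (RT/2F)·ln([Ca]_out/[Ca]),
recomputed every step when a calcium mechanism is present; before the first
mechanism update (or without one) a fixed placeholder (+30 mV) applies.

Calcium buffering follows the single-pool model
τ_Ca·d[Ca]/dt = −f·I_Ca − [Ca] + Ca_0 with defaults τ_Ca = 200 ms,
f = 14.96 µM/nA (for the 0.0628 mm² reference compartment; f scales
inversely with cell volume), Ca_0 = 0.05 µM, [Ca]_out = 3000 µM, T = 11 °C.
These are the conventional constants of the cited STG models; with the
burster's conductances they produce calcium excursions of tens of µM per
burst. Integral control of a channel density evolves an auxiliary "mRNA"
state, τ_m·dm/dt = Ca_target − [Ca], τ_g·dḡ/dt = m − ḡ; m may go
negative, ḡ is floored at zero, and the ḡ update reads the pre-update m
(synchronous update).

Graded synapses: s_∞(V_pre) = 1/(1+exp((V_half−V_pre)/Δ)) with
V_half = −35 mV, Δ = 5 mV; τ_s = (1−s_∞)/k₋, floored at dt so the
exponential-Euler update stays stable as s_∞→1. Glutamatergic synapses
reverse at −70 mV with k₋ = 1/40 ms⁻¹; cholinergic at −80 mV with
k₋ = 1/100 ms⁻¹.

## Integration

The default solver advances every relaxation variable (gating, synapse,
calcium, and the membrane potential itself, using
V_∞ = (Σ g·E + I/A)/Σ g and τ_V = C_m/Σ g) exactly along its instantaneous
exponential — the exponential-Euler scheme classically used for equations
of this form. It is unconditionally stable and keeps all gating and
synaptic states inside [0, 1] for any dt. Update order within one step:
synapse states → calcium reversals → gating → voltage → calcium mechanism →
integral controllers, with all cross-compartment reads (presynaptic and
gap-junction voltages) taken from the previous step. The calcium current
driving the buffering ODE uses the updated gating at the pre-update
voltage. Components are processed in canonical (path-sorted) order so
results do not depend on the order in which a model was assembled.

The inner loop runs as a compiled (numba) kernel over a flattened
structure-of-arrays view of the model; gating curves of every registered
channel type are pre-tabulated on a 0.02 mV grid over [−150, 100] mV and
linearly interpolated, so user-registered channels run at the same speed as
built-ins. The interpolation error (≲10⁻⁶ on sigmoid curves at this
resolution) is far below the O(dt) scheme error at any practical step.
Non-finite states abort the run with the failing step index.

Voltage clamp uses the same loop with the clamped compartments' V pinned to
the command value; gating evolves under the clamped voltage and the
reported clamp current is the total membrane current (what the amplifier
must inject, positive outward).

RK4 integrates the joint (V, Ca, gates) system of a single compartment with
the classical 4th-order rule, using the same tabulated curves; it exists
for cross-checking the default scheme and refuses networks. Unbranched
cables use Crank–Nicolson: the tridiagonal axial+membrane voltage system
(conductances frozen at the current gating, solved with a banded solver) is
advanced implicitly while gating advances by exponential Euler, staggered.
Axial coupling between cylindrical compartments i, j is the series
resistance R = ρ·(ℓᵢ/2)/(πrᵢ²) + ρ·(ℓⱼ/2)/(πrⱼ²) with ρ the axial
resistivity (Ω·cm, default 100). Compartment order in the tree defines the
chain; branching is out of scope.

Default dt = 0.05 ms resolves action potentials; out_dt must be a multiple
of dt and controls sampling only. Initial conditions are supplied by
`initialize`: V = −60 mV, [Ca] at the mechanism baseline, gates and synapse
states at their steady states — this removes startup transients and is what
every fixture uses. Integration always continues from the current model
state; together with deterministic solvers this makes
snapshot → integrate → reset → integrate reproduce continuations
bit-exactly.

## Serialization, snapshots, hashing

`serialize` flattens every parameter and dynamic variable into one vector
ordered lexicographically by full component path (e.g. `AB/NaV/gbar`), so
two trees with identical content serialize identically regardless of build
order; `deserialize` writes a vector back. Snapshots store that vector
under a case-sensitive name. The structural hash is an MD5 over the sorted
component-type identifiers together with the registered source text of
their rate equations — the analogue of hashing the component definitions —
and is invariant to parameter values and insertion order; the full hash
chains the structural hash with the serialized vector bytes, and is
embedded in every written trace for provenance. Both are exposed because
either identity (topology-only or topology+values) is useful.

## Protocol layer

Spike detection: upward crossings of 0 mV with a 1 ms refractory window —
robust for the spike heights of all fixtures. Bursts group spikes with
inter-spike intervals under 100 ms. f–I curves restore the model's
bookmarked state between amplitudes and discard a 500 ms transient.

Activation recovery clamps a single-channel cell at each step for 500 ms
(the slowest library activation, KCa, settles within ~180 ms; Kd within
~15 ms) and takes the mean of the last 10% as the asymptote. The
conductance–voltage curve I/(V−E) is normalized by its maximum and fitted
with a·σ(V_half, k)^n for each candidate n, multi-started over
V_half ∈ {−60, −40, −20, 0} and k ∈ {5, 15} mV. The free amplitude a is
deliberate: the top clamp step does not quite saturate the true activation
curve (for Kd, m_∞(+50 mV)⁴ ≈ 0.98), so a fixed-amplitude fit is dominated
by that normalization bias rather than by curve shape and can select a
wrong exponent; with a free, the true exponent fits to machine precision
and the comparison is decided by structure. Steps at the reversal potential
are dropped (division by zero) with a warning.

The trace-similarity cost embeds each voltage trace as points (V, dV/dt),
histograms both on a shared 100×100 grid over V ∈ [−80, 50] mV and a
symmetric dV/dt range taken from the first (reference) trace, normalizes by
point count, and sums absolute differences — 0 for identical traces, 2 for
disjoint embeddings. The binning is a documented constant, not inherited
from any source.

Parameter sweeps require an unambiguous path, restore the pre-sweep state
between and after runs, and replace interactive manipulation: they are the
programmatic API over which a GUI could be built, but no GUI is provided.

## Fixtures: what they emulate and what they do not

* `hh_neuron` — squid-axon-like spiker (NaV 1000, Kd 300, Leak 1 µS/mm²,
  A = 0.01 mm²): quiescent at rest, tonic at 0.2 nA (33 Hz).
* `bursting_neuron` — the 8-channel STG pacemaker (NaV 1000, CaT 25,
  CaS 60, A 500, KCa 50, Kd 1000, H 0.1, Leak 0 µS/mm², A = 0.0628 mm²).
  Without the calcium mechanism [Ca] is frozen and the cell spikes
  tonically; with it the cell bursts with ~1 s period and calcium
  oscillations locked to bursts.
* `homeostatic_neuron` — the burster with an integral controller on every
  non-zero conductance, initial densities at 5% of target.
  Ca_target = 79 µM is the measured time-averaged calcium of the reference
  burster; τ_g = 500 ms and τ_m,i = 5·10⁵/ḡ_target,i ms·µS/mm² implement
  the inverse-target rule that fixes the steady-state conductance ratios,
  scaled so convergence completes within a 30 s simulation. These
  timescales are orders of magnitude faster than biological transcription;
  they compress the demonstration without changing the fixed point.
* `pyloric_network` — AB (the burster, standing in for the electrically
  coupled AB/PD pacemaker group), LP and PY cells with 7 graded synapses of
  the two kinetic types. Synaptic weights were tuned once, by grid search
  over published-order-of-magnitude values, for a robust triphasic
  AB→LP→PY rhythm under this channel library; they are not a transcription
  of any published circuit instance. LP and PY here fire tonically between
  pacemaker bursts rather than in tight bursts — the onset order, not the
  burst envelope, is the modeled feature.
* `passive_cable` — 50 leak-only cylinders (r = 0.05 mm, ℓ = 0.632 mm,
  g_leak = 0.1 µS/mm², ρ = 100 Ω·cm), giving λ ≈ 15.8 mm and a total
  length of 2λ; the steady-state attenuation under end injection has the
  closed-form cosh profile used as the oracle.

All fixtures are deterministic and built in code; passing their tests shows
the solvers and mechanisms reproduce the qualitative physiology of these
idealized models, not that any parameter set matches a biological recording.

## Problem sizes in the test suite

The suite integrates single compartments for 2–30 s of model time at
dt = 0.05 ms (reference runs for the step-size study at dt = 0.0125 ms over
3–5 s), the network for 20 s, and the cable for 2 s — sizes chosen so each
protocol reaches its steady behavior with a comfortable margin.

## Known limitations

Conductance-based models only; fixed step size; no branched morphologies,
no temperature (Q10) scaling, no stochastic channels, no spike-triggered
synapses or conduction delays, no parameter optimization. Calcium-gated
activations must be separable (voltage factor times Ca/(Ca+K)). RK4 leaves
integral controllers to a forward-Euler sub-step after each RK4 step, and
the Crank–Nicolson cable path is implemented in Python (cable runs in this
package are short); both are documented trade-offs, not scheme errors.
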