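# Methods

## The model

`biopacer` implements a single-cell model of an engineered biological
pacemaker: a human ventricular myocyte (the ten Tusscher–Panfilov 2006
equation set, TP06, epicardial parameter variant) whose membrane current is
modified in two ways that mimic gene therapy:

* **I_K1 knock-down.** The inward-rectifier current is multiplied by a
  scaling factor `S_K1 ∈ [0, 1]`,
  `I_K1 = S_K1 · G_K1 · √(K_o/5.4) · x_K1∞(V) · (V − E_K)`.
  Suppressing I_K1 destabilizes the resting potential and permits diastolic
  depolarization.
* **I_f incorporation.** A sinoatrial-type funny current is added with its
  two ionic components, `I_f = I_f,Na + I_f,K`,
  `I_f,Na = S_f · G_f,Na · y · (V − E_Na)` and
  `I_f,K = S_f · G_f,K · y · (V − E_K)`, where `y` is the HCN activation
  gate. `I_f,Na` feeds the intracellular Na⁺ balance and `I_f,K` the K⁺
  balance, so chronic I_f expression loads the cell with Na⁺.

Optionally a low-voltage-activated T-type Ca²⁺ current
`I_CaT = G_CaT · dT · fT · (V − 45 mV)` (Kurata-style gating) is included;
its Ca²⁺ flux enters the dyadic subspace with the same convention as
I_CaL (a cytosolic-routing option exists).

The membrane equation is `dV/dt = −I_ion/C_m` with all currents as
densities (pA/pF); the full state has 22 variables (V, 15 first-order
gates, 5 concentrations, and the SR release-recovery variable).

## Density anchoring

Expression levels are communicated as current densities at −80 mV on the
steady-state I-V curve, the convention used for reporting knock-down and
over-expression levels:

* `S_K1 = 1` ⇔ 0.99 pA/pF of I_K1 at −80 mV,
* `S_f = 1` ⇔ −0.63 pA/pF of I_f at −80 mV (activation gate at its
  steady state).

Both anchors are evaluated under fixed reference conditions
(K_o = 5.4 mM, Na_o = 140 mM, K_i = 140 mM, Na_i = 7.67 mM). K_i = 140 mM
is used for the anchor because the raw TP06 conductance then yields
0.9928 ≈ 0.99 pA/pF at −80 mV; a multiplicative calibration (factor
0.9972 on G_K1) makes the anchor exact, so `density_to_scale` and
`iv_curve` round-trip. The I_f conductance pair is derived at import time:
the Na:K maximal-conductance ratio 0.5927 is taken from the human
sinoatrial formulation (it places the I_f reversal near −22 mV), and the
joint magnitude is fitted to the −0.63 pA/pF anchor. This makes the model
independent of the source model's absolute conductances.

## I_f gating: the one genuinely open formulation choice

The funny-current activation gate uses the human-SAN voltage dependence,
`y∞ = 1/(1 + exp((V + 52.5)/9))`, with the Verkerk-type time constant
`τ_y = 716.65 / (0.0708·e^{−(V+5)/20.28} + 10.6·e^{V/18})` ms. Two
alternatives were evaluated against the printed observables of the study
this model reconstructs:

* an *instantaneous* gate `y = y∞(V)` (suggested by a literal reading of
  the source's "time-independent" wording) degrades even the low-I_f
  cycle lengths by ~45% and fragments the stable region;
* negative-shifted activation midpoints (down to −96.9 mV, the
  intact-cell human value) abolish automaticity altogether once the −80 mV
  anchor is re-applied.

The dynamic −52.5 mV gate reproduces the I_K1-only and low/mid-I_f
operating points to ~1–2% and is the default. `instantaneous_y`,
`y_vhalf`, `y_slope` and `tau_y_scale` remain exposed for sensitivity
analyses.

## Numerical scheme

Gates are advanced with the Rush–Larsen exponential update (exact for a
first-order gate at frozen voltage, and the standard treatment for the
stiff Ca²⁺-dependent inactivation gates); the membrane potential and the
material balances use forward Euler. The default step is **0.01 ms**:
measured CL convergence is cleanly first-order (853.3 / 854.4 / 855.0 ms
at dt = 0.02/0.01/0.005 for a stable pacemaker), and 0.01 ms is the
largest step for which a further halving moves the CL by less than 1 ms.
Recording is decoupled from integration (default 1 ms sampling) and does
not affect the dynamics. Blow-ups (|V| > 300 mV or non-finite state)
return a partial trace plus an error so parameter sweeps can mark the
point as failed. The compiled inner loop integrates 800 s in roughly a
minute on one core.

## Wave grammar and classification

A *wave* is any depolarization excursion rising ≥ 15 mV above the
preceding minimum (the threshold separates incomplete depolarizations
from sub-threshold ripple and is configurable); it is *valid* when its
trough is below −20 mV and its crest above +20 mV. A *rest* is ≥ 1000 ms
of quiet, measured as the inter-crest interval minus a nominal 600 ms wave
duration so that slow regular beating (CL ≈ 1 s) does not register rests.
The five states are matched in order: no valid waves → State-1; one
terminal rest (lasting to the end of the record and ≥ 10× the preceding
mean CL) → State-2; any internal rest → State-3 (with burst
segmentation); persistent activity with incomplete waves after the
start-up transient → State-4; otherwise State-5. The first 60 s (capped
at a quarter of the record) are excluded from the State-4/5 adjudication
only. Peak *locations* are found on a 5-sample median-filtered copy of
the trace (noise robustness) while crest/trough *values* are read from
the raw samples (so noise-free threshold behaviour is exact); crossing
times are linearly interpolated.

## Pacing metrics

The upstroke fiducial is the interpolated upward crossing of −55 mV
(≈ the I_CaL activation threshold); CL is the mean inter-upstroke
interval of consecutive valid waves, DI runs from the per-cycle minimum
(MDP) to that crossing, the diastolic upstroke velocity is
`(−55 − MDP)/(t₂ − t₁)` in V/s (reported positive), and APD90 runs from
the upstroke fiducial to the downward crossing of
`crest − 0.9·(crest − MDP)`. The diastolic current integrals average
I_Na + I_NaCa + I_f (inward) and I_K1 + I_NaK + I_Kr + I_Ks (outward)
over each DI. *Valid pacemaking* means State-5 with CL ≤ 1000 ms. For
simulated records the measurement window is the final 400 s when the
record reaches 800 s, else the final half.

## Parameter-space sweeps

`run_sweep` simulates every (I_K1, I_f) density pair independently from
the default resting initial state (no continuation between points, which
would bias burst detection hysteretically), classifies and measures each
trace, and tabulates state, CL and validity. `stability_boundary` reports,
per I_f column, the largest I_K1 density labelled State-5 (or flagged
valid). Production maps use 800 s/point; the test suite's quick mode uses
300 s/point at dt = 0.02 ms on a coarse 5×5 grid, which is sufficient for
region ordering but can misread a slow burster as transient when the
record ends inside a quiescent phase.

## Synthetic fixtures

`trace_fixtures` renders each of the five grammar patterns as a stylized
AP train: an accelerating-exponential diastolic ramp (MDP → −45 mV), a
2 ms linear upstroke, and an exponential repolarization with exact
endpoint at the MDP; incomplete waves are sin² humps peaking below
+20 mV. Specs that cannot realize their pattern (e.g. a transient spec
whose terminal rest is shorter than ~11 CL) are rejected. Additive
Gaussian noise is seeded and optional. The generator tests grammar and
fiducial logic only — it reproduces none of the ionic mechanisms, so
passing round-trips say nothing about model biophysics, only about the
analysis pipeline.

## Fidelity and known limitations

With the defaults above the package reproduces the I-V anchors exactly
and the I_K1-only automaticity quantitatively (CL 1023 ms vs 1011 printed
at 0.05 pA/pF; 837 vs 833 at complete block). Behaviour that hinges on
the precise Na⁺ loading rate at high I_f reproduces qualitatively but not
to printed precision: our stable (State-5) boundary sits near I_K1 ≈
0.15–0.20 pA/pF at I_f = −3.15 instead of 0.248, transient pacemaking at
(0.297, −1.89) self-terminates at ~169 s (printed: 163 s) but with peak
[Na⁺]ᵢ ≈ 13.7 mM (printed: 11.8 mM), and equilibrated CLs at mixed
operating points run 5–9% long because the cycle length drifts upward
with the slow [Na⁺]ᵢ equilibration over the first ~600 s. Likewise, in
this implementation I_CaT always *shortens* the cycle length of an
established pacemaker (direct depolarizing action dominating its indirect
Ca²⁺-loading effect), at every conductance and with either Ca²⁺ routing.
These residuals trace to formulation details of the original C++
implementation (exact I_f kinetics and ion bookkeeping) that the
published equations do not pin down; the package reports all such
quantities as computed, without adjustment.

Out of scope by design: multicellular coupling, autonomic/β-adrenergic
modulation, Markov channel variants, temperature scaling, stimulus
protocols, and formal bifurcation analysis.
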