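# Methods

## Model

The cell is a single electrical and spatial compartment,
`C_m dV/dt = I_inj − Σ I_chan − g_leak(V − E_leak)`, with Hodgkin–Huxley
channels `I = g_max · Π x^p · (V − E_rev)`. All quantities use the fixed
unit system {mV, ms, pA, nS, pF}, depolarization positive, outward current
positive, so the dynamics contain no unit conversions.

**Steady states.** Gating steady states are Boltzmann sigmoids
parameterized either by a slope factor k (mV) or an equivalent valence z,
linked by `k·z = kT/e = 25.69 mV` (25 °C; recordings were at room
temperature, and this constant reproduces the nernstian sodium reversal of
+61.4 mV from the recording solutions to 0.1 mV). The activation gates of
the A-type and sodium currents are *defined* as the cube root of the fitted
macroscopic conductance curve: `a(V) = [g(V)/g_max]^{1/3}`. This makes
`g_max · a³(V)` equal the measured conductance–voltage relation exactly at
every voltage — the identity on which all analysis round trips rest. Note
the consequence: a root-of-Boltzmann is not a Boltzmann. Its half-point
sits `(kT/ez)·ln 7 ≈ 11.6 mV` left of the conductance midpoint and its
hyperpolarized foot decays with length `3kT/ez` (17.9 mV for the sodium
gate) rather than the directly fitted single-gate slope (~8 mV). The fat
foot produces a real sodium window current (~10 pA near −50 mV) discussed
under *Limitations*.

**Time constants.** τ(V) laws are phenomenological: exponential-plus-offset
`A·exp(−V/V_s) + C`, quadratic polynomials, or voltage-stitched piecewise
laws. Activation/inactivation development was measured over depolarized
test ranges (V ≥ −30 mV for I_A, V ≥ −50 mV for the sodium h gate) and
removal of inactivation over recovery ranges (V ≤ −70 mV); the stitched law
applies each fit on its measured range and bridges the unmeasured gap by
linear interpolation, so continuity is guaranteed and no dynamics are
invented inside a measured range. Every law carries a positivity floor
(0.005–0.5 ms for fast gates, inactive inside the measured ranges; 30 ms
for I_h, where the floor also regularizes the published law below −110 mV).

**Reference parameterization** (see `crcell/reference.py`): C_m = 4.07 pF,
g_leak = 1/1877.7 MΩ = 0.533 nS, E_leak = −70 mV; I_A (8.08 nS to E_K =
−101 mV; a³ gate from the V₀ = −12.3 mV / z = 3.8 curve; ha gate −52.7 mV /
7.59 mV), I_Na (12.7 nS; m³ from −34.6 mV / 4.3; h gate −70 mV / 9.4 mV),
I_h (falling Boltzmann −100 mV / 9.02 mV), I_Ca(L) (persistent rising
Boltzmann, −20 mV / 6 mV, τ = 1 ms). The A activation order defaults to 3
(the order used to extract the gate curve); order 4 — the assumption under
which time-to-peak is inverted to τ_m — is available as an argument, never
hard-coded.

### Parameters the source did not publish (invented, configurable)

- **E_Na = +63 mV** (model default). The conductance analysis divides by
  (V − 63); giving the model a different reversal (e.g. the nernstian
  +61.4) tilts the plateau of g(V) = I/(V−63) and biases the recovered
  valence by +5% and the maximal conductance by −8%, spoiling the round
  trip the model exists to support. The nernstian value remains available
  (`nernst`, `E_NA_NERNST_MV`, the `e_na=` argument).
- **g_h = 0.1 nS, E_h = −35 mV.** The published tail analysis is
  normalized, so only the activation curve matters for parameter recovery;
  the absolute conductance was chosen so the depolarizing sag becomes
  evident only below −90/−100 mV and amounts to a few mV on a −15 pA step,
  matching the qualitative description of these cells. (A conductance of
  1 nS would make I_h twice the leak at −100 mV — a dominant current, which
  these small cells do not show in standard saline.)
- **g_Ca = 0.15 nS, E_Ca = +65 mV, activation −20 mV / 6 mV, τ = 1 ms,
  no inactivation.** The measured value — a chord conductance of ~0.6 nS
  near the I–V peak — cannot be carried by an ohmic driving force: real
  L-type flux rectifies (GHK; with 2 mM external Ca²⁺ the true current at
  +40 mV is ~30% of the ohmic extrapolation), and any ohmic persistent Ca
  conductance above ~0.18 nS (= g_leak/3.04, from the slope of the
  steady-state I–V) folds the membrane's I–V curve, creating a stable
  depolarized plateau near +40 mV that contradicts the cell's observed
  single-spike, ohmic-late-phase behavior. 0.15 nS is the largest round
  value under the monostability bound; the Ca current remains inward,
  persistent, and maximal near the activation/driving-force optimum.

## Protocol engine

Gates advance by exponential Euler — the closed form
`x ← x_∞ − (x_∞ − x)e^{−dt/τ}` at the instantaneous V — which is
unconditionally stable and *exact* for piecewise-constant V (the discrete
update telescopes to the analytic relaxation; the voltage-clamp path
exploits this and evaluates whole constant-voltage segments vectorized).
The membrane potential advances by forward Euler at dt = 0.01 ms (0.05 ms
for the multi-second I_h sweeps); halving dt changes spike peaks and peak
clamp currents by <0.5%.

The clamp is ideal: no series resistance, no capacitive transient; in
voltage clamp the recorded current is the algebraic channel + leak sum. The
initial state is the steady state at the first segment's level, so there
are no settling artifacts. Current-clamp protocols that specify a holding
potential are implemented the way an amplifier implements them: a constant
bias current zeroing the net membrane current at the holding level. This is
not cosmetic — the cube-root m_∞ foot gives the reference cell a sodium
window current that would otherwise drift its rest ~13 mV depolarized of
the −70 mV at which the cells were actually held.

Channel isolation (`model.isolated("I_A")`) zeroes the other conductances
*and the leak*, the in-silico equivalent of pharmacological isolation plus
ideal leak subtraction; the constant term of a decay fit then contains only
sustained channel current, which is what the zero-time extrapolation
assumes.

## Analysis procedures

All fits are deterministic: exponentials are seeded by log-linear
regression, Boltzmanns by the interpolated half-maximum crossing and the
25–75% width. Each fit is idempotent (refitting its own prediction
reproduces the parameters to 1e−6).

- **Zero-time extrapolation:** fit `A·e^{−t/τ} + C` over [2·ttp, step end]
  (t from step onset, pre-step baseline subtracted) and report A + C — the
  open-channel current corrected for inactivation. If noise pushes the
  apparent peak so late that the window has <8 samples, the fit falls back
  to the final quarter of the step with a warning.
- **Conductance and gates:** g = I/(V − E_rev) pointwise; single-gate
  curves as (g/g_max)^{1/r}, values above g_max clipped with a warning.
- **Inactivation and recovery:** peak test currents normalized to the
  maximum, falling Boltzmann; recovery fitted as P_max(1 − e^{−gap/τ}),
  flagged when all gaps far exceed the fitted τ. The inactivating pulse of
  the double-pulse protocol lasts 100 ms (4.3× τ_ha at +20 mV): with
  incomplete inactivation the through-zero exponential fit is biased fast
  (36 vs 42 ms with a 50 ms pulse).
- **Sodium family preconditioning at −120 mV:** the availability curve
  (V₅₀ = −70, k = 9.4) leaves 4% of channels inactivated at −100 mV, an
  underestimate of g_Na,max the extrapolation cannot correct; −120 mV gives
  the complete removal of inactivation the procedure assumes.
- **I_h tails:** I_inst over [5, 15] ms after the step, I_ss over the last
  10%; tail amplitudes right after the transition referenced to the relaxed
  tail. Because that reference sits at the tail potential's own partial
  activation, the normalized curve is an affine image of the activation
  curve, and the fit therefore includes a free baseline term — without it
  the recovered slope steepens from 9.02 to 8.7 mV.
- **Time-to-peak inversion:** `ttp = τ_m ln(1 + p·τ_h/τ_m)` solved for τ_m
  by Newton iteration (monotone; no solution when ttp ≥ p·τ_h, which is an
  error).

## Synthetic data

Recording noise is additive white Gaussian on the measured channel (current
in VC, voltage in CC), seeded and byte-reproducible. It does not emulate
1/f noise, line pickup, seal leak, electrode drift, or capacitive
transients — so noise-robustness results bound only the fitting pipeline's
sensitivity to stochastic error, not to the structured artifacts of real
rigs. Populations jitter scale parameters (C_m, g_leak, g_max)
multiplicatively (default CV 10%, truncated at ±3 SD), midpoints by ±2 mV
and slopes by ±5%.

## Problem sizes and numerical choices

The standard runs use 9-sweep activation families (−40…+40 mV, 10 mV
steps, 100 ms / 40 ms steps for A / Na), 10 prepulse levels (−100…−10 mV,
500 ms), 10 recovery gaps (5–250 ms), 8 five-second I_h sweeps, and a
7-level current-clamp family (−15…+45 pA, 300 ms); dt as above. The full
reproduction table builds in ~30 s on one core.

## Known limitations

- **Late-phase I–V linearity:** the full reference cell gives r² = 0.986
  over −15…+45 pA (slope 2.07 GΩ, +10% of R_in), not ≥0.99. The bend is
  the sodium window current implied by the cube-root m_∞ foot; the
  directly fitted activation curve (midpoint −45.8 mV, slope 8.1 mV) would
  give a negligible window, but the model gate is deliberately the
  cube-root construction. "Almost linear" is reproduced; a stricter
  criterion is not attainable under this gate definition.
- **−50 mV preconditioning:** the printed inactivation curve leaves
  ha_∞(−50) ≈ 0.59, so a −50 mV prepulse suppresses the evoked A-current
  by ~40–50%, not to near zero as the qualitative description of the
  original recordings suggests; a single-Boltzmann HH gate has no slow or
  cumulative inactivation to close that gap.
- The double-pulse recovery τ at −70 mV measures 43.1 ms against a gate τ
  of 42.2 ms (published 41.9): the residual activation-gate occupancy at
  short gaps slightly distorts the peak-versus-gap curve.
- Markov channel schemes, Q10 temperature scaling, stochastic gating,
  multi-compartment cables and synaptic conductances are out of scope.
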