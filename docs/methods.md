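# Methods

`hiersong` implements a three-level hierarchical rate model of birdsong
generation and its online Bayesian inversion.  This note documents the
model equations as implemented, the calibration constants and why they
have the values they do, the numerical schemes, and the known
limitations — in particular which behaviours of the recognition filter
fall short of the idealized scheme and why.

## The generative hierarchy

Generation is strictly top-down.  Three neural levels run on one shared
time grid (model time units; `dt = 0.01` by default), and each level's
*causal states* (outputs) drive the level below, while its *hidden
states* evolve under the level's own dynamics.

### Level 3 — HVC sequence (winnerless competition)

`N = 8` neural-mass units with membrane potentials `x` and logistic
firing rates `S(x) = expit(gain (x − offset))` compete through lateral
inhibition:

    dx_i/dt = κ₃ [ S(x_i) (1 − Σ_j ρ_ij S(x_j)) − λ x_i ] + w_i

The inhibition matrix ρ follows the heteroclinic-chain recipe: each unit
inhibits its cyclic successor weakly (0.5), itself with strength 1.0 and
everyone else strongly (1.5).  Each single-winner state is then a saddle
with exactly one unstable direction pointing at the successor
(`chain_is_stable` verifies the eigenstructure on the Lotka–Volterra
competition skeleton, where the saddle spectrum is available in closed
form).  The defaults `gain = 10`, `offset = 0.3`, `λ = 0.1` place the
system in a *deterministic flow-through* regime: the loser rate floor
(S ≈ 0.02) is high enough that the successor needs no noise kick to
escape, so the sequence is periodic, noise-robust, and visits all N
units in order with ~10.2 time units per activation at κ₃ = 1.  The
output is the divisively normalized rate vector `v = S(x)/(0.05 + Σ S)`.

Because the drift is proportional to κ₃, time rescaling is *exact*:
halving κ₃ doubles every activation without changing anything else.
This single fact carries the model's account of the HVC cooling
experiments.

**Long chains.** The logistic floor does not vanish at inactive units,
so its summed inhibition grows with N and eventually either silences the
winner or (if the floor is deepened) freezes the successor below its
escape threshold.  `chain_preset(n)` therefore sharpens the sigmoid for
larger chains (gain 20 above 12 units, gain 50 above 40), calibrated so
flow-through sequencing survives at 32 and 100 units; only the rate
constant is then rescaled to restore the standard activation duration.
The pure Lotka–Volterra rate equations the construction is modelled on
have an exact zero floor and would need no such correction.

### Level 2 — RA attractor network

`M = 5` units form a continuous Hopfield network with an asymmetric
random coupling matrix `W` (spectral norm 0.6, fixed seed):

    dx/dt = κ₂ C (−x + W tanh x + I(t)) + w

`‖W‖₂ < 1` is the implemented sufficient condition for a unique globally
asymptotically stable equilibrium under any constant input (unit-slope
tanh contraction argument); `is_globally_stable` reports the norm as its
certificate.  Each HVC unit k contributes a constant steering vector
`I_k = ξ_k − W tanh(ξ_k)` that places the global equilibrium exactly on
the signed target `ξ_k ∈ {±a}^M` (a = 2, so tanh(±a) ≈ ±0.96) of the
k-th score pattern; the total input is the v-weighted mixture
`I(t) = Σ_k v_k(t) I_k`.  Because the steering input is derived from the
network's own `W`, two differently wired networks reach the same
activation patterns from different inputs — the compensation property
behind the "differently wired brains" experiment.

`C = diag(12)` sets the attractor settling time to ~0.08 time units,
about 1% of an activation.  This strong time-scale separation is the
architectural point of the level: pattern *identity* is RA's job, pattern
*timing* is HVC's.  It is what makes halving C invisible in the output
(the measured control-signal change is ≈1.6% RMS) while halving κ₃
stretches the whole song.  The level emits two outputs: normalized rates
`H((tanh x + 1)/2)` (which gate the oscillators) and the unnormalized
rates (exported for inspection only).

### Level 1 — oscillator bank and vocal control signals

Five Stuart–Landau oscillators at frequencies `m·ω` (m = 1..5,
ω = 2π/5 rad per time unit) hold quadrature pairs of unit radius; the
radial restoring force (rate 4) pins the amplitude so that on the cycle
each pair is exactly a sine/cosine generator.  RA gates the bank at the
output:

    y₁(t) = Σ_i v_i(t) s_i(t),    y₂(t) = Σ_i v_i(t) s_i(t − φ)

with φ a quarter period of the fundamental.  The delay is realized as a
per-oscillator phase rotation, which keeps the output map Markovian in
the state (required for recognition); for frozen gates y₂ is exactly the
time-shifted copy of y₁.  Affine maps produce the two vocal control
signals: air-sac pressure `p = 0.9 + 0.7 y₁` (dimensionless, phonation
threshold units) and labia stiffness `k = 1.58·10⁷ + 9.8·10⁶ y₂` rad²/s²
(fundamental frequency roughly 400–800 Hz).  One oscillator traces an
ellipse-like closed orbit in the (p, k) plane; harmonic mixtures deform
it into richer syllable-specific curves.

### Syrinx

The vocal organ is the labia-position oscillator

    x'' = r (p − β) x' − c x² x' − k x

integrated with fixed-step RK4 at 12 kHz, with the control signals
linearly interpolated onto real time at 0.08 s per model unit (one
activation ≈ 800 ms; the 8-step song ≈ 6.5 s).  β = 1 is the phonation
threshold: below it the origin is stable (mini-breaths), above it a Hopf
bifurcation yields a limit cycle whose amplitude saturates through the
cubic term (c = 3000) and whose fundamental grows like √k.  The pressure
excess is converted to a growth rate by r = 1000 s⁻¹.  A weak seeded
stochastic forcing on the labia velocity (sd 20, `syrinx.noise_floor`)
emulates the aerodynamic noise floor; without it the amplitude decays by
tens of orders of magnitude during sub-threshold intervals and phonation
cannot re-seed at the next syllable.  Setting the floor to zero recovers
the strictly deterministic equation used for the threshold and pitch
tests.

### The example song

Eight HVC steps map to RA patterns {2,3,4}, {1,3,5}, {1,4}, {5}, {2,5},
{1,2,3}, {1,4}, {3,4,5}: the first three are the documented example, the
remaining five are fixed repository constants chosen so that exactly 7
of the 31 possible patterns occur, one of them ({1,4}) twice.  The
repeat is consequential for recognition (below).

## Recognition

The listener observes only the two-channel control signal (normalized
back to (y₁, y₂) by the known affine constants) and infers posterior
state estimates at all three levels by gradient flow on precision-
weighted prediction errors — the D-step of a variational filtering
scheme under the Laplace assumption.  Parameters are fixed: the listener
has learned the song.

States are held in generalized coordinates (position + velocity,
embedding order 2; an order-3 variant exists but is experimental).
Per level, the errors are the order-0 causal error (input-from-below
minus predicted output), its linearized first-order companion on the
velocities, and the order-0 dynamical error (velocity estimate minus
drift).  The Jacobians inside the first-order errors are evaluated at
the current mode (a Gauss–Newton convention); the free-energy gradient
is exact for that objective, which is what the finite-difference check
verifies.  Each sample advances the mode by a matrix-exponential
(local-linearization) step of `dμ/dt = Dμ + ∂F/∂μ`.

Design choices that took real experimentation, with their rationale:

- **Clamped oscillators.** The level-1 hidden states are the listener's
  internal clock: autonomous, deterministic, and shared with the singer
  by the phase convention at song onset.  They evolve by their own flow
  and are excluded from the gradient.  Inferring them instead lets the
  filter absorb arbitrary sensory mismatch into slow oscillator
  amplitude/phase drift (a few 1e-4-sized dynamical errors per step buy
  large sensory gains), silently corrupting the clock and destroying
  gate identifiability.
- **Moderate sensory gain.** Gate inference is a regression of a
  2-channel stream on five known harmonics: instantaneously
  underdetermined, perfectly conditioned over a quarter fundamental
  cycle.  A very high sensory precision turns the filter into a
  per-sample projector that over-weights the present (tracking
  correlation drops by ~0.15); the default `z1 = 3·10²` integrates
  evidence over the basis rotation.
- **Velocity shrinkage.** Causal-state velocities carry a zero-mean
  prior (`dv ≈ 10`): gates and chain outputs are piecewise constant, so
  motion requires evidence.  Without it the unobserved null-space
  components of the gates drift without bound.
- **Soft RA dynamics, elastic top-down.** The RA drift residual is
  deliberately low-precision (`x2 = 3`): the input estimate absorbs
  small residuals instead of transmitting spurious forces into the
  chain.  The top-down causal precisions act as elastic couplings; in
  quasi-static balance they transmit exactly the bottom-up force applied
  to them, which is why the effective knobs are the *source* gains
  (sensory and gate-mismatch precisions) rather than the couplings.
- **Chain rest prior.** A weak Gaussian prior (precision 1) pulls the
  chain states toward the loser baseline (−0.1).  Transient inference
  forces otherwise push loser units into the saturated sigmoid tail,
  where the chain's own restoring flow is too weak to bring them back
  and sequencing stalls.
- **Initial state.** The listener starts its chain at the rest baseline
  plus seeded noise — deliberately different from the singer, which
  starts at the first saddle.  Lock-in takes about 1.5 activations; the
  experiments score tracking after a two-activation burn-in.

### Measured performance and honest limitations

On default-noise songs the filter reconstructs the sensory stream with
correlation ≈ 0.99 and the RA gates with ≈ 0.99; the HVC causal states
reach ≈ 0.88–0.90 (flattened correlation over all channels after
burn-in), with per-sample winner accuracy ≈ 0.93.  The remaining HVC-level
deficit has two sources, both structural:

1. **Transition lag.**  Evidence of a syllable change must propagate
   gates → RA state → RA input → chain; each stage adds delay, and the
   chain's transitions run ~1–2 time units behind the singer's.  At
   steady state (windows past the lock-in and away from the repeated
   pattern) the level-3 correlation runs 0.92–0.94.
2. **The repeated pattern.**  Steps 3 and 7 drive the *same* RA pattern
   {1,4}; only chain context distinguishes them, and the posterior
   genuinely splits between the twins until the chain catches up.

The same two facts shape the deviation experiment.  When the singer's
third syllable activates RA {1,4} but the listener expects {1}, the
mathematically cheapest explanation available to the listener is that
the song *skipped to step 7* (whose pattern is exactly {1,4}): the filter
jumps its chain there, explains the syllable essentially without error,
and jumps back afterwards.  Prediction-error surges are therefore
confined to the two out-of-order jumps rather than sustained across the
deviant syllable.  Position updates in a gradient-flow filter bypass the
velocity-consistency penalty (the dynamics error constrains velocities,
not positions), so no setting of the dynamics precision forbids the
jump; blocking it would require the higher-order path stiffness of a
deeper generalized-coordinate embedding.  The recovery half of the
deviation claim (error energy back within 2× baseline after the
syllable) does hold.

The tempo experiment behaves as intended: a 3% slowed song produces
error energies above the matched-tempo baseline in 100% of syllable
windows at all three levels, while the ideal run does not.

## Problem sizes and determinism

The default song is 81.25 time units (8,125 samples at dt = 0.01;
6.5 s of audio at 12 kHz).  One full recognition pass takes roughly half
a minute on one core; the scaling experiment uses a 100-unit chain
(generation only, dt = 0.002 for the stiffer sharp-gain preset) and a
32-step song recognized on a 2×-coarsened sample grid.  Every stochastic
path is driven by a `numpy` `default_rng` seed threaded from the single
top-level seed; identical seeds give bitwise-identical trajectories and
exported files.

## What the synthetic conditions do not show

All tests run on songs produced by the package's own generator: the
listener's model class is exactly the singer's, noise is Gaussian and
small (sd 10⁻³ hidden, 10⁻⁴ causal; a ×10 preset mirrors the
high-noise condition), and the oscillator phase convention is shared.
Real birdsong offers none of these: the control signals would have to be
extracted from sound, the listener's model is at best misspecified, and
phase alignment at song onset is not given.  Passing these tests
demonstrates the internal consistency and the qualitative phenomenology
of the scheme (lock-in, timing sensitivity, rewiring compensation), not
recognition performance on natural song.
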