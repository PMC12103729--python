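# Methods

This note records the modelling choices behind `koopgait`: the switched
ankle plant and its parameters, the synthetic-data protocol, the EDMD
identification and its evaluation protocols, the MPC formulation and
solver, and what the desk-scale studies do and do not demonstrate.

## Switched ankle plant

The ankle is a single hinge with phase-dependent inertia, driven by two
antagonist FES channels:

    J_σ θ̈ + f(θ, θ̇) = τ_pf(u_pf) + τ_df(u_df) + (1 − σ) r(θ) F_grf(t)
    f(θ, θ̇) = c θ̇ + k (θ − θ₀) + m g l · sin θ

* σ = 0 in stance, 1 in swing.  The *operational* phase signal is obtained
  by thresholding the GRF (> 1 N ⇒ stance), exactly the rule a GRF-sensing
  treadmill controller uses.  Because the half-sine GRF template is zero at
  the contact instant itself, the single heel-strike sample of each cycle
  is labelled swing; this is deliberate (the label must be a function of
  the measurable GRF) and the identification and evaluation code treat that
  one-sample segment as belonging to neither phase.
* Muscle recruitment is a piecewise-linear saturating curve in current:
  zero below threshold, linear to the maximum torque at saturation.
  Dorsiflexion is positive; the plantarflexor torque is negative.
* r(θ) = r₀ cos θ is the effective GRF moment arm.

### Parameter defaults and rationale

| parameter | default | units | rationale |
|---|---|---|---|
| J_P / J_D | 0.08 / 0.05 | kg·m² | foot + distal-shank effective inertia; stance slightly larger |
| c (viscous) | 1.2 | N·m·s/rad | damping ratio ≈ 0.55–0.7 with k below |
| k (elastic) | 15 | N·m/rad | passive + tonic ankle stiffness about neutral |
| θ₀ (rest) | 0 | rad | neutral ankle |
| m g l | 1.0 | N·m | ≈ 1 kg foot, 0.1 m centre-of-mass lever |
| threshold / saturation | 6 / 45 | mA | surface-FES recruitment range |
| max torque | 15 | N·m | FES-evoked ankle torque at saturation; makes ±15° set-points reachable inside the 10–25 / 10–20 mA boxes |
| GRF peak / moment arm r₀ | 350 N / 0.002 m | | slow, supported treadmill walking with the load path close to the joint centre; the product (0.7 N·m peak) is the *net* unbalanced external moment, since volitional co-contraction is not modelled |
| cycle / stance fraction | 1 s / 0.6 | | 200 samples per cycle at 200 Hz; standard stance share |

With these values the passive plant is an underdamped second-order system
(≈ 2.2–2.8 Hz natural frequency), mildly nonlinear through sin θ, the
recruitment dead-zone, and the stance-only GRF torque — the regime in which
a 13-dimensional lifted linear model can be predictive.

### Integration

Classical fixed-step RK4 at the sampling rate (optionally sub-stepped),
with zero-order hold on the currents *and on the phase flag*: each step
integrates a single smooth vector field, with the phase clock advancing
across stages.  The default grid (200 samples, 0.6 stance fraction) puts
every phase switch exactly on a step edge, so states remain continuous
across switches and the integrator observes its nominal fourth order
(verified by step-halving in the test-suite).

## Synthetic-data protocol

`DataGenConfig` defaults are the study conditions: 150 independent gait
cycles, 200 samples each at 200 Hz (30,000 samples); per cycle the initial
angle is uniform in [−20°, 25°], the initial velocity uniform in
[−2, 2] rad/s (the printed velocity range carries no units; rad/s is
assumed and configurable), and the active muscle's current ramps linearly
0 → 30 mA across its phase.  A second input mode draws one uniform level
in [0, 50] mA per phase per cycle.

The two modes serve different purposes:

* **Ramps** are the printed identification protocol and are used for every
  prediction study.  But a deterministic ramp is *perfectly collinear with
  the gait clock* — identical in every cycle — so the input's effect cannot
  be separated from time-of-cycle effects.  A ramp-trained model predicts
  ramp-driven cycles well and is useless for control (the swing-phase
  input gain even fits with the wrong sign).
* **Random levels** vary across cycles and identify the input gain; the
  closed-loop model is trained in this mode.

The generator does *not* emulate: sensor noise, torque ripple at the
stimulation frequency, muscle fatigue or activation dynamics, inter-cycle
timing variability, or multi-joint coupling.  Passing studies therefore
demonstrate correctness of the identification and control machinery under
clean, repeatable switched nonlinear dynamics — not robustness to
physiological variability.

## Identification (EDMD) and evaluation

The lifted regression uses the minimum-norm LAPACK least-squares solution
of K D_k ≈ D_{k+1} (equivalently F G⁺); the training pipeline adds a tiny
ridge (10⁻⁸) because the custom library is nearly collinear at gait-scale
angles (sin θ ≈ θ to cubic order).  Held-out prediction is insensitive to
this ridge over 10⁻¹⁰–10⁻⁶.  Rows of the operator that would evolve the
control observables are fitted and discarded; diagnostics (per-phase
residuals, Gram-matrix conditioning, recovery residual) are recorded on
the model.

The recovery map C is fitted over both phases pooled.  The reduced
controller model Ã = C K_xx C⁺ needs a right inverse of the non-square C;
the package uses the *data-weighted lift encoder* W = Ψ Z⁺ (regression of
the pooled lifted data on the raw states), i.e. the right inverse
restricted to the lifted training subspace.  The plain Moore–Penrose
pseudoinverse represents a state by the minimum-norm lifted vector, which
with collinear observables lies far off the training manifold and badly
corrupts Ã (a sign-flipped stiffness term, in practice).

**Rollout protocols.**  Held-out accuracy is measured by multi-step
rollout in the lifted space (lift once, iterate K_xx/K_xu, recover through
C), seeded with true samples:

* L = 1: one continuous rollout per cycle, starting at the first phase
  segment (i.e. skipping the degenerate heel-strike sample, where neither
  phase operator is defined).
* L > 1: per-phase-segment rollouts, each seeded with its segment's first
  true L-window.  A delay window straddling a switch mixes the two vector
  fields and is excluded from training by construction, so a cross-switch
  rollout is undefined for delay embeddings; the segment-wise protocol is
  the faithful generalisation and is applied uniformly in the
  embedding-length study (L = 1, 8, 50).

The train/test split holds out the last 20 % of cycles.  Angle RMSE is
reported in degrees on the reconstructed physical angle (error +
reference); the full-state 2-norm variant is also available.

## MPC formulation

State: the 2-d tracking error e = (θ − θ_d, θ̇ − θ̇_d).  Per horizon step
the phase schedule (from the cycle timetable, with the current step's flag
taken from the measured GRF) selects the active muscle, its current box,
and the error-subsystem blocks (A_ee, B_e) of the reduced model.  The
reference enters as a known exogenous signal through

    d_j = A_ee x_d,j − x_d,j+1

which is exact for tracking a known reference, because the same fitted
matrix advances the physical state and the error.  The fitted
reference-coupling block A_ed is *not* used for control: it is identified
only on the training-reference manifold (a one-dimensional clock orbit)
and extrapolates arbitrarily off it.

Costs: Q = diag(100, 1) per degree², R = 0.01 per mA² (degree-scale
weights make degree-sized errors dominate mA-sized inputs; converted to
radians internally), horizon 20 steps at 200 Hz.  The terminal weight S_σ
per phase solves the DARE of (A_ee, B_e, Q, R); the final predicted state
carries S *in place of* the stage weight Q — the DARE fixed point already
contains Q, and only this split yields the exact receding-horizon
tail-shift identity and the value decrease V_{k+1} = V_k − l(·) under the
LQR terminal policy.  That decrease is certified with the unclipped
policy; inside the terminal set the policy is feasible by construction,
while the default stance box (u_min = 10 mA, always-on stimulation) would
clip it near the origin for reasons unrelated to stability.

Constraints: the per-muscle current box is hard (projection); the ±20°
clearance band and the terminal set z'Sz ≤ ε (ε = 1) are soft quadratic
penalties (weights 1000 per degree² and 10⁻³), so the solver always has a
feasible iterate.  Q, R, S, ε are nowhere dictated by data and are exposed
in configuration.

**Solver.**  The condensed input-only problem is a strictly convex
piecewise-quadratic box program (≤ 20 variables).  It is solved by
projected Newton with active-set identification and backtracking on the
projected arc.  A first-order Barzilai–Borwein projected-gradient scheme
was evaluated first and stalls on this problem class: the degree²-vs-mA²
weight ratio drives the condensed Hessian's condition number to ~10⁹,
where 200 first-order iterations remain three orders of magnitude from
stationarity.  Projected Newton is exact here in a handful of iterations
and is validated in the tests against a dense least-squares oracle and
exhaustive input-grid search.

The closed loop warm-starts each solve with the shifted previous solution
and holds the previous input if a solve fails (logged per step).

## Study sizes and numerical choices

* Prediction studies and the acceptance script use 30–50 cycles (80/20
  split); the full 150-cycle protocol backs the sample-count check and the
  embedding-length study.  These sizes were chosen as the smallest at
  which the reported quantities are stable across seeds.
* Closed-loop studies run 3 cycles per speed analogue (treadmill speeds
  0.1/0.2/0.3 m/s mapped to 4/3/2 s cycle durations — an analogy, not a
  biomechanical reproduction), skipping the first cycle as transient, and
  report per-phase core RMSE (blend windows excluded) with SD over cycles.
* Set-point targets default to −15° (stance) / +15° (swing) inside the
  ±20° band, cosine-blended over 10 % of the cycle (slow-walking
  transitions are assumed smooth); with a zero blend window the reference
  is an exact step and its velocity channel is zero with declared
  discontinuity indices.
* Ties/degenerate cases: all-zero snapshot matrices raise a degenerate-fit
  error; rank-deficient lifted data triggers a warning and a regularized
  recovery solve; a non-stabilizable DARE pair raises.

## Known limitations

* The reduced linear model carries no affine term, so constant unmodelled
  torques (recruitment dead-zone offset, mean GRF moment) appear as
  steady-state disturbances that only feedback attenuates.
* Phase operators are valid on their own phase's clock region; predictions
  that cross a switch inherit a small hand-off error (L = 1 only).
* The value-decrease certificate is nominal (model-as-plant); no robust or
  dwell-time switched-stability analysis is attempted.
* Current amplitude is the only stimulation channel; pulse width and
  frequency modulation, fatigue, and volitional effort are out of scope.
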