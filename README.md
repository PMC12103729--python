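# koopgait

Koopman-operator modelling and switched model predictive control (MPC) of
functional electrical stimulation (FES) for ankle gait assistance — with a
self-contained musculoskeletal ankle simulator, so the whole identify →
predict → control loop runs at desk scale.

## The problem

FES restores plantarflexion (push-off, gastrocnemius) and dorsiflexion (toe
clearance, tibialis anterior) in people with drop foot or weak push-off by
driving the muscles with current pulses.  Designing those currents is a
constrained optimal-control problem on awkward dynamics: the ankle switches
between stance and swing, muscle recruitment saturates, and the ground
reaction force (GRF) loads the joint only while the foot is down.  The
package takes the data-driven route: lift the nonlinear dynamics into a
space of observables where they evolve (approximately) linearly, identify
one linear predictor per gait phase, and run a linear MPC on the result.

## The model

**Plant.**  A switched second-order hinge joint,

```
J_σ θ̈ + c θ̇ + k (θ − θ₀) + m g l sin θ = τ_pf(u_pf) + τ_df(u_df) + (1−σ) r(θ) F_grf(t)
```

with phase flag σ = 0 (stance) / 1 (swing) detected by thresholding the
GRF, piecewise-linear saturating recruitment curves per muscle
(threshold/saturation/max-torque in mA and N·m), and a half-sine GRF
template over stance.  Integrated by fixed-step RK4 with zero-order-hold
inputs at 200 Hz.

**Identification (EDMD).**  The tracking state z = [e; x_d] (error and
reference, angle and velocity each) is lifted by an observable dictionary
Ψ; snapshot pairs from each phase give the least-squares Koopman operator

```
K = F G⁺,   F = (1/M) Σ Ψ_{k+1} Ψ_kᵀ,   G = (1/M) Σ Ψ_k Ψ_kᵀ
```

whose state blocks (K_xx, K_xu), together with a fitted recovery map C
(z ≈ C Ψ), yield the switched linear predictor
z⁺ = Ã_σ z + B̃_σ u_σ.  Three dictionaries are built in: the raw `state`
coordinates, a `trig` family, and the 13-dimensional `custom` ankle library
(linear terms, sin/cos, squares, and products of the position-like
coordinates plus a constant), optionally delay-embedded over L past states.

**Control.**  A phase-switched receding-horizon problem at 200 Hz with a
0.1 s horizon: quadratic tracking cost Q = diag(100, 1) (degrees) and
R = 0.01 (mA), hard per-muscle current boxes (stance 10–25 mA, swing
10–20 mA), a soft ±20° clearance band, and a terminal cost/set from the
discrete algebraic Riccati equation of each phase's error subsystem, with
the LQR terminal policy certifying the value-function decrease
V_{k+1} ≤ V_k − l(·) on the nominal model.  The condensed box-constrained
problem is solved by projected Newton.

## Worked example

```python
from koopgait import (AnklePlantParams, DataGenConfig,
                      generate_dataset, run_prediction_study)

params = AnklePlantParams()
dataset = generate_dataset(DataGenConfig(n_cycles=30, seed=7), params)
report = run_prediction_study(dataset, params,
                              dictionaries=("state", "custom"),
                              embeddings=(1, 8), seed=7)
print(report.summary())
```

prints

```
config=e44fd08d3bd4 seed=7
dictionary  embedding_length  lifted_dim  rmse_mean_deg  rmse_sd_deg  n_train_cycles  n_test_cycles  meets_threshold
     state                 1           5         0.2294      0.01744              24              6             True
     state                 8          33        0.03707     0.006084              24              6             True
    custom                 1          13         0.1122      0.03698              24              6             True
    custom                 8          97        0.02633     0.008198              24              6             True
```

Each row is one (dictionary, embedding length) model fitted on the first
24 gait cycles and rolled out multi-step over the 6 held-out cycles with
the recorded currents and phase flags; `rmse_mean_deg` is the resulting
ankle-angle prediction error.  All four models meet the 0.5° accuracy
threshold; the nonlinear custom library beats the raw state coordinates,
and longer delay embeddings tighten the prediction further.

The same pipelines are scriptable from the shell:

```
koopgait config init                 # print all defaults as YAML
koopgait simulate --seed 7 --n-cycles 30 --out-dir data/
koopgait train    --data-dir data/ --dictionary custom --out model.npz
koopgait predict  --model model.npz --data-dir data/ --report rmse.csv
koopgait control  --model model.npz --speed 0.2 --out log.csv
koopgait evaluate --seed 7 --out-dir study/   # full prediction + closed-loop study
```

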