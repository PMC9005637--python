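# gaitphase

Continuous gait-phase estimation from sagittal thigh and torso kinematics,
with a focus on how torso information affects estimation accuracy across
walking speeds.

Wearable assistive devices (powered prostheses, exoskeletons) need to know
*where the user is in the gait cycle* — a phase τ̂ ∈ [0, 1) running from one
heel-strike to the next of the same leg — continuously and at every walking
speed. This package implements, as a tested and reusable pipeline:

* **Polar phase labeling.** Percent-cycle ϕ ∈ [0, 100] anchored at
  heel-strike is encoded as θ = 2πϕ/100, (P<sub>x</sub>, P<sub>y</sub>) =
  (cos θ, sin θ), which is continuous across the heel-strike boundary where
  the linear label jumps 1 → 0; predictions are decoded back with
  τ = atan2(P<sub>y</sub>, P<sub>x</sub>)/2π (plus 1 when P<sub>y</sub> < 0).
* **Sliding-window recurrent regression.** A five-layer network — four
  LSTM layers of 128/64/64/32 units (layer 1 bidirectional) and a dense
  2-output head — maps a 100-sample window of kinematic channels at 100 Hz
  to (P<sub>x</sub>, P<sub>y</sub>) at the window's last sample. Training:
  Adam, MSE, batch 64, ≤100 epochs, early stopping with patience 10 on
  validation loss. The network is implemented in numpy (forward, BPTT,
  Adam) and validated by finite-difference gradient checks; the estimator
  is a scikit-learn-style class (`PhaseLSTMRegressor`) with
  `fit`/`predict`/`get_params`.
* **Feature ablation × speed models.** Feature sets — Set 1: thigh angle,
  thigh velocity, torso angle, torso velocity; Set 2: drop torso angle;
  Set 3: drop torso velocity; Set 4: thigh only — crossed with three
  speed-dependent models by training conditions (general: C2–C5; slow: C2;
  normal-fast: C3–C5, where C2 = 0.4–0.8 m/s … C5 = 1.4–1.8 m/s), all on
  subject-disjoint train/validation/prediction partitions.
* **Variability analysis.** Per subject and speed, strides are
  time-normalized to 101 points and averaged; the 51×51 Pearson correlation
  matrix over [grand mean A, S₁…S₅₀] is summarized by its first row
  (mean ± SD of corr(A, Sᵢ)).
* **Evaluation.** MSE on (P<sub>x</sub>, P<sub>y</sub>), wrap-aware circular
  phase error, mid-stance (30–50 % of cycle) MSE, heel-strike detection
  error from downward wraps of the predicted phase, and two-way ANOVAs with
  Bonferroni-corrected post-hoc comparisons (α = 0.05, stars at
  0.05/0.01/0.001).
* **Synthetic cohorts.** A generator producing walkway-like multi-speed
  trials (thigh: one oscillation per stride; torso: forward lean with an
  exact 2-per-cycle oscillation; speed-dependent stride durations with
  log-normal jitter; smooth band-limited perturbations whose torso
  amplitude grows as speed drops), so the whole pipeline is testable
  without any external download.

## Worked example

```python
from gaitphase import (generate_cohort, VariabilityModel, run_grid)

cohort = generate_cohort(12, ["C2", "C3", "C4", "C5"], 2,
                         variability=VariabilityModel.informative_torso(),
                         seed=3)
result = run_grid(cohort, sets=("SET2", "SET4"), models=("general",),
                  n_prediction_subjects=3, window_len=100, train_stride=6,
                  hidden_units=(32, 16), bidirectional=(True, False),
                  max_epochs=8, patience=3, base_seed=5)
print(result.predictions.groupby("feature_set")["mse_polar"].mean())
```

prints (one training run per cell, a few minutes on one CPU core):

```
feature_set
SET2    0.031706
SET4    0.040730
Name: mse_polar, dtype: float64
```

i.e. on held-out subjects the model using thigh information *plus torso
angular velocity* (Set 2) reaches a lower polar-output MSE than the
thigh-only baseline (Set 4) — torso angular velocity carries usable phase
information even though torso signals are the more variable ones. The same
`AblationResult` carries per-condition errors, heel-strike detection errors
and training histories for every cell.

A command-line interface mirrors the library
(`gaitphase simulate | label | train | ablate | evaluate | report |
pipeline`); `gaitphase pipeline --config cfg.yaml --out run/` runs
simulate → variability → ablation → ANOVA end to end and writes tidy CSVs
plus a provenance manifest.

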