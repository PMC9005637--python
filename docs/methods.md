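# Methods

## The estimation problem

The gait cycle runs from one heel-strike to the next heel-strike of the
same leg. The continuous gait phase is a scalar τ̂ ∈ [0, 1) marking the
walker's progression through that cycle; wearable-device controllers use it
to synchronize assistance with the user. The estimator here regresses τ̂
from a sliding window of sagittal-plane segment kinematics: thigh angle,
thigh angular velocity, torso angle, torso angular velocity, sampled at
100 Hz.

## Phase labeling

Ground truth comes from heel-strike events. Between consecutive strikes,
percent-cycle ϕ rises linearly from 0 to 100; samples before the first or
after the last strike are unlabeled and excluded from training and
evaluation (phase is only defined between strikes; no extrapolation).
Because the linear label jumps 100 → 0 at heel-strike, the regression
target is the polar encoding

    θ = 2π·ϕ/100,   (Px, Py) = (cos θ, sin θ),

continuous across the boundary. Decoding uses τ = atan2(Py, Px)/2π with 1
added when Py < 0, giving τ̂ ∈ [0, 1) with exact 0 at heel-strike. Decoding
depends only on the output angle, so raw network outputs are decoded
without re-projection onto the unit circle; raw outputs are also kept for
MSE against the targets.

## Network and training

Window length 100 samples (1 s), stride 1 at prediction time; the target
belongs to each window's final sample. The default architecture follows
the five-layer design: recurrent layers of 128, 64, 64, 32 units and a
dense 2-output head. Which layers are bidirectional is configurable; the
default makes layer 1 bidirectional with its 128 units split 64 per
direction, layers 2–4 unidirectional. Training: Adam (learning rate 1e-3 —
a conventional default, exposed in config), MSE jointly over both outputs,
batch 64, at most 100 epochs, early stopping when validation MSE has not
improved for 10 epochs, restoring the best-epoch weights. Channels are
z-scored per channel with statistics from the training windows only.
Splits are always by subject: train, validation and prediction subject
sets are pairwise disjoint, mirroring a 42/8 train-test partition of a
50-subject cohort at full scale.

The LSTM/Bi-LSTM stack, backpropagation through time and Adam are
implemented directly in numpy (float64). Gate order (input, forget, cell,
output), forget-gate bias initialized to 1, uniform ±1/√(fan-in + units)
weight init. Gradients are verified against central finite differences in
the test suite (relative error < 1e-4 on probed coordinates). Sequence-to-
one readout takes the last timestep of the top recurrent layer's output
sequence (for a bidirectional layer: forward-last and backward-first,
concatenated).

## Experiment grid

Feature sets: Set 1 = {thigh angle, thigh velocity, torso angle, torso
velocity}; Set 2 drops torso angle; Set 3 drops torso velocity; Set 4 is
thigh-only. Speed models by training conditions: general C2–C5, slow C2,
normal-fast C3–C5; C1 (0.0–0.4 m/s, extremely slow) is never trained on.
Every grid cell shares one subject partition; per-cell seeds are
base_seed + CRC32(set|model), so any cell reproduces in isolation and cell
order is irrelevant. Every cell is evaluated per speed condition (C2–C5)
on the held-out prediction subjects: polar MSE, circular phase error
min(|Δτ|, 1−|Δτ|) ∈ [0, 0.5], mid-stance MSE (ground-truth ϕ ∈ [30, 50]),
and heel-strike detection error — each downward wrap (drop > 0.5) of the
predicted τ̂ series marks a predicted heel-strike at the linearly
interpolated crossing; predicted and actual events are matched greedily
nearest-first within half the median stride duration, unmatched events
counted as misses/false detections.

ANOVA: two-way with interaction on per-trial errors (per-sample errors are
grossly dependent), type-II sums of squares via statsmodels OLS, pairwise
Welch t-tests per factor with Bonferroni correction (raw p × number of
comparisons in the family, capped at 1), stars at 0.05/0.01/0.001.

## Variability analysis

For one signal and speed condition, each subject's strides are
time-normalized to 101 points (0–100 % inclusive — the gait-analysis
convention) and averaged into Sᵢ; the grand mean A averages the Sᵢ over
subjects. The (n+1)×(n+1) Pearson matrix over [A, S₁…Sₙ] is summarized by
the mean ± sample SD of its first row (corr(A, Sᵢ)). A includes subject i
(single-A construction); this biases coefficients up by O(1/n), a
leave-one-out variant is provided, and at n = 50 the two summaries differ
by < 0.01 (asserted in the tests).

## Synthetic cohorts

The generator emulates the structure of multi-speed walkway datasets so
the pipeline is testable without downloads. Per subject: a thigh pattern
of up to three harmonics of the stride frequency (defaults ≈ 40°
peak-to-peak, dominated by the first harmonic), a torso with mean forward
lean (≈ 5°) plus an exact 2-per-cycle oscillation (≈ 1.5°), and a
stride-duration scale. Walking speed is drawn uniformly in the condition's
bin; stride duration interpolates linearly from 1.6 s at 0.3 m/s to 0.9 s
at 1.6 m/s (plausible, fully configurable), jittered per stride by a
log-normal factor (σ ≈ 3 %). Trials hold 3 full strides plus 0.3 s margins
(window coverage needs ≥ 1 s of labeled data).

Two speed effects shape the cross-speed difficulty profile. Segment
excursions scale with speed (factor 0.55 + 0.45·v, clipped to [0.5, 1.4]):
stride length grows roughly 65 % from slow to fast walkway speeds and
thigh excursion tracks stride length, so slow-walking kinematics are
genuinely distinct from normal-and-fast patterns. And the kinematic progression *within* a stride
wanders around the event-anchored linear phase (band-limited warp, SD
0.008 of a cycle at C3, multiplied by 4.0/1.5/1.0/0.6/0.4 for C1…C5):
slow walking lacks the momentum that carries fast walking evenly through
the cycle, which puts an irreducible floor under slow-speed phase
estimation — largest in mid-stance, where progression stalls.

Perturbations are smooth band-limited noise (low-pass-filtered white
noise; raw white noise would make derivative channels unusable), scaled by
per-speed multipliers. Thigh variability falls monotonically as walking
speeds up; torso variability is far larger than thigh variability at every
speed, peaks at the slowest speeds, and is smallest near comfortable speed.
The torso models a wearable-style sensor pair: the torso *motion* acquires
a slow (≲ 0.15 Hz) postural drift; the angle *channel* adds broadband
estimation noise on top, while the velocity *channel* is the derivative of
the drifting motion plus its own small sensor noise. Angle estimates drift
and wander in practice while angular velocity is measured directly; this
is also what makes torso angular velocity much better phase-locked than
torso angular position in the generated cohorts, the structure real
walkway data shows. On noise-free trials velocity channels equal the
central-difference derivative of the angle channels exactly.

What the generator does *not* emulate: 3D marker-level detail,
frontal/horizontal-plane motion, asymmetry and pathology, fatigue or
trial-order effects, realistic force-plate waveforms (only a steep-onset
double-hump vertical-GRF template used to test event detection). Passing
tests therefore demonstrate that the pipeline recovers the *structure* the
generator encodes — not field performance on real gait data.

## Scaled-down studies

Full-scale training (50 subjects, 128/64/64/32 units, 12 cells) is far
beyond a desk run, so the pre-registered studies in
`gaitphase.experiments` use reduced sizes, chosen once:

* correlation study — 50 subjects × C1–C5 × 2 trials, default variability;
* ablation study — 20 subjects × C2–C5 × 3 trials with the
  informative-torso preset, Sets 2–4 × all three speed models, 32/16-unit
  network (layer 1 bidirectional), window 100, training windows thinned
  8×, ≤ 10 epochs, patience 4, 4 prediction subjects.

Three trials per condition matter: C5 trials are the shortest (fast
strides), and with fewer trials the fast condition is window-starved,
which confounds the cross-speed error pattern with data volume.

Because each cell is a single training run, between-cell comparisons are
judged against run-to-run variance: `run_variance_probe` retrains one cell
(thigh-only × general) several times on identical data, varying only the
training seed, and the SD of the replicate means is the yardstick — a
between-cell difference within ~2 SD is training noise, not signal. The
`replicates` argument of `run_grid` generalizes this to any cell.

## Numerical choices and degenerate inputs

Angles in degrees, velocities in deg/s, phases dimensionless. Central
differences (one-sided at boundaries) for all derivatives. GRF event
threshold 20 N with 0.1 s debounce (common gait-lab practice). No
smoothing by default; optional zero-lag 4th-order Butterworth (6 Hz)
exposed in config. Degenerate inputs raise typed errors: zero-norm
sagittal projections, coincident markers, constant trajectories in
correlation, (0, 0) in phase decoding, < 2 heel-strikes, unsorted event
lists. Too-short trials yield an empty window batch with a warning, not an
error. Exact-0 phase at heel-strike uses the half-open convention
τ̂ ∈ [0, 1) to avoid double-representing the cycle boundary.

## Known limitations

The numpy network trains on CPU only and is sized for small studies;
run-to-run variance of a single training run per cell is nonzero, so grid
comparisons should be read as orderings with paired statistics rather than
point estimates. The C3D path is not implemented (real data enters via the
CSV dialect). Heel-strike detection from predicted phase assumes the
prediction wraps once per stride; heavily corrupted predictions can
produce misses/false detections, which are reported separately rather than
folded into the timing error.
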