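# Methods

## Skeleton model and conventions

The canonical skeleton has 14 joints: Head, Neck, and left/right Shoulder,
Elbow, Wrist, Hip, Knee, Ankle, in a fixed documented order. Coordinates
are right-handed with gravity along −y by default (configurable at the
angle-computation entry point); lengths are unitless but must share one
scale between training and inference because joint-line distances scale
with the skeleton. Every frame is translated so the Neck sits at the
origin ("neck centering"), which removes absolute-position dependence and
is idempotent and distance-preserving.

## Features

Each joint is described by 81 numbers: its 3 coordinates plus its 78
joint-line distances — the perpendicular distance to the line through each
unordered pair of the other 13 joints, in lexicographic pair order over the
canonical joint order. Distances are computed with Heron's formula
(2·√(s(s−a)(s−b)(s−c))/base, s the semiperimeter), clamping tiny negative
radicands to zero. If the base pair is numerically coincident the true
line distance has no limit, so the point distance |J1−J2| is substituted:
a finite, deterministic fallback for noisy poses. On near-collinear
triples Heron's formula loses roughly half the significant digits (absolute
error ~1e−8 at unit scale); the vectorized and scalar paths are bit-equal.

Distances are computed against the full remaining-13-joint universe first;
the three streams then select joints: trunk = {Head, Neck, Shoulders,
Hips} (486 dims), arms = {Head, Neck, Shoulders, Elbows, Wrists} (648),
legs = {Head, Neck, Hips, Knees, Ankles} (648). Head and Neck are shared
by all three streams as postural context. These memberships are the
anatomically coherent reading of the stream split; the per-joint feature is
defined before the split, so stream membership does not change the feature
values.

## REBA rule engine

Angles are derived from segment vectors: trunk = mid-hip→neck against the
up direction, split into sagittal flexion (positive forward) and lateral
bending via a body frame built from the hip line; trunk twist = horizontal
angle between shoulder and hip lines; neck = neck→head relative to the
trunk direction; knee flexion = interior angle hip-knee-ankle (0 =
straight); upper-arm flexion = arm elevation from the hanging-down trunk
direction signed by its sagittal component, with abduction (>45° lateral)
and shoulder-raise (shoulder above neck by >5% of trunk length) modifier
flags; lower-arm flexion = 180° minus the interior elbow angle. Bilateral
support is inferred from the vertical ankle gap (<25% of trunk length).

Band thresholds and Tables A, B, C are the standard published REBA
constants, encoded as data arrays. The skeleton has no hand joints, so
the wrist partial entering Table B is fixed at neutral (1); consistently,
the 6-component score vector contains no wrist entry. Arms are scored per
side and the per-frame worst side (maximum) is used. Adjustments default
to no load, good coupling and no activity flags. The total is
Table C(A + load, B + coupling) + activity, clamped to [1, 15]; exhaustive
enumeration over all partials and adjustment combinations attains exactly
the integers 1..15 and is monotone in every input.

Risk levels bin the total half-open: Negligible (<2), Low [2,4),
Medium [4,8), High [8,11), Very High (≥11).

Integer score traces are piecewise constant and hard to regress, so
training targets are smoothed per component with a Savitzky–Golay filter,
default window 13 (even windows are normalized up to the next odd
integer), polynomial order 3 (the order is a package choice; scipy's
`mode="interp"` handles edges so length is preserved). Sequences shorter
than the window pass through unchanged with a warning.

## Variational network

All network code runs on a small vectorized reverse-mode autodiff core
written on NumPy (float32 by default; float64 switchable for numerical
checks), with Adam. Gradients are verified against central finite
differences in the test suite.

* **E_MS** — one 4-layer ReLU MLP per stream, widths K→512→1024→1536→2048
  (full scale), linear output.
* **E_T** — the three stream embeddings are three tokens with learned
  positional encodings; three self-attention blocks of 4 layers × 4 heads
  (post-norm residual layers, feed-forward expansion 2), with a linear
  reduction after each non-final block following the 2048→512→128
  schedule; mean-pool over tokens; two linear heads emit (μ, log σ²) of
  the 128-dim skeletal latent.
* **D_skel / D_reba** — six fully connected layers to the 6 score
  components. **E_reba** — five hidden layers plus the two statistic
  heads onto the 64-dim teacher latent.
* **M_skel / M_reba** — two-layer feed-forward maps on the concatenation
  [μ ‖ log σ²] emitting a new (μ, log σ²); M_reba maps the 64-dim teacher
  statistics into the 128-dim skeletal latent so the shared decoder D_skel
  can decode either path.

Distributions are parameterized as (μ, log σ²) for stability; sampling is
reparameterized (z = μ + σ·ε). Log-variance heads are initialized near
−4 (σ ≈ 0.14) so early training is close to deterministic; with the small
KL weight this materially speeds convergence without changing the
optimum. Decoder output biases are initialized to the training-target
mean. Stream features are standardized per dimension with train-split
statistics stored in the model bundle.

## Training

Phase 1 trains the two branches independently: skeletal (features →
scores) and teacher (scores → scores), each with loss β·KL(q‖N(0,I)) +
(1/K)Σ(y−ŷ)², K = 6. Phase 2 trains the alignment maps and fine-tunes
both encoders under L_align = L_align_skel + γ·L_align_reba with D_skel
frozen (a flag unfreezes it). Defaults: β = 1e−4, γ = 1e−2, Adam with
learning rate 1e−4, batch size 128. "Until convergence" is
operationalized as early stopping on a held-out validation split
(sequence-level when at least four sequences exist), with the best state
restored. The teacher branch costs orders of magnitude less per epoch
and receives a 5× epoch budget and 10× learning rate. Folds and
validation splits are always cut at sequence ids, never frames, to
prevent temporal leakage. Inference decodes the latent mean (no
sampling), so predictions are deterministic; a sampling flag restores
stochastic decoding.

The alignment sentence in the underlying formulation mixes
"classification" language with regression losses; the equations (MSE +
KL) are implemented as written. β is constant (no annealing).

## Synthetic data

Each degree of freedom (trunk flexion/side/twist, neck flexion/side, hip
and knee flexion per leg, shoulder flexion/abduction per arm, elbow
flexion per arm, shoulder elevation) follows an Ornstein–Uhlenbeck
mean-reverting walk squashed through tanh into a regime-specific range,
Savitzky–Golay smoothed, and clipped at hard anatomical limits. Forward
kinematics over a 13-bone tree (50th-percentile adult segment lengths in
meters) produces exact bone lengths every frame; a slow pelvis random walk
exercises translation invariance. Regimes: *neutral* keeps every angle
inside the lowest REBA bands (every frame scores total = 1); *mixed*
emulates everyday manual work and spans risk levels Low through High with
a Medium-dominated distribution; *extreme* reaches Very High (total ≥ 11)
through deep flexed twisted trunk, raised abducted arms and bent
single-leg stances. What the generator does not emulate: pose-estimator
noise and occlusion artifacts, self-contact constraints, load handling,
and realistic task semantics — so passing desk-scale tests demonstrates
that the architecture can recover REBA structure from clean kinematics,
not field accuracy on real video.

## Desk-scale experiment

The reference experiment simulates 8 mixed-regime sequences of 20 s at
30 fps (4800 frames), holds out the last 2 sequences, uses the `desk`
network preset (stream width 256, token dims 256→128→64, latents 32/16)
and a 25-epoch / patience-8 budget per stage at learning rate 5e−4 (the
shrunken preset tolerates and needs a larger step than the full-scale
default of 1e−4; phase 2 fine-tunes at a fifth of the phase-1 rate) —
problem sizes chosen so the full two-phase run finishes in a few minutes
on one CPU. Reported: per-component held-out MSE for phase 1, phase 2 and
the train-mean predictor; the phase-2/phase-1 total-MSE ratio; Pearson r
between predicted and true totals. The run is bit-reproducible for a
fixed seed (single-threaded deterministic kernels; all randomness flows
through seeded NumPy generators). At this abbreviated budget, training
quality varies noticeably from seed to seed (the short phase-1 schedule
can stop at a mediocre state, which the aligning stage then largely
repairs on the total score); the reference experiment therefore pins its
seed, and conclusions about the architecture should rest on the full
budget, not the desk one.

## Numerical choices and limitations

* Savitzky–Golay polynomial order defaults to 3 everywhere.
* Degenerate geometry (zero-length segments) raises a named error in the
  angle engine but is impossible in generator output by construction.
* The angle→band thresholds implement the standard REBA semantics;
  borderline postures (e.g., trunk flexion exactly 20°) bin deterministically
  via closed/open interval choices documented in the code.
* The full-scale preset (stream width 2048, latent 128) is implemented and
  validated for shape/gradient correctness but is not exercised end-to-end
  in the test suite; training it on real pose data is expected to require
  GPU-class throughput.
* REBA scores one side of the body in manual practice; the engine takes
  the per-frame worst arm, which can differ from a human assessor's choice
  on mixed asymmetric postures.
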