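# Methods

## The imaging problem

Electrocardiographic imaging (ECGI) reconstructs cardiac transmembrane
potentials (TMP, `U`, M nodes x L time samples, mV) from body-surface
potentials (BSP, `Omega`, N leads x L, mV) through the linear forward model
`Omega = H U`. `H` is severely smoothing, so the inverse problem is
ill-posed: many TMP distributions explain the same BSP, and noise is
amplified. This package regularizes the inversion with *a priori
physiological knowledge*: the healthy "standard" TMP of the same geometry,
injected both through the network architecture (cross-attention) and through
the objective function.

## Forward model

`H` is an equivalent-double-layer (EDL) operator on synthetic geometry: a
Fibonacci-lattice sphere of radius 50 mm (128 nodes by default) for the
heart surface inside a 200 mm electrode sphere (64 leads, quasi-uniform,
seeded random orientation). Entry (i, j) is the signed solid angle
contribution of the faces incident to node j seen from electrode i,
vertex-lumped (1/3 per face vertex) and scaled by -1/4pi, computed with the
analytic arctangent (Van Oosterom-Strackee) formula. The medium is
homogeneous and unbounded: no torso-boundary correction is applied. A
bounded-torso solution would rescale and further smooth `H` without changing
its structure; the infinite-medium kernel already reproduces the two
properties that matter for the inverse problem -- distance attenuation and
spatial low-pass filtering -- while staying exactly reproducible. Gauss'
theorem (total solid angle 0 outside / 4pi inside a closed surface) gives
two machine-precision invariants used in the tests: rows of `H` sum to ~0,
and a spatially uniform TMP is invisible at the body surface.

## Simulator

Per-node action potentials use a two-sigmoid template
`V(t) = resting + amplitude * s((t - t_dep)/w_up) * s((t_rep - t)/w_rec)`
with resting -90 mV, amplitude 100 mV, upstroke width 2 ms, recovery width
12 ms, action-potential duration 250 ms -- generic ventricular values. The
healthy activation sequence paces node 0 at t = 20 ms and propagates
activation along mesh-graph geodesics at 2 mm/ms. Lesions occupy a
Euclidean ball (default radius 15 mm) around a center node:

* ischemia (MI): amplitude reduced by a severity fraction, evaluation range
  25-80%;
* hypertrophy (VH): depolarization and repolarization delayed by 25-50 ms.

A single-node lesion would make the centroid-localization metric
degenerate, hence the 15 mm ball (2-4 nodes at the default mesh density).
Measurement noise is zero-mean Gaussian calibrated to a global
(all-lead, all-sample) SNR of 30/25/20/15 dB.

What the generator does *not* emulate: anatomical heart/torso shape,
transmural heterogeneity, tissue conductivity inhomogeneities, pathologies
beyond the two lesion families, correlated (non-white) measurement noise
and electrode misplacement. Passing results therefore demonstrate the
method's behaviour under an idealized but structurally faithful version of
the imaging physics, not clinical performance.

## The attention model

Three stages (defaults in parentheses):

1. **Potential embedding** (6 residual blocks): each block adds
   `Em(x) = Norm(Conv(LeakyReLU(Norm(Conv(x)))))` to its input; the
   convolutions are 1-D along time, kernel 3, depthwise with the kernel
   shared across channels, and the LayerNorms normalize over channels with
   scalar affine parameters. Sharing weights across channels keeps one
   embedding operator applicable to both the N-channel BSP and the
   M-channel prior, as the training procedure requires, and makes the
   composite receptive field exactly 6 x 2 x (3-1) + 1 = 25 samples.
2. **Feature decoding** (6 decoder blocks): attention tokens are *time
   samples*, features are spatial channels. The embedded BSP is stacked
   along the channel axis (2N = M) to match the TMP width. Each block runs
   self-attention, cross-attention with the embedded standard TMP as
   keys/values, and a position-wise feed-forward layer
   (`d_ff` = 256), each sublayer wrapped in dropout (p = 0.1), a residual
   connection and a LayerNorm; the cross-attention residual reuses the
   block input. No positional encoding is used: lead numbering is an
   arbitrary labelling, and dense maps over the channel axis are indifferent
   to it. Q/K project channels to `d_k` = 128; V is channel-to-channel.
3. **Output layer**: one linear map over channels. By default the head
   predicts the *deviation* from the standard TMP
   (`u_hat = u_std + (omega x + b)`, the `prior_skip` option) and its
   weights start at zero, so an untrained network outputs exactly the
   healthy prior and every gradient step is spent on the case-specific
   correction. The plain head of the original formulation
   (`u_hat = omega x + b`) is available by switching the option off.

Choosing time as the token axis is deliberate: tokens must be
distinguishable by content for attention to act, and duplicated *spatial*
tokens (the stacking step) would remain bit-identical through every
attention sublayer, forcing node i and node i+N to receive identical
reconstructions. Stacking channels instead leaves every node's output an
unconstrained function of all leads.

The residual/zero-init head matters enormously in practice: with a plain
Xavier-initialized head the network starts ~100 mV off the prior manifold
(an almost purely per-node constant offset) and spends its whole step
budget crawling back; with the skip it starts on the manifold and the
physics term's gradient, `H^T(residual)`, lies in the row space of `H`, so
training cannot reintroduce null-space error through the output path.

## Loss and training

`L = ||H u_hat - Omega||^2 + lambda ||u_hat - u_std||^2`, mean-square
reductions, lambda = 0.01. The forward term enforces the physics (no
measured TMP is ever used for training); the constraint term anchors the
reconstruction to the physiological prior. Mean (not sum) reduction keeps
lambda's meaning independent of the grid length.

The loss is evaluated on *scaled* signals: `U' = (U + 90)/100`,
`Omega' = Omega / rms(H u_std)`, `H` rescaled to match. Because `H` has
~zero row sums the resting offset drops out of the forward map exactly, so
the scaling is a pure reparameterization of the signals -- but it also
*defines* the balance of the two loss terms, and that choice is
substantive. The effective objective is generalized Tikhonov toward the
prior with regularizer `lambda (N/M)` against a unit-scale operator; its
closed-form minimizer (computable exactly, and used as a cross-check
throughout development) reconstructs at study scale with RE ~0.03,
CC ~1.0 and localizes lesions to a few mm. At the opposite convention --
raw mV units, where ~100 mV TMPs dwarf ~1 mV BSPs -- the optimum provably
leaves lesions uncorrected (the payoff `||H delta||^2` of a correction
`delta` is below `lambda ||delta||^2` for this operator's spectrum), so
that convention cannot produce localization at all. The unit-scale
convention is the one under which lambda = 0.01 reproduces the intended
regime.

Numerical choices that mattered:

* **Branch-scaled initialization.** Xavier init everywhere, but the
  residual-branch output matrices (attention V, feed-forward W2) are scaled
  by 0.1 so every block starts near the identity. Without this the
  6+6-block stack reliably converges to a stationary point whose output is
  uncorrelated with the target (observed on single-case overfitting runs;
  the scaled init takes the same case from loss ~1.0 to ~1.5e-3).
* **Optimizer.** Adam (lr 1e-3), linear warmup over the first 10% of
  steps, cosine decay to 5% of peak, global gradient-norm clipping at 5,
  and Polyak (EMA) averaging of the weights (decay 0.995) for the returned
  model. Convergence = max epochs or relative epoch-loss change < 1e-5.
  An optional continuation schedule on the forward-term weight exists for
  the plain (no-skip) head, which otherwise trains poorly; with the
  default residual head it is unnecessary and disabled.
* **Gradients.** The network is defined twice: a concise autodiff
  (autograd) reference implementation, and a hand-derived reverse-mode
  backward pass used by the training loop (~10x faster; the test suite
  asserts both produce identical gradients to machine precision).

The training corpus is simulated: 200 cases per task, lesion centers drawn
from the nodes not used by the 20-case evaluation set, severities/delays
uniform over the study ranges. Each epoch every case's BSP is perturbed
with Gaussian noise at an SNR drawn from {clean, 30, 25, 20, 15} dB, and
the forward loss is measured against the *clean* BSP (denoising-style
training). The augmentation reflects the evaluation protocol -- one
trained model is applied to both clean and noisy records -- and the clean
target prevents the physics term from chasing per-batch noise
realizations, which otherwise destabilizes the late phase of training.

## Baselines

* **Tikhonov** (`tikhonov_solve`, and `tikhonov_prior_solve` which shrinks
  toward the standard TMP): closed-form references, also used as
  independent classical cross-checks in tests.
* **ISTA**: gradient step `r = u - rho H^T (H u - Omega)` alternating with
  a proximal step; classical mode soft-thresholds `r` directly, learned
  mode passes it through trainable convolutions `B(soft(ReLU(A r)))`
  (8 filters, kernel 3, 6 unrolled iterations, per-iteration step sizes and
  thresholds). Trained with the same loss and corpus as the attention
  model, so architecture is the only manipulated variable.
* **FFNN**: per-time-sample MLP (64 -> 256 -> 256 -> 128, LeakyReLU), same
  loss and corpus.

## Evaluation

* RE: per-node relative L2 error, averaged over nodes.
* CC: per-node Pearson correlation, averaged over nodes.
* LE: distance between the coordinate centroid of the detected lesion node
  set and that of the true lesion node set. Detection compares the
  reconstruction with the standard TMP: ischemia = plateau amplitude
  (95th - 5th percentile) below 0.85 of the standard; hypertrophy =
  activation time more than 10 ms late. For delineation the activation
  time is estimated by the *derivative centroid* (positive-derivative-
  weighted mean time, ignoring derivative samples below 10% of the node's
  peak slope): on a partial mixture of an original and a delayed upstroke
  the steepest-slope estimate snaps to whichever upstroke dominates and
  reads the delay as zero, whereas the centroid shifts continuously with
  the recovered fraction; the slope floor stops low-level ripple far from
  the upstroke from dragging the centroid (worst at early-activating
  nodes, where the lever arm is longest). `activation_times` (argmax of
  the forward difference) remains the per-node activation map used for
  depolarization-time visualizations. Both thresholds are configurable;
  when thresholding finds nothing the fallback lesion area is the
  half-max cluster of the per-node deviation score (FWHM-style), so LE
  stays defined for every case.
* Statistics: paired t-tests (every solver reconstructs the same cases)
  and Cohen's d on paired differences; noise comparisons pool all four SNR
  levels. Significance stars at 0.05 / 0.01 / 0.001.

## Problem sizes used by the reproduction runs

The headline runs (`p2an.pipeline.study_config`, used by both the
acceptance script and the end-to-end tests) use the full spatial scale --
128 nodes, 64 electrodes, 20 evaluation cases and a 200-case training
corpus per task -- with a 4 ms / 480 ms time grid (L = 120) and compact
training schedules (attention model: 35 epochs, batch 10, d_ff = 128;
unrolled ISTA: 6 epochs at lr 1e-2; FFNN: 40 epochs), chosen so the whole two-task
study completes in roughly a quarter hour on one CPU. The time grid and
epoch counts are the package's scaling knobs; the library defaults (1 ms
grid, L = 500, 300 epochs) remain available through
`ExperimentConfig`/`ModelConfig`.

## Known limitations

* At the compact training schedules the network recovers depolarization
  *delays* only partially (a few ms of a 25-50 ms delay): delay-type
  corrections have short temporal support and converge much more slowly
  than amplitude-type corrections under the mean-square physics term.
  Hypertrophy localization is therefore markedly weaker than ischemia
  localization for the trained network, even though the closed-form
  optimum of the same objective localizes both to a few mm; longer
  training closes the gap in principle.

* The infinite-medium EDL kernel omits torso-boundary effects; absolute BSP
  amplitudes are not calibrated to clinical mV scales.
* The two-sigmoid template has no notch/plateau-phase morphology; CC values
  are therefore dominated by depolarization/repolarization timing.
* The synthetic study is easier than the anatomical one: a single fixed
  geometry, exactly known H, and white noise. Error and localization
  figures here are accordingly lower than what the same method achieves on
  realistic anatomy; comparisons between solvers (orderings, effect sizes)
  are the transferable result.
* The unrolled-ISTA and FFNN comparators are reference implementations at
  the cited architectural level, not tuned re-implementations of any
  specific published variant.
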