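# Methods

`numtwin` simulates how neural hyperexcitability degrades the learning of
symbolic arithmetic, using gain-modulated recurrent convolutional networks as
"digital twins" of individual children. This note records the models, the
synthetic-data generators, the estimators and the numerical choices, in the
order the pipeline runs them.

## Task and stimuli

The task is visually presented addition and subtraction over non-negative
integer operands with results in 0..18. Enumerating all ordered operand
pairs whose results stay in range (operands capped at 18) yields exactly 380
problems — 190 additions and 190 subtractions, and exactly 20 problems per
result value, so a uniform sample over problems is automatically balanced
over answers. Note that 0 must be admitted as an operand for these counts to
hold.

Each problem is rendered as a five-slot `3 x 28 x 140` image, `T1 U1 S T2
U2` (tens digit, units digit, operator, tens digit, units digit); a
single-digit operand gets an all-black tens slot. Digits are synthesized
procedurally rather than drawn from a handwriting corpus, so the repository
is self-contained:

- **handwritten_synthetic** (default): each digit is a fixed stroke
  skeleton (polylines and elliptical arcs in a unit box) deformed per
  variant by control-point noise (sigma 0.009 of the box), rotation (sigma
  2.5 deg), shear (sigma 0.04), isotropic scale (+/-6%), translation (sigma
  ~0.5 px), stroke thickness (2.1 +/- 0.5 px) and Gaussian blur. The
  deformation budget was chosen so that every glyph class stays unambiguous
  to a human reader; larger deformations make the 19-way task unlearnable at
  desk scale because held-out variants stop resembling the trained ones.
- **printed**: a plain 5x7 bitmap face upscaled 3x with +/-2 px random
  translation.
- **mixed**: each variant drawn from one of the two styles at random.

Operator glyphs are built from a "1"-like vertical stroke (length 16 +/- 2
px, thickness 2 +/- 1 px) and its 90-degree rotation; `+` overlays both.

What the generator does **not** emulate: writer identity and style
correlations across slots, the class-conditional shape statistics of real
handwriting corpora, ink texture, or segmentation noise. Tests passing on
these stimuli therefore show that the pipeline's *mechanisms* behave as
designed, not that any quantitative result transfers to real handwriting.

Each problem contributes `variants_per_problem` independent renders, split
half/half into train and test by seeded assignment, with hash-checked
disjointness. The full-scale protocol uses 100 variants (19,000 train /
19,000 test images); the desk profile uses 40.

## Network

Four recurrent convolutional blocks named V1, V2, V3, IPS (the dorsal-stream
stages the model is meant to mirror) feed a readout with 19 units, one per
answer. Every nonlinearity is the gain-scaled rectifier

    y = G * max(0, x)

preceded by a *normalization-only* batch norm: batch statistics are used in
training mode (so the input to each neuron has mean 0 and variance 1),
running statistics at evaluation, and there are no learnable scale/shift
parameters. The scalar gain G >= 1 is the model's handle on neural
excitability; the study grid is G = 1 + 0.25k, k = 0..16.

Block structure (shared-weight recurrence, per-timestep batch-norm
statistics, residual skip):

    u_0     = G relu(BN(conv_in(x)))          # V1: 5x5 stride 2; else 3x3
    u_{t+1} = G relu(BN_t(conv_rec(u_t)) + u_t)

with recurrence counts (1, 2, 4, 2) for V1..IPS and 2x2 max pooling between
blocks. Only the last timestep of each block is exposed to the
representational analyses. The readout is linear (no gain) on the globally
average-pooled IPS activations; a `flatten` readout over all IPS units is
available for very narrow models. No pretraining is used anywhere; weights
are He-initialized from a recorded seed.

Two mechanisms make high gain behaviorally costly even though batch norm
renormalizes each conv path: (i) the residual skip bypasses normalization,
so the recurrent update is progressively dominated by copying the
gain-amplified previous state rather than newly computed features, and (ii)
the readout input scales with G, sharpening the softmax and making early
training overconfident. Both effects grow with depth, which is why the
higher (V3/IPS) layers carry most of the representational signature.

Profiles: `full` uses channel widths (64, 128, 256, 512) and the full
17-gain grid over 3800 iterations — the published protocol, provided but
long-running. `desk` uses widths (16, 24, 32, 48), gains {1, 2, 3, 4, 5}
and 500 iterations, sized so that a 5-model sweep trains in roughly ten
CPU-minutes in the pure-numpy implementation while the gain-1 model still
reaches several times chance accuracy on held-out variants. All checkpoint
evaluations use a balanced subsample of 5 test variants per problem (1,900
trials); the chance baseline is 1/19 ~ 5.26% exactly because the test set is
balanced over answers.

## Training protocol

Cross-entropy loss, Adam with eta = 0.001 (beta = 0.9/0.999), batches of
100 stimuli sampled uniformly with replacement from the training variants
(structural balance makes batches label-balanced in expectation). One
iteration = one optimizer step. The batch index stream is drawn once from
the training seed and shared across gains, so every model sees the identical
example sequence. Evaluation checkpoints occur every 100 iterations,
including iteration 0 before any update; each checkpoint stores accuracy,
the 19x19 response-count matrix, the model and optimizer state (for exact
resumption), IPS mean problem activations, and all four layers' activations
at designated capture iterations (default: the final one).

`iterations_to_threshold` reports the first checkpoint at or above a target
accuracy (None if never reached). `extended_train` resumes a checkpoint at
unchanged gain, continuing the same data stream, until a target accuracy is
reached or a censoring cap of 5x the starting iteration is hit (reported as
censored, not an error); the extra training is also expressed as a
percentage of the starting iteration.

## Behavioral measures

From the response matrix `counts[s, r]` (true result s, response r):

- **accuracy** — diagonal mass over total;
- **numerical systematic error** (trueness) — mean over result levels of
  |mean response − true result|; a constant-9 responder scores 90/19;
- **numerical imprecision** (precision) — mean over levels of the
  *population* (1/n) standard deviation of responses; the measure describes
  a distribution, not an estimate, so no Bessel correction;
- **effective number of responses** — exp of the natural-log Shannon
  entropy of the answer distribution pooled over all test trials; exactly k
  for a uniform k-answer distribution, hence 19 at most.

## Representational similarity (NRS)

Per layer, mean activation vectors over the test variants of each of the
380 problems are correlated (Pearson, across units) for every problem pair.
Rows follow a canonical order: additions before subtractions, then
ascending result, then ascending first operand. Layers wider than 8,192
units are unit-subsampled with a recorded seed first. Zero-variance rows
yield undefined correlations, which are stored as NaN and excluded from
averages rather than zero-filled. Block averages: add-sub over all
cross-operation pairs; add-add and sub-sub over unordered within-operation
pairs excluding the diagonal (self-similarity is identically 1 and would
bias the mean). The operand-overlap analysis partitions the 190 x 190
cross-operation pairs into both/left/right/none shared-operand categories;
within-operation pairs are not included, matching the cross-operation
framing of the question.

`fisher_unz` (tanh) maps Fisher-z values back to the correlation scale; the
prediction stage correlates each child's model-predicted IPS add-sub NRS
with a synthetic "observed" value generated as
`tanh(coupling * atanh(pred) + eps)`, `eps ~ N(0, noise_sd)`. When no noise
level is configured, the pipeline sets it to `sd(z) * sqrt(1/r^2 - 1)` with
target r = 0.6 — the classical attenuation relation — demonstrating that a
moderate empirical prediction correlation corresponds to roughly equal
signal and noise on the z scale. This is a calibration demonstration, not
an empirical claim.

## Manifold geometry

The 380 mean problem activations of a layer form 19 result manifolds of 20
points. The mean-field capacity estimator expresses each manifold in its
own D+1-dimensional frame (principal axes of the centered points scaled by
the center norm, plus the center direction); for Gaussian probes T the
inverse capacity is the mean squared distance from T to the cone
{V : V·s <= -kappa over the manifold's points}. At the default margin kappa
= 0 this projection is solved *exactly* by non-negative least squares via
the Moreau decomposition; kappa != 0 falls back to L-BFGS-B on the
non-negative dual. Manifold radius and dimension come from the anchor
points of the same projections (mean norm of the axes component;
mean squared alignment of the probe with the anchor direction). Defaults:
200 probe draws per manifold, seeded; ambient spaces above 500 dimensions
are first reduced by a seeded Gaussian projection. Per-manifold inverse
capacities are averaged and inverted. Point manifolds recover the classical
function-counting limit alpha = 2.

The independent oracle tests linear separability of random balanced
manifold dichotomies directly (LP feasibility of a homogeneous hyperplane
with unit margin) and locates the projection dimension at which half the
dichotomies separate by bisection with linear interpolation; capacity is
manifolds divided by that dimension. Center correlation is the mean
*absolute* pairwise Pearson correlation between manifold centers —
alignment is sign-agnostic.

## Cohort and twin matching

The synthetic cohort stands in for 45 children (24 TD, 21 MLD; MLD defined
by a standard score below 90). Scores are drawn per group as a mixture of a
truncated-normal bulk and a small (10%) uniform component spanning the
group's full score range ([55, 90) MLD, [90, 130] TD). The uniform
component models the scattered extreme scorers a real cohort contains; it
also keeps the sample minimum and maximum — which define the min-max
normalization — stable, which a thin-tailed bulk alone cannot do. The bulk
location is calibrated by root finding so the asymptotic normalized group
mean equals the configured target (0.35 MLD, 0.70 TD); the configured SDs
(0.06 / 0.13) parameterize the bulk, so the overall group SD is slightly
larger. Group labels and the cutoff agree by construction.

Matching normalizes model accuracy by its min/max over *all* gains and
iterations of the sweep (computed once, before any matching) and children's
scores by the cohort min/max, then pairs each child with the gain minimizing
the L1 distance at a given iteration, ties broken toward the lowest gain
(conservative about hyperexcitability). The best iteration minimizes the
cohort-mean distance over the checkpoint grid. The permutation control
reassigns children's scores across the fitted models; the fitted mean is a
lower bound for every permutation draw because it is a mean of per-child
minima. Group comparisons use Welch's t-test and pooled-SD Cohen's d (the
variance-robust test; the conventional effect size).

## Pipeline, seeds, determinism

`run_experiment` executes stimuli -> sweep -> cohort -> matching ->
behavioral metrics -> NRS & prediction -> manifolds -> remediation ->
report. Every stage persists CSV/JSON/HDF5 artifacts under the run
directory and resumes from them if present; reruns with unchanged inputs
write byte-identical tables. All randomness derives from the single
experiment seed by fixed offsets. Computation is float32 (float64 in the
gradient-check tests and all statistical estimators); training is exactly
reproducible on a given platform.

## Known limitations

- Desk-scale quantities (accuracies, NRS levels, capacities) are not
  comparable to full-scale values; only signs, ranks and closed-loop
  recoveries are meaningful at this scale, and the acceptance checks are
  phrased accordingly.
- The remediation stage extends one model per matched gain, not per child;
  children sharing a gain share a trajectory.
- The mean-field estimator's radius/dimension conventions follow the
  anchor-point statistics described above; other published variants differ
  in normalization, so absolute values should be compared only within this
  package.
- The glyph bank's within-class variability is far simpler than real
  handwriting; robustness conclusions about stimulus style rest on the
  printed/mixed flags, not on realism of the handwritten synthesis.
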