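# Methods

This note records the models implemented in `motiondda`, the defaults they
ship with, and the reasoning behind choices the underlying procedure leaves
open.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic motion generation

The package emulates a VR collection protocol in which participants draw six
planar shapes with a hand controller.  Template curves are parametric
stand-ins chosen to match each shape's frontal silhouette: a unit square
(Cube), a 1:2 rectangle (Cylinder), the classic sextic heart curve
(16 sin³t, 13 cos t − 5 cos 2t − 2 cos 3t − cos 4t, rescaled), a
figure-eight (cos t, ½ sin 2t) crossing itself once at the origin
(Infinity), a circle of radius 0.5 (Sphere), and an equilateral triangle.
The downstream mathematics is shape-agnostic, so any planar silhouette with
the right class identity suffices.

Every template is centred at its point centroid and scaled so the larger
bounding-box side equals 1; all jitter and noise magnitudes are fractions of
the bounding-box diagonal, which makes them commensurable across shapes.

Variability has two levels, mirroring how repeated human trials behave:

- *participant style* — a per-participant anisotropic stretch
  (sd 5% about 1) and rotation (sd 5°) drawn once and applied to all of that
  participant's trials, so a participant is self-consistent;
- *trial jitter* — i.i.d. Gaussian point perturbation with sd 2% of the
  bounding-box diagonal.

Resampling to the fixed 32 points is uniform in cumulative arc length with
linear interpolation, preserving the end points.  This reproduces the
resampling step of the point-cloud ("dollar-family") gesture recognisers;
their cloud normalisation is deliberately not applied, since only the
resample step is needed here.

The default protocol (10 participants × 6 motions × 3 repetitions ×
3 sessions) yields 540 motions.

What the generator does **not** emulate: projection of genuine 3-D controller
paths onto the frontal plane, tremor spectra, fatigue drift within a session,
or pathological movement patterns.  Tests passing on these data show the
pipeline's machinery is correct under controlled conditions; they do not
certify accuracy figures on real patient recordings.

## Artificial databases

Seven database codes (X, Y, R, XY, XR, YR, XYR) assign ranges to three
augmentation parameters: horizontal-stretch start p_h and vertical-stretch
start p_v (percent; "varied" ranges span 10–50%, "neutral" ranges 90–100%)
and starting rotation θ (±5° neutral, ±45° varied).  For one source motion a
schedule of 20 parameter triples progresses from the drawn start values to
neutral (ratio 1, rotation 0); each transformed matrix gets 3 Gaussian noise
replicates (sd 2% of the transformed matrix's bounding-box diagonal by
default), giving 60 matrices per label, 360 per dataset and 20 datasets per
database.  Decisions where the procedure is open:

- *Schedule direction*: index 0 is farthest from neutral and index 19 is
  neutral, so a label's latent trajectory contracts toward its target as the
  episode progresses and the derived reward (distance) decays.
- *Random staircase*: defined as a monotone piecewise-constant sequence — a
  random plateau count (2–10) with uniformly random change-points, plateau
  values taken from the linear schedule at each plateau's start, final
  plateau pinned to the end value.
- *Per-parameter behaviours, shared index*: each of p_h, p_v, θ draws its
  own linear-or-staircase behaviour, but the three schedules share one index
  so the motion makes a single coherent progression toward the target.
- *Transforms act about the trajectory centroid* (stretch first, then
  rotation), keeping artificial motions co-located with their source.
- *Source re-draw*: the source motion for each label is drawn afresh from
  the participant pool for every one of the 20 datasets.

The split contract assigns 3 of the 20 datasets to a held-out test set and
forms a 5-fold cross-validation pool of 15 datasets (12 train / 3 validation
per fold).  These printed counts do not fill all 20 datasets; the remaining
2 are deliberately left unused rather than silently rescaling the ratios.

## Adversarial autoencoder

Networks are dense multi-layer perceptrons implemented directly on numpy
(forward and backward passes are a handful of small matrix products, so a
framework would add nothing).  The encoder maps the flattened 64-value
motion through 2–3 hidden layers to the 2-D code; the decoder mirrors the
encoder's widths in reverse; the discriminator reuses the encoder's hidden
stack with a 1-unit output read through a sigmoid.  Defaults: two hidden
layers of 64, ReLU activations, Adam at 1e-3, no dropout, minibatch 64.
Weights are Glorot-uniform; all randomness (initialisation, shuffling, prior
draws, dropout masks) derives from the single config seed.

The latent prior is a six-component 2-D Gaussian mixture with means on a
circle of radius 4 at angles 2πi/6 and anisotropic covariances (radial sd
1.0, tangential sd 0.5) — a polar-rose of petals pointing outward.  The
numeric values are a free choice; they set the scale of latent distances but
not the behaviour of any algorithm.

Training alternates reconstruction, discriminator and generator minibatch
steps; each step owns a disjoint parameter set and the other parts are
frozen (the test suite asserts bit-identity of the frozen parts).  The
generator step uses the non-saturating convention — encoder outputs
relabelled as real and the same cross-entropy minimised — which gives usable
gradients when the discriminator is winning.  Each of the three steps has
its own Adam state, as in the usual multi-optimizer setup of adversarial
models.  Discriminator probabilities are computed from logits; the
cross-entropy gradient is taken at the logit, and probabilities are clamped
at 1e-7 when the loss value itself is reported.

Semi-supervised mode concatenates the one-hot label to the discriminator
input and draws each prior sample from the label's own component.  The
encoder never receives labels in either mode.

Early stopping monitors the mean cluster KL of the validation embedding in
semi-supervised mode.  In unsupervised mode the cluster-to-component
correspondence is arbitrary during training, so the monitor falls back to
validation reconstruction error; the model returned is the one from the best
validation epoch, with a default patience of 20 epochs.  A non-finite loss
aborts training with the history attached.

## Latent evaluation

The Gaussian KL divergence is the standard closed form
½[tr(Σq⁻¹Σp) + Δμᵀ Σq⁻¹ Δμ − γ + ln(det Σq / det Σp)] with γ = 2, evaluated
in the direction D(prior ‖ fitted).  Near-singular fitted covariances are
regularised by +1e-8·I (logged) rather than rejected, since three collinear
points are a legitimate if degenerate cluster.  For unsupervised embeddings
the per-cluster divergences can optionally be computed under the
minimum-cost cluster-to-component matching (`assignment="optimal"`,
Hungarian algorithm); the default label-order assignment is the
semi-supervised convention.

k-NN accuracy uses K = 10 and majority vote; ties are broken by the smallest
summed neighbour distance among the tied classes, then by label order, so
predictions are deterministic.  The neighbour query is delegated to
scikit-learn; the test suite checks the whole classifier against a
brute-force all-pairs oracle.

Target centroids are per-label arithmetic means of the embedded reference
cohort (all 540 protocol motions by default).  Distances to the own-label
centroid are ordered by ascending schedule index with the three noise
replicates in consecutive positions, producing the 60-iteration reward
sequence per label.

## Bandits

All five agents start with optimistic estimates Q0 = 5 on every arm and
select arms by softmax at their own temperature τ.  The UCB radius is the
canonical c·√(ln t / 2N_k); arms never pulled receive an infinite bonus so
each arm is tried once (the softmax then splits all mass uniformly over the
untried arms).  The Kalman family initialises each arm's variance at
σ_ξ² + σ_ϵ², a weakly informative start on the model's own noise scale; the
pulled arm's posterior variance is then bounded above by σ_ϵ² after any
update, while every unpulled arm's variance grows by σ_ξ² per iteration.

The evaluator sees the full true reward vector (the agent sees only its
pulled arm) and forms P*(t) at τ* = 2.  The error increment uses the agent's
*pre-update* estimates — the knowledge its selection probabilities were
actually computed from — and the agent's actual selection probabilities
(including any optimism bonus or Thompson draw), since those are what drive
its decisions.

Default hyperparameters per agent were frozen from this package's own
exhaustive grid search (the full per-kind grids, three test reward sequences
from a code-X pipeline run in the unsupervised latent space, five episode
seeds, mean ae(60) minimised):

| agent          | frozen defaults                         |
|----------------|-----------------------------------------|
| boltzmann      | α = 1.0, τ = 2                          |
| boltzmann_ucb  | α = 1.0, c = 1, τ = 2                   |
| kalman         | σ_ξ² = 1.0, σ_ϵ² = 0.01, τ = 2          |
| kalman_iucb    | σ_ξ² = 0.05, σ_ϵ² = 0.01, c = 1, τ = 2  |
| kalman_ts      | σ_ξ² = 0.01, σ_ϵ² = 0.01, τ = 2         |

The synthetic reward generator used for agent comparisons emulates the
latent-distance regime: per-arm starts of 3–8 plane units decaying
piecewise-linearly to a 0–0.5 floor over 60 iterations, a mid-episode jump
(iterations 20–40) of 1–4 units on 1–3 arms that decays back out — a sudden
loss of motor control — and Gaussian jitter of sd 0.05 standing in for the
noise replicates.

## Genetic search

Genomes are 7-gene integer vectors over the architecture vocabulary (layer
count 2–3; constant/decreasing/increasing width pattern by powers of two;
first-layer width from {4, …, 512}; activations; learning rate; dropout).
Base-width indices that would leave the vocabulary under a pattern are
clamped, so every genome decodes to a valid configuration.  The search runs
50 individuals for 10 generations with tournament selection (10 parents,
tournament size 3 — the tournament size is unstated upstream and 3 is
standard), uniform crossover, 5% per-gene mutation, and single elitism
(added so the best-so-far trajectory is monotone, which also makes it
testable).  Fitness is the cross-validated mean cluster KL at a reduced
epoch cap (default 30) — full-budget fitness evaluation would multiply the
search cost by the epoch ratio without changing the ranking materially.

## Problem sizes in the shipped runs

The test suite and acceptance script run the pipeline at desk scale: AAE
comparisons use one fold of a single code-XYR database (4,320 training
matrices), two hidden layers of 64, at most 150 epochs with patience 20, and
3 seeds per mode; agent comparisons use 30 synthetic reward sets.  These
sizes were chosen so a full from-scratch reproduction completes in about a
minute on one CPU while leaving the qualitative contrasts (semi-supervised
vs. unsupervised embedding quality; Kalman-Thompson vs. Boltzmann-UCB
tracking error) clearly resolved.

## Known limitations

- Template curves and jitter are idealised; no claim is made that absolute
  accuracy or error numbers transfer to real recordings.
- The unsupervised model's cluster-to-component assignment is arbitrary, so
  its label-order mean cluster KL is not comparable to the semi-supervised
  value; use the optimal-assignment variant for cross-mode comparisons.
- The architecture search space is enumerable (a few thousand combinations);
  the genetic algorithm is provided for fidelity to the procedure, not
  because exhaustive search would be infeasible.
- Checkpoints store raw parameter arrays via numpy archives; they are not
  portable across incompatible package versions.
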