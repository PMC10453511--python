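# Methods

## Overview

`aesgrn` treats a gene regulatory system as a collection of interacting
agents: one forecaster per gene, all reading the same sliding window of
recent expression (the *state matrix*) and each predicting its own gene's
next value.  Composed under a synchronous clock they form a closed-loop
simulator of the expression dynamics.  Networks are inferred by running
this simulator to a steady state, overriding one gene at a time with a
perturbation function, and converting the slopes of every other gene's
response into calibrated edge probabilities.

## Data model and preprocessing

Expression data are *k* experiments of *b* observations over *n* named
genes (tab-separated text, blank lines separating experiments; an optional
leading `Time` column is validated for monotonicity and dropped).  The
first `train_fraction` (default 0.6) of experiments provide both the
per-gene min–max normalization constants and the training windows;
evaluation experiments are transformed with the same constants, so their
values may fall slightly outside [0, 1].  Constant genes map to zero with
a warning.  Normalization is per gene rather than global so that
low-dynamic-range genes are not flattened by high-expression ones.

Each agent's supervised set pairs the gene-major flattening of *m*
consecutive observations of all genes (gene 1's *m* lags oldest-first,
then gene 2's, …) with the focal gene's value one step ahead, giving
(b − m) rows of dimension n·m per experiment.  Windows never cross
experiment boundaries.  The flattening order is a convention that must be
fixed once, because the forecasters are not permutation-invariant; the
window spans exactly *m* steps (t−m+1 … t) so the input dimension is n·m,
matching the supervised-set shape.

## Agents

Three architecture families share a scalar-regression head:

| family | body |
|---|---|
| FCNN | three dense+activation blocks, dropout after the first |
| CNN  | Conv1D (64 filters, kernel 2, same-length) → activation → MaxPool1D(2) → two dense blocks with dropout |
| RNN  | LSTM → activation → two dense blocks with dropout |

CNN/RNN inputs are reshaped to *m* timesteps × *n* channels.  The networks
are implemented in numpy with explicit backprop; every layer's gradient is
validated against central finite differences in the test suite.  Training
minimizes MSE with minibatch Adam (batch 16, seeded shuffle), a
chronological 80/20 train/test split, early stopping on the held-out MSE
(patience 10, ≤200 epochs) and restoration of the best weights.  Given a
seed, initialization, shuffling and dropout are deterministic, so training
is bit-reproducible — a requirement for the closed-loop simulator, whose
perturbation responses must be attributable to the perturbation alone.

Hyperparameter tuning is random search over a declared space (dense widths
{16, 32, 64, 128}; activations {relu, tanh, sigmoid}; dropout U[0, 0.5];
LSTM units {16, 32, 64}; learning rate log-uniform [1e-4, 1e-2]), lowest
held-out MSE winning, ties to the first candidate.  When no tuning budget
is spent, fixed defaults are used: widths (16, 16, 16) for FCNN and
(16, 16) plus 16 LSTM units otherwise, learning rate 1e-2, dropout 0.
These defaults were selected by held-out one-step forecast error on
synthetic benchmark systems — small layers, and a learning rate large
enough for Adam to converge within the epoch budget at these sample sizes.

## The environment

The state matrix holds the last *m* values of all genes, columns oldest to
newest.  A step is synchronous: every agent reads the same pre-step state
(handed out read-only, so a faulty agent cannot leak its output into a
neighbour's input), the outputs form x(t+1), optionally clipped to
[0, 1.5] — wide enough to make mild extrapolation visible while containing
divergence — and the matrix shifts one column.  Simulations seed the first
*m* columns with real observations (zeros are available as the stated
alternative) and are deterministic given agents and seed state.

A perturbation overrides one gene's entry of x(t+1) for φ_d steps:

- *instant*: jumps to φ_b + φ_w immediately and holds for φ_d steps;
- *trapezium*: ramps linearly up over ⌊(φ_d − φ_p)/2⌋ steps, holds the
  peak (the remainder of the division extends the plateau), ramps back
  down symmetrically.

Values stay within [φ_b, φ_b + φ_w] ⊆ [0, G_i^max].  The perturbed gene's
forecaster is bypassed during the window but sees the perturbed history
afterwards, since the state matrix was overwritten in place.

## Evaluation

The evaluation target D_Y is the element-wise average over *all*
experiments — training ones included — because the averaged replicate is a
lower-noise estimate of the underlying trajectory than any single run.
Reliability R_ρ / R_η is the gene-averaged Pearson correlation / cosine
similarity between simulated and target trajectories; error Err_MSE /
Err_MAE the gene-averaged MSE / MAE.  The first *m* columns are excluded
everywhere (they are the shared seed), so all metrics compare (b − m)
points.  Zero-variance or zero-norm vectors score 0 with a warning.
Percentages are 100× the raw values.

## Architecture search

A solution assigns one architecture per gene.  Fitness is −Err_MSE of the
assembled simulator against D_Y, so higher is better and a failed training
run scores −∞.  The GA is generational with tournament selection (size 3),
uniform crossover (probability 0.8), per-gene uniform-reassignment
mutation (probability 0.2) and elitism of one — uniform operators because
the domain is unordered categorical, elitism so the best-ever fitness is
non-decreasing.  The budget of 100 evaluations counts every fitness call,
cache hits included.  Trained agents are cached per (gene, architecture),
so an assignment differing in one gene costs one extra training run, and
`fit_aes(use_ga=True)` seeds the initial population with the three uniform
assignments, guaranteeing the mixed result is never worse than the best
single-architecture baseline evaluated under the same cache.

## Network inference

For each gene *i*, independently from the same stabilized snapshot:

1. run the simulator until every gene's range over the last *m* produced
   values falls below ε = 1e-3 (configurable; at most 500 steps, after
   which the last state is used with a warning) — time t_f;
2. simulate *m* further stabilization steps;
3. apply the perturbation for φ_d = m steps (default width: half the
   gene's maximum observed expression; baseline: the gene's steady value;
   trapezium peak-hold φ_p = 2);
4. simulate *m* recovery steps;
5. record all genes over the Δt_r = 2m + φ_d steps after t_f as X_r;
6. r_ij = arctan(OLS slope of X_r's column *j* against step index).

Restarting every run from the same snapshot avoids carry-over between
perturbations.  Regression is on recorded levels rather than deltas — the
slope is identical either way.

Per target gene *j*: τ_j^p = median of the strictly positive entries of
column *j* of R, τ_j^n = median of the strictly negative ones, R_j^max /
R_j^min the column extrema.  The probability transform is linear from 1 at
R_j^min to ½ at τ_j^n, the quadratic through (τ_j^n, ½), (0, 0), (τ_j^p, ½)
in between, and linear from ½ at τ_j^p to 1 at R_j^max.  Two numerical
guards: (a) with asymmetric thresholds the interpolating parabola dips
marginally below zero on one side of the origin, so the output is floored
at 0; (b) a column with no positive (or no negative) entries has that side
collapsed — the missing side maps to 0 and the surviving side uses the
one-sided square law p = (r/τ)²/2 up to its threshold, which preserves
continuity, p(0)=0 and p(τ)=½ (the two-sided quadratic with a vanishing
placeholder threshold diverges instead).  Self-loops are excluded from the
AUC evaluation vector by default, following gold-standard convention;
p_ij is the probability that gene *i* regulates gene *j*, the orientation
given by the construction (perturb *i*, observe *j*).

AUC-ROC is the probability that a randomly chosen true edge outranks a
randomly chosen non-edge (ties ½), computed via scikit-learn and checked
against a brute-force pairwise oracle in the tests.

## Synthetic benchmark systems

`sample_network(n, density, seed)` draws an Erdős–Rényi directed network
without self-loops, weights uniform ±[0.3, 0.8] rescaled to spectral
radius 0.9; every nonzero weight is a gold edge.  Dynamics are the
discrete map x(t+1) = clip₀¹((1 − δ)·x(t) + Wᵀ tanh(x(t)) + ε) with decay
δ = 0.5 and process noise ε ~ N(0, σ²) injected into the recursion, so
fluctuations keep propagating through the couplings.  The tanh saturation
has unit gain at the origin: couplings act at full strength around the
operating point and the linearized relaxation is slow relative to the
series length, keeping trajectories informative about their regulators —
the statistical structure the learning step assumes.  Initial states are
uniform per experiment.  The generator emulates the *shape and statistical
role* of GeneNetWeaver-style exports (k experiments × b observations with
known ground truth), not its ODE/SDE kinetics: passing tests show the
pipeline recovers structure from data whose generative law is in this
family, and say nothing about thermodynamic realism.

Default study conditions throughout (benchmark scripts, acceptance run):
n = 10 genes, density 0.15, σ = 0.02, k = 5 experiments of b = 21
observations, state-matrix width m = 10, train fraction 0.6 — the shape of
a DREAM size-10 instance.

## Known limitations

- At the default series length, most of the evaluation window sits near
  the system's steady state, so Pearson reliability is noise-limited even
  for good simulators, and the 33 training windows of dimension 100 leave
  cross-gene couplings weakly identified: inference AUC on these
  artificial systems hovers near chance with large seed-to-seed spread
  (it rises with more experiments), consistent with the method's published
  behaviour on artificial benchmarks of this size.
- The slope-over-window readout compresses a pulse-shaped response into
  one number and the per-column median calibration amplifies noise in
  columns with no true regulator; both cost measurable ranking quality
  relative to reading the learned Jacobian directly, but are retained as
  the method's defining readout.
- Single-gene perturbations only; sign-labelled (activation vs inhibition)
  output is not produced — the probability collapses both regulation
  directions.
- Desk scale: CPU-only, tens of genes; no steady-state
  (knockout/knockdown) dataset variants.
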