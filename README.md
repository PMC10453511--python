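# aesgrn

Gene regulatory network (GRN) inference by *in-silico perturbation* of a
learned multi-agent gene-expression simulator.

## The problem

Given only time-series expression data — a matrix *D* of *b* observations
over *n* genes, possibly replicated across *k* experiments (the shape of
GeneNetWeaver/DREAM exports or small lab series such as the 8-gene *E. coli*
SOS DNA-repair panel) — which gene regulates which?  Instead of scoring
pairwise statistics directly, `aesgrn` first learns to *simulate* the
system and then performs the experiment a bench biologist cannot easily do:
transiently over-express each gene, one at a time, and watch who responds.

## The model

- **Agent** — one forecaster per gene, a small neural network
  *h_i* : R^(n·m) → R mapping the recent expression of *all* genes to gene
  *i*'s next value.  Three architectures are available per gene: a fully
  connected network (FCNN), a 1-D convolutional network over the time axis
  (CNN), and an LSTM recurrent network (RNN).
- **State matrix** *X(t)* — the shared n × m matrix of the last *m*
  normalized expression values.  A synchronous clock advances the closed
  loop: x(t+1) = (h₁(X(t)), …, hₙ(X(t))).
- **Architecture search** — a genetic algorithm over assignments
  S ∈ {FCNN, CNN, RNN}ⁿ (population 10, mutation 0.2, crossover 0.8,
  tournament 3, ≤100 evaluations) maximizes the fitness −Err_MSE of the
  assembled simulator; trained agents are cached per (gene, architecture).
- **Perturbation** — from a stabilized steady state, gene *i*'s row of the
  state matrix is overridden for φ_d steps by an *instant* (step) or
  *trapezium* (ramp–hold–ramp) function; all genes are recorded over the
  instability interval Δt_r = 2m + φ_d.
- **Regulatory value** — r_ij = arctan(α_j), the arctangent of the OLS
  slope of responding gene *j*'s recorded trajectory; |r_ij| ≤ π/2.
- **Edge probability** — per target gene *j*, the medians of the positive
  and negative entries of column *j* of R define activation/inhibition
  thresholds τ_j^p, τ_j^n; a piecewise map (linear–quadratic–linear, with
  p(0)=0, p(τ)=½, p at the column extrema = 1) converts r_ij into
  p_ij = P(gene *i* regulates gene *j*).
- **Evaluation** — simulator fidelity as gene-averaged Pearson/cosine
  reliability and MSE/MAE error (first *m* seeded columns excluded);
  network quality as AUC-ROC of the flattened p̂ against a gold-standard
  edge list.

## Worked example

```bash
python examples/02_fit_and_evaluate.py
python examples/04_infer_network.py
```

The first script samples a random 10-gene network (density 0.15), simulates
five experiments of 21 observations with process noise σ = 0.02, trains one
FCNN agent per gene and evaluates the free-running simulator:

```
R_rho        0.2886
R_eta        0.8030
Err_MSE      0.0001
Err_MAE      0.0081
n_points     11
```

`Err_MSE ≈ 1e-4` says one-step-coupled simulation stays close to the
averaged trajectories in normalized units; the modest Pearson reliability
reflects that, at this series length, most of the compared window is
already near the system's steady state, where trajectories are flat and
correlation is noise-limited.  The second script perturbs each gene with a
trapezium pulse and ranks all 90 candidate edges:

```
top 10 ranked edges (regulator -> target, probability, truth):
    G1 -> G2   p=1.000
    G1 -> G3   p=1.000
    G1 -> G9   p=1.000  edge
    ...
AUC-ROC against the gold standard: 0.513
```

An AUC of 0.5 is chance; small noisy training sets (here 33 windows of
dimension 100 per agent) leave the learned cross-gene couplings — and
hence the perturbation responses — only weakly informative, matching the
method's published behaviour on artificial benchmarks of this size.  The
other examples cover dataset generation, single-gene perturbation traces,
and GA architecture search.

A command-line interface wraps the same pipeline
(`aesgrn synth | fit | evaluate | simulate | perturb | infer`); see
`aesgrn --help`.

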