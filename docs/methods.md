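# Methods

## Problem

A drug screen measures the response of cell lines to compounds — activity
area (higher = more sensitive) or log IC50 (lower = more sensitive) —
yielding a real matrix `R ∈ R^{m×n}` with drugs on the rows, cell lines on
the columns, and a substantial fraction of cells unmeasured.  The task is
matrix completion: predict the unobserved responses from the observed
ones, using no side information (no gene expression, no chemical
descriptors).

## Model

### Global effect removal

Observed responses are decomposed additively,

```
R = R_global + R_drug + R_cell + R_res ,
```

by sequential unshrunk means: the global mean of all observed entries,
then the per-drug (row) means of what remains, then the per-cell-line
(column) means of what remains after that.  The decomposition is exact on
observed entries by construction; the interaction residual `R_res` is
what the network is trained on, and predictions are mapped back by adding
the effects.  Rows or columns with no observed entries receive effect 0,
which makes a cold-start unit fall back to the global-plus-opposite-axis
baseline.  No shrinkage is applied to the effect estimates.

Two consequences of the sequential order (global → drug → cell line) are
worth knowing: the residual's observed *column* means are exactly zero,
while its row means are only approximately zero under an incomplete mask;
and refitting effects on the residual returns an exactly zero global mean
but not exactly zero per-axis effects unless the matrix is fully
observed.  The additive identity above — the property the method needs —
holds exactly either way.

### Dual-branch network

The completer assumes the (residual) matrix is a blend of a linear and a
nonlinear function of a low-rank latent code.  One stack of fully
connected layers `W^(1..L+1), B^(1..L+1)` is applied to a trainable
latent input `Z ∈ R^{r×n}` (one column per cell line) in two ways:

* nonlinear branch: `f(Z) = σ(W^(L+1) σ(W^(L) ⋯ σ(W^(1)Z + B^(1)) ⋯ ) + B^(L+1))`
  with `σ = tanh` applied at every layer including the output;
* linear branch: the same affine maps composed with no activation.  With
  zero biases this collapses to `(∏_l W^(l)) Z`, i.e. a classical
  bilinear factorization whose left factor is the ordered weight product.

The prediction is `R̂ = α f(Z) + (1−α) lin(Z)`; `α ∈ [0,1]` sets the
nonlinear share and is applied identically in the training loss and at
prediction time.  The loss is a half mean-squared error over the observed
entries plus quadratic penalties on the latent input and the weights
(biases are not penalized):

```
L = 1/(2η) ‖M ⊙ (R − R̂)‖_F²  +  λ ( 1/(2n) ‖Z‖_F² + 1/2 Σ_l ‖W^(l)‖_F² )
```

with `η = |Ω|` the observed count, so that λ is comparable across matrix
sizes.  Both branches share one weight stack — the same parameters are
read twice — so every weight gradient accumulates a nonlinear-path and a
linear-path term; an untied variant (a second, independent stack for the
linear branch) is available as `tied_branches=False` for ablation.

A second network of the same form is trained on `Rᵀ` with one latent
column per drug (the "row net").  The default completion averages the two
nets' predictions; each side is also available alone, which is how the
per-side α-sweep tables are produced.

Because tanh bounds the nonlinear branch to (−1, 1), the model is meant
to run on GER residuals (roughly centred, unit-scale); the linear branch
carries whatever unbounded component remains.  A
`linear-output` variant was considered and rejected as a default: the
bounded output is part of the stated model, and the residual scale makes
it viable.

### Optimization: iRprop+

All trainables (weights, biases, latent input) are updated full-batch by
iRprop+ — resilient backpropagation with weight backtracking.  Each
scalar parameter carries its own step size Δ, multiplied by η⁺ = 1.2
while the gradient sign persists and by η⁻ = 0.5 on a sign flip (bounded
to [Δ_min, Δ_max] = [1e−6, 1.0], initial Δ₀ = 0.0125); on a sign flip
that coincides with a loss increase, that parameter's previous update is
reverted and its stored gradient zeroed.  Only gradient signs enter, so
the updates are invariant to positive rescaling of the loss — convenient
when the latent input itself is trained and gradient magnitudes vary
wildly between parameter groups.  Δ_max = 1.0 (rather than the customary
50) suits unit-scale residual data; all constants are configurable.

Weights and biases are initialized as Gaussian draws with std
`sqrt(2/(fan_in+fan_out))`; the latent input starts at zero.  Training
stops at `max_epochs` (default 2000) or when the relative loss change
stays below 1e−6 for 5 consecutive epochs.  Everything is deterministic
given the seed.

## Defaults and why

| parameter | default | rationale |
|---|---|---|
| rank `r` | 10 | generous for interaction structure after effect removal; must be < min(m, n) |
| hidden sizes | (4r, 2r) | two tapering hidden layers; depth beyond two bought nothing at these scales |
| `α` | 0.5 | equal branch weight; the sweep harness exists to tune it per dataset |
| `λ` | 1e−3 | chosen for unit-scale GER residuals: at 1e−3 held-out error approaches the noise floor, while 1e−2–5e−2 visibly underfit (the weight-norm penalty overwhelms the half-MSE data term) |
| activation | tanh | bounded, smooth, appropriate for centred residuals |
| epochs / tol / patience | 2000 / 1e−6 / 5 | full-batch iRprop+ on desk-scale matrices converges in hundreds of epochs; 2000 is headroom |

## Evaluation

Metrics are per-drug: Pearson correlation and RMSE between predicted and
measured responses over each drug's evaluated entries, averaged over
drugs (ave_PCC, ave_RMSE).  A drug needs ≥ 2 evaluated entries and
nonzero variance in both vectors to enter the PCC average (≥ 1 entry for
RMSE); skipped drugs are listed, and the two averages keep their own
denominators.  The `_sr` variants restrict each drug to entries at or
beyond its first/third response quartiles (linear-interpolation
quantiles) — the clearly sensitive and clearly resistant cell lines;
drugs with fewer than 4 evaluated entries keep all entries.  Note that
with exactly 4 entries the quartile filter does act (it keeps the two
extremes), so "sr equals plain" is guaranteed only below 4.

Cross-validation is entry-level: observed cells are dealt into k
near-equal random folds; each fold is hidden in turn (its entries treated
exactly like missing cells, with effects re-fitted on the remaining
training entries only), and the fold's predictions are assembled into one
matrix that is scored against the full observed mask.

Cold start hides one whole drug (or cell line) at a time.  A cold unit is
only predictable through the network whose *latent input* runs over that
axis — its code stays at the zero initialization and the effects supply
the additive fallback — so the leave-drug-out harness uses the row net
and the leave-cell-line-out harness the column net, unless a single side
is explicitly configured.  (The other net's output weights for a unit
with no data are never updated past their random initialization, which
would contaminate an averaged prediction.)

## Synthetic benchmark

The generator mirrors the model's own generative assumption: Gaussian
factors `C* (m×r)`, `D* (r×n)`; a nonlinear signal from a random tanh
network applied to `D*`; the blend `α_true f*(D*) + (1−α_true) C*D*`
rescaled to unit standard deviation (so `noise_std` reads as a
noise-to-signal ratio); additive global offset and Gaussian per-drug /
per-cell-line effects; entrywise Gaussian noise; and an exact-count
uniform mask.  The noiseless full matrix, true factors and true effects
are retained for scoring.

The standard benchmark is m=60, n=40, r=4, α_true=0.5, noise_std=0.1,
70% observed, effect scales (1.0, 0.5, 0.5), generator hidden sizes (8,),
seed 20240404.  Sizes are a deliberate scale-down of a public screen
(hundreds × dozens rather than hundreds × thousands) so the full CV and
sweep harnesses run on a laptop core in minutes; effect scales put the
additive structure at roughly half the interaction signal, and the
paired preprocessing comparison raises them to (2, 2, 2) with 30%
observation, where removing effects demonstrably matters.

What the generator does **not** emulate: the marginal response
distributions of real screens (violin shapes, block-missingness of
late-added drugs), inter-drug correlation from shared mechanisms, or
heteroscedastic assay noise.  Passing the recovery benchmarks therefore
shows the estimator recovers the structure it assumes, at realistic noise
and sparsity — not that it attains any particular accuracy on a given
public dataset.

## Numerical notes

* The masked loss is computed with unobserved cells zeroed before the
  residual, so stored values at masked entries (always NaN in the
  container) can never leak.
* Gradients are exact backpropagation through both branches; they are
  tested against central finite differences (step 1e−6) and against the
  closed-form regularized-MF gradient in the `L=0, α=0` reduction.
* Ranking ties in the top-k tables break by drug order, deterministically.
* Fold assignment shuffles observed coordinates with a seeded PRNG and
  deals round-robin, so fold sizes differ by at most one.
* Training aborts on non-finite loss and returns the last finite model,
  flagged `diverged`; non-finite gradients raise immediately.

## Known limitations

* Completion is transductive: the latent input is tied to the training
  matrix, so a fitted model completes matrices of that shape and
  identity only; new units go through the cold-start path, not
  `transform`.
* No side information; methods with expression or structure features
  will beat this model wherever those features carry signal.
* Per-parameter iRprop+ state doubles memory over plain gradient
  descent; irrelevant at screen scale, noticeable far beyond it.
* The quartile (`_sr`) averages use per-metric valid-drug denominators;
  with many near-constant drugs the PCC and RMSE averages can refer to
  different drug subsets (both are reported with their skip lists).
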