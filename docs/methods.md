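# Methods

## Data model and preparation

A session is a region×time matrix **X** ∈ ℝ^(N×T) with a fixed sampling
interval (default TR = 0.72 s).  Preparation follows a fixed order:

1. **Band-pass filter** — order-5 Butterworth, 0.04–0.07 Hz by default,
   applied forward–backward (`sosfiltfilt`) so it is zero-phase.  The
   filter order is a choice (only the band is prescribed by the upstream
   analysis convention); zero-phase filtering matters because a phase lag
   would corrupt exactly the lag structure the forecasters and the VAR
   model.  The filter acts on region-averaged series.
2. **Scaling** — `minmax01` maps each session onto [0, 1] using
   full-session statistics (this leaks test-range information by design
   of the convention it follows; a strict train-only variant can be built
   by scaling the splits separately).  `zscore` standardizes each region
   with statistics pooled over all sessions, and is the scale on which
   errors are reported and on which the influence perturbation (set to
   the sample mean = 0) is valid.
3. **Windowing** — stride-1 past/future pairs of lengths (T_p, T_f);
   exactly T − T_p − T_f + 1 pairs per session.  Windows never cross
   session boundaries.
4. **Split** — chronological per session: last ⌊0.1·n⌋ pairs test,
   preceding ⌊0.1·n⌋ validation, remainder training; then aggregated
   across sessions.  With T = 1200 and T_p = T_f = 60 this gives
   1081 pairs and a 865/108/108 split.

## Spatial coupling

The transition operator is T = D⁻¹A with D = diag(A·1).  Zero-degree
rows stay all-zero (no invented self-loops); the k = 0 identity term of
every graph filter carries self-influence.  Negative entries (possible in
the correlation-based A_CE) are clipped to zero before normalization so T
stays row-stochastic; an absolute-value option exists.  Diffusion
convolution computes Σ_k θ_k T^k x by k repeated sparse products — cost
linear in edges × K.  The adaptive adjacency is A_adap = tanh(V)/N with V
trainable from zero; the hybrid convolution sums the fixed-operator and
adaptive power series (their k = 0 terms are merged into one coefficient,
an equivalent parameterization).

Connectome embeddings: second-order biased walks (return parameter
p = 2, in-out q = 1, 100 walks of length 80 per node), then skip-gram
with 5 negative samples, window 10, 5 epochs.  The window/epoch/negative
counts are not prescribed upstream; they are common node2vec defaults.
The SGD uses mean-per-node gradients within each minibatch (a node
occurring many times in a batch receives one averaged step, not a
proportionally larger one), which keeps training stable on small
vocabularies; the default step size 0.25 is calibrated to this update
rule, not to per-pair word2vec updates.  Isolated nodes emit length-1
walks and get a zero row/column in A_CE instead of failing.  Embedding
training is seeded and single-threaded, hence deterministic.

## Forecasters

All models map (B, N, T_p) → (B, N, T_f), train by Adam on the MAE
objective, and run on a small reverse-mode autodiff engine written for
this package (`graphbold._tensor`): float64 numpy arrays, broadcasting
arithmetic, matmul, the standard nonlinearities, and one sparse-operator
application for graph convolution.

**DCRNN** — encoder–decoder of diffusion-convolution GRU cells
(2 layers, hidden 64 by default).  Gates: r, u = σ(GC([x‖h]) + b),
candidate c = tanh(GC([x‖r⊙h]) + b), update h′ = u⊙h + (1−u)⊙c.  The
decoder starts from a zero GO input; the output head is an affine map
from the top hidden state to one feature per node and step.  Scheduled
sampling feeds the decoder the true previous value with probability
ε_i = τ/(τ + exp(i/τ)) (one Bernoulli per decoder step per sample; τ
defaults to 2000 iterations — τ itself is a choice).  Validation and
testing always use the model's own predictions (ε = 0).  Gradient norms
are clipped at 5 to stabilize backpropagation through long sequences.

**GWN** — per layer: gated dilated causal convolution
h = tanh(D_C(Θ₁)x + b₁) ⊙ σ(D_C(Θ₂)x + b₂), then a graph convolution at
each retained time index with ReLU, a skip branch (taken after the graph
convolution — the reference layout leaves this open) and a residual add.
Kernel width R = 2 (the classic WaveNet choice; unprescribed upstream);
dilations double within a block (1, 2) and repeat across blocks; the
default 12 blocks × 2 layers give a receptive field
1 + (R−1)·Σd = 37 ≤ T_p = 60.  The head flattens channels×time per node
through two dense layers and emits all T_f horizons in one shot.

**TAtt** — input projected to M = 32 features; L = 4 layers of 4-head
causal attention.  Queries/keys/values share one ReLU projection per
head (width D = M/heads), scores are divided by D, and softmax runs over
t_j ≤ t_i: the strict predecessor set is empty at the first step, so the
mask is relaxed to include the current step everywhere.  Head outputs
are re-projected, concatenated, added to the input, and batch-normalized
(batch statistics in training, running averages with momentum 0.1 in
eval; the causality guarantee refers to eval mode).  After feature
collapse, one affine map over the time axis produces the T_f outputs
jointly (the emission scheme is unprescribed; joint emission is assumed).

**Training schedules** (named presets): DCRNN 70 epochs, batch 16,
η = 0.1 decayed ×0.1 at epochs 20/40/60; GWN 30 epochs, batch 8,
η = 10⁻⁴, decays at 10/20; TAtt 40 epochs, batch 16, η = 0.1, decays at
10/20/30.  Small-cohort presets double the epochs and shift the decays
(140 @ 40/80/120; 60 @ 20/40).  If validation MAE fails to improve for
10 epochs the best weights are restored and the next decay is applied
early; the best-validation weights are also restored before each
scheduled decay and at the end.

## VAR baseline

One pooled VAR(p) is fitted by OLS across the contiguous training
segments of all sessions.  Overlapping stride-1 training windows are
first reassembled into the contiguous span they cover, so observations
enter the regression once and lagged regressors never cross session
boundaries.  Multi-step forecasts iterate the one-step recursion on the
model's own predictions.  Order selection sweeps p = 5, 10, …, T_p and
picks the order minimizing T_f-step test MAE (a purely predictive
criterion); infeasible candidates are skipped with a warning.  The ADF
stationarity screen (α = 0.01, lag order by AIC) is reported but never
blocks fitting.  The parameter count N²p + N is exposed on the model —
the quadratic scaling the graph models avoid.

## Directed influence

For each silenced region n′ (input window set to 0, the sample mean of
standardized data; the future targets are never modified) the influence
on region n is the mean absolute forecast difference over test samples
and horizon steps.  The diagonal (self-influence, trivially large) is
excluded from the 0–100 rescaling statistics and from edge ranking, and
is set to 0 in the rescaled matrix.  Influence is evaluated on the test
split by default.

## Synthetic generator

x⁽ᵗ⁾ = γx⁽ᵗ⁻¹⁾ + βT x⁽ᵗ⁻¹⁾ + ε⁽ᵗ⁾ with ε ~ N(0, σ²), on a symmetric
Erdős–Rényi graph with Uniform(0, 1] weights; a burn-in of 200 steps is
discarded and stability (spectral radius of γI + βT below 1) is checked
before simulating.  Defaults: N = 20, density 0.2, γ = 0.5, β = 0.4,
σ = 1, T = 2000, 3 sessions — strong enough coupling to be detectable in
minutes-scale experiments while temporally autocorrelated like
band-limited BOLD.  The generator is exactly a VAR(1) with
A₁ = γI + βT, which closes the loop between modules: OLS recovery of A₁,
the forecasting benefit of supplying T, and influence-based edge
recovery all have known answers.  An optional band-pass of the
innovations exists but is off by default because it would break the
exact VAR(1) identity.  What the generator does *not* emulate: the
hemodynamic response, physiological/scanner noise, inter-subject
variability.  Passing tests on it therefore demonstrate correctness of
the machinery and sensitivity to known coupling — not performance on
real fMRI.

## Problem sizes used by the test suite and acceptance script

Multi-seed training experiments run on one session of T = 600 steps with
T_p = 10, T_f = 5, a 16-unit single-layer DCRNN, and a 12-channel
2-block GWN trained for 4–6 epochs (GWN at η = 10⁻³, matched to the
short run).  These sizes keep a 5-seed × 2-family × 2-operator
experiment at a few minutes on one CPU; the generator's coupling
conditions are the defaults above.  At these sizes the innovation noise
dominates the predictable signal, so absolute errors sit close to the
irreducible floor and the meaningful comparisons are *relative*: K = 1
versus K = 0, and edge versus non-edge influence ranking.

## Known limitations

- The autodiff engine is single-threaded float64 numpy; it is exact but
  not fast, which is why the shipped experiments are scaled down.
- The skip-gram implementation is minibatch mean-gradient SGD, not the
  asynchronous per-pair updates of word2vec; with very few total batches
  (tiny corpora) it needs more epochs or a larger step size.
- Batch normalization in TAtt mixes time steps through its batch
  statistics during training; causality holds exactly in eval mode.
- The influence measure explains what a trained model's forecasts depend
  on; it is not a claim of causal (effective) connectivity.
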