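# Methods

## Model

`ltrdose` fits a degree-`n_d` multivariate polynomial to dose-specific
drug-combination responses.  The polynomial's coefficient tensor is never
materialized; it is represented as a sum of `n_t` rank-one tensors, so that
evaluation reduces to products of inner products.  The production model is
the *extended* (reparametrized) form

    π(x) = Σ_t λ_t Π_{d=1..n_d} ⟨v_t^(d), A(U^(d)ᵀ D_{λ(u)} x)⟩,

with per-degree projections `U^(d) ∈ R^{n×n_k}` (a bottleneck when
`n_k < n`), factor weights `V^(d) ∈ R^{n_t×n_k}`, an input scaling vector
`λ^(u) ∈ R^n`, term scales `λ ∈ R^{n_t}`, an output projection
`Q ∈ R^{n_t×n_y}` and a pointwise activation `A`.  The *basic* form (free
factors `P^(d)`, no bottleneck) is kept as a separate evaluation path: with
the identity activation the extended model folds algebraically into it, and
the basic form folds into a dense coefficient tensor — the chain used by
the brute-force oracle tests at tiny sizes (`n^{n_d} ≤ 10^6` capped).

Inputs are homogenized (a constant-1 column appended **last**), so degrees
below `n_d` and the intercept are covered.  Because the factors are free
per degree slot, the model class contains asymmetric polynomials such as
`x₁²x₂` — a capability symmetric factorization machines lack, and relevant
here because drug slot A and slot B are not exchangeable once monotherapy
rows (slot B empty) enter the data.

The activation is configurable from {identity, tanh, sigmoid}; the default
is identity, which preserves exact polynomial semantics and enables the
tensor oracle.  The gradient formulas need only `A`'s pointwise derivative.

## Objective and training

The fitted objective is

    h = 1/(m·n_y)·‖Y − F D_λ Q‖²_F
      + C_p/(n_t·n_d·n_k)·Σ_d (‖U^(d)‖² + ‖V^(d)‖²)
      + C_q/(n_t·n_y)·‖Q‖²
      + C_λ/n_t·‖λ‖²
      + C_u/n·‖λ^(u)‖²,

where `F = ∘_d A(X D_{λ(u)} U^(d)) V^(d)ᵀ`.  All five gradient blocks are
computed analytically in a compact matrix form (residual `E = F D_λ Q − Y`;
leave-one-out Hadamard products via prefix/suffix scans, so one gradient
pass costs the same order as `n_d` forward passes).  Constant factors are
normalized so the gradients differentiate the objective *exactly*; a
central-finite-difference diagnostic (`ltrdose.diagnostics`) is the
arbiter and holds to ~1e-9 relative in the test suite.

Training alternates, per epoch: a seeded shuffle; mini-batch updates under
plain SGD, Nesterov momentum or ADAM (conventional coefficients); row
projection of `U`, `V`, `Q` onto the unit sphere after each batch; and an
exact ridge re-solve of `λ` on the full data (the objective is an ordinary
ridge problem in `λ` with everything else fixed — Gram matrix
`(FᵀF)∘(QQᵀ)`).  `λ` and `λ^(u)` are never normalized: `λ` carries each
term's magnitude (the analogue of singular values) and `λ^(u)` is a free
per-input scale.  Stopping: epoch budget, or relative objective improvement
below `tol` for `patience` epochs; divergence (objective exceeding 10³×
its initial value for three consecutive epochs) aborts with the trace.

Two design points deserve emphasis:

- **The update direction is descent.** The projection algorithm is run on
  the minimization objective with `−γ∇` steps; the non-increase of the
  objective under small full-batch steps is property-tested.
- **`C_u` (ridge on `λ^(u)`) is this package's addition.**  Because row
  normalization projects every row of `U` and `V` back to unit norm, a
  Frobenius penalty on those blocks (`C_p`) cannot shrink capacity — the
  projection undoes it.  The only per-input shrinkage dial the
  parameterization retains is `λ^(u)`; penalizing it performs soft feature
  selection and measurably stabilizes generalization on one-hot designs
  with many uninformative columns.  Default 0.

Optional trainer facilities used by the benchmark studies: a validation
split whose RMSE is traced per epoch, with `restore_best` returning the
best-epoch snapshot; in cross-validation, the validation slice is carved
from the training fold *at the same holdout grain as the scenario* (e.g.
whole drug pairs for S2/S3), because validating on random rows would reward
exactly the pair memorization the scenario punishes.  `cross_validate` can
also average predictions over independently initialized restarts (the
optimization is non-convex; restart averaging damps initialization
variance), discarding restart members whose validation RMSE is >10% worse
than the best member, and clips predictions to the training response range
(%-growth is a bounded assay readout; a high-degree polynomial should not
extrapolate beyond it).

## Feature encoding

The quintuplet *(drug A, drug B, conc A, conc B, cell line)* is one-hot
encoded in five contiguous blocks; a combination row has exactly five ones,
a monotherapy row three (its drug-B and conc-B spans all zero — the
sentinel is the absence of a category, not an extra one).  Concentrations
are encoded by level index, not molar value: the levels index the response
tensor.  Drug pairs are kept in the order given; the generator emits one
canonical orientation.

Auxiliary blocks: binary substructure fingerprints inserted once per drug
slot (`fp_a`, `fp_b`), and one block per omics type for the cell line.
Fingerprint bits present in all drugs or none are dropped (they carry no
information); omics features pass a top-variance filter (unbiased sample
variance across cell lines, `ceil(fraction·p)` kept, ties to the earlier
column, per omics type independently).  Two encoding-time options depart
from "use values as provided", both off by default at the `assemble` level
and enabled by the pipeline: z-scoring of the continuous omics columns
(their variances span orders of magnitude; binary fingerprints are never
standardized — centering indicator bits destabilized training in pilots),
and division of each auxiliary block by √(block width).  The latter keeps
wide blocks from dominating the row energy: under a degree-`n_d` product
model the prediction magnitude scales like (row energy)^{n_d/2}, and
unscaled 70-column blocks made optimization erratic.  Neither transform
changes the representable function class (both are absorbed by `λ^(u)` and
`U`).

The `FeatureLayout` records every block's span, names and vocabulary; it is
serialized with the model and checked at prediction time, and it drives the
weight-extraction analyses.

## Synthetic panels

The generator emulates a combination screen: all or a fraction of drug
pairs, each measured on an `n_conc × n_conc` grid in every cell line, plus
monotherapy rows at the same level indices; binary fingerprints with
shared substructures (bit prevalences in (0.15, 0.85)) and two forced
constant bits to exercise the filter; omics blocks with log-normal
per-feature standard deviations (heavy-tailed variance spectra, as real
omics panels show).

The hidden response surface is drawn from the model class itself (identity
activation), which makes recovery experiments well-posed: failures indict
the optimizer, not misspecification.  The surface is
`offset + scale·z` with `z` standardized over the panel, so the response
spread is exactly the requested scale; additive Gaussian noise is applied
on top and the noise-free values are retained (never written into public
output files).  Defaults: 4×4 grids, offset 40, scale 30 %-growth points,
noise 5 points, degree-5 rank-10 truth — a small panel with the data's
full structure.  A `misspecified` mode substitutes a saturating Hill-type
Bliss surface with a random pairwise interaction, outside the model class,
for robustness testing.

A configurable share `s` of the signal variance is routed through the
auxiliary features: `z = √(1−s)·z_idx + √s·z_aux`, where `z_aux` is a
substructure-driven drug effect — fingerprint main effects (structure–
potency) plus a low-rank fingerprint–fingerprint interaction.  Two further
knobs shape benchmark panels: `index_active_blocks` restricts which one-hot
blocks the index component uses, and `pair_structure="matching"` screens
every drug in exactly one pair.

## Benchmark studies and what they show

**Recovery** (`recovery_experiment`): 13 drugs × 15 cell lines × 4×4 grid
(49 raw features + constant = 50; 19,500 rows), degree-5 rank-10 truth, 5%
noise.  A rank-40 model (4× the generating rank — overparameterized
factorized models optimize far more reliably than exact-rank ones) reaches
held-out Pearson ≈ 0.99 in 150 epochs.  Factor recovery is *not* claimed:
the decomposition is not unique; the claim is prediction-level.

**Asymmetric expressiveness**: `x₁²x₂` fitted at degree 3 to R² > 0.999 —
the monomial a symmetric polynomial class cannot represent.

**Auxiliary-feature gain in S3** (`auxiliary_gain_experiment`): this is
the subtlest study.  Any function of fingerprints with low CP rank is
*exactly representable* by low-rank one-hot drug factors, so whenever every
test-pair drug has other training pairs, the identity route learns the
chemistry signal by proxy and fingerprints add nothing — a finding from
this package's pilot experiments that mirrors how small the auxiliary gain
is on real screens.  Fingerprints help precisely when drug-level
information is missing.  The benchmark panel therefore uses the matching
structure (80 drugs, one pair each, 3 cell lines): holding out a pair under
S3 (monotherapies also withheld) leaves both of its drugs with *zero*
training rows, so one-hot identities are uninformative and only shared
substructure bits can transfer their effects.  Both configurations train
the same deliberately small model (degree 2, rank 8): at that capacity the
model cannot memorize per-pair constants through the one-hot blocks, so
reducing training loss forces the compact, generalizing fingerprint
representation.  Per seed, predictions are pooled over all five folds
(every pair predicted once as held-out) and the tensor-only and
tensor+fingerprint Pearson correlations compared; the fingerprint
configuration won in 14 of 15 calibration panels (mean gain ≈ +0.05).
Omics features are excluded from this comparison: cell lines are never
held out in S2/S3, so omics columns cannot carry holdout-relevant signal
and act only as distractors.

**Importance recovery** (`importance_recovery_experiment`): half the
signal of a 6-drug × 30-cell panel runs through one expression column; the
panel has more cell lines (30) than omics columns (25) because under exact
collinearity (any omics column reproducible from the others) permutation
importance provably dilutes to zero — with 6 cells and 50 columns the
planted feature was never recovered, with 30/25 it ranks first in 5/5
calibration panels.  Protocol: each raw column permuted 20 times, the mean
drop in Pearson correlation is its importance; the homogeneous constant is
never permuted.

What passing these studies does *not* show: the generator draws from the
model class (except the misspecified mode), has no plate/batch effects, no
missing values, no dose–response monotonicity, and its fingerprints are
i.i.d. Bernoulli rather than correlated chemical series.  Real-screen
performance claims require real screens.

## Cross-validation scenarios

Folds are built at scenario-specific grains (S1: per-matrix stratified
entries, monotherapies always in training; S2: whole drug pairs across all
cell lines; S3: as S2 with every monotherapy row dropped from training;
S4: (pair, cell line) triplets).  Pair identity is unordered.  Every plan
carries machine-checkable guarantees (`CVPlan.verify`): train/test
disjointness, fold partition of the test universe, no held-out pair in any
S2/S3 training fold, zero monotherapy rows in S3 training, no held-out
triplet in S4 training.  Metrics (RMSE, Pearson, Spearman) are computed
per fold and aggregated as mean ± SD, never pooled across folds.

## Synergy scoring

The combination score of a dose–response matrix follows the NCI ALMANAC
convention: growth values truncated at +100; expected combination growth
`ya·yb/100` when both monotherapy growths are positive, `min(ya, yb)`
otherwise; score = Σ over the grid of (expected − observed), larger =
more synergistic.  The identical routine is applied to measured and
predicted matrices (monotherapy anchors from the measured table in both
cases), so score-level comparisons cannot be biased by convention
mismatches.  A hand-worked 2×2 example is frozen in the tests.
Discrimination analysis labels the top X% of measured scores as
synergistic, ranks by predicted scores, and reports AUROC and the area
under the precision–recall curve per threshold; single-class thresholds
are skipped with a warning.

## Numerical notes

- `solve_lambda` with `C_λ = 0` on a rank-deficient Gram matrix returns the
  minimum-norm solution and warns.
- Zero rows are left untouched by sphere projection (no division by zero).
- The dense-tensor oracle refuses above 10⁶ coefficients.
- Mini-batches: seeded permutation per epoch, last short batch kept; batch
  size is clamped to the sample count, so full-batch plain SGD is the exact
  degenerate case of the mini-batch loop.
- Model archives are a zip of the parameter arrays (`.npz`) plus a JSON
  header with format version, activation, hyperparameters and the feature
  layout; round trip is bit-exact.
- Problem sizes throughout the test and acceptance studies (panels of
  ~2,000–20,000 rows, ranks 8–60) were chosen so each study completes in
  minutes on one CPU while leaving the measured property a clear margin.
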