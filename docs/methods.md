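# Methods

## Model

All algorithms operate on a column-centered two-class matrix
`X_c (n × k)` with labels `y ∈ {−1, +1}`; centering parameters are
learned on training data only and reused for new samples, which keeps
repeated-split evaluation leakage-free. No column scaling is applied by
default (an optional unit-variance flag exists), since the methods only
presume centering.

**LDA.** With two classes the between-class scatter
`S_B = (m₁−m₂)(m₁−m₂)ᵀ` has rank one, so instead of the general
eigenproblem the discriminant is taken in closed form,
`w ∝ S_W⁺(m₂−m₁)`, which is exact, stable and extends to singular `S_W`.
The pseudo-inverse is evaluated from the thin SVD of the class-centered
data matrix `C` (`S_W = CᵀC`), which costs `O(n²k)` instead of `O(k³)`
and is what makes cross-validation affordable at `k = 500`. Singular
values of `S_W` below `1e−10` times the largest are truncated — standard
pseudo-inverse practice; the value is not critical because the truncated
directions carry within-class variation indistinguishable from zero.
`S_W` is the raw (unnormalized) scatter sum: any positive scaling only
rescales `w`, which is re-normalized, and a test asserts that
observational irrelevance. The sign is fixed so the +1 class projects
high, making thresholds and λ-blends reproducible.

**NIPALS-PLS.** Components are extracted by the classical alternating
iteration with convergence tested on the score vector `t` at relative
tolerance `1e−10` (max 500 iterations; a single-column response is
stationary after one pass, with `w ∝ Xᵀy` exactly). Deflation is
`X ← X − t pᵀ`, `Y ← Y − b t qᵀ` (the fitted part of Y — the standard
PLS1/PLS2 update), which yields mutually orthogonal scores and the exact
decomposition `X_c = T Pᵀ + E`. Coefficients are assembled in the closed
form `B = W (PᵀW)⁻¹ diag(b) Qᵀ` rather than accumulated iteratively.
NIPALS signs are arbitrary, so each weight column is flipped to make its
largest-magnitude entry positive; all derived quantities are invariant
to this. With a full set of latent variables the fitted values equal the
least-squares fit, which the tests pin against a pseudo-inverse oracle.

**LDA-PLS.** Per component, on the current residual: compute `w_lda`,
project `c = X w_lda`, regress `c` on `X` by NIPALS with `a` latent
variables, keep the coefficient vector `B`, then deflate by the rank-one
piece along the unit score `t = XB/‖XB‖` with loading `p = Xᵀt`.
Two genuinely open choices were resolved as follows:

- *Deflation direction.* Deflating along the extracted coefficient's
  score (so later components model variance the current direction has
  not explained) is the default; deflating along the LDA score is
  exposed as a `deflation="lda"` switch for sensitivity checks.
- *Recomputation.* `w_lda` is recomputed on each deflated residual
  (matching the loop structure of the procedure) rather than reused.

New samples are projected stage-by-stage with the stored loading pairs
and training score normalizations, so projecting the training data
reproduces the fitted scores exactly.

**ex-LDA-PLS.** The blend `w(λ) = normalize((1−λ)ŵ_lda + λB̂)` uses
unit-normalized inputs because the raw `B` differs from `w_lda` by an
arbitrary proportionality constant, which would otherwise make λ's scale
meaningless; the convex form is the simplest satisfying the endpoint
semantics (λ=0 ⇒ LDA, λ=1 ⇒ LDA-PLS, both returned exactly). λ is
selected by a single traversal of the 1001-point grid {0, 0.001, …, 1}:
the training set is split 50/50 stratified (seeded), LDA-PLS is fitted
on the selection half, and each blended direction is scored on the
verification half with the same pooled-variance Gaussian rule used
everywhere else; ties go to the smallest λ (minimal departure from LDA).
The grid evaluation is vectorized over λ; a test asserts it agrees
exactly with per-λ classifier fits. With more than one outer component
the same λ blends every component's direction pair.

## Evaluation protocol

The "Bayesian linear classifier" is realized as the linear Gaussian
discriminant: class-conditional Gaussians with pooled covariance and
empirical priors on the projected scores (a diagonal-covariance naive
switch is provided). A singular pooled covariance receives a logged
ridge of `1e−8 · trace/d`. Metrics: accuracy, G-Mean = √(TPR·TNR), and
F-Value (harmonic mean of precision and recall of the +1 class). Zero
denominators: no predicted positives gives F-Value 0 with a flag; a
class absent from the truth flags the metric NaN and excludes it from
means with a logged count.

Comparisons use stratified 7:3 train/test splits repeated 20 times
(stratification prevents empty-class folds on imbalanced data, which the
G-Mean discussion presupposes); per split, the latent-variable count is
chosen by stratified 10-fold cross-validation over 1–10 (smallest LV on
ties) and λ by the traversal above, both strictly inside the training
part — the only leakage-free reading of a one-line protocol. The PCA
baseline keeps the smallest component count whose cumulative explained
variance reaches 0.95; PLS-LDA fits LDA on the PLS score matrix and is
one-dimensional by construction. Train and test metrics are both
averaged over runs. The components sweep repeats the protocol per
component count (1–30 by default) with the latent-variable count held
fixed, since its purpose is isolating the effect of component count.

## Synthetic data

`make_toy2d` (defaults frozen: n=1224, gap 2.0, band half-width 0.3,
x-spread 6, 18% outliers at |x| up to 12 raised diagonally up to 5)
reconstructs the instructive two-dimensional geometry: wide horizontal
bulk bands dominate the within-class scatter, and diagonally displaced
outliers add cross-covariance that tilts `w_lda` off the vertical
separator by ~0.16 rad — enough that a pooled-Gaussian threshold on the
LDA projection misclassifies bulk corners (training accuracy ≈ 0.96–0.98
across seeds) — while the class-mean difference (equivalently the one-LV
LDA-PLS direction, since `B ∝ X_cᵀX_c w_lda ∝ m₂−m₁` there) tilts the
opposite way, so the λ-family sweeps through a perfect separator. The
generator verifies linear separability (vertical margin ≥ ε) before
returning. It does not attempt to reproduce any particular published
point cloud, only these structural properties.

`make_collinear_spectra` embeds an `n_informative`-dimensional latent
class signal (class-mean separation `class_shift`, unit within-class
latent spread) into smooth Gaussian bands of width `collinearity_length`
features, plus iid per-feature noise `noise_sd` — giving the
neighbor-feature collinearity of vibrational spectra and, with
`small_sample_flag`, a k > n matrix with singular `S_W`. Defaults
(n=200, k=500, 4 informative bands, width 25, shift 4, noise 0.1) give a
moderately hard problem; the small-sample acceptance check uses n=50,
k=500 with shift 6 (6σ class separation — the high signal-to-noise
condition under which every pipeline should exceed 0.95 test accuracy).
What these generators do *not* emulate: instrument baselines, cosmic
spikes, multiplicative scatter, heteroscedastic noise — so passing tests
demonstrate algorithmic correctness and the qualitative phenomena, not
performance on real spectra.

## Numerical choices and limitations

- All randomness flows through integer seeds (numpy `default_rng`,
  sklearn splitters); reports are byte-reproducible functions of
  (data, config, seed).
- Deflation stops early (with a warning) when the residual Frobenius
  norm falls below `1e−10` of its initial value; requesting more
  components than the rank supports returns the extracted subset.
- `PᵀW` condition numbers above `1e12` raise rather than silently
  producing garbage coefficients.
- Degenerate inputs raise typed errors: empty/one-class data, zero
  within-class variation, a mean difference annihilated by the
  pseudo-inverse cutoff, antiparallel blend inputs at interior λ.
- Strictly binary: multi-class extensions and kernel variants are out of
  scope, as are shrinkage-LDA baselines and spectral file formats.
- Problem sizes in tests and the acceptance script (n=50–100 structural
  checks, 5-run protocol at n=50, k=500) are chosen to exercise every
  code path, including the singular-scatter regime, at small scale.
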