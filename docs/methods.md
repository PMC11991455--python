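# Methods

## Setting and model

A band-passed EEG trial with `n` channels and `T` samples is represented by
its covariance matrix, a point on the manifold of symmetric
positive-definite (SPD) matrices. All geometry uses the affine-invariant
(Fisher–Rao) metric, `d(A,B) = ‖log(A^{-1/2} B A^{-1/2})‖_F`, which is
invariant under congruence `C → F C Fᵀ` for any invertible `F` (hence under
re-referencing and spatial filtering applied consistently to train and test)
and under inversion.

The training state of all classifiers is a *means field*: for each class,
the power means `P_h` of the class's trial covariances on the exponent grid
`h ∈ {±1, ±0.75, ±0.5, ±0.25, ±0.1, 0}` (11 means per class). `P_h`
interpolates between the harmonic (`h = −1`) and arithmetic (`h = 1`) means
with the geometric mean as the `h → 0` limit; sampling the whole family
captures class geometry at several effective signal-to-noise trade-offs
without tuning a per-subject `h`.

The MF classifier maps a trial `C` to the feature vector of squared
distances to all means (class-major, `h` ascending; 22 features for two
classes) and applies a two-class linear discriminant with pooled
within-class covariance, empirical priors, and no shrinkage beyond a
singularity ridge (`1e-6 · tr(Σ_w)/p`, applied only when the solve fails) —
keeping the pipeline free of tuned hyperparameters and fully deterministic.
More than two classes use one-versus-rest discriminants with argmax
assignment. MDM and MDMF classify by minimum (squared) distance; their
binary scores for AUC are the signed differences of per-class (minimum)
squared distances, a choice that the underlying decision rule does not
prescribe but that reduces to it at the decision threshold. Exact ties
always resolve to the lower class index.

## Solvers and numerical choices

**Power mean (`0 < h < 1`).** Multiplicative fixed-point iteration on a
square-root factor `X` of `P^{-1}`: `H = Σ_k w_k (X C_k Xᵀ)^h`,
`X ← H^{-φ} X` with exponent step `φ = 0.375/|h|`, stopping when
`‖H − I‖_F / √n <` tolerance, then `P = (Xᵀ X)^{-1}`. At convergence this is
exactly the self-consistency equation `P = Σ_k w_k (P #_h C_k)`. Negative
`h` uses the duality `P_h = [P_{-h}({C_k^{-1}})]^{-1}` with the warm start
inverted correspondingly; `h = ±1` short-circuit to the closed forms.

**Geometric mean.** Karcher flow
`G ← G^{1/2} exp(ε Σ_k w_k log(G^{-1/2} C_k G^{-1/2})) G^{1/2}` with initial
step `ε = 1`, halved (floored at `1e-3`) whenever the gradient norm
increases; convergence when the dimension-normalized gradient norm drops
below tolerance. It is not approximated by a small-`|h|` power mean.

**Defaults.** Tolerance `1e-7` and at most 150 iterations per mean. The
tolerance is loose enough to avoid needless iterations yet far below any
distance that matters for classification; the generous iteration cap buys
convergence in low-SNR cases. Non-convergence raises an error carrying the
final residual — means are never silently truncated.

**Warm starts.** Within a class, positive exponents are solved in decreasing
order starting from the closed-form arithmetic mean, negative exponents in
increasing order from the harmonic mean, each solve initialized at the
previous solution; `h = 0` is initialized from the mean at the smallest
available `|h|` (positive side on ties). Cold starts (when a mean is
requested alone) use the arithmetic mean for `h > 0`, the harmonic mean for
`h < 0`, and the geodesic midpoint of the two for `h = 0` — closed-form
points inside the set's convex hull. Uniqueness of each mean makes warm
starts a speed optimization only; a field test verifies warm- and
cold-started fields agree to well below solver tolerance.

**Matrix functions** are computed exclusively through the symmetric
eigendecomposition (batched over trial stacks in the solver inner loops).
Inputs asymmetric beyond a `1e-10` relative tolerance, or with a
non-positive eigenvalue, raise a validation error naming the offending
eigenvalue; below that tolerance matrices are symmetrized as `(S + Sᵀ)/2`.
No eigenvalue flooring is performed anywhere: positive-definiteness must
come from the OAS estimator.

**OAS covariance.** `(1−ρ) S + ρ (tr S/n) I` with the closed-form shrinkage
weight `ρ = min{1, [(1 − 2/n) tr(S²) + tr²(S)] / [(T + 1 − 2/n)(tr(S²) −
tr²(S)/n)]}`, and `ρ = 1` when the denominator is non-positive (sample
covariance proportional to the identity). Epochs are assumed zero-mean
(band-passed upstream); the sample covariance uses divisor `T` and no
centering option is exposed. Band-pass filtering, artifact handling and raw
EEG format parsing are deliberately out of scope — any standard EEG stack
can feed epochs in.

## Robust estimation

Per class, distances of all trials to the current mean are standardized
(`z = (d − mean d)/sd d`, sample sd with divisor `n−1`; a degenerate spread
below `1e-12` yields all-zero z, so nothing is trimmed). Trials with
`z > 2.5` are removed and the mean re-estimated, for at most 4 passes,
stopping early when no trial is flagged or when removal would leave fewer
than 2 trials (in which case it is skipped entirely, never partially
applied). For the field, the screen runs **once per class against that
class's geometric mean**, and the surviving subset (weights renormalized)
feeds the whole 11-mean field: screening separately per exponent would be
11× the cost and could leave different means estimating different
subpopulations. The trimmed field on a clean set equals the plain field
exactly.

## ADCSP

Stage 1 (entered iff dimension ≥ 28, reducing to 28): arithmetic class
means; for two classes the generalized eigendecomposition
`M₁ v = λ (M₁+M₂) v` with eigenvectors ranked by `|λ − 1/2|` (for more
classes, Pham AJD of the arithmetic means). Stage 2 (after stage 1, entered
iff dimension ≥ 10, reducing to 10): geometric class means jointly
diagonalized by Pham's algorithm, components ranked by the between-class
variance of `log(vᵢᵀ M_c vᵢ)` across class means — a discriminability score
chosen here because the variance-contrast it measures is exactly what
minimum-distance classification of covariances exploits. Below both
thresholds the filter is the identity. Filter rows are unit-normalized with
the largest-magnitude entry made positive, fixing the scale/sign
indeterminacy of both decompositions (Pham's criterion is invariant to row
rescaling). The entry/exit dimensions 28 and 10 are configuration with
these defaults, not hard-coded. Filters are fitted on training folds only
and applied to test trials by pure congruence. The Xdawn filter used for
event-related-potential pipelines is an established external method; any
object producing a projection matrix satisfies the same contract.

## Evaluation statistics

AUC-ROC under stratified 5-fold cross-validation; the fold assignment is a
pure function of (labels, k, seed) so compared pipelines always see
identical folds. Paired per-database comparisons: an exact one-sided
sign-permutation test over all `2ⁿ` sign assignments of the paired
differences (statistic: the mean; the observed assignment counts, so
`p ≥ 2⁻ⁿ`) for fewer than 20 subjects, else the one-sided Wilcoxon
signed-rank test with zeros dropped, mid-ranks, tie-corrected variance and
continuity correction. Combination across databases: weighted Liptak
(`z_i = Φ^{-1}(1 − p_i)`, combined `z = Σ w_i z_i/√(Σ w_i²)`, p-values
clipped to `[1e-15, 1 − 1e-15]`) and the weighted arithmetic mean of
standardized mean differences, both with `w = √n_subjects`. The SMD is
paired Cohen's d — `mean(d)/sd(d)` with divisor `n−1` and CI
`SMD ± 1.96 √(1/n + SMD²/2n)`; no small-sample (Hedges) correction is
applied. Identical score columns yield SMD 0 with an unbounded-CI flag;
databases under 2 subjects are excluded with a warning. Fold AUCs are
averaged within session, then across sessions within subject, before
testing.

## Synthetic data

SPD clouds are sampled in the tangent space: trial
`= C^{1/2} exp(S) C^{1/2}` with `S` symmetric Gaussian of scale σ, so center
and dispersion are independently controllable (a Wishart model would couple
them). Class centers sit a prescribed geodesic distance apart
(`I` and `exp(sep·V)`, `‖V‖_F = 1`). Outliers inflate dispersion by a factor
(default ×10) on a fraction of trials rather than translating centers —
the noisy-trial failure mode the robust estimator targets. Mixed-source
epochs draw latent sources with class-dependent variance on a designated
subset (contrast decaying as `0.75^i` per source to keep discriminative
directions non-degenerate), mix them with a random full-rank matrix, and add
white sensor noise at a per-channel average SNR. Default study conditions
for the benchmark-style checks: 4 channels, 40 trials per class, dispersion
0.2 (0.2 vs 0.6 in the heteroscedastic ordering study), separation 0.8–1.0,
10% outliers at ×10 where robustness is probed — sizes representative of a
single within-session BCI recording. All generators are pure functions of
their seed.

What the generators do **not** emulate: realistic EEG spectra and artifact
morphology, volume-conduction forward models, non-stationarity across a
session, and class structure richer than center/dispersion differences.
Passing tests therefore demonstrate correctness of the geometry, the
solvers, the trimming and the statistics under a controlled generative
model — not classification performance on any particular EEG database.

## Problem sizes

The shipped checks use 10×10 sets (6 matrices, 100 replicates) for solver
accuracy, 4×4 clouds with 40 trials per class (100 replicates for
robustness, 20 seeds × 5 folds for the classifier ordering), 32-channel
epochs for the dimension-guarantee check, and 1000 replicates of n = 12 for
null calibration of the exact test — sizes at which every quantity is
recomputed from scratch in seconds while the Monte-Carlo rates are stable
to a few percent.

## Known limitations

- Binary problems are the primary target (as in standard BCI benchmarks);
  multi-class support (one-versus-rest MF, AJD-based CSP) is functional but
  not the object of the headline checks.
- The LDA covariance divisor is `n − 2` (pooled unbiased); discriminant
  scores differ from implementations using divisor `n` by a positive scalar,
  which never changes decisions or AUC.
- The fixed-point solvers assume well-conditioned inputs as produced by OAS;
  means of nearly singular matrices may need more than the default 150
  iterations.
- Tangent-space classifiers (e.g. logistic regression on tangent vectors),
  often the strongest Riemannian baselines, are intentionally out of scope;
  the package's claim is about manifold-direct classifiers.
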