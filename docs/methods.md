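# Methods

## Model

`mintpls` fits a sparse multi-group partial least squares discriminant
analysis. Data are N samples × P variables (log-scale continuous expression),
partitioned into M independent studies, with one of K classes per sample.
The class membership is encoded as an N × K indicator matrix Y (columns in
lexicographic class order). For each dimension h the model maximizes the
study-size-weighted sum of per-study covariances between the data component
X<sub>h</sub><sup>(m)</sup>a<sub>h</sub> and the outcome component
Y<sub>h</sub><sup>(m)</sup>b<sub>h</sub> under unit-norm loadings, with an ℓ1
penalty on the gene loading a<sub>h</sub> only (b is never thresholded).

**Reduction to a penalized cross-product.** Because every study is centered
(and scaled) per variable before fitting, Σ<sub>m</sub>
X<sup>(m)ᵀ</sup>Y<sup>(m)</sup> equals the cross-product XᵀY of the
concatenated standardized matrices, and the per-study covariance weights
n<sub>m</sub>/(n<sub>m</sub>−1) are absorbed into the (consistent) n−1
variance convention. Each component is therefore a penalized rank-one
approximation of M<sub>h</sub> = X<sub>h</sub>ᵀY<sub>h</sub>, solved by
alternating updates

1. w ← M<sub>h</sub> b
2. a ← normalize(soft_threshold(w, λ(keepX)))
3. b ← normalize(M<sub>h</sub>ᵀ a)

until the ℓ2 change of a falls below `tol` (default 1e-6, `max_iter` 100;
non-convergence is a warning and returns the best iterate). The
dense-to-sparse special cases follow directly: keepX = P is multi-group
PLS-DA (component 1 is the top singular pair of XᵀY), and M = 1 is classical
PLS-DA. This reduction is verified in the test suite against an SVD oracle
and against the independent mixOmics implementation on a shared fixture.

**keepX parameterization and ties.** The penalty is expressed as the number
of genes retained: λ is set to the largest |w| strictly below the keepX-th
largest, so exactly keepX entries survive when magnitudes are distinct. If
several entries tie at the boundary they are all kept (with a warning) rather
than broken by index order, so selection never depends on column ordering.

**Initialization, sign, determinism.** b is initialized to the leading right
singular vector of M<sub>h</sub> — a deterministic, near-optimal start. After
convergence the quadruple (a, b, t, u) is flipped so the largest-magnitude
entry of a is positive. Fitting is therefore bitwise reproducible.

**Deflation.** Both blocks are deflated by regression on the *global*
component: p<sub>h</sub> = X<sub>h</sub>ᵀt<sub>h</sub>/(t<sub>h</sub>ᵀt<sub>h</sub>),
c<sub>h</sub> = Y<sub>h</sub>ᵀt<sub>h</sub>/(t<sub>h</sub>ᵀt<sub>h</sub>),
X<sub>h+1</sub> = X<sub>h</sub> − t<sub>h</sub>p<sub>h</sub>ᵀ, likewise for Y.
Deflating on the global rather than per-study partial components guarantees
mutually orthogonal global components and a single well-defined projection
operator for prediction; a per-study deflation variant would forfeit both
without a compensating benefit, so it was not adopted. The number of
components H defaults to K − 1.

## Standardization and validation

Within each study every X variable is centered and scaled to unit variance
with the unbiased n<sub>m</sub>−1 denominator; the same convention is
mirrored for Y (scaled iff `scale_y`, default on), since any consistent
denominator choice only rescales the objective. Two hard dataset rules
follow from the per-study scaling: every study needs more than 3 samples, and
at training time every study must contain every class (otherwise the class
and study effects are confounded and neither this nor any classifier can
separate them). A variable constant within some study has no defined scale
there; the default policy is an error, with an opt-in `drop` policy (warning
lists the dropped variables) because real multi-platform matrices commonly
contain such columns. A batch structure *within* a study is not auto-detected;
users should split such a study into sub-studies along the batch factor.

## Prediction

Test samples from a training study reuse that study's stored coefficients
(this makes the single-study model coincide exactly with classical PLS);
samples from a new study are centered and scaled within their own study
(hence also the >3 samples rule at test time). Scores follow the fitted
deflation sequence with the training projections p<sub>h</sub>; the indicator
matrix is estimated as Σ<sub>h</sub> t<sub>h</sub>c<sub>h</sub>ᵀ and
back-transformed with the **pooled** training Y statistics (class proportions
and pooled sds). Pooled rather than per-study back-transformation was chosen
because per-study Y statistics do not exist for unseen test studies; it
coincides with the per-study variant when M = 1. When Y is not scaled, each
predicted indicator row sums to exactly 1 (centered indicator rows sum to 0,
so the c<sub>h</sub> column sums vanish and the pooled class proportions sum
to 1); with Y scaling this identity is not guaranteed, which is why it is
asserted only for `scale_y=False`. Classes are assigned by the row-wise
maximal value, even when no entry is positive (warned); ties resolve to the
first class in class order (warned).

## Tuning

keepX is selected per component by leave-one-group-out cross-validation:
each study is held out exactly once (M folds, sorted study order, fully
deterministic) and predicted from a model fitted on the other studies; the
held-out study is standardized independently, so no scaling information leaks
across the split (verified: an affine rescaling of the held-out study changes
nothing). Tuning is forward: keepX values selected for earlier components are
frozen while the current component's grid is scanned; this matches the
per-component penalty structure and keeps the cost at M × |grid| × H fits.
The selection criterion is the balanced error rate — the average over classes
of the within-class misclassification proportion — which protects small
classes in unbalanced designs. Ties go to the smallest keepX (sparsest
model). The default grid is {1…10, 20, 50, 100, 200, 500} ∩ [1, P]; it is a
package default, not a canonical choice, and can be overridden. Folds whose
training part misses a class are skipped with a warning; a fold that fails to
fit is excluded from that candidate's mean.

## Synthetic data generator

`simulate_multistudy` draws
X[i,j] = offset[m,j] + scale[m,j] · (classMean[k,j] + ε), ε ~ N(0,1),
with offset ~ N(0, σ²<sub>study</sub>) and scale ~ LogNormal(0, τ²) per
(study, variable), and classMean carrying a shift of δ residual-sd units on
|S| informative variables assigned round-robin to classes. This emulates the
defining feature of cross-platform compilations — between-study variance
dominating between-class variance (additive offsets model platform location,
the multiplicative factor models platform sensitivity) — under the Gaussian
working assumption natural for log-scale expression summaries and for PLS.
Per-study counter-based seeding makes each study's draws independent of how
many studies the design contains. What it does **not** emulate: count-level
RNA-seq noise (negative binomial), probe-level artifacts, correlated gene
modules, class imbalance across studies, and nonlinear batch distortions.
Passing tests on these data therefore demonstrate correctness of the method
and its behaviour under additive/multiplicative study confounding, not
end-to-end performance on raw platform data.

Preset designs: `maqc-like` (3 studies × 2 classes × 10 samples/class, P=500,
δ=1, σ<sub>study</sub>=3, τ=0.3 — study effects 3× the class effect, the
regime where naive concatenation separates platforms), `mild`
(σ<sub>study</sub>=δ=1), and `null` (δ=0, no informative variable).

## Problem sizes used in the shipped analyses

The marker-recovery analysis (tests and `scripts/acceptance.py`) uses M=4
studies, 15 samples/class/study, K=2, P=1000, |S|=10, δ=1.5,
σ<sub>study</sub>=2, τ=0.3 over 25 replicates; the null analysis uses the
`null` preset over 10 replicates; the scale check fits 210 samples × 13,313
variables (a typical multi-study stem-cell training compendium) with H=2.
These sizes give stable Monte-Carlo summaries while keeping a full run of the
suite and the acceptance script in the tens of seconds on one CPU.

## Known limitations

* Only the keepX parameterization of the penalty is exposed (no λ path), and
  only regression-mode deflation with the maximal-distance classifier;
  centroid/Mahalanobis distances and ROC/AUC summaries are out of scope.
* The model assumes the class signal has a common direction across studies
  after per-study standardization; study-specific discriminant directions are
  averaged, not modelled.
* Upstream preprocessing (probe-to-gene mapping, background correction,
  within-sample normalization) must be done beforehand.
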