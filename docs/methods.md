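# Methods

## Problem setting

The package decodes binary movement intention ("d" vs "l" keypress) from
continuous 21-channel scalp EEG (10/20 layout, 200 Hz) in a self-paced
paradigm: the subject freely chooses which key to press and when, and the
keypress instant defines t = 0. Two analysis windows are cut per trial —
pre-movement [-0.85, 0) s and movement [0, 0.85) s, 170 samples each — and
classified independently. Beyond raw accuracy, the goal is interpretability:
a per-channel *importance* measure derived from a learned linear projection,
rendered as a scalp topography.

## Matrix-based entropy estimators

All information-theoretic quantities are matrix-based Renyi entropies of
order alpha: for a PSD kernel Gram matrix normalized to unit trace,
S_alpha = (1/(1-alpha)) log sum_i lambda_i^alpha over its eigenvalues. Joint
entropy of labels and points uses the Hadamard product of the binary
same-class Gram matrix and the Gaussian Gram matrix of the points (PSD by
the Schur product theorem), again trace-normalized. Conditional entropy and
mutual information follow by the chain rules, which then hold to round-off
by construction.

Choices that matter:

* **alpha = 1.01** (default): close to Shannon behavior while keeping the
  matrix power well-conditioned. Any alpha > 1 is accepted.
* **Unit-trace normalization of every Gram matrix**, marginal and joint
  alike. Without it the marginal is unbounded and the chain rule breaks;
  with it every entropy lies in [0, log n].
* **Eigenvalue clipping at 1e-12** before the matrix power: symmetric
  eigendecomposition of a PSD matrix produces tiny negative round-off
  eigenvalues; they are dropped from the spectrum (and from gradients).
* Natural logarithms everywhere; all entropies are in nats.

The entropy gap EG(L; Y) = E_pi[S(L, Y_pi)] - S(L, Y) replaces mutual
information with the joint-entropy surplus of randomly re-paired samples
and labels. Internally a permutation of the points inside the joint is
applied as the inverse permutation of the label Gram matrix (a spectrum-
preserving conjugation), so the point kernel is built once per evaluation.
The expectation uses n_perm = 10 permutations by default; exactness is
pinned by a test against full 4! enumeration at n = 4. Cases that are
permutation-invariant (collapsed projection, single-class labels) return
exactly zero because the estimator averages per-permutation *differences*.

## Metric learners

All three learners fit A (d x p) by full-batch gradient descent with Armijo
backtracking (c = 1e-4, shrink 0.5, step doubling after acceptance), at most
500 iterations by default, stopping when the relative objective change
falls below 1e-6. Gradients are analytic; the entropy-based ones chain
dS/dGram through the Gaussian kernel to A. All fits are deterministic given
`random_state`, and the objective trace is monotone up to line-search
tolerance by construction.

* **CEML** minimizes S_alpha(L | XA) subject to tr(A^T A) = p. The
  constraint is handled as Riemannian descent on the trace sphere: the
  Euclidean gradient is projected onto the tangent space and each step is
  retracted by rescaling A to the sphere. Kernel bandwidth sigma defaults
  to sqrt(p/2), matched to inputs whose total variance equals their
  dimension (the PCA conditioning guarantees this).
* **EGML** maximizes the entropy gap with no constraint — the gap closes at
  both scale extremes relative to sigma, so the objective itself selects
  the scale of A. The permutation set is drawn once per fit; redrawing per
  iteration would make the objective stochastic and invalidate the line
  search. Because gradients vanish at both scale extremes, the initial A is
  rescaled so the mean projected pairwise squared distance equals
  2 sigma^2, placing the start where the gap is responsive.
* **NCA** maximizes the expected soft leave-one-out 1-NN accuracy
  sum_i P_i, with P_ij the softmax over negative squared projected
  distances and P_ii = 0 (a point is not its own neighbor).

Initialization defaults to the first p right-singular directions of the
centered input (deterministic, sensible basin); seeded random orthonormal
is available. Single-class inputs are rejected: every objective is constant
in that case.

Known limitation: on objectives with flat, scale-degenerate maxima (NCA in
particular) plain gradient descent can settle in local optima that
curvature-based optimizers escape; the induced neighbor structure is
typically equivalent, and the cross-check test against an independent NCA
implementation compares leave-one-out accuracy rather than the matrices.

## Features and conditioning

Per channel, the 170-sample window yields either its raw time course (F2,
d = 3570) or "Cartesian" DFT features: DC real part plus (real, imaginary)
pairs for the kept bins. Bin spacing is 200/170 Hz; keeping k = 0..4
(≤ 4.71 Hz) gives 9 values per channel (F1B, d = 189), keeping everything
below Nyquist (k = 0..84) gives 169 (F1A, d = 3549). This bin-counting
convention — DC real-only, Nyquist excluded — is the unique one producing
both counts for a 170-sample window. Channel blocks are concatenated in the
fixed montage order and tracked in a channel-to-columns index map.

PCA conditioning keeps d_pc components and applies one global scale so the
total variance (trace of the covariance, ddof = 1) of the transformed
training data equals d_pc. No per-dimension whitening: relative component
variances are preserved, which is exactly what the sigma = sqrt(p/2)
default assumes. PCA is always fit on the training side of a split only.

## Classification and model selection

The classifier is the nu-SVM (LIBSVM via scikit-learn's NuSVC), linear or
Gaussian. Class 1 is the positive class; z > 0 predicts class 1 and z <= 0
class 2 (ties to class 2). Gaussian bandwidths are parameterized as
sigma_SVM = sqrt(c p) with grid multipliers c in {5, 1, 1/2, 1/4, 1/20};
nu is searched over {0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.8}. An infeasible nu
(exceeding twice the minority-class fraction) surfaces as an explicit
error; inside model selection such inner folds are skipped and logged.

Evaluation is nested stratified 10-fold cross-validation: candidates
(d_pc, p, nu[, sigma_SVM]) are scored by inner 10-fold CV with every stage
(PCA, learner, SVM) refit per inner fold; the best mean inner accuracy is
refit on the outer-train partition and scored once on the outer fold. Ties
prefer the simpler model (smallest d_pc, then p, then nu, then the largest
sigma_SVM). A single-candidate grid skips the inner loop, since there is
nothing to select. Method comparisons across matched folds use a two-sided
paired t-test; identical accuracy vectors return (t = 0, p = 1) and a
zero-variance nonzero difference is reported as the degenerate p -> 0 limit
with a warning.

## Importance maps

The composite map from features to the learned space is B = (Q s) A,
including the PCA scale. Distances in the projected space are invariant to
orthogonal right-rotations of B, so columns are canonicalized by the SVD
B = U D V^T: the sorted projection B~ = U D orders dimensions by singular
value, with signs fixed by making the largest-magnitude entry of each left
singular vector positive. Importance of channel k for dimension j is the
fraction of column j's squared norm carried by that channel's rows; each
column sums to one over channels, and the overall importance is the uniform
mean over the p columns. A zero singular value makes the ratio 0/0; that
dimension is assigned the uninformative uniform value 1/N_ch and flagged.
Experiment bundles average importance over the 10 outer folds, mirroring
how accuracies are reported.

Scalp rendering uses an embedded 2-D coordinate table for the 21-channel
10/20 montage (azimuthal-equidistant projection; A1/A2 at the ears) with
linear scattered-data interpolation — the interpolated field is exposed
directly so flatness and value checks run on the same numbers as the
rendering.

## Synthetic sessions

The generator emulates one self-paced keypress session: n_trials = 700 by
default at 200 Hz, inter-trial intervals 2.5 ± 0.5 s (uniform jitter),
balanced classes in random order, background noise = white (1 µV RMS) plus
1/f noise (unit scale) per channel. Class structure is planted as additive
raised-cosine templates (band 0.5–4 Hz, 3 µV):

* pre-onset: a readiness-potential-like negative deflection on F3/F4/Fz
  whose amplitude is class-modulated (factor 1 ± 0.5);
* post-onset: a deflection on C3/C4 lateralized by class (weights
  1 ± 0.6 swapped between classes).

Templates rather than filtered noise keep the planted structure
analytically known, so recovery tests have an exact ground truth. The
marker channel carries the class integer at the onset sample only. What the
generator does *not* emulate: volume-conduction correlations between
channels, eye/muscle artifacts, non-stationary drifts, and realistic
readiness-potential latencies — so passing recovery tests demonstrate the
pipeline's correctness, not expected performance on real recordings.

## Problem sizes used in the test and acceptance suites

Sessions of 40–200 trials, d_pc 10–20, p 1–2, learner iteration budgets
40–200, and n_perm 5 for EGML inside cross-validation. These sizes keep the
suites quick while leaving every measured property (recovery rates,
accuracy levels, estimator errors) in the same regime as the full-size
defaults; the generator defaults themselves stay at the full session scale.

## Degenerate inputs and tie-breaks

n = 1 point sets are rejected; duplicate points are fine (the kernel
handles them). Gram matrices with non-positive trace or eigenvalues below
-1e-8 (relative) are rejected. SVM decision ties predict class 2. Trials
whose window leaves the recording are dropped and logged; if none remain,
epoching errors out. PCA requests beyond the data rank raise an error that
names the rank.
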