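# Methods

## Problem setting

`smfcnet` classifies subjects from resting-state brain activity summarized
as per-region (ROI) time series. Each subject is an L×N matrix X (L time
points, N ROIs; the emulated cohort has N = 120 AAL2 parcels and L = 140
volumes after discarding the first 10 of 150). The pipeline has three
stages: construction of sparsified functional-connectivity networks (FCNs),
classification of the resulting network stack by a connectome-convolution
ensemble, and localization of the connections and regions that drive the
decision.

## Network construction

**Normalization.** Columns of X are centered and scaled to unit Euclidean
norm. Under this convention the Gram matrix P = XᵀX is exactly the matrix of
sample Pearson correlations, which is what the downstream equations assume.
(The alternative z-score convention — dividing by the standard deviation
with either L or L−1 — differs only by a global scale that would reappear as
a factor in P; unit-norm scaling is the unique choice making XᵀX a
correlation.) Constant columns are rejected with a diagnostic naming the
offending ROI.

**Weighted sparse representation (WSR).** Each ROI's signal is regressed on
all the others under a weighted L1 penalty:

    min_W  ½‖X − XW‖²_F + λ‖C ⊙ W‖₁,   diag(W) = 0,

where the penalty weight C_ji = exp(−P_ji²/σ) shrinks the cost of keeping
edges between strongly correlated regions (σ = 0.2 by default; it sets how
fast the penalty decays with correlation strength). The zero-diagonal
constraint removes the trivial self-representation; it is equivalent to
zeroing the i-th dictionary column when solving for column i. The problem
is solved by ADMM with splitting W = Z: the W-step is a single linear solve
reusing one Cholesky factorization of (XᵀX + ρI), the Z-step is an
elementwise soft-threshold at λC/ρ with the diagonal projected to zero.
Constants: ρ = 1, at most 500 iterations, Boyd-style primal/dual stopping
with absolute tolerance 1e-8 and relative tolerance 1e-6. The loose
classical tolerances (1e-6/1e-4) leave ~1e-4 residual error against a
converged coordinate-descent solution; the tightened defaults reach 1e-5
agreement at ~30 iterations on typical inputs, so the extra cost is
negligible. On hitting the budget the best iterate is returned with a
convergence warning rather than an exception. The returned matrix is the
splitting variable Z, which is exactly sparse.

**Topology and masking.** The support of W at each λ is symmetrized by the
OR rule — edge (i,j) present iff |W_ij| > ε or |W_ji| > ε, with ε = 1e-5
absorbing floating-point noise. (Symmetrizing by |W|+|Wᵀ| gives the same
support; only the support is consumed downstream.) The binary mask G is
applied elementwise to the correlation matrix, M = G ⊙ P, so retained edges
carry their *signed* Pearson weight bit-exactly and spurious correlations
outside the sparse topology are removed. Sweeping λ over the dyadic grid
2⁻⁴, 2⁻³, …, 2⁵ yields d = 10 networks of non-increasing density (density
monotonicity in λ holds for the lasso path and is asserted in tests;
support *nesting* is not guaranteed and is not asserted).

**Hard-threshold alternative.** For comparison, proportional thresholding
discards the q% weakest |P| edges for q ∈ {10, …, 90, 99}, keeping exactly
⌊(1−q/100)·N(N−1)/2⌋ edge pairs, ties broken lexicographically for
determinism. q = 0 (keep everything) is allowed as the degenerate limit.

## Classifier

Each of the d networks feeds its own two-layer branch. The first layer
applies H = 64 kernels of shape 1×N across rows ("regional connectivity":
each ROI's profile of connections is mixed into H features, output N×1×H).
The second applies V = 32 kernels of shape N×1 across the ROI axis
("spatial integration", output 1×1×V). Cross-shaped kernels match the
semantics of a connectivity matrix, where a node's receptive field is a
full row/column, not a square neighborhood. Branch outputs are
concatenated (d·V = 320 features at defaults) and passed through dense
layers of 128 and 64 units and a 2-way softmax. ReLU follows both conv and
both dense layers (the stated he_normal initialization of the conv kernels
presumes a rectifier; the dense layers use the Glorot-uniform convention).
Dropout 0.2 follows the concatenation and the first dense layer, active
only in training. An L2 penalty (1e-5) applies to the convolution kernels
only. Training is mini-batch Adam (lr 0.001, batch 20) on cross-entropy for
a fixed 200 epochs with no early stopping; the validation split is used
only for hyperparameter selection. With d = 1 the identical architecture is
the single-sparsity variant.

The network is implemented directly in NumPy (float32 parameters, manual
backpropagation, seeded RNG for initialization, shuffling and dropout), so
a fixed seed reproduces training bit-for-bit and the whole ensemble runs
on one CPU. At these sizes (≤ a few million parameters) a framework would
add dependency weight without speed.

## Evaluation protocol

Stratified 5-fold outer cross-validation; a fully random equal split
cannot guarantee both classes in every fold at these cohort sizes, so
stratification is used deliberately. Per outer fold, the training portion
is split 5 times into internal-train (80%) and validation (20%), each split
re-randomized; a 5-fold CV on each internal-train set trains 5 base
classifiers — 25 per outer fold. When a hyperparameter grid is given, mean
validation accuracy selects the combination whose classifiers are retained;
by default only the published configuration is trained. The 25 classifiers
vote on the held-out fold (odd count — ties impossible, and even-count
plans are rejected). The whole procedure repeats 10 times; metrics (ACC,
SEN, SPE, BAC = (SEN+SPE)/2, PPV, F1, AUC) are reported as mean ± std over
repetitions, with class 1 (patients) positive. AUC uses the rank statistic
over the ensemble score, defined as the mean positive-class softmax
probability across the 25 voters (the score definition is a package choice;
only the vote is specified upstream). Zero-denominator ratios are reported
as NaN, never as 0.

## Occlusion mapping

Edge importance: for each unordered pair (i,j), entries (i,j) and (j,i) are
zeroed in all d networks of every subject's stack; the ensemble's mean
majority-vote test accuracy is recomputed using the stored fold structure
(test subjects only — train-set evaluation would be optimistic), and the
drop from the unoccluded accuracy is the edge's contribution (reported in
percentage points, averaged over folds and repetitions). Region importance
zeroes ROI n's whole row and column; the drop is transformed as
D_n = exp(ACC − ACC_masked,n) with accuracies as fractions and min-max
normalized to C_n ∈ [0,1]. If all drops are equal, C is undefined and
reported as zeros with a warning. Both analyses run in pure evaluation mode
(a parameter checksum is asserted unchanged).

Occlusion measures *necessity*: if the class signal is redundant across
several connections, or the ensemble is at its accuracy ceiling, removing
one edge changes nothing and all drops are zero. Validation studies must
therefore operate below saturation (see below).

## Synthetic cohorts

Two groups are drawn from zero-mean multivariate normals. A shared
Erdős–Rényi support (default density 0.1) with values of magnitude
0.15–0.35 and random sign defines baseline off-diagonal covariance; a
chosen set of edges differs between groups by a fixed effect size. Matrices
are forced positive definite by shrinking the baseline off-diagonal values,
and the group difference by shrinking the effect size, each with a warning
and the realized values recorded in the returned ground truth. In
*precision* mode the construction is applied to the inverse covariance and
inverted (rescaled to unit diagonal), making the sparse support a
conditional-dependence ground truth while marginal correlations spread
along paths — the right testbed for support recovery. Optional AR(1)
temporal filtering (x_t = φx_{t−1} + √(1−φ²)ε_t) adds autocorrelation
without changing the cross-sectional covariance; optional white measurement
noise attenuates all correlations by 1/(1+noise_sd²). Defaults mirror the
emulated cohort's shape (57 + 68 subjects, 120 ROIs, 140 time points).

What the generator does *not* emulate: hemodynamic convolution, scanner
drift and motion artifacts, spatial smoothness between neighboring parcels,
and non-Gaussian or non-stationary dynamics. Passing the synthetic studies
shows the machinery recovers planted linear-covariance structure; it does
not certify performance on real BOLD data.

## Validation studies (`smfcnet.studies`)

Problem sizes are chosen so each study runs in minutes on one CPU, with
training reduced to 40 epochs (the planted effects are strong and the loss
plateaus far earlier).

* **Recovery** — 40+40 subjects, 20 ROIs, L = 200, two planted edges of
  covariance effect 0.4 under unit measurement noise. Two edges, not more:
  occlusion attributes by necessity, so planting many redundant edges (or
  running noiselessly at a 100% accuracy ceiling) makes every single-edge
  drop exactly zero and the attribution question degenerate. At this
  operating point the ensemble scores ~95% and both planted edges lead the
  occlusion ranking by an order of magnitude. Checked: nested-CV accuracy
  > 80%; ≥ half the planted edges in the top-2m occlusion ranks.
* **Permutation** — same cohort, labels shuffled: accuracy must lie within
  a 3σ binomial band of the majority-class rate.
* **Support comparison** — single subjects with sparse *precision*
  structure (density 0.12). The WSR mask is taken at λ = 2⁻², the grid
  point whose recovered density matches the planted density (support F1 is
  only informative when the estimated support size is commensurate with
  the truth; at large λ both methods return near-empty graphs and tie).
  The density-matched hard threshold of |P| keeps exactly as many edges.
  Checked: guided F1 ≥ hard-threshold F1 in ≥ 80% of 20 seeded replicates
  (typical means: guided ≈ 0.85 vs hard ≈ 0.79).

## Numerical and degenerate-input choices

* Correlations are clipped to [−1,1] and symmetrized against accumulation
  error; the diagonal is set to exactly 1 (and exactly 0 after masking).
* λ_max behavior: for λ ≥ max|P_ji|/C_ji the soft-threshold kills every
  coefficient and W = 0 is returned exactly.
* Hard-threshold ties: lexicographic (i,j) order, so results are
  reproducible across platforms.
* Ensembles require an odd voter count; even counts are a contract
  violation, rejected at plan construction.
* Softmax is computed with the max-subtraction trick; probabilities sum to
  1 within 1e-6 (asserted in tests).
* ROI indices are 0-based internally and 1-based in reports, matching
  atlas convention.

## Known limitations

* The full-scale protocol (10 repetitions × 5 folds × 25 base networks at
  200 epochs on 120 ROIs) is a multi-hour single-CPU computation; the
  shipped studies validate the machinery at reduced size rather than
  reproduce cohort-scale numbers, which depend on restricted clinical data.
* Occlusion importance is relative to the trained ensemble and the
  evaluation set; it is not a statistical test of group difference.
* The WSR solver returns the exactly-sparse splitting variable; coefficients
  just above the support tolerance ε = 1e-5 depend on convergence settings,
  though the downstream mask is insensitive to this in practice.
* Inner-loop hyperparameter search defaults to the published configuration
  only; the original tuning grid is not specified and is therefore left to
  the user's config.
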