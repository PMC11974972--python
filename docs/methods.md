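# Methods

This note documents the models and procedures implemented in `msnbiotyper`,
the choices made where the construction was genuinely open, and what the
synthetic-data experiments do and do not demonstrate.

## Morphometric similarity networks

Each subject contributes, per parcel, a sample of regional morphometric
values. For a pair of parcels the two samples are turned into discrete
probability mass functions by Gaussian kernel density estimation (Silverman
bandwidth, zero-variance fallback of 1e-3 times the grid span) on a shared
grid of 2^7 = 128 points spanning the pooled range of the pair extended by
10% per side. The similarity is

KLS(p, q) = exp(−D(p, q)),  D = Σ p ln(p/q) + Σ q ln(q/p),

which maps the symmetric Kullback–Leibler divergence into (0, 1], with 1
for identical distributions. Densities are floored at 1e-12 before
renormalisation so D is finite and KLS strictly positive. Pairwise pooled
grids (rather than one global grid) guarantee both densities are
representable wherever either sample has mass; grid-resolution stability
(|KLS_128 − KLS_1024| < 0.02 on smooth densities) is asserted in the tests.

## Hubness over a sparsity grid

Similarity matrices are binarised at sparsities 0.10–0.34 in steps of 0.01
by keeping the floor(s·R(R−1)/2) strongest off-diagonal weights; ties break
by ascending (row, col) index so the graph is fully deterministic. Per
threshold we compute degree centrality, nodal efficiency (mean inverse
shortest-path length; unreachable pairs contribute 0), and the
participation coefficient against a greedy modularity partition
re-estimated per threshold (the partition scope per subject/threshold is a
documented choice; greedy agglomeration is deterministic for a given
graph). Each region-metric curve is reduced to its trapezoidal AUC, giving
threshold-free features. Binary rather than weighted graphs follow from the
degree definition as an edge count.

## Normative modelling

Per region-metric, controls are fitted with Bayesian linear regression on a
design of: cubic age B-spline (5 interior knots at training-age quantiles,
boundary knots extended by 0.5 years; the basis sums to one and doubles as
the intercept), one-hot sex, and one-hot site with the first site as
reference (site as fixed effects keeps the posterior conjugate). Responses
may be Yeo–Johnson transformed (maximum-likelihood lambda on training
controls, constant input falls back to identity) and optionally warped with
a two-parameter sinh–arcsinh output warp fitted by marginal-likelihood
ascent; the warp falls back to "none" when it does not improve the
marginal objective. Precisions are set by evidence maximisation (type-II
ML, via the standard conjugate solver); a fixed prior precision switches to
a closed-form ridge posterior.

Deviations are Z = (t(y) − predictive mean)/sqrt(predictive variance), the
predictive variance being the noise variance plus design-projected weight
uncertainty. Controls get cross-validated (10-fold, site-stratified) Z so
nobody is scored by a model trained on them; 90% of controls per site form
the training set otherwise, with all cases in the test set. Fit quality is
summarised by EV, SMSE (MSE relative to the squared deviation about the
training mean) and MSLL (relative to the trivial training-moment
Gaussian). Subjects with any |Z| > 7 can be excluded and models refitted
(`outlier_pass='post'`); the default is off because the synthetic data
contain no gross non-fitters.

Transfer to an unseen site holds the reference posterior fixed and
estimates a site mean offset (mean adaptation residual) and variance scale
(root mean of squared standardised residuals) in the transformed space;
the offset standard error reported is scale·sqrt(mean predictive
variance)/sqrt(n). Residual site information is audited with a 2-fold
linear SVM predicting site from deviation vectors (one-vs-one, mean
balanced accuracy; 0.5 = clean).

## Extreme deviations and permutation nulls

Extreme deviation = |Z| ≥ 2. Group maps hold the proportion of subjects
with suprathreshold positive or negative deviations per region-metric;
case minus control gives difference maps. Group permutation reassigns
labels (two-tailed, add-one rule p = (1+#{|null| ≥ |obs|})/(n_perm+1));
spatial permutation relocates the observed map with spin surrogates and
compares per-region magnitudes. BH-FDR families are the regions within
each metric, mirroring per-metric reporting. The fused deviation map
averages the three z-scored net (positive − negative) difference maps.

## Fusion (mCCA + joint ICA)

Modalities are the three deviation matrices, column-centred and unit-
standardised (standardisation is a documented switch). Component count by
the Wax–Kailath/Rissanen MDL on the eigenspectrum of the concatenated
*centred* data — per-column rescaling is deliberately not applied there
because it breaks the flat noise eigenspectrum the criterion assumes — or
fixed by the caller. mCCA maximises the SUMCOR objective (sum of pairwise
canonical-variate correlations) by block coordinate ascent after PCA
whitening, with deflation between components. The canonical maps are
concatenated along the region axis and unmixed with natural-gradient
Infomax ICA (logistic nonlinearity, annealed learning rate, seeded
restarts); sources are sign-fixed so each source's largest-magnitude
region is positive. Subject mixing coefficients are least-squares
projections onto the source maps. A component is joint group-
discriminative when Welch t-tests on its coefficients separate the groups
in all three modalities at p < .05.

## HYDRA biotyping

k linear hyperplanes are alternately refitted (soft-margin linear SVM per
facet: assigned cases positive, all controls negative) and cases
reassigned to the facet with the highest expression score w·x + b. Each
facet's classes carry total weight 1/2 each, making the per-facet risk
invariant to how the cases distribute over facets — without this
normalisation, near-degenerate splits can spuriously win on raw summed
risk. The polytope objective is the negated total of per-facet regularised
risks; an iteration that would worsen it is rejected and the loop stops,
so the recorded trace is non-decreasing by construction. Restarts: one
k-means++ initialisation on case projections onto the top-k principal axes
of case-minus-control-mean space plus random assignments; the best final
objective wins. Empty facets reseed from the case the current polytope
represents worst.

Model selection runs k = 2..4 through 10-fold stability: the ARI between
fold-pair trainings on the cases present in both training sets, averaged
over pairs; chosen_k maximises the mean. Significance comes from
pseudo-group permutations of the controls (matching the case:control
ratio) with the same stability statistic; robustness from stratified
split-half fitting with Hungarian matching of biotype mean-deviation
profiles. Transfer uses the stored weights/biases to compute expression
scores and argmax labels (ties to the lowest index).

## Spatial decoding

Spin surrogates rotate the cortical centroid cloud (uniform SO(3) rotation
for the left hemisphere, its mirror image for the right) and reassign
values by greedy nearest-centroid matching (closest pairs first), so each
surrogate is an exact permutation of the input that approximately
preserves autocorrelation. Subcortical parcels cannot ride a spherical
rotation and are permuted uniformly among themselves. Spearman rho against
each receptor map shares one surrogate set generated from the deviation
map; BH-FDR runs across maps. PLS1 (w ∝ X^T y on column-standardised
terms, sign-aligned to the response) is bootstrapped over regions —
the observation units of the spatial regression — giving Z = weight /
bootstrap SD per term; component significance refits against spin-rotated
responses.

## Synthetic cohorts: what they emulate, and what not

The generators emulate: smooth monotone age trends (random cubic
polynomials with a dominant linear coefficient) with sex offsets and
per-site offsets drawn from N(0, 0.5·noise_sd); heteroscedastic Gaussian
feature noise; block-structured regional means inducing modular MSNs;
planted case biotypes as region-specific shifts in control-SD units
(defaults in the conventional 1–3 SD range; the literature provides no
empirical effect-size scale for biotype separations); biotype-dependent
symptom scores on a 0–1 scale (truncated Gaussians); annotation maps as
Gaussian fields over parcel centroids with a squared-exponential kernel
(default length-scale 25 mm, the order of the inter-parcel spacing at
90-parcel resolution) mixed to a controlled population correlation with a
target map; and three-modality stacks sharing one spatial component whose
subject loadings shift by a chosen effect in cases.

They do not emulate: 3-D image geometry and scanner artifacts, non-
Gaussian feature noise, realistic parcel shapes or symmetric hemispheric
centroids, longitudinal structure, or diagnosis-covariate confounding.
Passing tests therefore demonstrate algorithmic correctness and
statistical calibration under the stated generative family, not
performance on real MRI cohorts.

All randomness flows through labelled child streams of one root seed
(`_rng.child_rng`), so every stage is bit-reproducible and independent
operations never share a stream.

## Numerical choices and problem sizes

- Density floor 1e-12; KLS grids 128 points, extended 10% per side.
- Edge counts floor()ed; index-order tie-breaks everywhere a tie is
  possible (thresholding, argmax assignment).
- Permutation p-values always use the add-one rule; the lower bound is
  1/(n_perm+1).
- Infomax: learning rate 0.01, halved on divergence, annealed by 0.7 every
  200 steps; convergence at relative weight change < 1e-7; up to 5
  seeded restarts.
- The greedy spin-assignment inner loop is JIT-compiled with numba when
  available (pure-Python fallback; identical output).
- Test and acceptance problem sizes are chosen at desk scale: the
  end-to-end pipeline runs 60 cases / 80 controls at 30 parcels; the
  calibration checks use 2000/500 controls; fusion and biotype recovery
  use 300/300 subjects at 90 parcels / 270 features; permutation type-I
  checks use 200 simulated datasets at 1000 permutations. The type-I
  check for the spatial test uses the 90-parcel scale because rank-based
  spin p-values are too granular on much coarser parcellations to observe
  the nominal rate.

## Known limitations

- The sinh–arcsinh warp is fitted by a derivative-free profile search and
  is best treated as a robustness option; calibration guarantees are
  stated for the Gaussian path.
- Greedy modularity maximisation has a resolution limit; PC values at the
  sparsest thresholds on fragmented graphs depend on the partition of
  small components.
- The alternating HYDRA scheme is a local optimiser; the stability
  machinery (restarts, CV-ARI, permutation null) is the guard against
  reading structure into noise, not a global-optimality proof.
- mCCA deflation removes variate directions modality-wise; with strongly
  correlated planted components the later components are not orthogonal
  in region space.
- Spin surrogates assume centroids on (roughly) a sphere; strongly
  non-spherical centroid clouds degrade the autocorrelation preservation.
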