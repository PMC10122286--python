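# Methods

This note documents the statistical machinery implemented in `myofibspat`:
the models and their assumptions, the defaults and why they were chosen,
what the synthetic-data generator does and does not emulate, and the
numerical choices that affect results.

## Data model

A *section* is a set of n fiber centroids (x_i, y_i) with categorical type
labels, n ≥ 3, no duplicate coordinates.  For two-type analyses the labels
are encoded as spins z_i ∈ {−1, +1} (slow = −1, fast = +1); the fast set is
always supplied explicitly by the user.  Coordinates are unitless, and all
statistics are invariant to translation, rotation and uniform scaling —
pruning thresholds, the boundary alpha and the GAM standardization are all
defined relative to the data's own scale.

## Neighbor network

Fibers are declared neighbors through the Delaunay triangulation of the
centroids, pruned in two ways:

1. **Length rule** — edges longer than Q3 + 1.5·IQR of the edge-length
   distribution are removed.  The Tukey fence is scale-free and removes the
   spurious long edges that the triangulation draws across concavities and
   along the convex hull; the factor is configurable and `None` disables
   the rule.
2. **Boundary rule** — edges whose midpoint falls outside the section
   boundary polygon are removed (with a relative tolerance of 1e−9 of the
   median edge length, so perimeter edges whose midpoints lie exactly on
   the boundary survive floating-point rotation).

The boundary polygon is an alpha shape: the union of Delaunay triangles
with circumradius below alpha, defaulting to 2× the median Delaunay edge
length, which tracks the fiber packing density.  Very small alphas
(fragmented shape, dropped centroids) fall back to the convex hull with a
warning.  The tessellation shown in section plots is the Voronoi diagram of
the centroids clipped to this boundary; cell areas are checked to tile the
polygon to 0.5%.

These choices reflect standard computational-geometry practice; published
per-section statistics depend on the exact pruning, so the configuration is
exposed (`PruneConfig`) and the validation suite checks the network against
a brute-force empty-circumcircle oracle rather than against any particular
published edge count.

## Summary tests

All three tests condition on the observed type counts; "random" always
means a uniformly random permutation of the labels over the fixed network
(nonfree sampling).

**Mean cluster size.**  A cluster is a connected component of the subgraph
induced by fibers of the target type (default: the less prevalent type).
The statistic is (number of target fibers)/(number of clusters), compared
against the 2.5th–97.5th percentiles of the same statistic over 999 random
relabelings (seedable; percentiles use linear interpolation).  Above the
envelope: like-type attraction; below: repulsion.  The classical guidance
that the statistic is reliable only when the target type is under 30% of
fibers is surfaced as a `reliability_flag`, not enforced.

**Unlike neighbor pairs.**  U counts edges joining unlike types.  Its exact
null moments follow from inclusion probabilities: with m edges, n_s slow
and n_f fast among n fibers,

    E[U] = 2·m·n_s·n_f / (n(n−1)),

and Var[U] comes from the three pair classes (same edge, edges sharing a
fiber — counted via Σ d_i(d_i−1)/2 — and disjoint edges) with their
hypergeometric both-unlike probabilities.  This is algebraically the
classical join-count randomization variance; the implementation is
validated against exhaustive enumeration over all graphs on ≤ 5 nodes and
random graphs on ≤ 8 nodes at every count split before use.  The test is
z = (U − E[U])/√Var[U] against the standard normal, two-sided; significant
negative z means like-type attraction.  The normal approximation is
excellent at section scale (m ≈ 4–5 k); the calibration suite confirms a
~5% type-I error and N(0,1) z distribution at n = 1600.

**Abnormally grouped fibers.**  For each target-type fiber, the number of
like-type neighbors L_i is compared with its null distribution given the
fiber's degree d_i: hypergeometric with mean d_i(n_t−1)/(n−1).  Fibers with
L_i > mean + 1 sd are marked; any like-type cluster containing at least two
marked, mutually adjacent fibers is flagged in full, and the statistic is
the flagged fraction of target fibers.  Defaults: analytic per-fiber null
(a pooled threshold and a permutation-estimated null are config
alternatives), min_marked = 2.  This is a descriptive statistic, not a
test: it rises steeply with the overall target-type proportion (the suite
demonstrates the monotone trend on randomly labeled sections), so only
sections with similar type proportions should be compared.

## Binary Markov random field

The joint model Pr(Z = z) ∝ exp{α Σ z_i + β Σ_{i∼j} z_i z_j} has an
intractable normalizing constant, so estimation maximizes the
pseudolikelihood Σ_i log Pr(Z_i = z_i | rest) with

    Pr(Z_i = z | rest) = exp{z(α + β S_i)} / (2 cosh(α + β S_i)),
    S_i = Σ_{j∼i} z_j.

This is exactly a logistic regression of (z_i+1)/2 on S_i with coefficients
(2α, 2β).  The fit is a dedicated two-parameter Newton iteration with step
halving, converging to a per-observation gradient norm below 1e−8·n (an
absolute 1e−8 sits below the float cancellation noise of the score sum at
n ≈ 1600); permutation loops use a plain-Newton fast path that falls back
to the safeguarded one.  Perfect separation (e.g. an exact chequerboard) is
detected as non-convergence and the estimates are capped at |10| with a
warning.  log(2 cosh t) is computed as |t| + log1p(e^{−2|t|}).

Significance of β is judged against the 2.5–97.5 percentile band of β̂ over
999 random relabelings with fixed counts.  Under randomness β̂ falls inside
its own envelope ≈95% of the time (checked at n = 1600, 200 replicates),
and Gibbs-simulated data with (α, β) = (−0.2, 0.06) — the magnitude regime
of real sections — is recovered with |bias| < (0.05, 0.02) over 200
replicates.  Pseudolikelihood is used instead of full-likelihood MCMC
because the interactions of interest are weak (|β| < 0.1), where it is
known to be nearly efficient, and because envelopes need ~10³ refits per
section.

The BMRF answers "is there like-type interaction, and how strong?" for the
section as a whole; it is interpretable at any type proportion but says
nothing about *where* in the section the pattern sits.

## Logistic GAM

The probability p_i that fiber i is fast is modeled through

    log(p_i/(1−p_i)) = β₀ + β₁x_i + β₂y_i + Σ_{k≥3} β_k b_k(x_i, y_i).

*Basis.*  Coordinates are centered and scaled by their root-mean-square
radius (conditioning of the radial kernel).  The b_k form a low-rank
thin-plate regression spline: K knots chosen by deterministic
farthest-point sampling, kernel η(r) = r² log r evaluated fiber-to-knot,
projected onto the orthocomplement of the affine polynomials at the knots
(Z with T_kᵀZ = 0).  The design is [1, x, y, E Z]; the penalty is zero on
the affine block and ZᵀE_kkZ (positive definite for distinct knots) on the
wiggly block, so the null space of the smoother is exactly the plane.
K = 3 degenerates to the plain GLM design.  Default K = min(30, n/4) + 3 —
large enough for the smooth, muscle-scale trends of interest, small enough
that a fit takes milliseconds.

*Fitting.*  Penalized IRLS maximizes ℓ(β) − (λ/2)βᵀSβ with Cholesky solves
and step halving; edf = tr{(XᵀWX + λS)⁻¹XᵀWX} ∈ [3, K], decreasing in λ.

*Smoothing selection.*  λ minimizes a Laplace-approximate REML criterion
(−ℓ_p(β̂) − (rank(S)/2)·log λ + ½ log|XᵀWX + λS|, constants dropped) over a
25-point log grid on [1e−4, 1e8] refined by golden-section search; GCV
(n·dev/(n−edf)²) is the alternative.  The search is deterministic; a
boundary minimum is returned with a warning — on trend-free sections the
criterion correctly drives λ to the upper boundary and the fit collapses to
the plane (edf → 3).  A fixed λ can be supplied for manual exploration.

*Prediction.*  The surface is the inverse logit of the linear predictor on
a regular grid masked to the boundary polygon.  The implementation is
cross-checked in the suite against an independent penalized-GAM
implementation (R mgcv with an isotropic 2-D smooth, REML) at the level of
fitted probabilities.

*Multinomial extension.*  For C ≥ 3 types, C−1 linear predictors against
the most frequent (reference) type share one basis under the softmax link;
each predictor gets its own λ, selected on its one-vs-rest binary fit, and
the coefficients are then jointly estimated by quasi-Newton maximization of
the penalized multinomial likelihood, started from the one-vs-rest fits.
With C = 2 the code delegates to the binary path, so the reduction to the
logistic GAM is exact.  Types with fewer than K/2 fibers trigger a basis
reduction; fewer than 10 fibers triggers an instability warning.  The GAM
deliberately never uses the neighbor network — smoothing alone localizes
information — which is enforced structurally: the module depends only on
the boundary polygon, for masking.

## Synthetic sections

`generate_lattice_section` places fibers on a unit-spacing grid with
uniform jitter (default 0.2 of the spacing), emulating the quasi-hexagonal
packing of real sections at the only level the statistics see: centroid
positions.  Default study scale is 40×40 = 1600 fibers, inside the
1,000–2,500 range of real soleus sections.  Labels come from either

* `simulate_bmrf_labels` — a Gibbs sampler that sweeps fibers in random
  order resampling z_i ~ σ(2α + 2βS_i); 500 sweeps default, far beyond the
  mixing time at the weak couplings of interest (|β| < 0.1; a warning fires
  for |β| > 1 where mixing deteriorates).  At β = 0 it reduces exactly to
  i.i.d. labeling with Pr(fast) = σ(2α), which the suite verifies by a
  pooled chi-square on neighbor-pair-type frequencies.  The default
  simulation conditions (α, β) = (−0.2, 0.06) reproduce a slow-majority
  section with weak like-type attraction, the regime reported for real
  soleus muscle.
* `simulate_surface_section` — independent labels from a smooth p(x, y)
  (constant, linear gradient, radial, or a user callable), the generating
  process of the logistic GAM.

Every generator is a pure function of its inputs and one integer seed.  Not
emulated: fiber morphology (areas, perimeters, shape anisotropy), the
fascicle substructure and edge effects of real sections, staining
ambiguity/hybrid fibers, and serial-section correlation.  Passing tests
therefore establish correctness of the estimators and calibration of the
tests under the stated models — not robustness to segmentation error or to
model misspecification in real tissue.

## Group comparison

`batch_fit` fits the BMRF per section from a (path, group) manifest;
`compare_group_params` compares the per-section α̂ or β̂ between two groups
with Welch's t test (pooled-variance optional) and a two-sided
Mann–Whitney U (exact for groups ≤ 20 without ties, normal approximation
with tie correction otherwise).  This is a pragmatic post-hoc comparison of
per-section estimates; a hierarchical joint model across sections is out of
scope.  The suite checks null calibration (~5% rejections for identical
generating parameters) and power (separated groups detected) rather than
any fixed cohort's p-values.

## Numerical and design notes

* Permutation envelopes: 999 permutations by default (199 minimum), 2.5/97.5
  percentiles with linear interpolation, one explicit seed per call, no
  global random state; results embed (n_perm, seed).
* Degenerate inputs: single-type sections, absent target types, edgeless
  networks and zero-variance null distributions raise typed errors (or
  warn and return the defined limit where one exists, e.g. proportion 0 on
  an edgeless network).
* Verdict conventions: attraction iff the statistic exceeds the upper
  envelope bound (strict), repulsion below the lower; join-count verdicts
  switch at two-sided p < 0.05.
* The mean-cluster-size permutation and the envelope machinery hold type
  counts fixed, making all tests conditional on composition.
* Coordinates from image software with y increasing downward are accepted
  as-is; every statistic is reflection-invariant.

## Problem sizes used in validation

Calibration and recovery runs use 40×40-fiber sections (the low end of real
soleus scale) with 199-permutation envelopes inside replicate loops and
999 permutations for single-section analyses; 500 replicates for test
calibration, 200 for envelope coverage and parameter recovery, 50 (tests) /
20 (acceptance script) replicates for GAM surface recovery at ~2000 fibers.
These sizes give Monte-Carlo standard errors comfortably inside the
asserted tolerance bands while keeping the full validation suite at desk
scale.

## Known limitations

* The BMRF assumes a single global interaction β over the whole section;
  anisotropic, distance-weighted or locally varying interactions are not
  modeled.
* Pseudolikelihood envelopes treat the network as fixed; uncertainty from
  segmentation and triangulation pruning is not propagated.
* GAM surfaces are reported without pointwise confidence bands.
* The abnormal-grouping statistic is intrinsically composition-dependent;
  it is provided for comparability with prior practice, with its caveats
  surfaced.
* Published per-section values from any particular study depend on that
  study's exact neighbor-pruning pipeline; with different pruning, small
  shifts in edge counts propagate to the join-count expectation and to β̂.
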