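# Methods

## Observer model

Each stimulus on the 7 × 7 design grid is represented as a bivariate
Gaussian in a latent color × material space. Conventions that fix the
units (not fittable): the target's mean position is the origin, and the
perceptual noise is zero-mean, independent across dimensions and trials,
with standard deviation 1 per dimension. Free parameters are the
color-material weight `w ∈ [0, 1]` and the positional mapping from
nominal levels (−3…+3) to mean positions, one mapping per dimension:

| variant   | form                          | params/dimension |
|-----------|-------------------------------|------------------|
| linear    | a₁s                           | 1                |
| quadratic | a₁s + a₂s²                    | 2                |
| cubic     | a₁s + a₂s² + a₃s³             | 3                |
| full      | one free position per level   | 6                |

No affine term: level 0 maps to position 0 in every variant. All
mappings are constrained so the 7 implied positions are strictly
increasing, lie within ±20 noise units, and adjacent levels are at least
0.25 apart (¼ noise SD). On a trial the observer draws noisy samples of
the target and both tests, forms per-dimension differences ΔC and ΔM
between each test draw and the target draw, scales them by w and 1 − w,
combines them with a Euclidean or city-block norm, and picks the test
with the smaller distance. Exact distance ties (measure-zero under
continuous noise) are broken 50/50 from the session RNG; any
deterministic rule would bias Monte-Carlo estimates.

## Choice-probability engine

P(choose test 1) given (w, p1, p2) has no closed form because the two
distances share the target draw and, for the Euclidean metric, are
correlated non-central quadratic forms. The engine therefore simulates
it: for the default table, 10 weights linearly spaced in [0, 1] crossed
with 20 positions linearly spaced in [−20, 20] on each of the four
position axes, 3000 simulated trials per cell. Queries between grid
nodes use tricubic B-spline interpolation (`scipy.ndimage`
`spline_filter` + `map_coordinates`, mirror boundary), which reproduces
node values exactly; interpolated probabilities are clipped to
[10⁻⁴, 1 − 10⁻⁴] before entering log-likelihoods because cubic
interpolation can overshoot [0, 1].

Construction uses common random numbers: one set of noise-draw triples
(target, test 1, test 2) is shared by every cell of a weight slice, and
each cell is symmetrized over the two stimulus orderings. Consequences:
the complement law P(p1, p2) + P(p2, p1) = 1 holds exactly; cells with
p1 = p2 are exactly ½; Monte-Carlo error is correlated across
neighboring cells (which smooths rather than roughens the interpolant);
and the build takes seconds instead of the hours that independent
per-cell streams would need. Rebuilding with the same seed is
bit-for-bit reproducible.

Known limitation: with 20 grid points the position spacing is ≈ 2.1
noise units. Where the choice probability changes over a comparable
scale — chiefly when both tests sit far from the origin at nearly equal
weighted distances — cubic interpolation on this grid can err by up to
~0.1 for the Euclidean metric (measured against 10⁶-draw direct
simulation; typical off-grid error is below 0.01). This is a property
of the fixed grid resolution, not of the build scheme. Fits are rarely
sensitive to it because such stimulus configurations are uninformative
and adaptively placed trials avoid them. A reduced preset (positions
step 4, 1000 trials/cell) exists for fast test pipelines and trades
additional interpolation bias for speed.

## Fitting

The likelihood of a parameter set is the product over trials of the
interpolated probability of the observed choice. Trials are first
aggregated to unique ordered stimulus pairs with binomial counts —
adaptive placement concentrates trials on few pairs, so this cuts an
objective evaluation to one vectorized interpolation over a few hundred
points. Optimization is multi-start L-BFGS-B (default 10 starts: weights
spread over 0.1–0.9, linear slopes over the adaptive procedure's 0.5–6
range) on a transformed scale:

* `w` on a logit scale, avoiding stalls at the 0/1 boundary;
* polynomial coefficients raw, with a smooth quadratic barrier (weight
  10⁶) on spacing/range violations over the 7 design levels, validated
  post hoc — constraints bind at the design levels only, since
  positions exist only there;
* the full variant as log gap increments above the minimum spacing, so
  monotonicity and spacing hold by construction.

Forward-difference gradients are computed in one batched objective call.
Convergence tolerance is 10⁻⁶ on the objective. If a polynomial
solution ends marginally outside the feasible set, it is re-polished
under explicit inequality constraints (SLSQP); reported solutions
satisfy the constraints to ~10⁻⁹, i.e. to float tolerance at an active
boundary. Degenerate data whose every pair has identical tests leave
the likelihood flat; the fit then returns w = 0.5 with minimal-spacing
positions and a non-identifiability flag rather than arbitrary output.

The weight/slope-ratio ridge: scaling one dimension's positions can be
compensated by the weight with little likelihood change, so single fits
wander along this ridge. Multi-start matters; the bootstrap quantifies
the remaining uncertainty.

## Model selection

8-fold cross-validation on one shared partition per dataset, reused
across all variants and metrics. Fold assignment permutes trials within
each source stream (full-range, restricted-range, random) and deals
them round-robin, so folds are balanced to ±1 trial and stratified by
source. Within each metric a ladder descends full → cubic → quadratic →
linear: the more complex variant survives only if the fold-paired
one-tailed t-test on held-out log-likelihoods is significant at 0.05.
Zero-variance fold differences degenerate the t statistic; a constant
positive difference counts as significant in its sign's favor, a zero
difference as non-significant (the test's limiting behavior). The two
ladder winners are compared by mean held-out log-likelihood — the higher
mean wins regardless of significance, exact ties preferring Euclidean
(the arbitrary convention used to drive the adaptive procedure) — and a
post-hoc two-tailed paired t-test is reported against α = 0.05/12
(Bonferroni across a 12-observer study). Fold fits warm-start from the
full-data fit of the same spec plus one default start.

## Adaptive trial placement

The adaptive procedure is QUEST+ over the cubic/Euclidean model with a
7-dimensional grid: per dimension, linear coefficient 0.5–6 (5 levels),
quadratic and cubic coefficients −0.3–0.3 (4 levels each); weight
0.05–0.95 (5 levels) — 32 000 raw combinations, filtered to those whose
implied positions satisfy the monotonicity/range/spacing constraints
(6480 with the default grid). The prior is uniform over valid
combinations (unstated in the source design; the standard QUEST+
default). Choice likelihoods per (combination, pair) are precomputed
into a matrix from the Euclidean lookup table and cached by content hash
(optionally on disk); restricted-range candidate sets reuse columns of
the full-range matrix. Each trial selects the pair minimizing expected
posterior entropy — computed with precomputed x·log x matrices so a
trial costs four matrix-vector products — with ties broken to the
lowest lexicographic pair index for deterministic replay. Posterior
updates are Bayes' rule with a 10⁻⁶ per-trial likelihood floor so
near-certain unexpected responses cannot zero the posterior.

## Session simulator

The default design is 8 blocks × 270 trials: per block, nine 30-trial
sub-blocks — six adaptive over the full ±3 range, one over ±2, one over
±1, one sampling pairs uniformly at random (without replacement within
the sub-block, with replacement across blocks). Trials run in groups of
9, one per sub-block, order randomized within each group. Each adaptive
sub-block keeps its own posterior, and states persist across blocks by
default (whether the original procedure reset between blocks is not
stated; persisting maximizes information and a config flag exposes the
reset variant). Responses come from fresh noisy draws through the
decision rule — the generative process itself — not from the lookup
table, so simulator and fitted model share no approximation.

What the simulator does not emulate: real observers' criterion drift,
lapses, sequential dependencies, or any color-material interaction —
the generating model is exactly the fitted model family. Passing
recovery tests therefore demonstrates that the pipeline can invert its
own generative process at experimental scale, not that the model is
true of human data.

## Analyses

*Bootstrap*: 100 iterations by default; each resamples N-of-N trials
with replacement (ignoring block structure, matching trial-level
resampling) and refits with starts = defaults + full-data solution; the
central 68% interval of the weights is reported. *Trade-off curves*:
for each color-match material level, the predicted probability the color
match beats each material match, computed at the 7 design levels (the
model defines positions only there). *Slope ratio*: ordinary
least-squares slope of position against nominal level per dimension,
color over material. *Recovery study*: simulate → select → fit (→
bootstrap) per generating observer, reporting generating vs recovered
parameters.

## Problem sizes and tolerances

Acceptance-scale runs use the full design: full-resolution tables, the
full 6480-combination adaptive grid and 2160 trials per observer. The
recovery tolerance is ±0.10 on the weight with rank order preserved
across the three observers (generating weights 0.16 / 0.52 / 0.85): the
ridge described above leaves individual weights recovered only to
roughly ±0.1 at this trial count, while their ordering is stable.
Module tests use the reduced table preset and a few-level coarse
adaptive grid; their tolerances are correspondingly wider and stated
inline.
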