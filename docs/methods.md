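# Methods

This note documents the statistical model behind `engagetraj`, the
design decisions taken where the method leaves choices open, what the
synthetic-data generator does and does not emulate, and the package's
known limitations.

## Data model and preprocessing

The unit of analysis is a participant's daily binary log-in series over
the 182 days (26 weeks) following randomization; day 0 is the
randomization date.  Multiple log-ins on one day collapse to a single
indicator, and events outside the half-open window [0, 182) are ignored.
Participants with no log-in at all are excluded before any modelling
(their count is reported): the analysis set is defined by at least one
use of the app, and an all-zero series carries no trajectory shape.

**Presmoothing window.**  The trailing 7-day moving average includes the
current day (days t−6..t) and shrinks at the series start (mean over
days 0..t for t < 6) instead of zero-padding.  A strictly preceding
window, or zero-padding, would systematically attenuate week-1 activity —
precisely the signal that distinguishes short-lived users — so the
inclusive, shrinking convention is used.  Window length is configurable;
7 days matches the weekly cadence of app-engagement behaviour.

## Functional PCA

FPCA is computed by eigendecomposition of the smoothed covariance
surface on the 182-point integer-day grid:

* **Covariance smoother.**  Local-linear smoothing with a Gaussian
  kernel, applied separably along each axis of the raw covariance
  (`S G Sᵀ`) — the standard fast realization of a 2D product-kernel
  smoother on a tensor grid.  Default bandwidth 7 days, the natural
  weekly scale of the data.  On rows where the local-linear normal
  equations degenerate (tiny bandwidths), the smoother falls back to the
  local-constant (Nadaraya–Watson) estimate; bandwidth 0 is the
  documented no-smoothing limit and reproduces plain PCA of the centered
  curves exactly, which the test suite exploits as an oracle.
* **Diagonal handling.**  The diagonal is *not* excluded when smoothing.
  Diagonal removal exists to dodge measurement-error inflation in
  sparse-design FPCA; here the daily noise is already absorbed by the
  7-day presmoothing, and the curves are dense and complete.
* **Quadrature.**  Trapezoidal weights on the unit-spaced grid.
  Eigenfunctions are unit-norm under the quadrature inner product, signs
  fixed so each eigenfunction's largest-magnitude element is positive.
* **PSD projection.**  The smoothed surface is symmetrized and negative
  eigenvalues are clipped to zero.
* **Component count.**  K = smallest number of components whose
  cumulative eigenvalue share reaches the variance threshold (default
  0.90).  Scores are direct numerical integrals of the centered curves
  against the eigenfunctions — appropriate for dense complete data; no
  conditional-expectation (PACE) scoring is provided.
* **Degenerate input** (fewer than two curves, or numerically identical
  curves) raises an error rather than returning a trivial model.

On the synthetic cohorts below, one component reaches 90% for the
three-group arm and up to eight are needed for the two-group arm; on
real trial data the same rule retained three to four components.  The
threshold, not the count, is the contract.

## Clustering and choice of k

* **PAM.**  BUILD initialization followed by best-improvement SWAP
  iterations, Euclidean dissimilarity on the retained FPC scores.
  BUILD+SWAP is only 1-swap optimal, so instances with at most 5000
  medoid subsets are solved exactly by enumeration — same contract,
  guaranteed optimum, and it makes the brute-force oracle tests a true
  identity rather than a heuristic claim.  Ties resolve to the lowest
  index throughout, so results are reproducible.
* **CLARA.**  Five subsamples of size min(n, 40 + 2k) (the classical
  recipe), incumbent medoids carried into subsequent subsamples,
  solutions scored by full-data dissimilarity.  With subsample size ≥ n
  it reduces exactly to PAM.
* **Distance.**  Unweighted Euclidean on scores.  Scores inherit the
  eigenvalue scale by construction, so no re-standardization is applied;
  an eigenvalue-weighted variant can be had by scaling scores before
  clustering.
* **Prediction strength.**  Ten random half-splits (seed-controlled).
  Per split, both halves are clustered; test points are classified by
  nearest train-half medoid; the statistic is the minimum over test
  clusters of the fraction of within-cluster point pairs kept together
  by that classification; ps(1) ≡ 1.  Computed on scores (the same
  representation the clustering uses).
* **Choice of k.**  Candidates must reach prediction strength ≥ 0.6 with
  every group ≥ 5% of the sample; the largest qualifying k is chosen,
  and a standardized separation diagnostic (minimum between-group mean
  distance over pooled within-group SD) is reported but not enforced.
  The default candidate set is k ∈ {2, 3}.  That narrow default is
  deliberate: for engagement data of this kind the prediction-strength
  criterion at threshold 0.6 does not by itself rule out splitting the
  large, dense low-engagement group (such splits replicate across
  half-splits with ps ≈ 0.65–0.8), so a wider search range promotes
  subdivisions of the disengaged mass that add no scientific structure.
  Restricting candidates to 2 and 3 mirrors how the original analyses of
  such cohorts proceeded; both bounds are configurable.
* **Naming.**  Group persistence = last week with mean weekly log-ins
  ≥ 1.0; groups are ordered by persistence (ties by total mean log-ins,
  then group index) and named "⟨persistence⟩-week users".  Two groups
  with identical persistence would share a name; ordering stays
  deterministic.

## Outcome and membership models

Logistic fits use the binomial GLM (IRLS) and multinomial fits the
baseline-category logit (Newton), both to a 1e-10 likelihood tolerance.
Inference is Wald: OR = exp(β), 95% CI = exp(β ± 1.96·SE); profile
likelihood is out of scope.  Designs are checked for rank (collinear
terms are named in the error) and for separation (|β| > 15 raises an
explicit error rather than returning a meaningless fit).

The outcome model forces the trajectory-group dummies (reference = least
persistent group) and selects covariates by univariate screening at
α = 0.05 followed by stepwise AIC in both directions, starting from the
forced-terms model; ties break by term name so the procedure is
deterministic.  Outcomes are analysed complete-case by default, with a
missing-coded-as-smoker sensitivity switch.  The membership model routes
to multinomial (k ≥ 3) or logistic (k = 2) automatically, with the same
screen-then-stepwise covariate path.  No multiple-testing correction is
applied across report rows.

## Synthetic cohorts

The generator plants archetype trajectory groups specified by 26 weekly
mean log-in counts, a mixture weight and an abstinence probability.  The
two presets encode the published arm descriptions: a three-group arm
(week-1 means 2.0 / 4.6 / 5.4, weights 610:303:156, abstinence
0.23/0.30/0.56) and a two-group arm (week-1 means 1.4 / 2.8, weights
695:369, abstinence 0.21/0.23).  Weekly means beyond the published
anchors decay geometrically (ratio 0.5) to a floor of 0.1, additionally
capped at 0.95 so "below one log-in day per week" stays strictly true in
every disengaged week; the published ranges for the persistent group
(5.4→5.0, 4.7→3.1, taper to 2.0 by week 17) are linearly interpolated.

**Sampling scheme.**  By default a participant's week-w log-in count is
⌊m_w⌋ + Bernoulli(m_w − ⌊m_w⌋) — exactly the planted mean in
expectation, with minimal week-to-week dispersion — and the log-in days
are placed on a fixed, evenly spaced weekday template for that count.
This encodes two modelling commitments: group members use the app with
week-to-week consistency, and the day-of-week pattern carries no
information (the published groups are described, and differ, only at the
weekly scale).  An alternative `binomial` scheme draws each day as an
independent Bernoulli(m_w/7), optionally with first-order day-to-day
persistence.  The balanced scheme is the default because independent
daily thinning makes individual trajectories so overdispersed that the
planted groups are no longer well separated in smoothed-trajectory
space — under it the two-group arm's planted split cannot be recovered
by any clustering method (its Bayes misclassification rate is ~20%) —
whereas the published groups are distinct, recoverable shapes.

Outcomes are Bernoulli with logit = logit(group abstinence probability)
plus optional covariate effects; covariates default to effect-free so
the planted group rates are exact marginals.  Outcome missingness is off
by default (a 12% missing-completely-at-random option mirrors typical
retention).  Cohorts are byte-reproducible from the seed.

**What passing tests do and do not show.**  The synthetic cohorts have
crisply separated groups, no within-group heterogeneity in engagement
propensity, no day-of-week or calendar effects, and
missing-completely-at-random outcomes at most.  Recovery of planted
structure under these conditions validates the pipeline's mechanics —
presmoothing, FPCA, k selection, medoid clustering, model fitting — not
its behaviour on real logs, where group boundaries are fuzzier, the
number of retained components is larger, and covariates genuinely
confound.

## Numerical choices and degenerate inputs

Likelihood convergence 1e-10 (100 iterations); eigenfunction
orthonormality and score centering hold to 1e-6; eigenvalues are clipped
at zero after PSD projection; AIC ties in stepwise selection break by
term name; all stochastic stages consume named integer seeds (children
derived via `SeedSequence`).  Empty k ranges, k > n, subsamples smaller
than k, unknown arm labels, unknown participants, unparseable
timestamps, all-zero eigenvalue spectra, all-event or no-event outcomes,
rank-deficient designs and separated fits each raise explicit errors.

## Problem sizes

The bundled analyses run at the published arm sizes (n = 1069 and
n = 1064, 182 days); a full simulate-cluster cycle takes on the order of
a second per arm, and the whole validation suite a few tens of seconds.

## Limitations

Dense complete daily grids only (no sparse/irregular FPCA); no
model-based functional clustering or alternative k-selection statistics
(silhouette/gap); no causal interpretation of group–outcome associations
(engagement is post-randomization behaviour, not an assigned exposure);
no session-level engagement measures (duration, page views); Wald
inference only.
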