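# engagetraj

Functional clustering of daily app log-in trajectories, and models linking
the resulting engagement groups to a binary 12-month smoking-abstinence
outcome.

Digital smoking-cessation trials record, for every participant, whether
the assigned app was opened at least once on each of the 182 days after
randomization.  `engagetraj` turns those binary series into data-driven
*trajectory groups* and asks two questions: do the groups differ in their
odds of quitting at 12 months, and which baseline characteristics predict
group membership?  The package is aimed at biostatisticians analysing
engagement logs from randomized digital-intervention trials, and ships a
synthetic-cohort generator so the entire pipeline can be exercised and
validated without access to trial data.

## Method

For participant *i* with daily indicators $Y_{i}(d)\in\{0,1\}$,
$d = 0,\dots,181$:

1. **Presmoothing.** $X_i(t) = \tfrac1{|W_t|}\sum_{d \in W_t} Y_i(d)$ with
   $W_t$ the trailing 7-day window $\{t-6,\dots,t\}$ (shrinking at the
   series start), giving a dense functional datum on $[0,1]$.
2. **FPCA by smoothed covariance.** The pooled covariance surface
   $G(s,t)$ is smoothed with a local-linear product-Gaussian kernel
   smoother (bandwidth 7 days), symmetrized, PSD-projected, and
   eigendecomposed under trapezoidal quadrature:
   $\int G(s,t)\,\phi_k(t)\,dt = \lambda_k \phi_k(s)$.  Each curve is
   summarized by its scores
   $\xi_{ik} = \int (X_i(t)-\mu(t))\,\phi_k(t)\,dt$ on the first $K$
   components, $K$ chosen so the eigenvalue share reaches 90%.
3. **Clustering.** Scores are clustered with CLARA (PAM on subsamples,
   scored on the full data).  The number of groups $k$ is chosen among
   candidates $k\in\{2,3\}$ by *prediction strength* (threshold 0.6) plus
   a minimum group size of 5% of the sample; the largest qualifying $k$
   wins.  Groups are named by engagement persistence — the last week in
   which the group's mean weekly log-in days stays $\ge 1$ ("1-week
   users", "4-week users", ...).
4. **Outcome models.**  Abstinence (30-day point prevalence at 12 months)
   is regressed on trajectory-group dummies (lowest-use group as
   reference) by maximum-likelihood logistic regression, with baseline
   covariates screened univariately ($\alpha=0.05$) and selected by
   stepwise AIC; odds ratios carry 95% Wald intervals.  Group membership
   itself is modelled by a baseline-category multinomial logit ($k\ge3$)
   or logistic model ($k=2$).

The synthetic generator plants archetype trajectory groups with the
published mean weekly log-in profiles, mixture weights and group-specific
abstinence probabilities, so pipeline output can be compared against a
known truth.

## Worked example

```bash
engagetraj simulate --preset icanquit-like --n 1069 --seed 1 --outdir cohort/
engagetraj cluster  --indir cohort/ --outdir clusters/ --seed 2
```

prints

```
1069 participants retained, 0 excluded (zero log-ins)
k=3 prediction_strength=0.992
  1-week users: n=609 (56.97%)
  4-week users: n=297 (27.78%)
  26-week users: n=163 (15.25%)
```

i.e. the pipeline recovered three trajectory groups: 57% of the cohort
effectively stops using the app after the first week, 28% disengages over
about four weeks, and 15% keeps logging in about twice a week through
month six.  The association step then quantifies how abstinence differs
across those groups:

```bash
engagetraj associate --indir cohort/ --clusterdir clusters/ --outdir models/ \
    --covariates age,female,minority,hs_or_less,heavy_smoker
```

writes a Table-style CSV for this synthetic cohort (planted abstinence
23% / 30% / 56%):

```
                term  odds_ratio  ci_low  ci_high  p_value
           Intercept       0.624   0.382    1.021    0.060
 group[4-week users]       1.030   0.747    1.420    0.856
group[26-week users]       3.982   2.770    5.724    0.000
                 age       0.983   0.971    0.995    0.007
```

The 26-week-user interval comfortably covers the closed-form value
implied by the planted rates,
$0.56\cdot0.77/(0.44\cdot0.23)\approx4.26$ (here `age` happened to pass
the univariate screen on a covariate-effect-free cohort, as a 5% screen
will).  `engagetraj report-figures` plots the group mean weekly log-in
curves.

Every command is deterministic given its `--seed`, and all outputs carry
the configuration hash in a header comment.

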