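# Methods

This note documents the models behind `coashift`, the choices made
where the methodology was genuinely open, what the synthetic-data
generator does and does not emulate, and the numerical conventions a
user should know before trusting or extending the results.

## Centre-of-abundance estimation

The annual centre of abundance is a ratio estimator: stratum centroid
coordinates weighted by stratum abundance indices, one axis at a time.
Its uncertainty comes entirely from the posterior uncertainty of the
indices, which we receive as 95% bounds and convert to SDs under a
normal approximation, `sd = (hi − lo)/3.92`.

Propagation is first-order Taylor throughout, with three modelling
commitments:

* **Stratum posteriors are treated as independent.** The upstream
  hierarchical survey models induce cross-stratum correlation that
  their published outputs do not expose; ignoring it will typically
  understate COA variance somewhat. This is a stated limitation, not a
  fixable bug at this interface.
* **Years with all-zero indices are dropped**, not imputed; the OLS
  slope needs no balanced panel. Dropped years are logged and reported
  in the results object.
* **Latitude–longitude covariance is ignored** when the two axis
  trends combine into a displacement; the axes are estimated
  separately and combined by the Pythagorean identity with
  `Var(d) = (a²Var(a) + b²Var(b))/d²`. At `d = 0` the gradient is
  undefined and the conservative `√(Var(a)+Var(b))` is returned.

Degrees convert to metres at 111,320 m/deg; longitude is additionally
scaled by `cos(latitude)` evaluated at the species' mean annual COA
latitude. A config switch (`degree_to_metre`) offers a fixed reference
latitude (equirectangular) variant and a no-correction variant for
sensitivity checks; whether one converts each axis to metres before or
after combining is immaterial because the latitude factor is constant
within a species.

The single-stratum case is a useful sanity anchor: the COA equals that
centroid with zero variance regardless of index uncertainty, because
the ratio's gradient vanishes there.

## Cohort-timing classification

The question is whether hatch-year (HY) and after-hatch-year (AHY)
birds pass through latitudes on the same schedule. Banding latitude is
regressed on Julian day per age class with a penalized cubic B-spline
(10 basis functions, curvature penalty). The smoothing parameter
minimises the GCV score `n·RSS/(n − edf)²`, profiled in closed form
through one generalized eigendecomposition per fit and a 57-point log
grid of penalties — mathematically the standard GCV-selected penalized
regression spline, implemented directly on statsmodels' B-spline basis
so that a full species fit costs milliseconds rather than seconds.
Exact equivalence with any particular thin-plate implementation is not
claimed and not needed: the tests assert recovery of the generating
curve, not coefficient identity.

The autumn window is detected automatically (the original procedure
was visual and hence not reproducible): the longest contiguous run of
days on which the pooled curve declines faster than ε = 0.005°/day,
required to fall at least δ = 2° in total; a manual window can be
supplied in the config. Because the automated window keeps the flat
pre- and post-migration plateaus at its edges, the overlap index for
strongly separated cohorts floors around ~0.55–0.6 rather than
approaching 0; this is inconsequential for classification against the
0.85 threshold but worth knowing when interpreting raw index values.

Overlap is `∫min(f̂_HY, f̂_AHY) / ∫max(·,·)` after min–max normalising
each curve on the window. The integrals are exact for the
piecewise-linear curves: the day grid is refined with every crossing
point before the trapezoid rule is applied. The index is symmetric and
invariant to affine transformations of either raw curve. The
alternative normalisation `∫min / mean(∫f̂_A, ∫f̂_B)` is available
behind `overlap_form` for sensitivity. Classification uses a strict
`>` at the threshold (0.85 itself is age-separated), and day-of-year
wraparound (migrations spanning the new year) is not handled.

Sample-size floors — 1,000 records per species, 30 per age class
inside the window — return an `insufficient_data` result rather than
raising, and such species are excluded from the refined-flocking model
pool while remaining in the binary-flocking pool.

## Trait models

The response is each species' displacement (m/yr) with its propagated
SE; predictors are the standard migratory/demographic trait set,
Z-scored (sample SD, n−1) once before any filtering, plus treatment-
coded factors with "solo" as the flocking reference so class
coefficients read directly as increments over solo migrants.

**Residual covariance.** `V = σ²C + diag(se²)`, with `C` the Brownian
correlation from the consensus tree (`C_ij` = shared root-to-MRCA path
length; unit diagonal after scaling; non-ultrametric trees are scaled
by per-tip depths with a warning). This additive measurement-error
form is the standard reading of reciprocal-SE-weighted phylogenetic
regression; a pure fixed-weights variant (`V ∝ diag(se²)`) is provided
as a config alternative.

**σ² estimation: REML for inference, ML for selection.** The profile
over σ² is a bounded 1-D optimisation on log σ². With a design of ~12
covariates that are themselves phylogenetically structured, the plain
ML profile is badly biased low — the covariates absorb precisely the
deep-branch components that carry most of the Brownian variance, and
simulation at n = 81 shows σ̂² at roughly half its true value with a
~25% false-positive rate for the flocking term. The restricted
likelihood removes this bias (simulated false-positive rate ~5–7%,
coverage ~95%), so `PGLS.fit()` defaults to REML. REML likelihoods are
not comparable across different fixed-effect sets, so every candidate
fit inside the AICc model-averaging sweep uses ML (`method="ml"`), the
standard convention for information-theoretic selection.

**Selection and averaging.** VIF screening (`1/(1−R²)` by ordinary
regression of each design column on the rest) removes the worst
offender above 5 stepwise, ties broken toward the later column, factor
dummy blocks removed whole. All subsets of the filtered predictors are
enumerated (intercept always included, factors as blocks, a 2²⁰
tractability cap), subsets with fewer than 10 species per predictor
column are excluded, and models within 2 AICc units of the best are
averaged. `AICc = −2logL + 2k + 2k(k+1)/(n−k−1)` with k counting
coefficients plus σ². Averaging is full (zero-substituted) by default
with the revised unconditional SE `Σ w_i √(se_i² + (β_i − β̄)²)`;
conditional averaging is available. CIs use the normal 1.96 multiplier
(the t correction is negligible at n ≥ 81 and is deliberately not
applied); p-values, where shown, are z-based.

## The synthetic-data generator

The generator reproduces the statistical structure each stage consumes,
with every planted quantity recorded in a ground-truth JSON:

* **Survey indices**: an isotropic Gaussian abundance surface (SD 3°)
  on a 10×10 grid of abstract strata spanning 35° of latitude, its
  centre drifting at the planted velocity and its mass following the
  planted trend; stratum medians get multiplicative lognormal noise
  (log-SD 0.1) and 95% bounds at `exp(±1.96·0.1)`, so the claimed
  posterior SD matches the realised noise and coverage statements are
  meaningful. The geometry keeps the surface ≥4 SD inside the grid for
  the 50-year window — edge truncation otherwise biases the recovered
  drift low.
* **Banding records**: observation days uniform over the year; each
  bird's latitude declines sigmoidally (transit width 8 days) from 48°
  to 32° around an individual passage midpoint drawn from
  `N(class mean, 10 d)`, HY shifted by the planted separation (40 days
  for age-separated species in full-study mode), plus 1.5° noise.
* **Traits**: continuous covariates are Brownian on a depth-1 Yule
  tree, mapped to field-realistic positive scales; the flocking class
  evolves by a symmetric 3-state Markov process (rate 1.5 per unit
  depth), producing the phylogenetic clumping the PGLS must confront;
  the true shift is baseline (500) + class effect (defaults 2,660 /
  800 / 0 m/yr, the magnitudes the motivating study reports) + optional
  covariate effects + a Brownian deviation (SD 1,000 m/yr), observed
  with a lognormal per-species SE (median 800 m/yr, log-SD 0.4).
* **Full-study mode** (`simulate_study`): the planted per-species true
  shift becomes the drift speed of that species' abundance surface in
  a random compass direction (floored at a small positive value, since
  displacement is a magnitude), and banding separations follow the
  planted class — so the survey, banding and trait files are mutually
  consistent and the whole pipeline can be validated against one
  ground truth.

What the generator does **not** emulate: observer effort and
detectability, spatial correlation between stratum posteriors,
non-Gaussian/multimodal range shapes, range fragmentation, spring
migration, sex-structured timing, and real survey stratum geometry.
Passing tests therefore demonstrate correctness of the estimators
under the stated generative assumptions, not robustness to every
pathology of real survey data — most notably, the coverage results
inherit the independence assumption noted above.

## Problem sizes and determinism

The standard validation studies (shared by the test suite and
`scripts/acceptance.py`) use: 21 Monte-Carlo oracle instances at 10⁵
draws; 200 drift-recovery replicates at 50 years × 100 strata; 100
synthetic species per cohort-separation condition; 500 Brownian
calibration replicates at 50 tips; 200 null and 200 power replicates
at the 81-species pool; and one full-pipeline study at 40 species —
sizes chosen so the whole battery completes in about a minute on one
core while keeping binomial noise on the calibration rates near one
percentage point. Every generator and experiment is deterministic
given its seed; replicate sub-seeds are drawn from a single
`numpy.random.default_rng(seed)` stream.

## Known limitations

* Independence of stratum posteriors and of the two axis trends
  (above) — propagated SEs are approximate lower bounds.
* The Taylor linearisation degrades when stratum CVs grow large
  (≳30%) or indices concentrate near zero; the 2% Monte-Carlo
  agreement is established for the moderate-CV regime survey
  posteriors occupy.
* Automated window detection can differ from expert visual windows
  for species with multimodal or longitudinal migrations; the config
  accepts a manual window per run.
* Candidate enumeration is exhaustive and exponential in predictor
  blocks; beyond 20 blocks the driver refuses rather than subsample.
* The consensus tree is taken as known; posterior tree uncertainty is
  out of scope.
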