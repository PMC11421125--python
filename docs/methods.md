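# Methods

`movestate` implements a behavioral-change analysis for GPS-collared
ungulates: movement segmentation into two latent behavioral states,
state-specific habitat selection at the step scale, and two-step population
inference relating individual selection coefficients to experience proxies
(previous-season calf fate and female age), together with an in-season
calf-survival model. This note documents the models, the numerical choices,
and what the synthetic-data generator does and does not emulate.

## Movement segmentation (two-state HMM)

Steps are straight-line segments between consecutive fixes at a nominal
3-hour interval. Each step carries a length `l` (m) and a turning angle
`phi` (radians, counterclockwise positive, wrapped to (-pi, pi]), the signed
change in bearing relative to the previous step; `phi` is undefined at the
start of each contiguous segment.

Emissions per state:

* step length: zero-inflated gamma — an atom `zero_mass` at exactly 0 m
  (stationary fixes) mixed with a gamma density, parameterized by mean and
  SD (shape = (mean/sd)^2, scale = sd^2/mean). The atom is a probability
  mass, so the likelihood mixes masses and densities; this is unproblematic
  because the comparison set at l = 0 is identical across states.
* turning angle: von Mises(mu, kappa). Undefined angles contribute the
  length factor only.

The latent state follows a first-order Markov chain with transition matrix
`Gamma`; the initial distribution is tied to the stationary distribution of
`Gamma` (standard for long tracks; saves one parameter). The likelihood is
the product of scaled-forward likelihoods over all contiguous segments,
pooled across animals with one shared parameter set (a single
population-level segmentation; the alternative — per-animal HMMs — would
leave short tracks with poorly identified transition probabilities).

Fitting maximizes the pooled forward log-likelihood directly (L-BFGS-B on
working scales: log for positive parameters, logit for probabilities,
unconstrained-then-wrapped for the von Mises mean), rather than EM; this
handles the zero-mass mixture cleanly. Convergence: relative log-likelihood
tolerance 1e-8, at most 500 iterations; non-convergence is flagged and the
best iterate returned. Starting values: restricted state mean 100 m (SD
100 m, zero mass 0.001, turning-angle mean pi, concentration 0.001);
exploratory state mean 450 m (SD 450 m, zero mass 0.001, angle mean 0.1,
concentration 0.99). The zero mass is estimated, not fixed. After fitting,
states are relabeled in ascending order of gamma mean (index 0 =
restricted), and the Viterbi algorithm assigns each step its most probable
state per segment, with ties broken toward the restricted state.

## State-specific habitat selection (iSSF)

Data are split by individual-year and decoded state. Per slice:

1. **Tentative distributions.** A gamma is fitted by ML to `l + 1` m — the
   1-m offset keeps exact-zero steps inside the gamma support — and a von
   Mises concentration (mean fixed at 0) to the defined turning angles via
   A1(kappa) = mean(cos phi). Slices with fewer than 30 steps, or with
   degenerate (constant or near-constant) lengths, are excluded and counted.
2. **Available steps.** Each used step with a defined previous bearing
   becomes a stratum: 25 alternative steps are drawn from the tentative
   gamma (minus the 1-m offset, floored at 0) and von Mises (turn around the
   previous bearing). Off-raster endpoints are redrawn up to 20 times, then
   the stratum is dropped with a log entry.
3. **Covariates.** Distance to forest, to human settlements, and to roads
   are extracted at the end of each used and available step
   (nearest-cell semantics, 25-m grid) and z-scored per individual-year over
   used and available endpoints jointly (sample SD). Per individual-year —
   not per individual pooled across years — because the models are fitted
   per individual-year and the covariate scale must match the model's data
   slice.
4. **Conditional logistic regression.** The design has 15 terms: the 3
   habitat covariates, each interacted with night and with the high- and
   low-hunting-pressure levels (day and the pre-season period are reference
   levels; main factor effects are absorbed by the stratum), plus the
   movement terms `l`, `ln(l + 1)`, `cos(phi)` (never standardized). The
   stratified likelihood sum_s [eta_used - log sum_26 exp(eta)] is maximized
   by Newton-Raphson with step-halving (tolerance 1e-8 relative); SEs come
   from the inverse observed information. All-zero columns within a slice
   are dropped as inestimable. Coefficients exceeding |beta| > 15 on the
   standardized scale indicate quasi-separation; such fits are flagged and
   excluded from the second stage. Separation arises when a covariate is
   nearly constant within strata (short restricted-state steps on a smooth
   distance field carry little within-stratum contrast), which is a genuine
   identifiability property of the design, most visible in small slices.

Temporal factors: *hunting pressure* has three calendar levels — none
(Aug 1 until the day before the season opener, the second Monday of
October), high (the opener plus 21 calendar days), and low (thereafter
through Dec 31). *Time of day* is day iff the geometric solar elevation at
the step's end time is >= 0 degrees, computed with the NOAA solar-position
algorithm at the study latitude (about 57 N).

## Two-step population inference

Each converged slice contributes one coefficient record (estimate, SE) per
estimable habitat term, annotated with the female's previous-season calf
fate and age. For each of the 24 coefficient sets (3 covariates x {main,
x night, x high, x low} x 2 states), four candidate models are fitted with
inverse-variance weights 1/SE^2:

| model | formula |
|---|---|
| null | y ~ 1 |
| age | y ~ age |
| calf fate | y ~ calf fate |
| full | y ~ calf fate x age |

AICc uses the weighted-Gaussian log-likelihood with weights treated as known
precisions and the residual variance profiled at its MLE; the parameter
count includes the residual variance. The same convention applies to all
four candidates, so delta-AICc is internally consistent. Models with
delta-AICc < 2 (strict) form the retained set and are combined by
conditional (natural) averaging with renormalized Akaike weights; averaged
SEs use the unconditional-variance formula. Predictors appearing in no
retained model are reported as "n.i.".

A predictor is counted as *improving model performance* when the best
candidate containing it is retained and has lower AICc than the best
candidate without it. Retained-set membership alone is not used for this
statistic: adding a useless parameter costs only ~2.1 AICc, so under a null
cohort it stays within the delta-AICc < 2 band roughly half the time, which
would report systematic false inclusion.

**Movement.** Per slice, the selection-updated expected step length is

    l_mean = (k + beta_ln(l)) / (1/theta - beta_l),

the mean of the tentative gamma with shape updated by the ln-length
coefficient and rate updated by the length coefficient. (`k` is the shape
and `theta` the scale of the tentative gamma; only this reading makes the
expression the updated-gamma mean.) The update is undefined when the
updated rate or shape is not positive; such slices are excluded with a log
entry. The response delta = l_mean - observed mean step length is modeled
per state with the same four candidates as ordinary (unweighted) linear
models; the selected model is the AICc-best, with the full retained set kept
for inspection.

## Cohort analyses

*Calf fate vs age*: two-sided Mann-Whitney U (U reported for the loss
group), exact when both samples are tie-free and C(n1+n2, n1) <= 2e5 —
enumerability, not the product n1*n2, bounds the exact computation — else
the tie-corrected normal approximation.

*In-season calf survival*: binomial GLM (logit link) of survived_all (1 =
no calf lost in the ongoing season, also for twin litters) on age, litter
size before the season (numeric 1/2), and their interaction. Complete
separation raises an error. Note that females contributing several years
are treated as independent rows, replicating the source design.

## Synthetic-data generator

The generator is the test bed: every parameter is known.

* **Landscape** (10 x 10 km, 25-m cells by default): forest as 8 random
  rectangular patches, roads as 6 straight lines crossing the extent,
  settlements as 12 small blocks — feature densities chosen to resemble
  rural southern Sweden, where some forest edge and road is within a few
  hundred meters of most points. Each covariate raster is the exact
  Euclidean center-to-center distance to the nearest feature cell.
* **Tracks**: fixes every 3 h; the latent state switches by a Markov chain
  with 0.95 self-transition per state (mean bout ~2.5 days, consistent with
  multi-day foraging/relocation bouts at this sampling rate and with
  reliable decodability of the two states). Each realized step is selected
  among 50 candidate steps drawn from the current state's emissions, with
  probability proportional to exp(beta . covariates at the endpoint); with
  beta = 0 realized steps are exact emission draws. Candidates are
  reflected at the landscape boundary (counted). Start rules: a single
  Aug-1 burst, or three bursts placed in the three hunting-pressure periods
  so short tracks still populate all calendar levels.
* **Cohort**: entry ages uniform on 3-12 incrementing yearly, twin
  probability 0.4, previous-season calf fate an independent fair coin
  (deliberately uncorrelated with age), and in-season survival Bernoulli
  with logit p = 2.5 - 0.062 age - 2.502 n_calves + 0.232 age x n_calves —
  slope magnitudes at the scale the survival model is meant to detect, with
  the intercept set for realistic (~60-90%) survival.
* **Stratum-level selection** (`simulate_selection_strata`): the clean
  generative counterpart of the conditional logistic model — 26 candidates
  per stratum from known tentative distributions, used step chosen by
  exp(beta . z-scored covariates) — used for estimator recovery and
  calibration studies, where track-level simulation would make the true
  coefficient scale depend on each slice's z-scoring.

Not emulated: home-range confinement (tracks are free-roaming with boundary
reflection), serial autocorrelation of behavior beyond the first-order
chain, habitat-dependent state switching, real road-network or settlement
geometry, and observation error in fixes. Passing tests therefore
demonstrate estimator correctness under the model's own assumptions, not
robustness to their violation in field data.

## Problem sizes and determinism

Validation runs use 128 individual-years (64 females x 2 years) with 300
fixes per individual-year in three bursts — large enough that every slice
clears its 30-stratum minimum and the structural counts (256 first-stage
models, 24 candidate-model sets) are exercised end to end — plus 20,000
steps for HMM parameter recovery, 50 replicate slices for iSSF recovery,
200 for null calibration, and 1e6 draws for the step-length-formula check.
All randomness flows from explicit seeds through `numpy.random.Generator`;
rerunning any stage with the same configuration and seed reproduces
byte-identical outputs.

## Known limitations

* The pooled HMM assumes all animals share emission and transition
  parameters; strong individual heterogeneity would bias the segmentation.
* Quasi-separated slices are excluded rather than penalized (no Firth-type
  correction); at small per-slice sample sizes this loses a few slices.
* Conditional-logistic MLEs carry O(1/n_strata) small-sample bias, visible
  in the movement terms of small slices.
* The weighted-Gaussian AICc treats the first-stage SEs as known, ignoring
  their estimation error, as is standard in two-step inverse-variance
  approaches.
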