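# Methods

This note records the modelling choices, default parameters, numerical
conventions and known limitations behind `heatqtl`. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The multi-environment mixed model

The baseline model for a plot-level trait across t environments is

y = Xτ + Zu + Z_g u_g + e,

* **Fixed (Xτ):** one mean per environment plus one level per
  (check variety, environment). Check varieties (parents and local
  controls) are fully replicated and treated as fixed; DH lines never
  appear in X.
* **Genetic (Z_g u_g):** u_g is environment-major of length r·t with
  covariance Δ ⊗ I_r. Δ is factor-analytic, Δ = ΛΛᵀ + Ψ, with the upper
  triangle of Λ's first k rows pinned at zero for rotational
  identifiability. The default FA order is k = 1 for t ≤ 4 and k = 2 for
  t ≥ 5 (a single genetic variance when t = 1); diagonal and unstructured
  (Cholesky-parameterised) forms are also available.
* **Random design terms (Zu):** optional independent row, column or
  replicate-block effects per environment, one variance each. They default
  to *off* in `build_design`: the synthetic trials plant no extraneous
  polynomial trends, and boundary-zero variance components only degrade
  convergence diagnostics. Real-data users should switch them on.
* **Residual (e):** independent between environments; within environment j,
  N(0, σ²_j · AR1(ρ_col) ⊗ AR1(ρ_row)) over the column-major plot grid.
  Incomplete grids (dropped plots) use the dense principal submatrix.

### REML estimation

Variance parameters are estimated by damped average-information (AI) REML:

* Likelihood, solves and log-determinants go through the Woodbury identity
  on C = Σ⁻¹ + ZᵀR⁻¹Z. R⁻¹ is applied through the small per-axis AR1
  factors (closed-form tridiagonal inverses), never as a dense plot × plot
  matrix on complete grids. For the scan's pair Δ_a ⊗ G + Δ_p ⊗ I the
  inverse of the genetic covariance is taken in the eigenbasis of G
  (t × t blocks per eigenvalue).
* The AI step solves (AI + λ·diag AI)δ = score; λ grows tenfold on any
  step that leaves the parameter domain or decreases the likelihood and
  shrinks by 3 on success — a Levenberg-style fallback in place of
  explicit EM steps, chosen because it is monotone and domain-safe for
  every structure at once.
* **Bounds and the active set.** Variances are floored at
  1e-8 × var(y) (never exactly zero, keeping every covariance invertible);
  autocorrelations are clipped to |ρ| ≤ 0.98. A parameter sitting on its
  bound with an outward-pointing gradient is frozen out of the AI system
  for that iteration; without this, boundary components (e.g. a marker-based
  additive variance whose truth is zero) stall the optimiser for dozens of
  iterations.
* **Starting values** are moment-based: per-environment residual variances
  from duplicate-plot differences of the p-rep design
  (Var(y₁ − y₂) ≈ 2σ²), and the across-environment genetic covariance from
  line-by-environment means (leading principal components seed Λ).
* Convergence: relative log-likelihood change below `tol` (default 1e-8
  for baseline fits, 1e-5 inside the scan) with a stabilised step.
  Fixed-effect SEs come from (XᵀV⁻¹X)⁻¹; variance-parameter SEs from the
  inverse AI matrix.

The engine's log-likelihood and analytic scores are verified in the test
suite against dense direct evaluation and numerical differentiation.

## Genome scan

Two runs per trait: the performance run tests a fixed across-environment
marker effect a_ij; the responsiveness run replaces the regressor with the
plotwise product of a climatic covariate and the marker score, so b_ij is a
trait response per covariate unit. Both runs guard against polygenic
confounding with u_a ~ N(0, Δ_a ⊗ G₋ᵢ) (leave-one-chromosome-out genomic
relationship, avoiding proximal contamination) and u_p ~ N(0, Δ_p ⊗ I).

* **Δ_p follows the baseline FA-order rule.** It must carry the
  cross-environment genetic covariance: a marker effect constant over
  environments is exactly collinear with that covariance, and replacing
  Δ_p by a diagonal inflated the measured genome-wide null false-positive
  rate from ≈0.05 to ≈0.37 in this package's calibration scenario.
* **Δ_a is diagonal.** Its truth sits at or near zero under the generator
  (line-level G×E deviations are not marker-based), and a factor-analytic
  surface at the zero boundary is a saddle. The relationship kernel gets a
  ridge of 1e-8 × mean diagonal so rank-deficient GRMs stay invertible;
  no marker-count scaling is applied to G = MMᵀ (the variance component
  absorbs scale).
* **Variance-parameter economy.** By default variance parameters are
  re-estimated once per chromosome under the null and held fixed across
  that chromosome's markers (`vc_mode="chromosome"`); each marker then
  costs two projections. `"global"` estimates them once genome-wide (used
  by the large recovery studies below), `"per_marker"` refits REML at
  every marker. Warm starts chain chromosome to chromosome.
* **Covariates enter raw (uncentred).** With only the interaction term in
  the model, centring the covariate changes the regressor by a multiple of
  the marker main effect and biases b̂ under the generative model; the
  raw-scale regressor keeps the planted-effect estimate unbiased. The
  reported normalised effect (b̂ × covariate range) is invariant to
  rescaling of the covariate either way.
* **Thresholding.** Per chromosome, eigenvalues λ of the interval-marker
  correlation matrix contribute 1(λ ≥ 1) + (λ − ⌊λ⌋) to the effective test
  count; chromosome counts are summed genome-wide (the per-chromosome-sum
  convention), the per-test level is 1 − (1 − α)^(1/M_eff) with α = 0.05
  per run, and the Wald threshold is the χ²(1) quantile. Eigenvalues are
  rounded to 8 decimals first: an eigenvalue a hair below an integer (a
  duplicated marker's pair {2, 0}) must not contribute a spurious
  fractional part.
* **Pruning:** markers above threshold are visited most-significant first;
  ties break to the lower cM position; each kept marker suppresses
  same-chromosome markers within 30 cM. The final joint model excludes
  interval markers within 30 cM of any selected marker from the genomic
  term (if that empties the map, the genomic term is dropped with a
  warning and the polygenic term carries the background). Collinear
  selected regressors are resolved by dropping the weaker scan signal.
* **LOD** is reported as Wald / (2 ln 10), the 1-df χ²–LOD correspondence.

## Marker preparation

* Encoding: AA → +1, BB → −1, missing preserved (DH material, no
  heterozygotes).
* Imputation: a missing score becomes its conditional expectation under the
  two-state no-interference DH chain given the nearest observed flanking
  markers, with Haldane recombination fractions θ(d) = ½(1 − e^(−2d/100));
  a single observed flank gives x(1 − 2θ). Verified against exhaustive
  enumeration of gamete haplotypes.
* Markers identical in both position and score vector collapse to one
  representative (first in map order; idempotent).
* Interval markers score the mean of the two flanking unique-position
  markers at the interval midpoint. Chromosome-terminal markers are carried
  through as their own scan columns so chromosome ends stay scannable;
  column metadata retains flank names so an alternative interval algebra
  can be swapped in.
* Map summaries divide total genetic length by the unique-position count
  (the convention that reproduces all five published mean intervals at
  one-decimal precision).

## Degree-day phenology

Daily mean = (tmin + tmax)/2, base temperature 0 °C, cumulative from the
sowing date (0 °Cd on the sowing day itself). Anthesis per line ×
environment is the first day reaching the line's thermal target
(spike-emergence °Cd plus an offset, default 100 °Cd — a config parameter,
as its field value is not recoverable). Windows: anthesis = −300 to
+100 °Cd around anthesis; grain fill = +100 to +600 °Cd. Boundary
convention: a window includes the first day its opening threshold is
reached and ends the day before its closing threshold is reached; day
counts use strict thresholds (> 30.0, > 35.0 °C). Growing-season rainfall
sums 1 May – 31 Oct and is environment-level.

## The synthetic-trial generator

What it emulates: biparental DH genotypes on a multi-chromosome linkage
map (Haldane model, no interference — chosen for its closed-form oracle);
partially replicated designs where every line is sown once per environment
plus one duplicate in a uniformly chosen environment of its year (mean
replication 4/3) and checks are fully replicated, grids padded to
completeness with filler check plots; daily min/max weather with a
sinusoidal seasonal mean, diurnal range, Gaussian noise and Poisson
heatwave runs that raise the maximum; plot values = environment mean
+ planted QTL terms + line-by-environment deviations with covariance
ΛΛᵀ + Ψ + AR1 × AR1 spatial residuals. Duplicate plots share their line's
genetic value; checks carry fixed effects only.

What it does not emulate: segregation distortion, heterozygosity or
selection during DH production; year-to-year removal of extreme maturity
types; marker-based polygenic background (G×E deviations are drawn
independently per line, so the scan's additive kernel term is truly null);
multi-trait correlations; sub-daily temperature structure (all covariates
are daily summaries, for which daily min/max is sufficient). Passing tests
therefore demonstrate correctness of the machinery and calibration under
this generative model — not robustness to, e.g., phenology mis-estimation
or non-Gaussian field effects in real trials.

## Validation scenarios and problem sizes

Defined in `heatqtl.validation` and used by both the test suite and
`scripts/acceptance.py`:

* **Calibration:** 150 lines × 3 environments (one year), 3 chromosomes ×
  120 cM × 40 markers, no QTL; per-environment genetic variance ≈ 0.31
  with cross-environment correlations ≈ 0.8, spatial σ² = 0.3,
  ρ_row = 0.35, ρ_col = 0.25. The genome-wide false-positive rate of the
  thresholded performance scan is measured over 200 simulations in the
  test suite (100 in the acceptance script).
* **Recovery:** 400 lines × 6 environments (two years); planted
  performance QTL of 0.4 phenotypic SD and responsiveness QTL whose
  range-normalised effect is 0.35 SD on an anthesis-average-maximum
  covariate spanning ≈ 4.8 °C across environments (19.5–24.3 °C, the
  spread of contrasting field seasons) plus 0.3 °C line-level noise.
  Detection = a pruned significant marker within 15 cM of the planted
  position with the planted sign. The test suite runs 16 replicates (the
  acceptance script 8) with the 90% detection requirement widened by two
  binomial standard errors for the reduced count; scans use
  `vc_mode="global"`, whose Wald statistics differ from the per-chromosome
  default only through second-order variance-parameter differences.

## Known limitations

* Wald tests treat estimated variance parameters as known (no
  Kenward–Roger-type small-sample correction); calibration is demonstrated
  at r ≥ 150, not for very small populations.
* The FA likelihood surface can hold local optima; moment-based starts and
  damping make fits reproducible, but pathological datasets may need
  user-supplied starting values.
* One trait and one population per analysis (populations are analysed
  separately); no epistasis, no multi-covariate joint responsiveness
  model, no physical-position annotation.
* `per_marker` variance re-estimation is provided but is orders of
  magnitude slower and is not exercised at scale in the test suite.
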