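# Methods

This note documents the statistical model, the synthetic-data generators,
the numerical choices, and the known limitations of `qgmix`.

## Outcome model and mixture summary

The outcome is binary (self-reported autoimmune skin disease).  With
exposures `X` (n × 17) coded into octiles `X^q` (integer codes 0–7) and
covariates `Z` (smoking history, age in years, male sex, parental
rheumatoid arthritis, other autoimmune disease; household income > $30k
only in sensitivity runs), the conditional model is the logistic GLM

    logit P(Y_i = 1 | X^q, Z) = β₀ + Σ_j β_j X^q_ij + Σ_k α_k Z_ik .

The residual term sometimes written alongside such models has no separate
role in a Bernoulli GLM; it is realized here as the Bernoulli sampling
noise of the outcome draw.

The mixture is summarized three ways:

* **Conditional ψ** = Σ_j β_j, the log odds ratio for raising every
  exposure by one octile simultaneously, holding covariates fixed.  This
  identity is exact by construction and asserted to machine precision.
* **Signed weights** w_j = β_j / Σ(β over same-sign components).
  Positive weights sum to +1 and negative weights to −1 whenever both
  signs occur; components with β_j = 0 get weight 0, and weights are
  undefined (NaN) if every β_j is exactly 0.
* **Marginal ψ** from the g-formula: for each level j ∈ {0,…,q−1} every
  mixture code is set to j (covariates untouched), each subject's outcome
  probability is predicted from the fitted model, and the pooled n·q
  counterfactual records are fit with the marginal structural model
  logit E[Y^j] = m₀ + ψ_marginal · j by maximizing the Bernoulli
  quasi-likelihood with the predicted probabilities as fractional
  outcomes.  Under the logistic link ψ_marginal ≠ ψ_conditional in
  general (non-collapsibility); an identity-link variant of both stages
  is provided, under which the two agree exactly and which serves as a
  structural test.  If all counterfactual probabilities coincide (a null
  mixture with no covariates) the MSM slope is returned as exactly zero
  rather than fit from a degenerate regression.

## Quantization

Each column is centered to zero mean (this cannot change the codes but
mirrors the standardization step of the motivating analysis) and cut at
its empirical quantiles at probabilities k/q, k = 1..q−1, using linear
interpolation of order statistics (`numpy.quantile`'s default).
Duplicate breakpoints — routine for zero-inflated point-source burdens —
are collapsed and counted; a value's code is the number of distinct
breakpoints strictly below it, so ties share the lowest applicable code
and heavily tied columns occupy fewer than q codes.  Constant columns
yield all-zero codes with a logged warning.  Codes are invariant to any
positive-slope affine transform of a column (property-tested).

## Model fitting

Maximum likelihood by Newton/IRLS written from first principles:
convergence when the maximum absolute score falls below 1e-8 or the
relative log-likelihood change falls below 1e-10, within 100 iterations;
step-halving keeps the iteration monotone; the covariance is the inverse
observed information.  Quasi-complete separation is reported as an
explicit error naming the diverging columns, detected as fitted
probabilities within 1e-10 of 0/1 together with coefficients beyond ±15
log-odds.  Fractional outcomes in [0, 1] are accepted (Bernoulli
quasi-likelihood), which the MSM stage uses.  The fit is verified in
tests against the closed-form 2×2 log odds ratio (to 1e-8), an
independent BFGS optimizer, and statsmodels' GLM.

## Bootstrap inference

Nonparametric bootstrap over subjects (default B = 1000, matching the
motivating analysis).  Octile breakpoints are re-estimated on every
resample by default, because quantization is part of the estimator; a
reuse-original-breaks switch exists for diagnostics.  The percentile
interval is primary; a normal-approximation interval and a p-value
2·Φ(−|ψ̂/SE_boot|) from the bootstrap SE are reported alongside (the
motivating analysis does not state its CI flavor, so both are emitted).
Resamples whose refit fails (separation in a resample is the usual cause)
are skipped and counted; more than 1% failures aborts inference with
diagnostics.  A 200-simulation study at n = 1000, B = 200 (sizes chosen
to keep the default validation suite fast) checks that the 95% percentile
CI covers a planted null within ±4 percentage points; simulations that
trip the >1% guard produce no interval and are tallied separately rather
than entering the coverage denominator.

## Exposure construction

All coordinates are planar projected kilometres (the buffer and decay
operations presuppose a metric plane; geodetic transformations are out of
scope).  Operations, all deterministic:

* **Nearest-centroid linkage** (tract-level pollutants): Euclidean
  nearest centroid via a k-d tree, with exact ties re-resolved in favor
  of the lowest centroid id; equality with a brute-force scan is tested.
* **Raster extraction** (gridded pollutants): the cell containing the
  point under half-open [edge, next-edge) membership in both axes, so a
  point on an interior edge belongs to the higher-index cell.  Points
  outside the extent are flagged missing and logged.
* **Multi-year mean** over 2000–2015, excluding missing years with a
  logged count; all-missing rows propagate as missing.
* **Decayed point-source burden**: Σ_j C₀j · exp(−3 d_ij / a_r) over
  sources of the chemical within the buffer radius r_b (default 5 km).
  The decay range a_r is not stated in the motivating analysis; the
  default a_r = r_b = 5 km leaves the kernel at e⁻³ ≈ 5% at the buffer
  edge, making the truncation nearly immaterial.  Sources beyond the
  buffer contribute nothing even though the kernel is positive there.
  Source masses are per-source mean annual releases over the years
  present in the source table (the generator emits explicit zeros for
  inactive years within 2000–2016); whether the original analysis
  averaged before or after decay weighting is unstated, so
  averaging-first is the documented choice.  The four BTEX chemicals are
  kept as separate columns, not pooled.
* **Road density**: total length of each segment's exact geometric
  intersection with the 5 km disc, computed analytically from the
  circle–segment intersection (for a chord at perpendicular offset h the
  clipped length is 2√(r² − h²)).  The result is invariant to
  subdividing segments into collinear pieces; tests cross-check against
  shapely's polygon clipping.

Assembly into the canonical 17-column matrix fails hard on any missing
value, listing the offending participant ids; explicit opt-in dropping
(with a logged count) is available, because silent exclusion would bias
the analyzed n.

## Synthetic cohort generator

Defaults reproduce the published cohort characteristics: n = 9060, age
mean 42.42 (SD 15.84), 67.1% female, 39.5% smoking history, 7.6% parental
rheumatoid arthritis, 73.4% income > $30k, 12.5% outcome prevalence.
Choices where the published tables are silent:

* **Age** is drawn from a normal truncated below at 18 years (the cohort
  is adult-recruited; the floor is configurable).  The pre-truncation
  location is solved by root-finding so that the *truncated* mean equals
  the target — a plain location shift would violate the floor.  The
  realized SD is consequently smaller than the printed 15.84 (≈13.5);
  the mean is the calibrated quantity.
* **Indicators** are independent Bernoulli draws at the printed
  marginals.  No joint demographic structure is claimed; an explicit
  correlation hook is deliberately absent from the defaults.
* **Other autoimmune disease**: the published table reports 35.5% with
  *any* autoimmune disease including the 12.5% outcome; the marginal of
  the "any other autoimmune disease" covariate is not printed.  The
  default 0.30 sits between the disjoint-overlap lower bound (0.23) and
  0.355.
* **Home coordinates** come from a mixture density on a 400 × 300 km
  domain: 60% clustered (SD 15 km) around five urban centers, 40%
  uniform — emulating a mostly-one-state cohort concentrated in urban
  corridors.
* **Outcome**: Bernoulli draws from the logistic model on the octile
  scale.  Planted coefficient presets take each β_j and α_k to the
  natural log of its published odds ratio (the per-octile
  interpretation), or spread ln(published mixture OR)/17 uniformly; the
  intercept is then calibrated by monotone root-finding so the mean
  predicted probability over the realized design equals the target
  prevalence to 1e-6.
* **A published inconsistency**: the printed pm10 odds ratio (0.999) and
  its printed signed weight (−0.1322) cannot both be right — the weight
  implies an OR near 0.989, and with that correction all 17 recomputed
  weights agree with the printed weight column to within rounding and
  the coefficient sum returns to within rounding of the printed mixture
  OR.  The per-component preset therefore plants the corrected value;
  both the verbatim and corrected sets are kept in `qgmix.reference`.

## Synthetic landscape generator

The spatial route emulates the *kinds* of inputs the real analysis
consumed, not their physics:

* **Pollutant surfaces** are Gaussian-smoothed white-noise fields
  (autocorrelation scale 25 km, cell 10 km), cross-correlated by mixing
  shared latent fields through the Cholesky factor of a declared
  inter-pollutant correlation matrix (species block 0.5, criteria block
  0.4, BTEX block 0.6, traffic-linked cross terms 0.3–0.35, baseline
  0.15).  Per-year surfaces share a common base field plus a 20%-SD
  yearly perturbation scaled so the 2000–2015 mean surface carries the
  target SD.  Surfaces are clipped at zero.
* **Calibration**: the published exposure summary describes the cohort
  cross-section, so each pollutant's multi-year mean is affinely
  rescaled against a residential-density-weighted reference sample to
  hit the printed mean/SD; BTEX source masses (Eq.-linear) are rescaled
  so the reference-density mean burden matches the printed mean; road
  segments are selected by cumulative per-segment contribution until the
  reference mean road density matches.  Cohort-sampled column means then
  match the printed values to within a few percent.
* **Point sources** follow a homogeneous Poisson process (0.02 sites/km²,
  each site releasing a given chemical with probability 0.85) with
  log-normal base masses (log-SD 1.0), bounded active-year windows, and
  20% yearly jitter; burdens are zero-inflated (~25–30% of residential
  locations see no source within 5 km).  The printed BTEX SDs
  (coefficient of variation ≈ 6–12) reflect real-world source clustering
  that a homogeneous process cannot reproduce while keeping cohort means
  stable; the generator prioritizes means, and burden SDs are emergent
  (CV ≈ 2).  The same applies to road-density SD.  The fast *direct*
  sampler (Gaussian copula, zero-inflated log-normal BTEX at 45% zeros,
  log-normal road density) does match the printed SDs exactly in
  expectation and is the route used for replicated statistical
  experiments, where the spatial machinery itself is not under study.
* **Centroids** (tract-style) are sampled from the same residential
  density and carry the criteria-pollutant field values.

What passing tests therefore show: the estimator recovers planted truth
under realistic marginals, correlation, zero-inflation and spatial
structure.  What they do not show: fidelity to real atmospheric
chemistry, transport, emission trends, or the joint demographic
structure of any real cohort.

## Pipeline and reproducibility

A single master seed spawns named substreams (covariates, exposures,
outcome, bootstrap), so each stage is independently reproducible and runs
are byte-identical under a fixed seed.  Every report embeds a SHA-256
hash of the canonical config.  The full spatial route is the default for
pipeline runs; `exposure_mode="direct"` selects the distributional
sampler.  Validation protocols use 100 replicate cohorts of n = 9060 for
parameter recovery (the rarest covariate's per-replicate log-OR sampling
SE is ≈0.12, so replicate averaging is what pins the means down) and a
200 × B=200 coverage study at n = 1000; these sizes are the package's
validation design, chosen to make Monte-Carlo error small relative to
the tolerances they are compared against.

## Known limitations

* No interaction or nonlinear mixture terms; exposures are time-fixed.
* Planted coefficients live on the octile scale; they are not
  comparable to per-µg/m³ effects.
* The landscape generator's variograms, emission trends, and BTEX/road
  dispersion are stylized (see above); the exact distance metric and
  pre/post-decay averaging of the original analysis are unstated and
  were fixed by documented choice.
* Percentile and normal bootstrap intervals can differ at small n; the
  percentile interval is primary.
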