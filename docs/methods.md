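# Methods

## Scope and model

`batchsw` computes the design variance and power of the treatment-effect
estimator in batched stepped wedge cluster randomized trials, under two
analysis families, and verifies both by simulation.

**Linear mixed model.** Outcomes follow
`Y_bkti = β_bt + θ X_bkt + α_bkt + ε_bkti` with batch-specific fixed
period effects β_bt, a treatment effect θ shared across batches,
correlated cluster-period random effects α and iid residuals ε.  The
within-cluster correlation structure is set by var(α_bkt) = σ²_α and
cov(α_bkt, α_bks) = r_ts σ²_α with

| structure | r_ts (t ≠ s) |
|---|---|
| `hussey_hughes` | 1 |
| `nested_exchangeable` | r |
| `discrete_decay` | r^\|t−s\| |

Because time enters only through batch-specific period effects, "period"
means time-on-trial (1…T within each batch); the calendar alignment of
batches is recorded for layout but has no effect on any variance.  This
is the source of the package's central property: **power is robust to
delays between batches**, which both the closed forms and the simulation
subsystem demonstrate.

**Marginal (GEE) model.** For binary or count outcomes,
`g(μ_bkti) = β_bt + θ X_bkt` with link g ∈ {logit, identity, log} and
variance function v(μ) ∈ {μ(1−μ), μ, constant}.  The model-based
variance of θ̂ for a batch is the Schur complement of the
quasi-information Σ_k D_kᵀ W_k⁻¹ D_k, with W_k built from v(μ) and a
working correlation (within-period ρ, between-period r_ts ρ).  Here the
variance depends on the assumed control-mean trajectory of each batch,
so the robustness-to-delay property holds exactly only when the control
prevalence is constant over time; with secular trends, per-batch
prevalences must be supplied and the per-batch variances combined.

**Batch combination.** In both families, with separate period effects
per batch the GLS/GEE estimator is a precision-weighted combination of
per-batch estimators: var(θ̂) = (Σ_b 1/var_b)⁻¹.  For B identical
components with C_b clusters per sequence this equals var₀ / Σ_b C_b,
i.e. a single component with the pooled number of clusters per sequence.

## Exactness of the cluster-period-mean reduction

All closed-form computations operate on cluster-period means, which is
exact, not an approximation:

* linear model: the mean of a cell has covariance
  V[t,s] = σ²_α r_ts + 1{t=s} σ²_ε/m, and profiling the period effects
  out of the GLS information reproduces the full individual-level GLS
  variance (the package ships a brute-force individual-level oracle,
  `gls_oracle`, and the test suite checks agreement to 1e−8 relative on
  designs up to 200 observations, including incomplete designs and
  non-identical batches);
* marginal model: m exchangeable individuals per cell average to
  cov(Ȳ_t, Ȳ_s) = v_t(1 + (m−1)ρ)/m on the diagonal and
  √(v_t v_s) ρ r_ts off it.  With the identity link and a constant
  variance function this reduces algebraically to the linear GLS
  variance, which the tests verify across structures.

Unobserved cells (incomplete designs) are first-class: the affected rows
and columns of V and of the design matrix are deleted per sequence —
complete-cell analysis, no imputation.

## Parameters and conventions

* **ICC conventions.** `from_icc_cac` splits a total variance
  (σ²_α = ρσ², σ²_ε = (1−ρ)σ²; σ² defaults to 1 so a continuous effect
  is standardized).  `binary_as_linear` instead fixes
  σ²_ε = p(1−p) at the control prevalence and back-solves
  σ²_α = ρσ²_ε/(1−ρ).  At ρ ≤ 0.05 the two differ negligibly; the
  worked-example reproduction uses `binary_as_linear`.  Both are exposed
  because both circulate in practice.
* **Power conversion.** Two-sided normal approximation with known
  variance, power = Φ(|θ|/√var − z_{1−α/2}), α = 0.05 by default.  No
  small-sample degrees-of-freedom correction is applied; the theoretical
  power is a property of the design variance alone.
* **GEE period-effect parameterization.** `gee_var_batch` accepts
  `categorical` (default; one nuisance coefficient per within-batch
  period — the assumption-lean choice recommended for batched designs),
  `linear` (intercept + slope in period) and `none` (intercept only).
  The choice matters: with a flat 28% prevalence on the worked example,
  the power is 79.8% with categorical period effects and 98.8% with
  none.  `none` is appropriate only when the control prevalence is
  genuinely constant; the worked example's constant-prevalence scenario
  is computed this way, matching how that scenario is conventionally
  calculated, while the declining-prevalence scenario uses the
  categorical default.
* **Overlap.** Defined as the number of shared calendar periods between
  consecutive batches (0 = disjoint, T = fully aligned for equal-length
  components); the start offset of the next batch is T − overlap.  Power
  routines warn that overlap is ignored, by design.

## Simulation subsystem

**Continuous generator.** Per replicate: β_bt ~ N(0, 1) independently
for every batch-period (so the analysis cannot borrow time trends across
batches), α_bk ~ MVN(0, σ²_α R) per cluster, ε iid.  Defaults mirror a
two-batch, 6-period, 4-clusters-per-sequence, m = 10 configuration with
ρ ∈ {0.01, 0.05, 0.1}, r ∈ {1, 0.95, 0.75} and θ ∈ {0, 0.15}.

**Binary generator.** The conditional linear family for exchangeable
within-cluster correlation: observations are drawn sequentially with
conditional success probability
λ_j = μ_j + b_jᵀ(y_{1:j−1} − μ_{1:j−1}),
b_j = Σ_{1:j−1,1:j−1}⁻¹ σ_{1:j−1,j}, which reproduces the marginal
means and pairwise correlations exactly.  Feasibility (every λ_j in
[0,1] for every binary history) is checked sharply before any draw and
violations raise an error naming the bound; exchangeable correlation
only (cac = 1) — decaying structures are out of the generator's scope.
The control prevalence trajectory is 0.4 + 0.01·t in within-batch period
t, with a risk-difference effect (default grid 0 and 0.025) added in
intervention cells; feasible ICCs are small (ρ = 0.5 is rejected at
these means, ρ ≤ 0.2 accepted).

**Analysis models.** Continuous data are analyzed by a REML linear
mixed model with batch-specific categorical period effects, the
treatment indicator, and random cluster and cluster-period effects.  The
fit operates on cluster-period means with a random cluster intercept:
the cluster-period effect and the averaged residual are not separately
identified from means, but only their sum enters the covariance of the
means, so inference on θ is unchanged while fitting is roughly two
orders of magnitude faster.  The optimizer falls through a retry ladder
(default → L-BFGS → Powell) because the default method stalls near the
variance boundary when the ICC is small.  Binary data are analyzed by
GEE with logit link, exchangeable working correlation, batch-specific
intercepts and batch-specific *linear* period terms, and the robust
(sandwich) variance — deliberately a different time parameterization
than the continuous analysis, mirroring how such trials are analyzed in
practice.  Replicates that fail to converge are counted and excluded;
a cell with more than 10% failures is flagged unreliable.

**Theoretical companions.** Continuous cells use the linear GLS power.
Binary cells use the marginal-model variance with the identity link and
binomial variance function (the generating model is additive on the risk
scale) and batch-specific linear period effects to mirror the analysis
model.

**Determinism.** Every replicate's generator is seeded from
(seed, replicate index, cell fingerprint), where the fingerprint hashes
the design (including calendar layout), variance components and effect.
Any cell or single replicate is therefore reproducible in isolation, and
distinct overlap values receive independent streams — so the empirical
overlap-robustness check compares genuinely independent Monte-Carlo
estimates rather than re-fits of identical data (with batch-specific
period effects, re-using one stream across overlaps would reproduce the
same datasets bit for bit and the comparison would be vacuous).

**Problem sizes.** The packaged checks run each simulation cell at 200
replicates (Monte-Carlo SE ≈ 3.5 points near 50% power, ≈ 1.5 points
near the 5% level), a scale chosen so the full suite runs comfortably on
a laptop; the generator and grid runner default to 1000 replicates
(MC SE ≈ ±1.3 points at 80% power) for production use.

## What the simulations do and do not show

The generators implement the assumed models exactly: equal cluster-period
sizes, no missing data beyond designed incompleteness, normal random
effects, exchangeable binary correlation, and treatment effects constant
across batches and periods.  Passing calibration checks therefore
validates the variance algebra and the estimation pipeline, not
robustness to model misspecification (unequal cluster sizes, open/closed
cohort sampling, treatment-effect heterogeneity, decaying correlation in
binary data are all out of scope).  One real-data caveat carries over:
variance components used for a batched design should be *within-batch*
(conditional on batch effects); an ICC estimated without a batch term
will typically be larger, and no deflation is attempted here.

## Numerical notes

* Estimability is detected via the Schur complement of the treatment
  information; designs whose treatment indicator is confounded with the
  period effects (for example a schematic with no observed control cell)
  raise an inestimable-design error, and the individual-level oracle
  names aliased columns via an SVD of the information matrix.
* Covariance matrices are checked for positive definiteness; the
  smallest eigenvalue is reported when the check fails.
* A tiny ridge (1e−12) stabilizes the Cholesky factor of σ²_α R in the
  continuous generator when σ²_α = 0.
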