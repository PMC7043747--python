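# Methods

## The problem

In a two-arm trial with a time-to-event endpoint, the population-average
hazard ratio can hide clinically meaningful heterogeneity: some covariate
profiles benefit from the experimental arm while others do not.  `credsurv`
estimates, with an explicit multiplicity guarantee, *which covariate profiles
benefit*.  Its output is a pair of subgroups (D, S) over a grid of predictive
covariate points z such that, with posterior probability at least 1 − α
*jointly over the whole grid*,

    D ⊆ B ⊆ S,

where B is the true benefiting subgroup.  D is the exclusive subgroup (every
profile in D benefits), S is the inclusive subgroup (no profile outside S
benefits), and S \ D is the region where the data are not yet decisive.

## Model

The regression stage is a Cox model with treatment–covariate interactions,

    λ(t | x, z, θ) = λ₀(t) · exp(x′β + θ·z′γ),     θ ∈ {0, 1},

with prognostic covariates x, predictive covariates z (carrying a leading
intercept — the treatment main effect — unless disabled), and an unspecified
baseline hazard λ₀.

The cumulative baseline hazard receives a gamma-process prior: the time axis
is partitioned at 0 < s₁ < … < s_J (cutpoints at empirical quantiles of the
event times; the last cutpoint just beyond the largest observed time), and
the increments h_j = H₀(s_j) − H₀(s_{j−1}) are a priori independent

    h_j ~ Gamma(shape = b·[H*(s_j) − H*(s_{j−1})], rate = b),

so the prior mean of H₀ is the parametric guess H* and b weights the pull
towards it.  The coefficients get a Gaussian prior N(μ₀, Σ₀).

Grouping the data into per-interval risk sets R_j and failure sets M_j
(intervals half-open on the left; a subject is at risk through its exit
interval and contributes a failure only there) yields the grouped-data
likelihood

    L(β, h) = ∏_j exp(−h_j ∑_{k∈R_j∖M_j} e^{η_k}) ∏_{m∈M_j} (1 − e^{−h_j e^{η_m}}),

with η the combined linear predictor.

### Posterior sampling

A Metropolis-within-Gibbs sweep updates

1. each coefficient by adaptive random-walk Metropolis on its full
   conditional (proposal scales tuned to ≈0.3–0.5 acceptance during burn-in,
   then frozen);
2. the full coefficient vector once per sweep by an adaptive joint Metropolis
   move whose proposal covariance is the (exponentially forgetting) empirical
   posterior covariance, Cholesky-factored and rescaled toward ≈0.25
   acceptance during burn-in.  Componentwise moves alone mixed with
   integrated autocorrelation times of 30–45 on correlated coefficient
   blocks, which is too slow for the default 1500-sweep budget; the joint
   move restores efficient exploration without changing the target;
3. every hazard increment h_j.  The exact full conditional is the gamma
   density of the no-failure terms times the failure product
   ∏(1 − e^{−h_j e^η}).  The update is independence Metropolis–Hastings with
   proposal Gamma(b·ΔH*_j + d_j, ∑_{R_j} e^η + b) — the conjugate update
   after linearizing 1 − e^{−u} ≈ u — corrected in the acceptance ratio to
   the exact conditional.  With no failures in the interval the proposal
   *is* the conditional and is always accepted.  A `h_update="literal-eq13"`
   switch instead Gibbs-samples the gamma conditional that simply omits the
   failure product, for audit; it is not the default because it changes the
   stationary distribution.

Linear predictors are clipped at ±50 before exponentiation (clips are
counted and surfaced in the diagnostics).  Draws are deterministic given the
seed.

### Partition resolution

The number of intervals J defaults to `min(#distinct event times,
max(20, n_events / 5))` — about five events per interval with a floor of 20
intervals.  The trade-off is real and was measured during development: very
coarse partitions (J = 20 at n ≥ 500) lose the within-interval ordering of
risk sets and visibly bias strong coefficients (checked against the
partial-likelihood MLE), while one-interval-per-event recovers the
continuous-time fit but gives up the finite-sample stabilization that the
saturating failure terms provide at small n.  Either extreme is available
through `n_intervals`.

### Hyperparameter defaults

| parameter | default | rationale |
|---|---|---|
| μ₀, Σ₀ | 0, 10²·I | weak; likelihood-dominated inference |
| H* | constant rate = events / total follow-up | crude scale-matching guess |
| b | 0.01 | weak prior weight on the baseline guess |
| sweeps / burn-in / thin | 1500 / 500 / 1 | 1000 kept draws |
| J | ≈ n_events/5, floor 20 | see above |

## Personalized treatment effects

Two PTE measures are computed per posterior draw on a covariate grid:

* **log hazard ratio** log Δ_H(z) = z′γ.  Benefit: z′γ < log δ_H (δ_H = 1 by
  default).  Independent of x and of the baseline — valid only under
  proportional hazards between arms.
* **RMST difference** Δ_Rd(x, z) = ∫₀^ν [S(t|θ=1) − S(t|θ=0)] dt, the gain in
  ν-restricted life expectancy.  Benefit: Δ_Rd > δ_R (δ_R = 0 by default).
  Each draw's survival curves come from S(t) = exp(−H₀(t)e^{x′β + θz′γ}) with
  H₀ the cumulative sum of that draw's increments, each increment spread
  uniformly over its interval (piecewise-constant hazard).  That spreading
  choice makes every RMST an exact sum of closed-form exponential segments —
  no quadrature error; the alternative (mass at the cutpoints) would shift
  RMSTs by O(interval width).

The restriction time ν defaults to the 90th percentile of observed follow-up
and is recorded in the output; under proportional hazards the *sign* of Δ_Rd
equals the sign of −z′γ for every draw, so benefit classification at
δ_H = 1, δ_R = 0 is identical for the two measures (a property the test suite
asserts draw by draw), and subgroup results are insensitive to ν there.

For non-proportional settings an arm-stratified variant fits separate
baseline increments per arm (shared partition and prognostic block).  The
interaction intercept is dropped — the arm-1 baseline absorbs the treatment
main effect, which would otherwise be unidentified — and only the RMST
difference is meaningful (`log_hr` raises).

## Simultaneous credible subgroups

With Δ̂(z) and sd(z) the posterior mean and SD per grid point, the band

    Δ̂(z) ± w_α · sd(z)

uses the empirical (1 − α) quantile w_α over draws of
sup_z |Δ^{(m)}(z) − Δ̂(z)| / sd(z).  The statistic is used on the
absolute-deviation scale so that the quantile is directly the band
multiplier; the squared-scale variant is exposed for audit
(`scale="squared"`).  Zero-variance grid points are excluded from the sup and
classified by comparing their degenerate value with the threshold.  Then

* benefit-below (log HR): D = {upper < log δ_H}, S = {lower ≤ log δ_H};
* benefit-above (RMSTd): D = {lower > δ_R}, S = {upper ≥ δ_R};

the strict/non-strict asymmetry is kept exactly as stated; threshold ties are
logged.  A multiplicity-*uncorrected* pointwise pair (per-point posterior
benefit probability > 1 − α for D; ≥ α for S) is provided for comparison; it
requires α < 0.5, since for α ≥ 0.5 its own complement rule can break D ⊆ S.
The nesting D_simultaneous ⊆ D_pointwise and S_pointwise ⊆ S_simultaneous
holds on every posterior the suite generates.

## Synthetic data

The generators define the study conditions and are first-class, tested code.

**Proportional hazards.**  Baseline cumulative hazard H₀(t) = λ·t^{ν_w}
(λ = 0.05, ν_w = 1.1); covariates x₁ = z₁ ~ Bernoulli(½), x₂ = z₂ ~
Uniform(−3, 3); z = (1, z₁, z₂); arms Bernoulli(½) (a forced 50/50 switch
exists); T by inverse transform T = [−log U / (λ e^{x′β + θz′γ})]^{1/ν_w};
censoring C ~ Exp(0.02).  Note the baseline is the operative inverse-transform
form λ·t^ν, not (λt)^ν — the two differ only by a reparameterization of λ.

**Non-proportional hazards.**  Treatment-arm baseline rate 0.01 constant;
control-arm rate 0.01 before t_c = 30 and 0.1 after; both arms scaled by
e^{x′β}, the treatment arm additionally by e^{z′γ} (defaults β = (0.7, 0.7),
γ = (0.5, −0.5, −0.5)).  The between-arm hazard ratio is e^{z′γ} before t_c
and e^{z′γ}/10 after.  Event times invert the two-branch piecewise cumulative
hazard exactly.

**Truth and metrics.**  The default evaluation grid crosses z₁ ∈ {0, 1} with
61 equally spaced z₂ values on [−3, 3] (intercept 1; companion x = (z₁, z₂)).
The true benefit set uses z′γ < log δ_H for the log HR and exact integration
of the generating survival curves for the RMSTd (Gauss–Legendre for the
Weibull-type curves; closed form for the piecewise-exponential ones).  Each
replicate is scored by: total coverage 1{D ⊆ B ⊆ S}; pair size |S∖D|/G;
sensitivity |D∩B|/|B| (NaN when B is empty, matching the study convention);
specificity |D^c∩B^c|/|B^c| (1 when the complement is empty); and the mean
squared error of the posterior-mean PTE surface.  The RMSTd window for the
non-proportional study integrates [0, t_c + 50] by default; a
`window_start = t_c` switch restricts to [t_c, t_c + 50].

**What the generators do not emulate:** covariate-dependent or informative
censoring, ties induced by coarse measurement, missing covariates (rejected
at load), time-varying covariates, and model misspecification of the
prognostic block.  Passing the study therefore demonstrates calibration of
the subgroup machinery under a correctly specified regression, not
robustness to those features.

## Study sizes and reproducibility

The bundled acceptance study runs the six-truth × n ∈ {50, 100} factorial at
100 replicates per cell (both PTE measures, 80% level, δ_H = 1, δ_R = 0,
1000 kept draws after 500 burn-in sweeps) and the n = 500 / n = 1000 cells at
25 replicates; these sizes give binomial Monte Carlo SEs of ≈0.04 (coverage
at 100 replicates) and are the package's chosen reporting scale.  All
replicate seeds are spawned deterministically from one root seed, and
per-cell results are resumable through the CLI.

## Known limitations

* The simultaneous band is Gaussian-calibrated (mean ± multiple of SD).  For
  strongly skewed PTE posteriors a quantile-based band would be preferable;
  only a basic normality sanity check is built in.
* Coarse partitions bias strong covariate effects (see above); the default
  resolution rule removes this at the cost of some small-sample stability.
  Posterior-mean PTE surfaces attain partial-likelihood efficiency but
  inherit its heavy tails under near-separation at small n.
* No left truncation, interval censoring, competing risks, or time-varying
  covariates; missing covariate values are rejected at load.
* The stratified model is a proportional-within-arm working model; it
  captures arm-level non-proportionality (its design target) but not
  covariate-dependent crossing hazards within an arm.
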