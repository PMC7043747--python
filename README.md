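# credsurv

Bayesian credible subgroup identification for time-to-event endpoints.

## The problem

Trial populations are heterogeneous: a treatment that looks neutral on
average may help some covariate profiles and harm others.  Testing
treatment–covariate interactions point by point has low power and, worse,
ignores multiplicity — claiming benefit for *every* profile in a region is a
joint statement, not a collection of marginal ones.  `credsurv` is for
biostatisticians who need confirmatory-grade subgroup statements from
right-censored two-arm data: it produces a pair of subgroups (D, S) over a
covariate grid such that, jointly at credible level 1 − α,

    D ⊆ B ⊆ S,

where B is the true benefiting subgroup: everyone in the exclusive subgroup
D benefits, no one outside the inclusive subgroup S does, and S \ D is the
region where the data cannot yet decide.

## The model

The regression stage is a Cox model with treatment interactions,
λ(t|x,z,θ) = λ₀(t)·exp(x′β + θ·z′γ), fitted in a Bayesian way: a
gamma-process prior on the cumulative baseline hazard — independent
increments h_j ~ Gamma(b·ΔH\*(s_j), b) over a partition of the time axis —
and a Gaussian prior on (β, γ), sampled by Metropolis-within-Gibbs on the
grouped-data likelihood.

The posterior draws are converted into a personalized treatment effect (PTE)
at each grid point z: the log hazard ratio z′γ (benefit: below log δ_H), or
the restricted-mean-survival-time difference ∫₀^ν [S₁ − S₀] dt (benefit:
above δ_R), which stays meaningful without proportional hazards.  A
simultaneous band Δ̂(z) ± w_α·sd(z), calibrated by the empirical quantile of
the sup of standardized deviations over the grid, then yields
D = {points whose whole band is on the benefit side} and
S = {points whose band has not crossed entirely to the other side}.

A full simulation framework (Weibull-type proportional-hazards generator and
a piecewise-exponential non-proportional one, true benefit sets, and the
total-coverage / pair-size / sensitivity / specificity / MSE metrics) is
included, as is an arm-stratified model variant for RMST differences under
non-proportional hazards.

## Worked example

```python
import credsurv as cs

cfg = cs.PHSimConfig(n=200, beta=(0.0, 0.0), gamma=(1.0, -1.0, 3.0), seed=7)
data = cs.simulate_ph(cfg)

model = cs.GammaProcessCox(data)
res = model.fit(n_iter=1500, burn_in=500, seed=1)
print(res.summary().round(3))

grid = cs.default_grid()  # z1 in {0,1} x 61 z2 values on [-3, 3]
pair, band = res.credible_subgroups(grid, measure="log_hr", delta=1.0, level=0.8)
print(f"|D| = {pair.exclusive.size}, |S\\D| = {pair.uncertainty.size}, "
      f"|S^C| = {grid.G - pair.inclusive.size}")
```

prints

```
          posterior_mean  posterior_sd  significant  accept_rate
effect
x1                -0.362         0.231        False        0.425
x2                 0.047         0.065        False        0.330
treat              0.806         0.285         True        0.477
z1:treat          -1.241         0.342         True        0.395
z2:treat           3.398         0.231         True        0.466
|D| = 56, |S\D| = 8, |S^C| = 58
```

The interaction coefficients recover the generating γ = (1, −1, 3) within
their posterior spread (`significant` flags |mean| > 1.96·SD, the summary
convention).  At the 80% level the band classifies 56 of the 122 grid
profiles as benefiting (true log hazard ratio below 0), 58 as
non-benefiting, and leaves 8 undecided — and since the truth here is known,
one can check the pair: `cs.true_benefit_set` + `cs.evaluate_pair` report
total coverage 1.0, sensitivity 0.98, specificity 1.0 for this replicate.

The same objects drive the RMST-difference analysis
(`measure="rmstd"`, restriction time defaulting to the 90th percentile of
follow-up) and the arm-stratified fit
(`GammaProcessCox(data, stratify_by_arm=True)`).

## Command line

```bash
credsurv fit       --config fit.yaml --out out/          # draws + summary
credsurv subgroups --draws out/ --out sub/ --level 0.8 --measure loghr
credsurv simulate  --config sim.yaml --out data.csv
credsurv study     --config study.yaml --out study/      # resumable factorial
credsurv evaluate  --replicates study/ --out summary.csv
```

Every run writes a config echo (seeds included) sufficient to reproduce it.

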