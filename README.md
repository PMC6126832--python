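# geosfa — Bayesian geoadditive stochastic frontier analysis of hospital quality of care

`geosfa` estimates a quality-expanded notion of hospital technical
efficiency for a single medical condition (the motivating application is
acute stroke care). Instead of treating patient volume as the thing to
maximize and cost as the thing to minimize, the model asks: given the
risk profile of the patients a hospital treats, how few deaths,
readmissions, physicians and nurses could it have used? It is written
for health-services researchers and hospital-market regulators who have
report-card style panels (hospital × year) with risk-adjusted outcome
indicators and a district map, and who want efficiency scores,
determinants of inefficiency, and policy-scenario arithmetic with full
posterior uncertainty.

## The model

Output is **log risk-adjusted patient volume**,
`y_it = log(ExpMor_it / r̄_t)`: the expected 30-day deaths of hospital
*i*'s patients in wave *t* (from an upstream patient-level risk
adjustment) scaled up by the inverse of the wave's mean observed
mortality rate `r̄_t`. The production frontier is Cobb-Douglas
(optionally translog) in two *quality* inputs — observed 30-day deaths
and readmissions, with a zero-input dummy device `D`, `k* = max(k, D)`
so that hospitals with zero deaths stay in the sample — and two
*resource* inputs, physician and nurse FTEs:

    y_it = β₀ + β₁ D^mor_it + β₂ D^readm_it + β₃ log mor*_it + β₄ log readm*_it
           + β₅ log phys_it + β₆ log nurse_it + λ_t + v_it − u_it

with Gaussian noise `v_it ~ N(0, σ_v²)` and one-sided inefficiency
following the *scaling property*

    u_it = u*_it · α_it,   α_it = exp(η_it),   u*_it ~ N⁺(0, σ_u*²),

so a hospital's inefficiency *scale* is driven by observables and
spatial structure:

    η_it = Σ_j δ_j z_jit + τ_t + f_struct(dist_i) + f_unstruct(dist_i).

The determinants `z` cover specialization, stroke-unit certification,
market concentration, outpatient supply, ownership, teaching status and
case-mix shares. `f_struct` is an intrinsic Gaussian Markov random
field (ICAR) on the district contiguity graph (districts are neighbours
iff they share a border), `f_unstruct` an iid district effect; both have
inverse-gamma variance hyperpriors and the structured field is
identified by a sum-to-zero constraint. `η` has no intercept — its
level is the scale of `u*`.

Fitting is by MCMC (conjugate draws for `β`, the latent `u*` and all
variances; adaptive Metropolis on the closed-form skew-normal marginal
likelihood for `δ` and the spatial fields). Post-estimation delivers
technical efficiency `TE = exp(−u) ∈ (0,1]`, the inefficiency share
`γ = σ_u²/(σ_v²+σ_u²)`, input-oriented **slack resources**
`x_k (1 − exp(−u/β_k))`, marginal effects of each determinant on TE and
on slacks (closed forms for the half-normal case), DIC/WAIC model
comparison across spatial specifications, and a propensity-matching +
difference-in-differences refit for the certification effect. A
synthetic-panel generator with known ground truth stands in for the
proprietary report-card data.

## Worked example

`examples/02_fit_frontier.py` simulates ≈200 hospitals over 5 waves on
a 5×5 district lattice, prepares the panel and fits the district-level
struct+unstruct model (12 000 iterations, 2 000 burn-in, thinning 10):

```
frontier elasticities (posterior mean, stars = CI excludes 0):
                 mean     sd stars
log_mor_star    0.443  0.029   ***
log_readm_star  0.287  0.027   ***
log_phys        0.035  0.053
log_nurse       0.001  0.053

selected inefficiency determinants (negative = reduces inefficiency):
             mean     sd stars
SUCert     -0.930  0.123   ***
SUnonCert  -0.550  0.069   ***
MSStrDis   -0.832  0.218   ***
log_HosBed -0.533  0.038   ***
PrivHos     0.394  0.099   ***

generating values: SUCert -1.167, SUnonCert -0.592, MSStrDis -0.829,
                   log_HosBed -0.555, PrivHos 0.310
sigma_v^2: 0.131 (true 0.142)
```

The mortality elasticity (0.443) exceeds the readmission elasticity
(0.287), staffing elasticities are small and positive, and the
inefficiency determinants recover their generating signs and
magnitudes: certified stroke units reduce the inefficiency scale about
twice as strongly as non-certified ones. `examples/03_effects_and_slack.py`
turns a fit into efficiency scores, marginal effects and the national
scenario product (0.401 deaths/hospital × 937 hospitals → 376 deaths
averted per year); `examples/04_model_comparison.py` shows DIC/WAIC
selecting the district-level spatial model when the generating process
has a true district effect; `examples/05_matching_did.py` runs the
matching + DID certification check.

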