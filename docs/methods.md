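# Methods

## Observation model

For hospital *i*, wave *t*:

    y_it = x_it' β + λ_t + v_it − u*_it exp(η_it),
    v_it ~ N(0, σ_v²),   u*_it ~ N⁺(0, σ_u*²)  (half-normal),
    η_it = z_it' δ + τ_t + f_struct(dist_i) + f_unstruct(dist_i) [+ h_i].

`y` is the centered log risk-adjusted patient volume; `x` holds the
zero-input dummies, the floored log quality counts, log staffing, and
(in translog mode) all squares and cross-products of the four
continuous log inputs. The inefficiency predictor `η` has no intercept:
a constant shift of `η` is indistinguishable from rescaling `σ_u*`, so
the innovation scale carries the level.

Because `u = u* exp(η)` scales the *random variable*, the standard
deviation of `u` is `σ_u* exp(η)` — the variance scales with
`exp(2η)`, not `exp(η)`. The source analyses of this model family print
both conventions in adjacent equations; the scaling-property form (the
random variable multiplied by the factor) is implemented throughout,
including in the marginal likelihood and all post-estimation formulas.

Two latent-granularity options exist for `u*`: observation-specific
(default) and hospital-specific time-invariant. The substance question
— whether inefficiency innovations refresh each wave — cannot be
settled on the data the model is meant for; both are supported and the
default mirrors the per-observation treatment of the composed error.

## Variable construction

- **Output.** `y_it = log(ExpMor_it / r̄_t)` with `r̄_t` the unweighted
  mean across hospitals of each hospital's observed mortality rate
  (deaths / case volume) in wave *t*; a volume-weighted variant sits
  behind a flag. Records with `ExpMor = 0` have no defined log output
  and are flagged out of the fit with a logged count.
- **Zeros.** Default: indicator `D^k = 1{k=0}` and `k* = max(k, D^k)`
  so `log k* = 0` at zero; alternative (`rescale_half`): `k* = k + 0.5`
  for all records, with the `D` columns dropped from the design.
- **Centering.** The output and the four log inputs are centered at
  their grand means (offsets stored, exactly invertible); the intercept
  is then the frontier value at sample means. The inefficiency-design
  covariates are also mean-centered by default: this leaves every `δ`
  coefficient unchanged (only the absorbed level moves into `σ_u*`) and
  decorrelates the `δ`-level direction from `log σ_u*` in the
  posterior, which matters for mixing. Wave dummies stay raw so `τ_t`
  keeps its reference-wave reading. Counts are accepted as nonnegative
  reals; integrality is not enforced. Rows with missing required fields
  are dropped with a logged count — no imputation.

## Priors

Flat priors on `β` and `δ` (the published convention for this model
family); `IG(0.001, 0.001)` on `σ_v²`, `σ_u*²`, `τ²_struct`,
`τ²_unstruct`, `τ²_hospital`; iid Gaussian `f_unstruct` and `h`;
intrinsic GMRF (ICAR) `f_struct` with precision structure
`K = D − A` on the border-sharing district graph (binary, unweighted
adjacency), identified by per-component sum-to-zero.

Proper Gaussian priors on `β`/`δ` are available
(`Priors(beta_prior_var=…, delta_prior_var=…)`). Two uses: (1) sampler
validation, which needs prior moments to exist; (2) desk-scale data.
At a few hundred treated observations, the likelihood in a scale
coefficient `δ_j` tends to a positive *constant* as `δ_j → −∞` (the
affected observations degenerate to pure noise), so the flat-prior
posterior has a heavy left shoulder: posterior means of genuinely
negative effects overshoot by ~0.2 and 95% intervals undercover. A
`N(0,1)` prior on `δ` is the package's recommended regularization below
roughly a thousand observations and is what the recovery experiments
use; at the ~5,500-observation scale of real report-card panels the
flat default is innocuous.

## MCMC

One sweep:

1. **Collapsed block** (when `μ* = 0` and `u*` is observation-level):
   `δ` in blocks of ≤ 8 and each spatial/hospital effect site-wise by
   adaptive random-walk Metropolis on the *marginal* skew-normal
   likelihood (u* integrated out analytically), immediately followed by
   a fresh exact draw of `u*` from its truncated-normal full
   conditional — jointly a partially-collapsed Gibbs draw of
   `(δ, f, h, u*)`. Collapsing removes the strong `δ`↔`u*` coupling
   that makes conditional-likelihood random walks mix an order of
   magnitude slower. Where no pointwise marginal exists (hospital-level
   `u*`, or `μ* ≠ 0`) the same updates run on the conditional
   likelihood instead.
2. `β`: conjugate Gaussian draw on the adjusted response `y + α u*`.
3. Variances: conjugate inverse-gamma draws; the ICAR variance uses
   shape `a + rank(K)/2` and rate `b + f'Kf/2` with
   `rank(K) = #regions − #components`.

Proposal adaptation: Robbins–Monro step-size targeting 0.25 (blocks) /
0.44 (single sites), plus Haario-style empirical-covariance proposals
per `δ` block once ≥ 200 adaptation sweeps have accumulated; adaptation
runs only during burn-in. `δ` proposals are pre-scaled by inverse
column standard deviations. Structured-field updates proceed by graph
coloring (sites within a color class are mutually non-adjacent, so
their updates vectorize exactly); districts hosting no hospitals are
Gibbs-sampled from the GMRF prior conditional, so the structured field
covers *all* districts while the unstructured effect exists only for
observed districts. After each structured sweep the field is re-centered
to per-component sum-to-zero with a compensating rescale of
`(u*, σ_u*²)` that leaves `u = u*α` and hence the likelihood exactly
invariant. Degree-zero districts (islands) keep a structured effect of 0.

The truncated-normal primitive is the exact inverse log-CDF
`m + s·(−ndtri_exp(log U + log_ndtr(m/s)))` — vectorized, no rejection
loop, stable for standardized bounds far in either tail.

Chains start from a warm start: L-BFGS maximization of the marginal
likelihood over `(intercept shift, δ, log σ_v², log σ_u*)` with the
other frontier coefficients at OLS and fields at zero, then `u*` drawn
at that mode. All randomness flows through one seeded generator;
identical seeds give bitwise-identical stored draws. The reference
protocol stores every 100th of 120,000 iterations after a 20,000 burn-in
(1,000 draws); the bundled experiments use 12,000/2,000–3,000/9–10.

**Validation.** A successive-conditional (Geweke-style) simulator —
alternate one transition sweep with a data redraw, under proper priors
(`IG(3,2)` variances, Gaussian `β`, `δ`) — must reproduce the prior
marginals of `δ` and all variances; this exercises every full
conditional jointly, including the collapsed block, on a
20-observation, 4-district model with an unstructured spatial term (the
improper ICAR prior has no prior moments to reproduce; the structured
machinery is instead checked against closed-form constrained-Gaussian
moments on 2- and 3-region graphs and by parameter recovery).
Split-chain R-hat and ESS are computed for every fit, with a warning
below ESS 100.

## Model comparison

DIC (`D̄ + p_D`, `p_D = D̄ − D(θ̄)`) and WAIC (pointwise
log-predictive minus the pointwise posterior variance penalty), both on
the **marginal** likelihood with `u` integrated out analytically, so
models with different latent dimensions are comparable; the
conditional-on-`u` alternative is behind a flag. Comparisons are
guarded by a data fingerprint (hash of the response vector) — criteria
across different observation sets raise an error.

## Post-estimation

- `TE_it`: posterior mean of `exp(−u*_it α_it)`; for the half-normal
  the closed form `E[exp(−u)] = 2 e^{σ_u²/2} Φ(−σ_u)` provides the
  oracle and fast evaluation at the "average hospital" (`σ_u` at
  sample-mean covariates).
- `γ = σ_u²/(σ_v² + σ_u²)` with `σ_u = σ_u* exp(η̄)` evaluated at
  sample means — the evaluation point is a documented, configurable
  choice.
- **Slack** of input *k*: single-input contraction at fixed output and
  other inputs, `slack_k = x_k (1 − exp(−u/β_k))`, requiring a positive
  elasticity `β_k`; per-draw at the average hospital, or per observation
  at posterior-mean `u` with national totals as within-wave sums. The
  one-input-at-a-time (input-oriented) reading follows from the verbal
  definition of slack as the amount of a *single* resource removable at
  unchanged output; the near-total mortality slack it implies for an
  average hospital is consistent with that reading, not with a radial
  contraction.
- **Marginal effects** of determinant `z_j`: through
  `dσ_u/dz_j = δ_j σ_u`; derivative form
  `δ_j σ_u · 2e^{σ_u²/2}(σ_u Φ(−σ_u) − φ(σ_u))` for TE (and the
  analogous expression for expected slack), discrete 0→1 differences by
  default for binary determinants. Effects on TE are reported ×100.
  Both forms are validated against central finite differences.
- **Scenario arithmetic**: per-hospital effect × hospital count,
  reported raw and as the printed integer.
- Signs are structurally linked: an inefficiency-reducing determinant
  (`δ_j < 0`) has a positive TE effect and negative slack effects.

## Synthetic panels

The generator emulates the report-card setting: an unbalanced panel
(per-wave dropout 3%) over waves 2006/08/10/12/13; districts on a g×g
rook lattice (default 20, ≈ 400 districts; coarse map by square
blocks); binary determinants at realistic prevalences (certification
11–12% by the last wave, 60% of certificates predating the panel and
the rest switching on mid-panel, which feeds the matching + DID
design); bivariate log-normal staffing at correlation 0.95; quality
counts with exact-zero shares rising 0.08 → 0.16 across waves, zeros
assigned by thresholding a latent size-severity index (small hospitals
record zeros) with a Poisson option; case volumes consistent with a
14.8%-mean observed mortality rate; expected mortality constructed so
the preparation pipeline inverts the simulation exactly. Default
coefficient magnitudes are set near the published application's point
estimates (simulation defaults, not estimates), and the default
innovation scale `σ_u* = 1.517` reproduces that application's
variance regime (`σ_u² = 2.30` vs `σ_v² = 0.142`, `γ = 0.94`). With
`σ_u* ≈ 0.42` the unconditional mean of `exp(−u)` sits near 0.73
instead — the generator exposes the dial and the tests exercise both.

What the generator does *not* emulate: patient-level risk adjustment
(expected deaths are constructed, not modelled), real German geography
(lattice contiguity instead), longitudinal covariate dynamics beyond
certification adoption and staffing noise, and any selection of
certification on performance (assignment is random — which is exactly
what makes the DID check interpretable). Passing tests therefore
demonstrate correct inference *given the model*, not robustness to the
misspecifications real report-card data may contain.

## Bundled experiments (problem sizes)

- **Recovery/calibration**: 20 replicates of 200 hospitals × 5 waves on
  a 5×5 lattice, single active determinant `δ_SUCert = −1.0`, `N(0,1)`
  prior on `δ`, chains 12,000/2,000/10. Checked: mean recovery within
  ±0.35, ≥ 90% interval coverage, hospital-level efficiency rank
  correlation > 0.8.
- **Model-selection direction**: 10 replicates of ≈180 hospitals ×
  3 waves on a 6×6 lattice with 3×3 coarse blocks, full-magnitude
  defaults, chains 12,000/3,000/9; the district struct+unstruct model
  must attain the lowest DIC against no-spatial and coarse alternatives
  in ≥ 9/10. The coarse blocks must genuinely under-resolve the smooth
  ICAR field, and DIC differences of a few points are chain-noise —
  hence the 3×3 blocks and the longer chains.
- **Sampler validation**: 20,000 successive-conditional cycles on the
  20-observation model.

## Known limitations

- Free `μ* ≠ 0` is plumbed through the conditional-likelihood path but
  untested beyond prior sanity; the marginal likelihood (and hence
  DIC/WAIC and the collapsed updates) requires `μ* = 0`.
- Flat-prior posteriors for scale coefficients are ill-behaved at small
  treated counts (see Priors); the package warns by documentation, not
  at runtime.
- DID interaction coefficients rest on a handful of matched switchers
  in small panels — wide, heavy-tailed posteriors there are a property
  of the design, not the sampler.
- The certificate-age split, alternative stroke-unit thresholds and
  district health covariates ship as preset configurations referencing
  recoded covariate columns the caller must supply; no dedicated
  recoding code exists.
- "Significance" stars mark posterior credibility intervals excluding
  zero at 1/5/10% — a Bayesian reading of a frequentist notation.
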