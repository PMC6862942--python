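# Methods

## Model and assumptions

Both fitters assume the same measurement-error model for 24-h recalls of
a nearly-daily consumed dietary component (zero intake on < 5% of
person-days). On the Box-Cox scale `g(x; λ) = (x^λ − 1)/λ` (natural log
at λ = 0),

```
g(R_ij; λ) = β₀ + Σ_k β_k X_ki + Σ_l β_l Z_lij + u_i + e_ij,
```

with normal, mutually independent person effects `u_i ~ N(0, σ²_u)` and
within-person errors `e_ij ~ N(0, σ²_e)`. The recall is taken to be an
unbiased instrument: a single recall does not equal that day's true
intake, but the long-run average of recalls equals the person's usual
intake. Recalls within a person are assumed independent (nonconsecutive
days). A person's usual intake is then

```
T_i = Σ_t π_t · E_e[ g⁻¹(lp_it + u_i + e; λ) ],
```

the day-type-weighted (π = 4/7 weekday, 3/7 weekend by default)
expectation of the back-transformed intake over the within-person error,
where `lp_it` is the linear predictor with the temporal covariates set to
day type *t*. Population summaries are survey-weighted functionals of
the distribution of `T_i`.

With replicate recalls (`AmountOnlyModel`) both variance components are
identified and estimated by maximum likelihood. With a single recall per
person (`OneDayModel`) only the total residual variance
`V = σ²_u + σ²_e` is identified; an external variance ratio — ideally
estimated from a comparable population, with a comparable covariate set,
in one of the three conventions within:between (α), within:total (β),
between:total (γ) — supplies the split. The ratio must describe the
*unstructured* components only: covariate-explained variation is removed
by the regression before the split.

## Parameters that matter

| parameter | meaning | default | rationale |
|---|---|---|---|
| λ grid | candidate Box-Cox powers | 0 to 1, step 0.01 | log case included exactly; grid search is reproducible and robust |
| external ratio | within:between (or β/γ) | — (required for one-day) | the critical user input; see sensitivity sweep |
| M | person-effect draws per sampled person | 100 | pseudo-population resolution; raising M refines but does not shift summaries |
| nodes | Gauss–Hermite nodes for `E_e[·]` | 9 (odd ≥ 3) | matches the inner expectation to a 10⁶-draw Monte-Carlo check within 0.5% over λ ∈ [0,1], σ²_e ≤ 1 |
| day-type weights | weekday/weekend shares | 4/7, 3/7 | Friday–Sunday weekend definition |
| F | Fay coefficient for BRR | 0 (classical) | set to the release's value when using survey replicate weights (e.g. 0.3 for NHANES-style weights) |
| margins | TOST equivalence | 5% of reference (means, percentiles); 0.5 pp (prevalence) | conventional practical-equivalence margins |
| sweep multipliers | ratio mis-specification | 0.25…2.0 (9 values) + 1.0 | brackets halving and doubling the ratio |

## Estimation details

**One-day fitter.** λ is chosen by refitting the survey-weighted
regression at every grid power and scoring the linearity (R²) of the
normal probability plot built from the survey-weighted 1st–99th residual
percentiles against `Φ⁻¹(p/100)`; ties resolve to the smaller power.
This formalizes the graphical normality check and extends to weighted
data, where classical normality tests do not. Coefficients come from
weighted least squares; the residual variance uses a degrees-of-freedom
correction based on the Kish effective sample size,
`V = (Σw r²/Σw) · n_eff/(n_eff − p)` with `n_eff = (Σw)²/Σw²`, which is
unbiased in the equal-weight limit. When the table contains repeated
recalls only the first per person is used (with a warning).

**Amount-only fitter.** For each grid power the Gaussian random-intercept
likelihood is profiled analytically: given θ = σ²_u/σ²_e the GLS
coefficients and the residual scale have closed forms, leaving a bounded
one-dimensional search over log₁₀θ ∈ [−8, 8] (θ = 0 is checked
explicitly; a boundary estimate of σ²_u triggers a warning and an
infinite reported ratio). Likelihoods are compared across powers with
the Box-Cox Jacobian term `(λ−1) Σ w log R` included. Survey weights
enter as person-level frequency-style weights on each person's
likelihood contribution (a pragmatic weighted ML; design uncertainty is
carried by replicate-weight reruns, not by the weights' second-order
properties). ML rather than REML is used throughout.

**Distribution stage.** Each sampled person contributes M independent
draws of `u`, each with weight `w_i/M`; the inner expectation over `e`
uses Gauss–Hermite quadrature. Back-transform arguments with
`λy + 1 ≤ 0` have no positive preimage and are clipped to zero intake;
the clipped share is reported (`clipped_fraction`) and is essentially
zero for realistic fits. Percentiles of the pseudo-population use the
same weighted-percentile rule as the λ selector (midpoint plotting
positions on the weighted empirical CDF with linear interpolation) for
internal consistency; the rule is invariant to rescaling all weights.
All draws derive from a single seeded generator, so results are
bit-reproducible given the seed.

**Sensitivity sweep.** Only the variance split is recomputed per
multiplier — λ and the coefficients stay at the nominal fit, because the
external ratio enters the workflow after transformation and regression —
and the identical seed is reused, so per-multiplier differences isolate
the ratio effect. The nominal ratio is converted to the within:between
convention before scaling, which remains valid for any positive
multiplier (scaling a β or γ value directly could leave (0, 1)).

**Survey comparison.** Between-method standard errors re-run *both*
fitters under each replicate weight set and difference per replicate,
respecting the correlation from the shared sample. Replicate reruns keep
each method's full-sample λ (switchable), which stabilizes the SE.
TOST uses z-tests; the reported p-value is the larger one-sided p.

## Zero intakes

Box-Cox requires positivity, but the nearly-daily definition admits a
few zero recalls. Default: zeros are shifted to half the smallest
positive observed intake before transformation, with a logged count; a
`zero_handling` switch drops them, or refuses, instead.

## The synthetic generator

`GeneratorSpec`/`generate` draw data from exactly the model above:
continuous age (uniform 19–80), a three-level population group
(proportions 0.40/0.35/0.25) standing in for race/ethnicity indicators,
a weekend indicator with P = 3/7, gamma-distributed survey weights
(mean 1, shape 4) or equal weights, and Box-Cox-scale effects. The
default scale is a vitamin-A-like nutrient: λ = 0.25, intercept 16 on
the transformed scale (≈ 625 units/d at the median), σ²_u = 0.5,
σ²_e = 1.0 (within:between ratio 2), a small positive age slope (0.01
per year), group effects (0, +0.3, −0.2) and a weekend effect of +0.2.
Generated back-transform arguments with no positive preimage are clipped
to zero and counted against the < 5% nearly-daily budget; a spec
implying ≥ 5% zeros is refused. The truth table carries each person's
drawn `u` and closed-form usual intake (41-node quadrature with the
generating parameters), enabling end-to-end recovery checks.

What the generator does **not** emulate: survey design structure
(strata/PSUs, clustering, nonresponse), recall-instrument bias,
heteroscedastic or correlated within-person errors, and episodic
(zero-inflated) consumption. Passing recovery tests therefore
demonstrate correctness of the estimators *under the model*, not
robustness to violations of it.

## Identifiability of the Box-Cox power

λ is only strongly identified when the residual spread is large relative
to the transformed-scale mean (equivalently, when the original-scale
distribution is clearly skewed). At the vitamin-A-like default scale the
selected power has a sampling SD of roughly 0.04–0.07 at n = 2000–5000
for both fitters; at a small-unit, vitamin-E-like scale (transformed
intercept ≈ 3) it is pinned within ±0.05 per realization. The package's
parameter-recovery experiments therefore use the small-unit scale when
the quantity under test is λ itself. This is a feature of the method,
not a defect: distribution summaries are robust to moderate λ
differences as long as the variance *ratio* is appropriate, which is
also why the two fitters may legitimately select different powers on the
same data.

## Known limitations

* The weighted mixed-model likelihood is a pseudo-likelihood; its SEs
  are not design-consistent on their own — use the BRR machinery for
  inference.
* The likelihood is unbounded in the degenerate σ²_e → 0 case (identical
  recalls within persons); the fitter returns the boundary solution with
  a near-zero within-person component rather than failing.
* Prevalence near a cutoff is highly sensitive to small relative shifts
  of the intake distribution when the usual-intake CV is small; compare
  prevalences between methods or specifications with their sampling
  error in mind, not as point values.
* Temporal covariates are assumed to be 0/1 day-type indicators; the
  distribution stage averages over exactly two day types.
* BRR replicate-weight *generation* (for simulation) supports Hadamard
  orders that are powers of two ≥ 4; analysis of externally supplied
  replicate weights has no such restriction.
* Episodically consumed foods (two-part models), health-outcome
  regression calibration and multivariate intake are out of scope.
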