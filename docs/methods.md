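# Methods

## Exposure model

Per-iteration exposure to an agent is `E = c · a · (v/100) / bw` in
mg/kg bw/day, the product of four independent random inputs:

| input | distribution (default) | unit | note |
|---|---|---|---|
| `c` concentration | per-agent risk function (below) | mg/ml after conversion | g/100 g × 10 × density; mg/L × 0.001 |
| `a` liquid/day | Normal solved from P25 = 3, P75 = 5 → μ = 4, σ ≈ 1.4826 | ml/day | truncated at 0 |
| `v` vaporized | Uniform(6, 81) | % | enters as fraction v/100 |
| `bw` bodyweight | Normal(73.9, 12) | kg | truncated at 0 (mass below 0 ≈ 1e-9; cosmetic) |

The liquid density behind the g/100 g → mg/ml conversion is fixed at
1 g/ml and exposed as an argument of `convert_concentration`. 100%
bioavailability of the vaporized fraction is assumed; no pharmacokinetics.

Default concentration risk functions (the packaged survey results):

* nicotine — Normal(11.023, 13.134) mg/ml, truncated at 0;
* glycerol — Weibull(shape 1.8104, scale 44.812) shifted by −2.8327 g/100 g, truncated at 0;
* 1,2-propanediol — Triangular(−18.939, 91.8, 100.45) g/100 g, truncated at 0;
* ethylene glycol — log-logistic(location −0.40204, scale 5.15, shape 1.8215) g/100 g, truncated at 0;
* 1,3-propanediol, thujone, ethyl vanillin — empirical resampling of the
  54-value measurement vector with non-detects as zeros.

## Distribution library

The log-logistic uses the three-parameter actuarial convention
`F(x) = 1/(1 + ((x−γ)/β)^(−α))` for `x > γ` (scipy's `fisk`); its mean
`γ + β·(π/α)/sin(π/α)` exists only for α > 1 — the default ethylene-glycol
spec (α ≈ 1.82) therefore has a finite mean but infinite variance, which
matters for refitting (below). A normal may be specified by two quantiles
(`normal_from_quantiles`); the quantile equations are solved first and
truncation applied afterwards (the alternative order changes nothing
measurable here, the mass below zero being ~0.35%).

Shift applies before truncation: bounds are expressed on the shifted
variable. Truncation is exact — the inverse CDF is restricted to
`[F(lo), F(hi)]` — with no rejection loop; a property test confirms
distributional equality with rejection sampling (two-sample KS, n = 10⁴).
Construction rejects truncation windows carrying zero mass.

Sampling inverts the CDF on either iid uniforms (`srs`) or Latin-Hypercube
uniforms (`lhs`): one draw per stratum `[(i−1)/n, i/n)`, stratum order
randomly permuted, permutations independent across the four model inputs.
The generator is numpy's PCG64 with explicit seeding; per-input streams are
spawned from a single `SeedSequence`, so results are reproducible
bit-for-bit but do not depend on Mersenne-Twister specifics.

Analytic means exist for: normal (incl. truncated, via `truncnorm`),
uniform (truncation intersects the support), untruncated triangular /
Weibull / log-logistic (α > 1), and empirical vectors. Everything else
falls back to 4096-node Gauss–Legendre quadrature of the quantile function
on (0,1), accurate to <0.1% for every spec used here (checked against the
closed forms where both exist).

## Fitting and model selection

Candidate families {normal, shifted Weibull, triangular, log-logistic,
uniform} are fitted by scipy maximum likelihood (triangular and the
3-parameter families by numerical MLE with free location, so a negative
triangular minimum is allowed); non-detects enter as literal zeros, and
every fitted spec carries a lower truncation at 0. Families are ranked by
the KS sup-distance between the empirical CDF and the fitted (truncated)
CDF; no Lilliefors correction — the statistic only ranks, it is never a
test. Below 30% positive incidence parametric fitting is abandoned for
empirical resampling of the full vector; 0.30 separates the sparse agents
(4–26% incidence) from the fitted ones (≥65%) with margin on both sides.

Two caveats established by the test suite:

* a *heavily* truncated normal (the nicotine spec, ~20% mass removed) is
  not re-selected from its own large sample — plain-MLE normal parameters
  describe the truncated draws poorly and KS prefers a shifted Weibull.
  Stability of re-selection holds for mildly truncated specs;
* with infinite-variance concentrations (ethylene glycol) a 54-sample
  refit does not stabilise the exposure mean or median — deviations of
  +40% and one divergent-mean fit were observed across seeds. Refit
  round-trip accuracy of ±25% is demonstrated only for the
  finite-variance agents.

## MOE assessment

`MOE = threshold / exposure` per iteration; zero-exposure iterations give
+∞, kept in the percentile summary (serialized as the string `inf` in
CSV). The point estimate `threshold / mean(exposure)` is reported
alongside, since "average MOE" in the ratio sense is dominated by
near-zero exposures. The primary threshold (LOAEL/NOAEL/BMDL10/NOEL) is
always the numerator; ADI/MRL values are carried in the registry for
guidance-value comparisons only. Risk bands key on the median MOE:
animal-derived endpoints use 10/100 (the classical 10×10 uncertainty
factor), human-derived endpoints 1/10.

## Sensitivity analysis

Standardized regression coefficients: OLS of the z-scored exposure on the
four z-scored inputs, with R² reported (≈0.7–0.8 here — the exposure
formula is multiplicative, so the linear fit is an approximation). A
rank-transformed variant is available (`rank_based=True`). Zero-variance
inputs are excluded and flagged with coefficient 0. Concentration is the
dominant input for six of the seven agents; for 1,2-propanediol its
coefficient (~0.50) statistically ties with vaporization (~0.58) because
the two inputs have nearly equal coefficients of variation. Bodyweight is
always negative and weakest.

## NMR validation statistics

Calibration lines are OLS of integral ratio (analyte vs TSP/TMS reference)
on concentration; the residual SD uses the n−2 denominator.
Regression-based limits: LOD = 3.3·s_yx/slope, LOQ = 10·s_yx/slope — the
3.3/10 constants are conventional and configurable; nothing downstream
depends on them. SNR-based limits: SNR = peak amplitude / (2 × noise-window
SD) (the factor 2 mirrors the Bruker `sino` convention, configurable),
LOD/LOQ at SNR 3/10. Dilution factors: aqueous preparation 600/60 = 10,
chloroform 900/100 = 9; mg/L in tube → mg/ml sample divides by 1000 after
multiplying by the dilution factor.

Method comparison regresses method B on method A with 95% t-based CIs on
slope and intercept; the methods "agree" when the slope CI covers 1 and
the intercept CI covers 0. Non-detects default to zero substitution
(`as_zero`), which keeps double-non-detect pairs as origin anchors — with
the packaged 15 NMR/HPLC nicotine pairs this yields r = 0.984; dropping
non-detect pairs instead gives r = 0.849 on the 10 numeric pairs.

## Synthetic data

The generator emulates a 54-sample market survey: per agent, each sample
is positive with the survey incidence and positive concentrations are
drawn from the agent's risk function (empirical agents resample their
positive measurements only, the incidence supplying the zeros). Label
metadata plants a configurable number of discordances (default: 5
nicotine-containing samples labelled "nicotine-free", 1 labelled product
without nicotine), with concordant labels jittered ~15% around measured
values. The unpublished 1,3-propanediol and ethyl vanillin measurement
vectors are reconstructed by deterministic moment matching (alternating
affine correction and bound clipping) to the printed incidence, mean, SD
and range — they are synthetic stand-ins, not the original data. What the
generator does **not** emulate: between-agent correlation within a sample
(formulation constraints such as solvent fractions summing to ≤100 g/100 g),
measurement error, or values censored below the LOD rather than at zero —
so passing round-trip tests demonstrate correctness of the pipeline
arithmetic, not robustness to those real-data features.

## Problem sizes and numerical choices

Simulations use 10,000 LHS iterations (the headline analysis size;
acceptance runs finish in well under a second per agent). Reseeded
tolerance estimation uses 20 runs. The fit-stability property is exercised
at n = 10⁴ samples × 10 seeds for two source families; the factorization
oracle at n = 10⁵. Empirical quantiles are inverse-ECDF (type 1)
throughout; at n = 10⁴ the quantile convention is immaterial at reported
precision. Exposure percentile tables print to three significant figures.

## Known limitations

* Oral toxicological thresholds are compared against an inhalation-like
  exposure route; no route-to-route extrapolation is attempted.
* Inputs are treated as independent — no copula between concentration and
  consumption behaviour.
* The nicotine-dependence hazard is out of scope (no usable dose–response
  basis), as are BMD modelling from raw dose–response data and any NMR
  spectral processing (integrals arrive as numbers).
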