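# Methods

This package implements an explanatory-model analysis of socioeconomic
inequalities in cardiovascular (CVD) mortality: how much of the excess CVD
mortality hazard of lower socioeconomic position (SEP) groups is accounted
for by childhood socioeconomic conditions and by adulthood material,
behavioural and psychosocial risk factors. Because the cohort it was designed
around is not publicly deposited, the package ships a synthetic-cohort
generator with the same generative structure, so every stage of the pipeline
is exercised and tested end to end.

## Exposure coding

Adulthood SEP is a four-level education indicator (1-low … 4-high, reference
4-high); childhood SEP is the father's occupational class (professional /
white-collar / blue-collar, reference professional). Risk factors are coded
from raw questionnaire responses:

- **Smoking**: never / former / current (identity mapping).
- **Physical activity**: three weekly-frequency bands (sports, transport,
  leisure) are mapped to 0 / 0.5 / 1.5 / 2.5 hours; transport + leisure is
  "moderate" activity. The four printed class definitions (inactive, little
  active, moderately active, active) do not tile the 4³ grid of band
  combinations and overlap at the 3.5-hour boundary, so the shipped rule is a
  pure function of total weekly hours — total ≤ 1 inactive, (1, 2.5) little
  active, [2.5, 3.5) moderately active, ≥ 3.5 active — which reproduces every
  stated example, is total, single-valued, and monotone in total hours. The
  "<1 h sports with 0–1 h moderate → little active" special case is *not*
  applied where it would break monotonicity (it would rank 0.5 h of sports
  above 0.5 h of leisure at the same total).
- **Alcohol**: weekly units = drinking days × units per drinking day; classes
  are sex-specific with half-open upper bounds — women (0,7] light, (7,14]
  moderate, >14 heavy; men (0,10], (10,21], >21; 0 units = abstainer.
- **BMI**: weight/height², upper-inclusive bins ≤20 / (20,25] / (25,30] / >30.
  Whether exactly 20.0 is underweight or normal is ambiguous in the source
  material; we take ≤ 20 as underweight.
- **Adversity scales** (4 neighbourhood, 3 housing items): any observed
  adverse flag → "one or more"; fully observed zeros → "none"; otherwise the
  ≥1 detector is unresolvable → missing.
- **Life events**: 0 / 1 / ≥2 of a nine-item inventory.

Item non-response is kept as an explicit `missing` category in every factor
(missing-as-category); only missing adulthood SEP excludes a participant.

## Follow-up

Follow-up runs from baseline (1991-04-01) to the register linkage date
(2007-10-15), 16.54 years at 365.25 days/year. CVD death (ICD-9 390–459,
ICD-10 I00–I99) is the event; other-cause death, emigration and survival to
the end censor (cause-specific hazard — competing-risks estimands are out of
scope). Deaths dated on baseline get half a day of follow-up so times stay
positive. Analytic-sample exclusions: age < 40 at baseline (exactly 40
retained), self-reported severe heart problems / heart attack / stroke in
the preceding five years, missing education; the tally reports per-criterion
counts and their overlap.

## Model sequence and factor screening

Seven sex-stratified Cox models, all with continuous linear age:

1. adulthood SEP; 2. + childhood SEP; 3. + material factors; 4. +
behavioural factors; 5. + psychosocial factors; 6. + all three adulthood
blocks; 7. + everything including childhood SEP.

A candidate risk factor enters its block only if (a) its substantive levels
improve a Cox model already containing age, childhood SEP and adulthood SEP
(likelihood-ratio test, df = substantive levels − 1, the missing dummy kept
in both fits so the test never rides on non-response), and (b) its
distribution varies by adulthood SEP (Pearson chi-square with the missing
level excluded); both at α = 0.05 (configurable). Missing categories are
always estimated but never drive selection.

Estimation is Newton–Raphson maximization of the partial likelihood with
Breslow tie handling by default (the convention of the statistical software
the analysis design assumes) and Efron selectable. The solver
(`cvdineq._cox`) is vectorized (suffix sums over the ascending-time sort;
the information matrix uses the cumulative-hazard weighting identity) so a
study-sized fit costs ~30 ms — a requirement of the bootstrap below. It is
validated against statsmodels (Breslow), lifelines (Efron) and a brute-force
partial-likelihood maximization on a small fixture. Dummy levels whose
carriers have no events are dropped from a fit (their ML coefficient is
−∞ and they carry no hazard information); Wald 95% CIs; convergence requires
the score to vanish at the optimum; coefficients beyond |β| > 15 are treated
as separation.

## Attenuation, bootstrap, decomposition

For each SEP level with base hazard ratio HR₁ from model 1 and adjusted HR_k
from model k:

    attenuation% = 100 · (HR_k − HR₁) / (HR₁ − 1)

computed on the HR scale (the log-scale variant does not reproduce the
published worked examples). Display rounding is half-away-from-zero to
integer percent. Cells with |HR₁ − 1| < 0.05 (configurable) are flagged not
evaluable; rendered tables also print "–" where the rounded attenuation is
≥ 0, i.e. where adjustment did not move the HR toward 1 — matching the
publication convention of printing percentages only for attenuated cells.

The 95% interval around an attenuation is a bias-corrected accelerated
(BCa) bootstrap: participants are resampled with replacement within the
sex-specific analytic set, *both* models are refit per resample (the only
construction that propagates the joint sampling noise of the two HRs), and
the BCa endpoints use z₀ = Φ⁻¹(share of bootstrap values below the point
estimate) and the jackknife acceleration a = Σd³ᵢ / (6(Σd²ᵢ)^{3/2}).
Degenerate cases degrade with flags rather than fail: a one-sided bootstrap
distribution falls back to the percentile interval; zero jackknife variance
sets a = 0. The jackknife is exact leave-one-out up to n = 2000 and grouped
leave-k-out with ~200 seeded groups above (cost control; negligible effect
on a). Resamples with no events or non-convergent fits are discarded and
redrawn; more than 10% discards is a hard error. B = 1000 resamples is the
reference design; the bundled analysis drivers and acceptance script use
B = 200 to keep a full two-sex run in tens of seconds (the interval widths
are indistinguishable at the reported rounding).

The life-course decomposition takes the positive "percent explained"
magnitudes C (childhood only, model 2), A (adulthood factors only, model 6)
and T (everything, model 7):

    direct childhood  = T − A
    direct adulthood  = T − C
    indirect childhood (via adulthood factors) = C + A − T

which sum to T identically. Published footers use rounded inputs; the
package computes from unrounded attenuations and rounds last (both are
reported). The decomposition is arithmetic on fitted attenuations, not a
formal causal-mediation estimand; no bootstrap is attached to its
components.

## Synthetic cohort

The generator emulates the study population's structure, with the documented
facts as calibration targets and everything else chosen once as
field-plausible defaults:

- **Sizes and marginals**: 5,395 men / 6,306 women; adulthood-SEP marginals
  proportional to the explanatory-table group sizes (men 1270/1795/1088/1242,
  women 1961/3079/774/492, low→high); childhood marginals 0.55/0.30/0.15
  (blue/white/professional — plausible for fathers of a 1991 Dutch cohort
  recalling 1930s–60s occupations).
- **SEP association**: a Gaussian copula links the two ordinal indicators;
  its latent correlation is solved numerically (bivariate-normal rectangle
  probabilities + Brent root-finding on the midrank Spearman of the implied
  joint) to hit the target rank correlation 0.345. An unattainable target
  raises a config error naming the feasible bound.
- **Ages** uniform on [40, 75] (the analytic range); log-linear age effect
  0.08/year on the CVD hazard, 0.09/year on other-cause mortality.
- **Risk factors** are drawn on the raw questionnaire scale from logit (or
  latent-ordinal / normal-BMI) models with gradients in both SEP indicators,
  expressed per factor as coefficients (b_adult, b_child) on normalized
  adversity scores u ∈ [0, 1] (1 = lowest SEP). Intercepts were set so that
  current-smoking prevalence ≈ 42% (men) / 28% (women) and
  overweight/obesity ≈ 46% / 39%, the documented cohort rates.
- **Hazard effects** per coded level default to the published age-adjusted
  estimates (e.g. current smoking HR 1.85 for men, 1.87 for women; inactive
  1.71 / 2.09), plus modest direct (unmediated) SEP effects; the exponential
  baseline CVD hazards (1.40 × 10⁻³ men, 5.4 × 10⁻⁴ women per year at age
  57.5 for the reference pattern) were solved by the package's own
  deterministic calibration helper so that CVD death fractions over the
  16.54-year window land near 9.7% / 6.2%. Events are generated from the
  *true* exposure values; missingness (per-column rates of 0.5–8%, MCAR) is
  injected afterwards, so coding and modelling see realistic non-response.
- The resulting default cohort is qualitatively study-like — a low-SEP
  excess hazard largely attenuated by material and behavioural adjustment —
  but its marginal SEP gradient is somewhat steeper than the study's
  (model-1 low-SEP HR ≈ 2.1–2.9 across seeds vs 1.84 published): many
  moderate published per-factor effects stack multiplicatively with the
  configured gradients. Only the correlation and death-fraction targets
  above are calibrated; tests assert those, not the full joint distribution.
  What passing tests show is therefore that the *machinery* recovers known
  constructions, not that the generator matches the real cohort beyond the
  documented targets.

**Mediation scenarios** (`make_mediation_scenario`) rewire the config for
recovery tests, with three designated mediators (smoking, physical activity,
housing tenure): *null* — direct SEP effects only, covariates pure noise
(no gradients, no hazard effects), expected attenuation 0; *full* — no
direct effect, strong mediator gradients, expected attenuation −100%;
*partial* — both channels. For the partial scenario the implied attenuation
is computed from the coefficient construction itself (a covariate-only
Monte-Carlo estimate of E[exp(Σγx) | SEP level] ratios, no survival data)
and recorded in the config. Non-mediator covariates carry no hazard effects
in any scenario: strong nuisance effects would otherwise inflate the
conditional SEP hazard ratio upon adjustment (hazard-ratio
non-collapsibility) and bias the attenuation away from its construction —
the same phenomenon that makes the HR-difference method only approximately
a mediation estimand; with rare events and noise-free mediator blocks the
approximation error is well inside the recovery tolerances.

## Numerical choices and degenerate inputs

- Year length 365.25 days; dates ISO-8601; empty string = absent.
- Copula solve tolerance 1e-5 on the latent correlation; probability vectors
  validated to 1e-12.
- Cox convergence: max |score| < 1e-9 × events, damped Newton with
  step-halving; ties: Breslow default, Efron optional (Efron's loop is
  O(distinct event times × n p²) and intended for modest n).
- Bootstrap RNG: one `numpy` `default_rng` per call, fully seed-determined;
  reruns with the same seed are bit-identical.
- `boot = 0` runs the pipeline without intervals and flags the output.

## Known limitations

- Attenuation percentages on the HR scale are unstable when the base HR is
  near 1; such cells are flagged rather than reported, and bootstrap
  replicates can still be heavy-tailed when resampled base HRs approach 1
  (the BCa interval absorbs this but widths become large, as the published
  middle-SEP columns also show).
- The decomposition is bookkeeping over nested-model attenuations; it
  inherits non-collapsibility and is not a natural direct/indirect effect.
- The generator draws risk factors independently given SEP; real factors are
  mutually correlated (e.g. smoking × alcohol), which mainly affects how
  much attenuation overlaps between blocks.
- Proportional-hazards diagnostics, frailty, time-varying effects and the
  occupational-class crosswalk are out of scope.
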