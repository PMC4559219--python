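# Methods

This note documents the statistical procedures the package implements,
the assumptions behind them, the free parameters of the synthetic data
generator, and the numerical choices made where the design was open.

## Case ascertainment from claims

Claims are modelled on a person × calendar-quarter grid; quarters are
the atomic time unit and no within-quarter dates exist. "Permanently
enrolled" means all four quarter flags set for the year; only such
person-years enter denominators (partially enrolled person-years are
retained but flagged ineligible, never silently dropped).

A *diabetes-related claim* is any ICD-10 code beginning E11, E12 or
E14. E10 (type 1) is excluded by design; E13 is excluded because it is
commonly used for pancreoprive diabetes, which is pathophysiologically
closer to type 1. Both still count for *control* exclusion, which uses
the full E10–E14 range. Code matching is prefix-based on the
three-character category, except explicitly subdivided codes (N08.3,
H36.03 in the comorbidity lists) which match at their stated precision.

Prevalent-case rules, evaluated per person-year in fixed bookkeeping
order (case status itself is order-invariant, which the test suite
asserts):

1. diabetes-related claims in ≥ 3 of 4 quarters;
2. antidiabetic prescriptions (ATC A10A/A10B) in ≥ 2 quarters;
3. ≥ 1 prescription together with ≥ 1 diabetes-related claim.

Rule 3 in the source algorithm also admits a prescription combined with
a glucose/HbA1c laboratory billing position; laboratory billing codes
are not representable in this data model, so that arm is not
implemented (a documented limitation, not a switch).

**Incidence.** A case in year *Y* is incident if the person was fully
enrolled in *Y−1* with *neither* a diabetes-related claim *nor* an
antidiabetic prescription then. Requiring absence of prescriptions is a
deliberate reading of "any diabetes-related claim": a prescription alone
qualifies a person as a case, so a drug-treated diabetic of *Y−1* must
not count as incident in *Y*. The incidence denominator is the matching
at-risk population — fully enrolled in both years and claim- and
prescription-free in *Y−1*.

## Standardization, trend, SPR

Strata are 5-year age bands with a wide 0–19 first band and an open 75+
band, crossed with sex; age is calendar year minus birth year (no birth
dates in the model). Direct standardization uses

p = Σ w·p_as,  Var(p) = Σ w²·p_as(1−p_as)/d_as,  CI = p ± 1.96·√Var,

treating stratum case counts as independent binomials; the CI is
truncated to the admissible range and no continuity correction is
applied (standardized CIs on large cohorts are symmetric and narrow).
The standardized estimate is invariant to uniform scaling of reference
counts and bounded by the extreme stratum rates; the variance formula is
checked against a stratum-binomial bootstrap in the test suite. By
default each analysis year is standardized on that year's reference
table; a `fixed:<year>` mode pins one table for sensitivity analyses.
When no external reference is supplied the cohort standardizes on
itself, making standardized = crude — the default test path.

The Cochran-Armitage trend test uses equally spaced integer scores per
calendar year on the crude (cases, denominator) pairs; all-zero or
all-full tables are reported as degenerate (Z = 0, p = 1) rather than
raising. The standardized prevalence ratio is the ratio of two
standardized prevalences computed on identical weights, with the
log-normal CI exp(ln SPR ± 1.96·√(Var₁/p₁² + Var₀/p₀²)). In pipeline
runs on small cohorts the reference is restricted to age-sex cells
populated in both strata so that both sides use the same weights.

District analyses standardize each district twice — on its own
population (local burden) and on the state reference (comparability) —
and optionally bin estimates into prevalence classes for mapping; map
rendering itself is out of scope, the per-district CSV is the product.

## Case-control design

1:1 matching within year on the analysis stratum (5-year band × sex);
exact single-year age matching is not attempted because grouped ages are
all the aggregated data supply. Controls are drawn uniformly without
replacement from fully enrolled persons without any E10–E14 code that
year; a control serves at most one case per year but may be reused
across years. Exhausted strata produce an explicit unmatched-case
report. The odds ratio is computed from the pooled 2×2 table with the
Woolf CI, not from a conditional pairs analysis: matching is accounted
for by design (controls reproduce the cases' age-sex margin exactly when
fully matched, asserted by test), and the pooled estimator is exactly
reproducible from the published prevalence pairs, which the acceptance
checks exploit. Zero cells get a flagged 0.5 continuity correction.

## Fractional-polynomial curves and the age shift

Age groups (adults only, 20+) are transformed to class-mean ages:
"a-b" → (a+b)/2 (so "20-24" → 22), and the open "75+" band → 80 years
by default (configurable; no authoritative value exists for the open
band's mean). Stratum prevalences at those ages are fitted by ordinary
least squares on the percent scale (numerical conditioning; the
semi-maximum age is scale-invariant, asserted by test), unweighted by
default because the fit targets aggregated rates; weighting by stratum
denominators is available.

Model selection is an exhaustive search over all 8 degree-1 and 36
degree-2 power choices from {−2, −1, −0.5, 0, 0.5, 1, 2, 3} (x⁰ ≡ ln x,
a repeated power p contributing x^p and x^p·ln x), keeping the
minimum-RSS candidate; exact RSS ties resolve to the simpler model. The
closed-test selection procedure of the original fractional-polynomial
literature is deliberately not used: exhaustive minimum-RSS is simpler,
reproducible, and sufficient for curve summarisation. R² = 1 − RSS/TSS
on the fitting points; a flat response (TSS = 0) is reported as R² = 1
with a degeneracy flag.

The curve maximum is taken over the *fitted* curve on the fitting
domain (dense 2001-point grid plus bounded local refinement), not over
the observed points — the statistic intersects the fitted curve. The
semi-maximum level is half that maximum; the reported age is the
leftmost crossing on the rising limb (left of the argmax), solved with
Ridders' bracketing root finder (exponential correction to false
position; bracket tolerance 1e-12, ≤ 100 iterations — the test suite
checks it against bisection to 1e-6 and better). If the curve already
exceeds the level at age 20 the crossing lies below the analysis
domain and the result is "NC" (not calculable), as is any stratum
without a rising-limb crossing. The age shift is
round(age_without − age_with) to whole years, half-up; NC propagates.

## Synthetic claims generator

The generator emulates the structure the analysis assumes, with one
global seed feeding named substreams so the latent truth table can be
regenerated without rebuilding claims. Defaults are fixed study
conditions, not tuning knobs:

* cohort observed 2007–2010, 47 % male, age distribution resembling a
  large statutory insurer, 4 districts;
* T2DM prevalence by age rising from 0.2 % (0–19) to 28 % (75+),
  crossing 5 % in the early 50s and ~15 % at 60–64;
* per-quarter probability 0.85 that an active diabetic's quarter carries
  a diabetes code (`coding_completeness`); the per-quarter coding
  probability of real physicians is unreported, so this is a free
  parameter, documented as such;
* a persistent per-person code style drawn once from
  E11 / E14 / both / E10 / E13 with probabilities .42/.14/.38/.04/.02 —
  chosen so multiple coding and "E14 alone" shares resemble observed
  coding-pattern reports; E10/E13 styles create realistic
  under-ascertainment since those codes never qualify;
* 55 % of diabetics drug-treated, receiving an A10B prescription in any
  quarter with probability 0.75 (chronic-therapy refill cadence; free
  parameter);
* 12 % of person-years lose full-year enrollment (matching ~88 %
  permanently insured), implemented as truncated leading enrollment
  spells;
* comorbidity status drawn per person-year from logistic age curves
  asymptote/(1+exp(−slope·(age−midpoint))) with separate parameters for
  persons with and without T2DM; default midpoints and semi-maximum
  levels echo claims-based surveillance estimates (e.g. hypertension
  60.5/40.3 years). Draws are independent across years — no
  within-person persistence of chronic disease — which matches the
  per-year cross-sectional analyses but understates within-person
  correlation over time;
* optional per-district multipliers on the T2DM prevalence curve create
  a regional gradient for district-analysis tests.

The reference population defaults to the cohort's own baseline age-sex
counts. Because the cohort is closed and ages while individual disease
status is drawn once at baseline, multi-year standardized series drift
slightly downward relative to the crude series — an artifact of the
closed design that a yearly refreshed insured population does not have,
and one reason recovery tests use single-year cohorts.

What passing tests therefore show: the estimators and rules are
arithmetically correct, deterministic, and recover known truth under
the generator's assumptions (independent binomial strata, logistic age
curves, quarter-level coding). What they do not show: robustness to
miscoding correlated within practices, enrollment gaps shorter than a
quarter, secular coding drift, or regional coding culture — none of
which the generator models.

## Problem sizes and numerics

Recovery tests use cohorts of 4 000–100 000 persons: 50 000 for
ascertainment error rates and generator-curve convergence (3–3.5
binomial SEs), 100 000 for the end-to-end semi-maximum shift recovery
(tolerance ±2 years around the configured 20), 100 000 per year for
trend detection at the published effect size, 1 000 bootstrap
replicates for the variance check (10 % relative tolerance). These
sizes give comfortable statistical resolution for the stated tolerances
while keeping the default suite fast. Least-squares fits use
`numpy.linalg.lstsq` with rank checking; singular candidate designs are
skipped, and an error is raised only if every candidate is singular.
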