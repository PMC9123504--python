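# Methods

This note documents the models, parameters, calibration machinery, and
numerical choices behind `prostasim`, and what the synthetic fixtures do and
do not emulate.

## Population and other-cause mortality

The simulated population is a male cohort resembling the Bahamas around
2020: 70 440 men aged 40–84 at baseline (counts declining exponentially
with age at 3%/year of age, rounded by largest remainder so the total is
exact), plus a constant stream of entrants at exact age 40 on January 1 of
each year 2021–2040, equal to the baseline count at age 40 (2 810/year).
Birthdays fall on January 1, so a man's integer age is constant within a
calendar year; this makes person-years exact and cheap.

Other-cause mortality comes from a Gompertz–Makeham lifetable,
q(a) = 1 − exp(−(λ + α·e^(γa))) with λ = 8×10⁻⁴, γ = 0.09 and α solved by
root bracketing so life expectancy at birth is 75.0 ± 0.5 years. The
published-table situation — annual probabilities ending at 84 — is emulated
by truncating at 84 and extending with Holt–Winters double exponential
smoothing (additive trend, no seasonality) applied to the log hazard
−log(1−q) over the observed tail (ages 60–84). Working on the log hazard
guarantees positive forecasts; a perfectly log-linear hazard is continued
exactly. The table is closed at 95 (q = 1): every life is finite. Within a
year of age, death times are uniform. The lifetable is held constant over
calendar time.

## Natural history

Latent onset has a piecewise-constant hazard over 5-year bands from age 35
(0.002/yr at 35–39 rising to 0.028/yr at 75+), giving ~72% lifetime latent
prevalence by the age cap of 100 — consistent with the high latent burden
autopsy studies report in elderly men. Both variants share this onset model;
their parameter values are documented stand-ins in the spirit of published
prostate-cancer microsimulation models, not fits to proprietary data.

**Variant P (progression-based).** A continuous-time Markov chain over
(stage, grade): stages cT1 → T2 → T3 → metastatic at rates
(0.08, 0.10, 0.12)/yr, grades ≤6 → 7 → ≥8 at (0.04, 0.05)/yr, and a
clinical-diagnosis clock with rate λ_dx(stage, grade) increasing from
0.008/yr (cT1, ≤6) to 0.5/yr (metastatic). Grade at first appearance is
age-independent (0.85, 0.12, 0.03); the age–grade correlation emerges from
progression. Progression is deliberately independent of PSA; the PSA
observed at a test is a lognormal draw conditional on (stage, grade)
(medians 2→40 ng/mL, σ_log = 0.7), with a benign age-growing distribution
(median 0.7 ng/mL at 35, +1.5%/yr, σ_log = 0.55) for cancer-free men.

**Variant F (PSA-linked).** Grade is fixed at onset, drawn from onset-age
band mixes that weight high grade more at older onset. Each man's log-PSA
is linear in age with slope 0.02/yr before onset, plus a grade-specific
additional slope (0.10, 0.15, 0.22)/yr after onset and a per-person frozen
Gaussian level shift (σ = 0.45) — so repeated tests on one man are
perfectly correlated. Diagnosis and metastasis hazards are linear in the
current PSA level (0.02 and 0.004 per ng/mL·yr). Event times are drawn by
exact inversion of the piecewise exponential-growth cumulative hazard; a
zero growth rate falls back to the constant-hazard path.

Both samplers are vectorized with a shape-deterministic draw stream: every
step consumes fixed-size arrays regardless of how many men remain active,
so two runs with the same seed and cohort size consume identical
randomness even under different parameters — the common-random-numbers
contract the calibration relies on.

Baseline men's histories are simulated from age 35, so some are already
clinically diagnosed at baseline (prevalent cases): they are not incident
events, are never screened, and their cancer-death clock restarts at
baseline, which is the exact conditioning on being alive given exponential
survival (memorylessness). That the pyramid slightly over-represents
prevalent disease relative to a fully renewal-consistent population is a
known simplification.

## Screening

A strategy is a list of protocol ages; a test happens in the calendar year
a man reaches that age if it falls in the program window (2022–2040) and
he is alive, undiagnosed, and attends (default 100%). PSA strictly above
the threshold (default 10 ng/mL) triggers a biopsy; biopsy finds existing
cancer with 80% sensitivity and records the true current stage and grade
(no grading error). False-positive biopsies are counted as resource use.
Only diagnosis ends participation — a negative biopsy does not. Detection
is instantaneous.

Overdiagnosis follows the counterfactual definition: a detection in a man
whose no-screening arm contains no clinical diagnosis before death. For
all other detections the lead time is the counterfactual diagnosis age
minus the test age.

## Survival and the two benefit mechanisms

Cancer-specific survival after diagnosis is exponential per (stage class,
grade), with stand-in medians of (14, 9, 5) years localized and
(3.5, 3, 2) years metastatic — an intentionally simple parametric form for
pre-screening-era survival of untreated men; the mortality calibration's
common scale factor absorbs the approximation. Curative treatment
(localized, Gleason ≥8 only, in both arms) multiplies the hazard by 0.55
(proportional hazards: treated survival is the baseline curve to the power
0.55).

*Cure rate*: a screen-detected, non-overdiagnosed man is cured with
probability 1 − e^(−β·lead); cured men never die of prostate cancer, and
uncured men die exactly when they would have without screening, so with
β = 0 screening saves no lives, exactly. *Stage shift*: a man who would
have been diagnosed metastatic without screening but was detected while
localized draws survival from the detected state (treatment rule applied
to that state), anchored at the counterfactual diagnosis age — lead time
itself confers nothing. The scope flag `shift_scope="any_earlier"` extends
the shift to any strictly earlier state; it is off by default because a
grade-only shift into the treated category can, in corner cases, shorten
survival relative to the untreated counterfactual state and violate the
"screening never increases mortality" guarantee.

Overdiagnosed detections receive no survival benefit and cannot die of
prostate cancer in either arm; their treatments (if the rule matches) are
counted as resource use.

## Calibration

Three stages in a fixed order, each conditioning on the last. All
objectives are deterministic functions of the parameters given the master
seed (common random numbers), so derivative-free searches see no noise.

1. **Incidence.** Only the diagnosis-hazard block moves: three multipliers
   on λ_dx over current-age bands <55, 55–69, 70+ (applied to
   λ_dx(stage, grade) in variant P and to the PSA→diagnosis coefficient in
   variant F). The objective is the summed squared relative error of
   simulated lifetime age-group incidence (events and person-years
   accumulated within 40–54, 55–69, 70–84 over a pyramid-weighted cohort
   followed from baseline to death) against the targets. Nelder–Mead,
   warm-started at the log ratio of targets to first-pass rates with a
   0.3-step initial simplex. Failure to bring any group inside 10% is
   flagged in the report, not raised. Self-calibration (targets generated
   from known multipliers under the same seed) recovers the multipliers to
   well within 5%.
2. **Mortality.** A single scale on all cancer-death hazards is rooted
   (Brent) so the no-screening age-standardized mortality among men 40–84
   in 2040 equals the anchor, 154.5 per 100 000. The response statistic is
   the *expected* ASR given each simulated history — the exponential death
   time is integrated out analytically (conditional Monte Carlo) for both
   the death count and the person-years — which makes the response smooth
   and monotone in the scale where the realized single-year count is a
   jagged step function (~170 deaths at default scale). Realized and
   expected statistics agree in expectation; the realized one is retained
   for reporting.
3. **Cure slope.** β is fitted so a reference trial-like scenario — a
   cohort aged 55 at program start, tests every 4 years at 55/59/63/67,
   threshold 3 ng/mL — yields a cumulative prostate-cancer mortality rate
   ratio of 0.80 over 13 years of follow-up. Under common random numbers
   each detected savable man flips from died to cured at an exact threshold
   β_i = −log(1−u_i)/lead_i, so averted deaths are a step function of β and
   β is placed between the order statistics bracketing the required count.
   A fresh-seed confirmation run is included in the fit report.

Default budgets: 2×10⁵ life histories per incidence evaluation, 3×10⁵ for
the mortality world, 2×10⁵ for the reference cohort. The full three-stage
calibration runs in well under a minute on one CPU.

## Outcomes

Rates are directly age-standardized to the simulated 2020 population aged
40–84 (the baseline pyramid). Screen detections count as incident cases in
their detection year, producing the expected incidence spike at program
start. Lives saved require a cause-of-death flip (prostate-cancer death
averted); a delayed cancer death contributes only to life-years gained,
which are summed over all paired differences in death ages and attributed
to screening regardless of when after 2040 they accrue. The
treatments-per-life-saved ratio uses *additional* (screening-attributable)
treatments; both arms' totals are emitted. Diagnosis conservation —
screened-arm diagnoses equal no-screening diagnoses plus overdiagnoses —
holds exactly per seed by construction.

## Synthetic fixtures: what they emulate, and what they do not

The incidence targets (60, 600, 1400 per 100 000 person-years for 40–54,
55–69, 70–84) are plausible for a high-incidence Caribbean population of
mostly African ancestry; the mortality anchor (154.5 per 100 000) pins the
no-screening 2040 level; the screening-cohort sample (4 300 men, median
first-test age 54, right-skewed lognormal attendance ages clipped to
40–84) is drawn from the packaged model itself, so validation comparisons
(`validate_screening_profile`) are self-consistency checks with binomial
3-SE bands, not external validation. Passing them shows internal coherence
of the pipeline, not fidelity to any real screening program: the fixtures
contain no attendance selection effects, no site heterogeneity, no digital
rectal examination pathway, and no secular trends.

Two quantitative consequences of the fixture design are worth recording.
First, with the 2020 pyramid as the standardization standard and the
anchored 2040 mortality, lifetime prostate-cancer deaths of the 2022–2040
population without screening center near 9 500 — the level is sensitive to
the (unstated-in-principle) choice of standard population and to the
stand-in incidence levels. Second, under cohort-wise screening that runs
through 2040, the screened-minus-unscreened incidence difference after the
initial spike decays toward the annual overdiagnosis rate, which is
positive; a sustained crossing below the no-screening curve within the
projection window is not a structural prediction of this design (test
yields only deplete when a second test age revisits an already-screened
birth cohort).

## Numerical choices and degenerate inputs

Ages are capped at 100 in the natural-history samplers; the closed
lifetable ends lives by 95 regardless. Hazard inversions walk band
segments with `cumsum`/`argmax`; zero rates simply never accumulate
hazard. Lifetables must be closed before vectorized death sampling.
Strategies validate ages to [40, 84] and probabilities to [0, 1]; ties at
the biopsy threshold do not trigger biopsy (the rule is strictly greater).
Zero lives saved makes harm-benefit ratios "undefined" (a sentinel, never
infinity). Unknown keys in parameter files are rejected outright.

## Problem sizes used in tests

The test suite calibrates at 6×10⁴ histories per evaluation and exercises
populations between a few thousand and the full 126 640 (baseline plus
entrants); the acceptance checks use 2×10⁵-history calibration, the full
population for absolute counts, and 4–6× population multiples where a
ratio or rate benefits from variance reduction (ratios are scale-invariant
in the population multiplier). The whole suite runs in a few minutes on
one CPU.
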