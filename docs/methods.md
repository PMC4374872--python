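# Methods

This note documents the models and procedures implemented in `sugarkit`,
the parameter choices that matter, and what the synthetic-data generator
does and does not emulate.

## The challenge protocol as implemented

Time is measured in integer minutes from the first (fasting) sample.
The expected glipizide schedule is {0, 30, 60, 90, 120, 180, 240} and the
OGTT schedule {0, 30, 60, 90, 120}, but schedules are data: every reader
and derivation accepts any strictly increasing schedule starting at 0, and
nothing is ever interpolated to unsampled times (in particular not to 150
or 210 minutes, which the protocol does not collect).

The termination engine scans post-baseline times in order and stops at the
first rule violation, truncating the series inclusively — which makes it
idempotent. Rule priority is: neuroglycopenic symptoms; then glucose
≤ 2.77 mmol/L *with* hypoglycemic symptoms (inclusive bound); then glucose
< 2.50 mmol/L regardless of symptoms (exclusive bound). A baseline below
the 4.44 mmol/L dosing gate yields a `not_dosed` outcome and no endpoint
derivation. Neuroglycopenia is driven purely by the recorded symptom flag
(clinical judgement is not computable from the data), and staff-discretion
stops are representable only through an explicit override field, never
inferred. Completed challenges carry `termination_time = 240`, so "early
terminator" is the pure predicate `termination_time < 240`.

## Endpoints

Trough/peak search excludes time 0: baseline is the reference the endpoint
is measured against, and a trough at baseline would make Δ(0→trough)
degenerate at 0. Ties break to the earliest time, since discrete schedules
make exact ties possible.

"Adjusted for baseline" has two legitimate operationalizations and both
are kept, recorded per endpoint in the table's provenance metadata:

- **area endpoints** subtract baseline × interval length from the
  trapezoid area (`auc_trapezoid(..., baseline_adjust=True)`), and the
  area over the glucose curve is `AOC(t) = G₀·t − AUC(0,t)`;
- **scalar endpoints** (trough, time-to-trough, insulin peak, glucose at
  120, insulin at 60, and the Visit-2 fasting values) are residuals of a
  cohort-level OLS fit on the corresponding baseline value, so they exist
  only after a cohort pass and have mean 0 within it.

The counter-regulatory slope, (G₂₄₀ − G_trough)/(240 − t_trough), is
absent for rescued participants (oral carbohydrate would contaminate the
endogenous recovery signal), for early terminators, and when the trough
falls at 240 minutes (zero denominator). Endpoints whose time window
extends past a truncated series are absent, never extrapolated: a 60-min
terminator has no Δ(0→90), no 0–120 area, and no 0–240 insulin area. The
baseline-adjustment status of the 0–240 insulin area is ambiguous in the
endpoint menu, so both variants are emitted.

Deltas are consistently *later minus earlier* (Visit 2 − Visit 1,
time t − time 0), so a glucose drop or a metformin response is negative.

## Insulin-sensitivity indices

HOMA-IR is glucose [mmol/L] × insulin [pmol/L] / 22.5. Keeping insulin in
pmol/L (rather than converting to µU/mL) is deliberate: it is the only
convention consistent with the index's published cohort units
(mmol·pmol/L²) and magnitudes (~8 at typical fasting values).

The Matsuda index is 10000/√(FG·FI·meanG·meanI) in mg/dL and µU/mL; the
package converts from mmol/L (× 18.016) and pmol/L (÷ 6.0). The insulin
conversion factor is assay-dependent; 6.0 is the conventional
radioimmunoassay value and is a configurable argument. OGTT means are
unweighted over the schedule including time 0.

## Comparisons

Paired and two-sample contrasts are t-tests with 95% confidence intervals;
the two-sample test pools variances. Traits configured as non-normal
(defaults: insulin, HOMA-IR, glucagon, proinsulin; glucose untransformed)
are compared on the natural-log scale, and the reported paired estimate is
then the mean paired log difference — its exponential is the
geometric-mean ratio. Which traits are log-transformed is configuration,
not an automated normality test. Pairs missing either side are dropped;
nothing is imputed. Exactly identical paired vectors return a 0 difference
with a logged zero-variance warning rather than NaN; degenerate
single-value groups return the mean difference with NaN inference, which
is what makes contrasts of two printed group means expressible.

## Genetics

Risk scores are unweighted allele-count sums — no effect-size weighting.
The default missing-call policy leaves a participant's score absent if any
panel call is missing; rescaling to the full panel size or per-SNP
mean-imputation are available behind explicit options and flagged in the
score's provenance by the caller. Association models are OLS with additive
genotype coding; ethnicity enters as indicators against a
non-Hispanic-White reference (the largest group), or defines strata fitted
without the ethnicity covariate. Strata with fewer than 10 complete cases
are skipped with a warning. No multiple-testing correction is applied by
default. The shipped 34+14 panel (`genetics.synthetic_panel`) is a
synthetic stand-in with generated identifiers; a real panel is user data
supplied as `panel.tsv`.

## Power

The 1-df noncentral chi-square parametrization (λ = n·r²/(1−r²)) was
chosen because it is the standard large-sample form for a variance-
explained association test; it reproduces 89%/99% power at n = 1000 for
r² = 0.01/0.05 at α = 0.05. The variant's population frequency is
irrelevant in this mode (the parametrization absorbs it) and is accepted
with a logged note. `power_variance_explained_finite` gives the exact
noncentral-F power of the finite-sample slope t-test; it is the reference
used when validating the Monte-Carlo oracle, since at n of a few hundred
it sits visibly (≲0.01) below the asymptotic value. r² = 0 returns α
exactly.

For the effect-difference mode the tested trait is the difference of two
standardized endpoints with correlation ρ, var(D) = 2(1−ρ); the default
ρ = 0 is exposed in configuration because no assumed correlation is
stated for the cross-challenge question. At n = 1000, ρ = 0, MAF 0.05 and
an effect difference of 0.45, the analytic power is ≈0.87; the module
reports its assumptions alongside the value rather than asserting any
particular printed figure, since the n and ρ behind such figures are not
fixed by the design.

The Monte-Carlo oracle simulates Hardy-Weinberg genotypes (MAF 0.3 in
variance-explained mode, where frequency is immaterial), adds the implied
per-allele effect to a unit-residual-variance phenotype, and runs the
closed-form OLS slope t-test vectorized over replicates.

## The synthetic cohort generator

The generator's defaults are the study conditions:

- **Demographics.** Ethnicity weights 436/133/45/39 over non-Hispanic
  White / non-Hispanic Black / Hispanic / Asian; per-group normal age and
  BMI (e.g. NHW 50.9 ± 16.4 years, 31.0 ± 7.3 kg/m²); 47.5% male.
- **Genetics.** Hardy-Weinberg genotypes, independent SNPs (no linkage
  disequilibrium), effect-allele frequencies spread over ≈(0.25, 0.81)
  and centered so the expected scores match the observed medians
  (36/68 glucose, 15/28 insulin).
- **Visit-1 biochemistry.** Fasting glucose 5.27 ± 1.06 mmol/L plus an
  additive 0.0256 mmol/L per glucose-risk allele (centered at the panel
  expectation); fasting insulin log-normal with median 36.1 pmol/L plus
  0.078 pmol/L per insulin-risk allele.
- **Glipizide response.** Dosed participants get glucose = baseline −
  amplitude × k(t) with k a Gaussian bump (width 60 min) re-anchored to 0
  at t = 0 and 1 at the drawn trough time (modal 120 min), plus 0.08
  mmol/L measurement noise; insulin rises by a log-normal amplitude
  (median 220 pmol/L) peaking modally at 60 min. Hypoglycemic symptoms
  are Bernoulli given the glucose band (0.35 below 2.77 mmol/L, 0.08 in
  (2.77, 3.3], 0 above); neuroglycopenia has probability 0.02 below 2.77.
  The drop amplitude Normal(2.45, 1.05) mmol/L is calibrated so ~30% of
  dosed participants hit a stopping rule before 240 min (a 5-seed scan at
  n = 5000 gives 28.2–31.9%, mean 30.4%). Every early terminator is
  rescued with carbohydrate by default; the flag is independent in the
  data model and the policy configurable.
- **Metformin / Visit 2.** Dose compliance 26/6/10/21/546 over 0–4 doses;
  94.8% attendance; treated fasting glucose shifts by −0.23 mmol/L (SD
  0.55 between visits), treated fasting insulin by −0.19 on the log
  scale. The OGTT adds a Normal(3.5, 1.2) mmol/L glucose excursion
  peaking modally at 60 min on the same bump kernel.

Positivity floors (0.5 mmol/L on fasting glucose, 1.5 mmol/L within
challenge trajectories) sit far below the distributions' support so they
cannot truncate tails and bias configured effects.

**What the generator does not emulate.** Fasting glucose is normal,
whereas the enrolled distribution is right-skewed (diabetes-enriched);
consequently ~20% of simulated participants fall below the 4.44 mmol/L
dosing gate versus ~2% observed — the early-termination calibration is
conditional on being dosed and unaffected, but absolute "not dosed" counts
are not comparable. There is no pharmacokinetic model of drug
concentrations, no glucagon/incretin dynamics, no linkage disequilibrium
or population structure beyond the declared ethnicity covariate, and no
dependence of the glipizide response amplitude on genotype. Passing tests
therefore demonstrate that the pipeline recovers the structure it is told
to generate — endpoint arithmetic, censoring contracts, score/association
algebra, calibrated stop-rule behavior — not that real cohorts satisfy
these distributional assumptions.

## Numerical choices and problem sizes

All randomness flows from a single integer seed per run;
internally-derived seeds come from `numpy.random.SeedSequence` spawning.
Areas use `numpy.trapezoid`; residuals use least squares via
`numpy.linalg.lstsq`; association fits use `statsmodels` OLS. Floating
comparisons in the identity AOC + AUC = baseline × t hold to 1e-9
relative. Test-suite simulation sizes — 5000 participants for calibration
checks, 200 replicates for parameter recovery at n = 527, 500 replicates
for type-I calibration, 2000 replicates per cell of the power grid — keep
the full suite under a minute while leaving the binomial bands meaningful.

## Known limitations

- The Δ(0→90) endpoint for a 60-minute terminator is absent by contract;
  carrying the last observation forward was rejected as imputation.
- The per-endpoint choice between subtraction and residual adjustment for
  "baseline adjusted" is a convention; both paths are exposed and tagged.
- Comparisons assume independent (or paired) sampling; no mixed models or
  repeated-measures covariance beyond pairing.
- The ethnicity F-test treats declared ethnicity as the structure
  covariate; genetic principal components are out of scope.
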