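# Methods

## Problem setting

Administrative health data — a cancer registry, hospital discharge
abstracts, ambulatory-care records and laboratory feeds — record the dated
diagnostic milestones a colorectal cancer (CRC) patient accrues before
diagnosis: fecal immunochemical tests (FIT), primary-care blood work (iron,
ferritin, MCV, hemoglobin), colonoscopies, colorectal surgeries, abdominal
CT scans, and coded symptom diagnoses (rectal bleeding K625/K552/K922,
abdominal pain R100–R104, unexplained weight loss R634, change in bowel
habits R194, bowel obstruction K566; colonoscopy CCI 2NM70/2NM71/2NQ70/
2NQ71; surgery 1NQ87/1NQ89/1NM87/1NM89/1NM91; CT 3OT20). The default code
table also accepts the transcription variant "INM87" for 1NM87 seen in some
published code lists. During the first COVID-19 wave these pathways were
disrupted — screening paused, endoscopy suspended — and the analysis here
measures that disruption and supports recovery planning.

## Cohort construction

Adults (≥18) diagnosed within the study window are linked to all milestone
events from `diagnosis_date − lookback` to `diagnosis_date`, both ends
inclusive (lookback default 365 days; the boundary convention is a package
choice, since "the year prior" does not pin down inclusivity). Events dated
after diagnosis are dropped with a warning; events with codes outside the
table are retained in files but ignored by analysis. Patients with multiple
CRC diagnoses contribute one, selected uniformly at random under the run
seed. Patients with no milestone in the window are excluded (they carry no
interval information and would skew estimates). Diagnoses on or before the
pre/intra cutoff (default 29 Feb 2020; 4 Mar 2020 available as an
alternative convention for jurisdictions dating the period from the first
reported case) are pre-pandemic, later ones intra-pandemic.

## Pathway classification

A pathway is defined by its initiating event: the earliest FIT
(screening), blood test (primary-care blood-test pathway) or
symptom/obstruction diagnosis (symptomatic pathway) in the lookback
history. Histories containing only procedures are unclassified. Same-day
ties resolve by the fixed priority FIT > blood test > symptom. This
earliest-initiator rule is deliberately simple: it matches the clinical
reading of "pathway initiated by…" and, on realistic inputs, leaves a
procedure-only stratum of roughly a quarter of patients unclassified. PCA
on the per-patient milestone count matrix — columns standardized,
correlation matrix eigendecomposed, components with eigenvalue ≥ 1
retained (Kaiser), varimax then promax rotation — is provided as a
diagnostic for refining the taxonomy; assignment itself stays rule-based
so it is auditable. Promax uses power 4 (the conventional default) with
the element-wise target sign(v)·|v|⁴ defined as 0 at v = 0, which keeps
perfectly block-structured matrices well posed. A chronology check reports
the fraction of expected template milestone pairs (initiator →
colonoscopy → surgery) observed in nonnegative date order.

## Intervals

`pairwise_interval` measures first-from-event to first-to-event on/after
it; this first-to-first convention reads the interval as the wait from the
initiating test, and by construction never returns negative values. The
total interval runs from the earliest milestone to the diagnosis date.
Symptom boundaries pool all symptom/obstruction categories. Summaries are
the sample median (midpoint for even n), IQR via linear-interpolation
quantiles (a convention choice, documented so printed IQRs are comparable
across software rather than bit-matched), and a percentile bootstrap for
the median's 95% CI (default 5000 replicates, seeded; values are sorted
before resampling so the CI is invariant to input order). The percentile
bootstrap was chosen over BCa for transparency; for a median on several
thousand observations the difference is negligible. Pre/intra pathway-mix
shifts are summarized per group as the pre-count-weighted average of
sub-pathway proportion differences (negative = decline during the
pandemic).

## Severity model

Staging is typically unavailable in fresh registry data, so diagnosis
during a hospital admission — an inpatient colonoscopy, surgery or CT
dated exactly on the diagnosis date (a ±k-day window is configurable,
default 0) — proxies severe presentation. Relative risks come from
modified Poisson regression: a Poisson GLM with log link fit to the binary
outcome (via IRLS in statsmodels, convergence tolerance 1e-10, max 100
iterations) with the HC0 sandwich covariance (bread = inverse Fisher
information, meat = summed score outer products, no small-sample
correction — appropriate at cohort sizes in the thousands). For a
saturated binary-exposure model the sandwich SE has the closed form
sqrt((1−p₁)/(n₁p₁) + (1−p₀)/(n₀p₀)), which `unadjusted_rr` implements
directly and the test suite uses as an independent oracle against the GLM
route. Age enters as a continuous per-year term; no clustering of standard
errors is applied.

## Backlog scenarios

The scenario engine assumes colonoscopy is the binding bottleneck: a
fraction f (default 0.856) of CRC patients is diagnosed via at least one
colonoscopy and no other constrained procedure, and a fraction y₀ (default
0.0166) of monthly colonoscopies yields a CRC diagnosis within 30 days
(attribution window inclusive of day 0 and day 30). Expected monthly
diagnoses are E_m = V_m·y₀/f; a scenario with capacity multiplier c and
yield y delivers D_m = V_m·c·y/f; the backlog follows
B_m = max(0, B_{m−1} + E_m − D_m). Using the same volume identity for both
E and D makes the steady state exact: at c = 1 and y = y₀ the backlog is
constant and the surge is identically zero. The recursion floors at zero
(a cleared backlog cannot go negative), which also makes the final backlog
monotone non-increasing in both c and y. `clearance_search` scans a
capacity × yield grid and reports clearing scenarios plus the
Pareto-minimal frontier. Capacity multipliers are plain scale factors: a
"140% increase" in common parlance is ambiguous between c = 1.4 and
c = 2.4, so the engine takes c directly and leaves the reading to the
caller. The 9-month default horizon reflects the clinical guidance that
colonoscopy more than 9 months after a positive FIT is associated with
higher odds of advanced-stage CRC.

## Synthetic registry generator

The generator emulates the linkage the analysis expects, with defaults
describing a large provincial CRC cohort during the first pandemic wave:
4.03% of diagnoses intra-pandemic; classified-pathway mix 31.2/47.4/20.5%
(screening/blood/symptom, renormalized) pre-pandemic and 15.9/46.1/38.2%
intra-pandemic (the cohort-level expression of suspended screening); 24.8%
unclassified; age from the six-band cohort distribution (18–39 … 80+),
57.3% male; cancer site 67/4/29% colon/rectosigmoid/rectum. Waiting times
are log-normal — right-skewed with positive support, the natural family
when only a median m and IQR q are known — with σ solved exactly from the
quantile identity q = 2m·sinh(σ·z₀.₇₅): FIT→colonoscopy (72, 86),
blood→colonoscopy (55, 95), symptom→colonoscopy (3, 31), CT→diagnosis
(7, 44) days; colonoscopy and surgery fall on the diagnosis date. Gaps are
clipped to the lookback window so every generated event is recoverable by
linkage. The hospital-diagnosis outcome is drawn from a log-link
(multiplicative-risk) model — baseline risk 0.18 at the reference patient
(male, age 65, pre-pandemic, no FIT, no obstruction) with RRs 1.24
(intra), 1.01/year (age), 1.05 (female), 0.47 (FIT), 2.88 (obstruction) —
so the configured RRs are exactly the estimands of the modified Poisson
stage; the generator errors if >1% of patients would exceed probability 1
(no capping occurs at the defaults). Outcome-positive patients receive an
inpatient procedure on the diagnosis date, so the flag reproduces the
latent outcome exactly. The procedure stream emits 8000 colonoscopies per
month — not an observed figure, but chosen so expected monthly diagnoses
(8000·0.0166/0.856 ≈ 155) match the cohort's diagnosis rate — with
first-wave capacity multipliers 0.5 (March), 0.0 (April), 0.5 (May), 0.8
(June–December 2020), and a 1.66% Bernoulli yield diagnosed 0–30 days
after the procedure.

What the generator does **not** emulate: referral and triage behaviour,
comorbidity, multi-initiator histories (each patient has one initiating
category, so classification fidelity on generator output is essentially
perfect — real data will be messier), interval shifts within the intra
period, tumour biology, staging or survival. Passing recovery tests
therefore demonstrates that the estimators are consistent for the
quantities the generator encodes, not that real registry data meet the
generator's assumptions.

## Problem sizes and numerical choices

Interval recovery uses 6000 screening-pathway patients and 5000 bootstrap
replicates; severity recovery uses a 50,000-patient cohort (roughly 2000
intra-pandemic patients, giving a robust SE near 0.035 on the log period
RR); yield recovery uses 12 months × 10,000 procedures; the convergence
property is checked at 5,000 vs 50,000 patients over 10 seeds. The
bootstrap resample matrix is chunked to bound memory at large n. PCA drops
constant columns with a warning and requires ≥2 usable columns;
eigenvalues conserve the trace of the correlation matrix to 1e-8.

## Known limitations and caveats

- Published cohort summaries of this design contain internal rounding
  tensions (e.g. a screening share quoted both as a 6.5-point reduction
  and as 31.2% → 15.9%); the package asserts neither reading — the
  comparison functions report what the data give.
- The unadjusted period RR from marginal 2×2 counts carries a closed-form
  robust CI that can be slightly narrower than CIs computed on the full
  estimation sample; only point estimates should be compared across
  sources.
- The hospital-diagnosis proxy conflates severity with admission practice;
  period effects on it are subject to selection bias when delays
  differentially defer mild presentations, which is exactly why the
  severity covariates (FIT, obstruction) are included.
- The backlog engine is deterministic given its rates; it propagates no
  sampling uncertainty from the yield estimate.
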