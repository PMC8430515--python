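# crcdelay

Analysis toolkit for quantifying pandemic-induced diagnostic delay in
colorectal cancer (CRC) from linked administrative health records, aimed at
cancer-surveillance analysts and health-system planners. During the first
COVID-19 wave, screening programs and endoscopy units were suspended; the
resulting drop in CRC diagnoses left a backlog of undiagnosed patients.
This package reconstructs *how* patients were being diagnosed, *how long*
each step took, *whether* intra-pandemic patients presented with more
severe disease, and *what* colonoscopy capacity and diagnostic yield would
be required to clear the backlog — and ships a synthetic registry generator
so the whole pipeline is testable without access to protected health data.

## What it computes

Given a patient registry table and a dated milestone event table (FITs,
blood tests, colonoscopies, surgeries, CT scans, coded symptom diagnoses,
ICD-10/CCI-coded), the pipeline:

1. **Pathway classification** — links each patient's milestones within a
   1-year lookback and assigns a diagnostic pathway by the earliest
   initiating event: screening (FIT), primary-care blood test, or
   symptomatic/urgent care; procedure-only histories are unclassified. PCA
   of the milestone count matrix (Kaiser criterion, promax rotation) is
   available to check which milestones cluster together.
2. **Interval estimation** — waiting times between milestone pairs and the
   total interval (first milestone → diagnosis), summarized as median, IQR,
   and a percentile-bootstrap 95% CI for the median (5000 replicates):
   for values *x₁…xₙ*, CI = (2.5th, 97.5th) percentile of resampled medians.
3. **Severity model** — flags hospital-based diagnoses (inpatient
   diagnostic procedure on the diagnosis date) and fits *modified Poisson
   regression*: a log-link Poisson GLM on the binary outcome with a robust
   sandwich (HC0) variance, so RR = exp(β) with CI exp(β ± 1.96·SE_robust).
   Covariates: pandemic period, age, sex, FIT, bowel obstruction.
4. **Backlog scenarios** — estimates the monthly CRC yield of colonoscopies
   (diagnosis within 30 days of the procedure), and runs the recursion
   B_m = max(0, B_{m−1} + E_m − D_m) with expected diagnoses
   E_m = V_m·y₀/f and scenario diagnoses D_m = V_m·c·y/f (volume V_m,
   baseline yield y₀, scenario capacity multiplier c and yield y, fraction
   f of CRC patients diagnosed via colonoscopy), reporting clearance months
   and the Pareto-minimal capacity × yield frontier.

## Worked example

```python
import crcdelay as cd

study = cd.StudyConfig()                                 # pre/intra cutoff 2020-02-29
cohort = cd.generate_cohort(cd.SimulationConfig(n_patients=50_000, seed=1))
patients = cd.assign_period(cohort.patients, study)
linked = cd.link_lookback(patients, cohort.events, study)
patients, _ = cd.exclude_no_milestones(patients, linked)
for r in cd.severity_analysis(patients, linked)["adjusted"]:
    print(f"{r.term:20s} RR {r.rr:.2f} ({r.ci95[0]:.2f}, {r.ci95[1]:.2f})")
```

prints

```
intra_period         RR 1.22 (1.15, 1.30)
age_years            RR 1.01 (1.01, 1.01)
female               RR 1.06 (1.03, 1.10)
any_fit              RR 0.49 (0.46, 0.52)
bowel_obstruction    RR 2.89 (2.80, 2.99)
```

i.e. on this synthetic cohort, intra-pandemic patients carry a ~22% higher
adjusted risk of being diagnosed in hospital; screen-detected (FIT)
patients about half the risk; bowel obstruction nearly triples it. The
generator's defaults encode exactly these effects, so the fit demonstrates
parameter recovery by the modified Poisson stage. The `examples/` scripts
walk each capability the same way (`python examples/severity_model.py`,
etc.), and `crcdelay run --simulate --seed 42 --out report/` writes the
full table set from the command line.

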