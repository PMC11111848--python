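# Methods

## The case/non-case design

FAERS is a spontaneous-report database: there are no denominators, so
risk cannot be estimated, only *disproportionality* — whether an event is
reported relatively more often for the target drug than for the
background of all other drugs. Reports where the target drug is coded
primary suspect (ROLE_COD = "PS") are cases; every other surviving
report is background. Counting is at report level: a report listing the
same preferred term twice contributes one (report, PT) pair, and the
2×2 margins b and d are the remaining report–event *pairs* of each arm,
so the four cells always sum to the number of distinct pairs in the
dataset at the chosen MedDRA level. SOC-level tables are the same
counting lifted to distinct (report, SOC) pairs.

### Deduplication

A case may appear under several PRIMARYIDs (follow-up versions sharing a
CASEID), and versions cross quarterly files, so all quarters are
concatenated before deduplication. Per CASEID the report with the most
recent FDA_DT survives; ties go to the higher PRIMARYID. An
unparseable FDA_DT sorts as earliest, so a dated version always beats an
undated one — the more informative record is preferred. The rule is a
pure function of the DEMO table and idempotent.

### Statistics and the dual criterion

* ROR = (a·d)/(b·c); 95% CI = exp(ln ROR ± z·√(1/a+1/b+1/c+1/d)) with
  z = 1.96 (Woolf). Any zero cell makes the estimate undefined; no
  continuity correction is applied, because the signal rule's n ≥ 3
  requirement makes the zero-cell case irrelevant for signals and a
  correction would silently change every small-count estimate.
* IC (default `noren` variant): IC = log₂((a+0.5)/(E+0.5)) with
  E = (a+b)(a+c)/N; IC025 = IC − 3.3(a+0.5)^(−1/2) − 2(a+0.5)^(−3/2).
  The shrinkage by 0.5 keeps the IC finite at a = 0 and pulls
  small-count estimates toward 0. The `bate1998` variant implements the
  original BCPNN posterior-moment mean and variance (priors
  α₁ = β₁ = 1, α = β = 2) with IC025 = E(IC) − z·√V(IC). A `fixed_z`
  variant (IC − z·σ with caller-supplied σ) exists for sensitivity
  experiments only; it is not a calibrated credibility bound. All
  outputs record the variant label.
* Signal flag: a ≥ 3 ∧ ROR ci_low > 1 ∧ IC025 > 0. Undefined
  statistics never flag.

No multiple-testing adjustment is applied — the dual criterion itself is
the conventional guard in this field — so across hundreds of screened
terms a few false flags are expected under the null; this is a known
limitation of the method, quantified here by the null-calibration check
(≈2–5% of terms exceed the ROR threshold under independence).

Gender-stratified screening re-runs the identical machinery inside each
stratum (background = other drugs' reports of the same stratum);
reports of unknown sex are excluded from strata but kept in the pooled
analysis, so stratum counts of a term sum to the pooled count only when
an "unknown" stratum is included.

The head-to-head comparator analysis restricts the universe to reports
whose primary suspect is the target or the comparator drug and computes
the same odds ratio on (target∧term, target∧other, comparator∧term,
comparator∧other). A zero cell (e.g. the comparator never reported the
term) yields an undefined marker rather than a corrected estimate.

Ranking of signal tables is by report count ("frequency") or by ROR
("strength"), with ties broken by the other key and then by term name,
so output ordering is total and deterministic.

## Time to onset

Onset = EVENT_DT − earliest resolvable START_DT of the suspect drug, in
days, one interval per report. Dates resolve by precision class: 8
digits → exact day; 6 digits → the 15th of the month (month midpoint);
4 digits or empty → the report is excluded, as are non-positive
intervals (a zero-day interval cannot lie on the Weibull support, whose
published minimum here is 2 days). Exclusion counters reconcile:
input = used + no_start + no_event + non_positive.

The two-parameter Weibull (scale α in days, shape β) is fitted by
maximum likelihood (scipy's constrained-location fit); 95% CIs are
computed from the analytic observed information of the log-parameters
and exponentiated, which guarantees positive bounds and is the standard
normal approximation for positive parameters. Classification: early
failure if the shape CI's upper bound < 1, wear-out if the lower
bound > 1, random otherwise. Descriptive summaries use type-7 (linear
interpolation) quartiles and fixed 30-day bins (0, 30], (30, 60], ….

A constant sample (shape MLE divergent) and samples below n = 10 are
refused with explicit errors rather than fitted.

## The synthetic generator

The generator emulates the structure of FAERS quarterly extracts, not
any real corpus: '$'-delimited DEMO/DRUG/REAC/THER/INDI/OUTC files per
quarter with the column subset this pipeline reads, a PT→SOC map file,
and a `GroundTruth` object carrying exact per-PT contingency counts,
duplicate groups with intended survivors, and pre-masking onset draws.

Defaults are the study conditions of the motivating analysis: 1,693
target reports over 2019Q4–2023Q3 with the observed yearly reporting
profile (7.4/19.5/49.7/23.4% over 2020–2023), the observed demographics
mix (55.2% female, 62.8% missing age, 99.9% US), onset intervals drawn
from Weibull(β = 0.59, α = 25.61 days), and date-completeness
probabilities (0.22 full, 0.07 month, 0.11 year, 0.60 absent per date
field) chosen so that ≈(0.29)² ≈ 8% of reports yield a usable interval,
matching the observed 139/1,693. The background is a deliberately
scaled-down stand-in for "all other drugs": 50,000 reports (20,000 in
the bundled examples) over 200 drugs and 300 PTs with Zipf(1) marginals,
drug and event sampled independently except for planted signals. Events
per report follow a geometric distribution capped at 8 with mean ≈ 2.8.

Planted signals replace mid-rank background PTs; the target's event
distribution multiplies their baseline probability by the configured
multiplier (defaults 20/15/10) and rescales the unplanted remainder, so
the expected target-to-background reporting-rate ratio equals the
multiplier exactly. Duplicates clone a report under a higher PRIMARYID
with FDA_DT advanced 1–90 days (20% keep the same FDA_DT, exercising the
tie-break branch), so the intended survivor is always the clone.

What the generator does **not** emulate — and hence what passing tests
do not establish about real FAERS: correlated drug–event structure
(confounding by indication and co-medication), MedDRA coding noise and
multiaxial SOC links, free-text drug-name variants needing
normalisation, reporting-trend dynamics (e.g. the post-approval
reporting peak), and non-independent duplicate content (real follow-ups
revise fields). One visible consequence of the date-masking model:
onset intervals recovered after month-midpoint imputation are a coarsened
version of the true draws, so the refitted shape parameter on masked
synthetic data runs above the generating 0.59 (≈0.8 in the worked
example) while still classifying as early failure; parameter-recovery
checks therefore use unmasked draws.

## Numerical and design choices

* Name matching is exact after uppercase and trim, against DRUGNAME or
  PROD_AI; fuzzy matching is out of scope.
* PTs absent from the user-supplied MedDRA map are annotated "UNMAPPED"
  and counted; the map is a user input because the dictionary is
  licensed.
* Indication PTs (INDI) are never counted as adverse events; only REAC
  rows enter the contingency tables.
* Reporting year derives from FDA_DT (receipt date).
* Display rounding is 2 decimals for ROR/CI and IC/IC025; computations
  are full precision throughout.
* Problem sizes in the test suite and acceptance script (8,000–98,000
  background reports, 200 Weibull replicates at n = 139) were chosen as
  the smallest scales at which the sampling error of each check is an
  order of magnitude below its acceptance margin.
* End-to-end determinism: a single seeded generator per corpus, stable
  mergesort ordering everywhere, and fixed CSV formatting make repeated
  runs byte-identical for identical configuration.
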