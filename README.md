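# faers-signal

Disproportionality signal detection and time-to-onset analysis for
spontaneous adverse-event reports in the FDA Adverse Event Reporting
System (FAERS) quarterly ASCII format.

The package is aimed at pharmacovigilance analysts who want a tested,
reproducible version of the standard post-marketing safety workflow: parse
the quarterly extracts, deduplicate case versions, extract the reports
where a drug of interest is the primary suspect, screen every MedDRA
preferred term (PT) and system organ class (SOC) for disproportionate
reporting, compare the drug head-to-head against a comparator, and model
the time from treatment initiation to event onset. A synthetic FAERS
generator with exact ground truth makes the whole pipeline testable
without downloading anything.

## Methods in brief

Every drug–event pair is summarised by the 2×2 table of report–event
counts (a: target drug with the event, b: target drug with other events,
c, d: the same for all other drugs). Two statistics are computed per
term:

* **Reporting odds ratio** ROR = (a·d)/(b·c) with the Woolf log-scale
  95% confidence interval exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d)).
* **BCPNN information component** IC = log₂((a + 0.5)/(E + 0.5)) with
  E = (a+b)(a+c)/N, and its lower credibility bound
  IC025 = IC − 3.3·(a+0.5)^(−1/2) − 2·(a+0.5)^(−3/2) (Norén's closed
  form; the original posterior-moment formulation is available as the
  `bate1998` variant).

An event is a **signal** only when both methods agree: a ≥ 3 reports,
ROR lower confidence limit > 1, and IC025 > 0.

Onset intervals (therapy START_DT to EVENT_DT, with month-precision
dates resolved to the 15th) are fitted with a two-parameter Weibull by
maximum likelihood; 95% CIs come from the delta method on the
log-parameters. A shape-parameter CI entirely below 1 indicates *early
failure* — a hazard that decreases with time on the drug, i.e. events
cluster shortly after initiation.

## Worked example

```python
import tempfile
from pathlib import Path
from faers_signal import (SynthConfig, generate_quarters, load_quarters, deduplicate,
                          select_cases, read_meddra_map, event_pairs,
                          DisproportionalityModel, WeibullTTOModel,
                          extract_tto_samples, map_events)

work = Path(tempfile.mkdtemp())
config = SynthConfig(seed=1, n_background_reports=20_000, n_target_reports=1_693)
truth = generate_quarters(config, work / "faers")   # writes DEMO22Q1.txt, ...

raw = load_quarters(work / "faers")
survivors = deduplicate(raw.demo)                   # latest FDA_DT per CASEID
cases = select_cases(raw, ["LUMATEPERONE"], "PS", survivors)
meddra = read_meddra_map(work / "faers" / "pt_soc_map.txt")
cases = map_events(cases, meddra)

pairs = event_pairs(raw, survivors)                 # all report-event pairs
results = DisproportionalityModel(pairs, set(cases.report_ids), term_soc=meddra).fit()
print(results.signals[["term", "n", "ror", "ror_ci_low", "ror_ci_high",
                       "ic", "ic025"]].round(2).to_string(index=False))
```

prints

```
              term  n   ror  ror_ci_low  ror_ci_high   ic  ic025
             MANIA 95 16.93       12.37        23.19 2.85   2.51
          SEDATION 70 15.11       10.60        21.55 2.77   2.37
SEROTONIN SYNDROME 60 11.28        7.91        16.09 2.57   2.14
```

Exactly the three event terms the generator planted (with rate
multipliers 20, 15 and 10) are flagged as dual-criterion signals among
the 300 preferred terms screened: MANIA was reported in 95 of the 1,693
target-drug cases, 16.93 times the reporting odds of the 20,000-report
background, and its IC025 of 2.51 is well above 0. Continuing with the
onset analysis:

```python
samples, counters = extract_tto_samples(cases)
print(f"usable onset intervals: {counters['used']} of {counters['reports']} cases")
print(WeibullTTOModel(samples).fit().summary())
```

```
usable onset intervals: 128 of 1693 cases
Weibull time-to-onset analysis
n = 128
median (IQR): 22 (7-44) days
scale alpha = 34.88 (95% CI 27.68-43.95) days
shape beta  = 0.79 (95% CI 0.69-0.90)
pattern: early failure
first 30 days: 60.16% of events
```

Only 128 of 1,693 reports carry both a resolvable therapy start and
event date (the generator masks dates at realistic FAERS completeness);
the fitted shape of 0.79 with CI below 1 classifies the onset pattern as
early failure.

The same pipeline is available from the shell:

```bash
faers-signal simulate --config generator.yaml --out data/
faers-signal run --config run.yaml        # writes the full table set
faers-signal compare --config run.yaml --term MANIA
```

`faers-signal run` writes `demographics.csv`, `soc_signals.csv`,
`pt_signals.csv` (plus rankings by report count and by signal strength,
and per-sex strata), `comparator.csv`, the time-to-onset summary and
monthly histogram, and a `run_log.txt` whose counters reconcile exactly
(reports = survivors + removed duplicates; survivors = cases +
non-cases; onset input = used + excluded).

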