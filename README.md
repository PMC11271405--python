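# pgtflow

Outcome-analysis pipeline for precision-guided treatment (PGT) cohorts:
modality-specific response adjudication, trial endpoint derivation, survival
inference, and a synthetic cohort generator, driven by a single CLI.

## What it does

- **Data model / IO** (`pgtflow.model`, `pgtflow.io`): typed cohort model
  (patients, recommendations, treatment courses, serial assessments) over a
  four-table CSV interchange format with a shipped JSON data dictionary.
  Time is integer day offsets; all invariants are validated on load.
- **Response adjudication** (`pgtflow.adjudication`): percent-change band
  classification for solid-tumor/CNS/PET imaging (PD at +25%, PR at −30% or
  −50% depending on modality, CR at total disappearance; an alternative set
  with the +20% PD bound is selectable), categorical rules for evaluable but
  non-measurable disease, and marrow/circulating blast rules for acute
  leukemia. Best response per course honors the 6-week minimum for stable
  disease.
- **Endpoints** (`pgtflow.endpoints`): evaluability filter (≥4 weeks on
  treatment, no progression in the first 4 weeks, evaluation available) with
  reason-coded audit trail; treatment-anchored PFS; 24-week objective
  clinical benefit; the intra-patient PFS ratio with its five eligibility
  criteria (benefit = ratio > 1.3 and ≥4 weeks absolute gain); OS grouping by
  first post-MTB treatment; 0–3 favorable-factor score.
- **Statistics** (`pgtflow.stats`): from-scratch Kaplan–Meier, k-group
  log-rank, Cox proportional hazards (Efron/Breslow ties, Newton–Raphson),
  Pearson chi-squared, and Clopper–Pearson exact binomial intervals.
- **Simulation** (`pgtflow.simulate`): reproducible synthetic cohorts with a
  configurable log-hazard-ratio structure over tier-1 evidence, fusion/SV
  target, pre-treatment progression status and disease group; trajectories
  are constructed so adjudication reproduces the drawn response categories
  exactly.
- **Fixtures** (`pgtflow.fixtures`): deterministic mini-cohorts, including
  `printed_counts`, which reproduces the published course-level tallies
  end-to-end (70 measurable → 6/19/24/21; 90 evaluable; 53/97 OCB; 13/31
  PFS-ratio benefit; 110/256 uptake).
- **Reporting** (`pgtflow.reporting`, `pgtflow.cli`): response/OCB/uptake/
  PFS-ratio summaries, stratified outcome tables (2-year PFS with Greenwood
  log(−log) CIs, log-rank and chi-squared comparisons), and waterfall/
  swimmer/KM figure-backing CSVs.

## CLI

```sh
pgtflow simulate --seed 1 --n-patients 385 --out-dir cohort/
pgtflow adjudicate --in-dir cohort/ --thresholds paper --out responses.csv
pgtflow endpoints  --in-dir cohort/ --cutoff-day 1650 --out-dir endp/
pgtflow analyze    --in-dir cohort/ --out-dir analysis/
pgtflow report     --in-dir cohort/ --out-dir report/
```

All outputs are tidy CSV/JSON; logs go to stderr. `--config` accepts a YAML
file for either the simulation parameters (`simulate`) or the analysis knobs
(`endpoints`/`analyze`/`report`).

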