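# cardiotriage

Constraint-metric-driven variant triage for inherited cardiomyopathies.

Diagnostic gene-panel sequencing of cardiomyopathy patients produces
far more variants of uncertain significance (VUS) than variants that
can be acted on. This package implements a reusable pipeline that folds
two kinds of published gene-constraint evidence into ACMG/AMP five-tier
classification:

* **case excess / etiological fraction** — for a gene (or protein
  region), cardiomyopathy subtype and variant class, the enrichment of
  rare variants in clinical cases over a population reference:
  `CE = f_case − f_ctrl` and `EF = (f_case − f_ctrl)/f_case = 1 − 1/RR`.
  EF estimates the probability that a rare variant of that class in an
  affected carrier is disease-causing;
* **gnomAD gene constraint** — `pLI > 0.90` (truncating variants) or
  `mis_z > 3` (missense/in-frame), for genes without burden analyses.

On top of these the pipeline provides:

* an ACMG rule engine with the EF-banded hotspot criterion
  (PM1@supporting/moderate/strong at EF ≥ 0.80/0.90/0.95), tiered
  co-segregation (PP1 at ≥3/≥5/≥7 meioses), PS4 at ≥15 probands, PM2 at
  popmax AF < 0.004%, and the full published combining table evaluated
  over effective strengths;
* validation of a cohort's prior (likely) pathogenic calls against the
  constraint metrics (route-split concordance, founder accounting);
* VUS triage — immediate reclassification to likely pathogenic
  (EF ≥ 0.90 with PM2, PP3, PP4 and an independent (L)P combination) or
  prioritization for co-segregation/functional follow-up — with a full
  rationale trail per decision;
* cohort reporting (diagnostic yield, yield increase, per-subtype
  tallies) with exact half-up rounding from raw counts;
* a seeded synthetic-cohort simulator, a deterministic 2,002-patient
  reference cohort, and an EF-estimator calibration experiment.

It is aimed at clinical-genetics laboratories and methods researchers
who want to exercise or adapt constraint-based reclassification rules
on their own annotated variant tables. Inputs are plain TSVs
(post-annotation diagnostic records), not VCFs; see
[docs/methods.md](docs/methods.md) for the model, numerical choices and
limitations.

## Worked example

Compute burden statistics from raw carrier counts (cases vs reference):

```text
$ cat counts.tsv
gene    subtype  variant_class  case_carriers  case_n  control_carriers  control_n
DSP     DCM      truncating     20             100     2                 1000
TTN     DCM      truncating     5              100     0                 60706

$ cardiotriage burden --counts counts.tsv
gene  subtype  variant_class  ce     ef    p_value      significant  ef_ci_low  ef_ci_high
DSP   DCM      truncating     0.198  0.99  4.6018e-20   true         0.957838   0.997628
TTN   DCM      truncating     0.05   1     1.08703e-14  true         NA         NA
```

For DSP, 20% of cases but 0.2% of reference samples carry a rare
truncating variant: the case excess is 0.198 and the etiological
fraction 0.99 — a rare DSP truncating variant in a DCM patient is
~99% likely to be causal (95% CI 0.96–0.998), comfortably inside the
strong-evidence band (EF ≥ 0.95). TTN shows EF pinned at 1 (no
reference carriers); with a zero cell the interval is reported missing.

Run the pipeline end to end on the packaged reference cohort:

```bash
cardiotriage fixture --out-dir fx
cardiotriage validate --variants fx/variants.tsv --constraints fx/constraints.tsv
cardiotriage report   --variants fx/variants.tsv --constraints fx/constraints.tsv
```

The validation table shows, pooled over subtypes, that 354 of 378
unique (L)P variants in burden-analysed genes would also have been
called (L)P from case excess alone (94% concordance; 4% of the
CE-route variants are discordant founder variants, which evade
frequency-based evidence by design), against 12 of 22 (55%) for genes
where only gnomAD constraint is available. The report then summarises
triage:

```text
total_patients                   2002
diagnosed_patients               430
diagnostic_yield_pct             21.5%
reclassified_patients            28
reclassified_new_diagnoses       25
yield_increase_pct               1.2%
unique_vus_reclassified          23
unique_vus_prioritized           106
prioritized_ce_no_diagnosis_pct  5.6%
gnomad_route_no_diagnosis_pct    1%
prioritized_unique_vus_pct       5.3%
combined_selected_patients       132
combined_selected_pct            6.6%
```

23 unique VUSs in 28 patients meet the immediate-reclassification
gates, giving 25 patients (1.2% of the cohort) a first molecular
diagnosis; a further 106 unique VUSs are prioritized for follow-up,
so 6.6% of patients end up with at least one actionable or
follow-up-worthy variant. Thresholds can be overridden with
`--config thresholds.json` (e.g. `{"ef_reclass": 0.95}` reclassifies
only strong-band variants: 17 unique VUSs on the same cohort).

Simulated cohorts with configurable statistical structure come from
`cardiotriage simulate --seed 7 --n-patients 2002 --out-dir sim/`, or
from `cardiotriage.generate_cohort(SimConfig(...))` in code.

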