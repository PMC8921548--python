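# Methods

## The model

The package operationalises a constraint-metric framework for
interpreting rare variants found by diagnostic gene-panel sequencing of
cardiomyopathy patients (HCM, DCM, ACM, LVNC, and referrals without a
confirmed subtype).

For a gene (or protein region), subtype and variant class — truncating
(frameshift/nonsense/canonical splice) vs non-truncating (missense,
in-frame indel) — published burden studies compare the pooled frequency
of rare variants in clinical cases against a large population reference.
With carrier frequencies `f_case` and `f_ctrl`:

* **case excess** `CE = f_case − f_ctrl`,
* **etiological fraction** `EF = (f_case − f_ctrl)/f_case = 1 − 1/RR`,
  where `RR` is the carrier risk ratio.

EF is an attributable fraction: the probability that a rare variant of
that class, seen in an affected carrier, is actually disease-causing.
It is bounded above by 1 (attained exactly when no reference carrier
exists) and is *undefined* — not zero — when no case carrier exists,
since a fraction attributable among exposed cases has no meaning
without exposed cases.

Genes absent from the burden studies fall back to gene-level population
constraint from gnomAD: `pLI > 0.90` for truncating variants and
`mis_z > 3` for non-truncating ones, with strict class–metric pairing
(pLI is never applied to missense variants, mis_z never to truncating
ones; a missing class-matched metric makes the screen inconclusive,
i.e. negative).

## Evidence assignment and combination

EF feeds the hotspot criterion PM1 at banded strengths:

| band            | strength   |
|-----------------|------------|
| EF ≥ 0.95       | strong     |
| 0.90 ≤ EF < 0.95| moderate   |
| 0.80 ≤ EF < 0.90| supporting |

Bands are left-closed and apply to truncating and non-truncating
variants alike, each through its own class-specific EF, and to protein
regions where region-restricted estimates exist (a region entry whose
interval contains the variant's residue takes precedence over the
gene-wide entry; among overlapping regions the highest EF wins).

The other criteria this pipeline can assess: PM2 when the variant is
absent from population data or below 0.004% (4×10⁻⁵); PP3/PP4 from
in-silico and phenotype-specificity input flags; PS4 at ≥15 probands;
and tiered co-segregation PP1 at ≥3/≥5/≥7 informative meioses
(supporting/moderate/strong, highest tier only — the tiers are nested).

`combine` evaluates the standard five-tier combining table over
*effective* strengths, so an upgraded PM1 at strong counts as a strong
criterion in every counting rule. Pathogenic rules take precedence over
likely-pathogenic; simultaneous pathogenic- and benign-side hits are
contradictory and yield VUS. Benign-side rules are implemented for
completeness but no input path emits them: none of the cardiomyopathy
variant classes shows significant depletion in cases, so provisional
down-classification is out of scope.

## Triage flow

For each prior-VUS observation (rarity-gated at popmax AF ≤ 10⁻⁴, the
inclusion cut of the underlying burden analyses):

1. resolve the governing constraint entry (gene, class, subtype;
   unclassified-CM patients may match any subtype's entry — phenotype
   matching is impossible for them — while LVNC patients can only be
   served by the gnomAD route, since no LVNC burden analyses exist);
2. if the stratum has **significant case excess**: assign evidence and
   *reclassify to LP* when EF ≥ 0.90 **and** PM2, PP3 and PP4 all hold
   **and** the combining rules independently reach (L)P; otherwise
   *prioritize* for co-segregation/functional follow-up;
3. otherwise, if the gnomAD screen passes **and** the gene is
   established for a specific subtype: *prioritize* (never reclassify —
   gene-level intolerance alone is considered insufficient for an
   immediate (L)P call);
4. otherwise leave the variant untouched.

Requiring significant case excess in addition to EF ≥ 0.90 on the
reclassification path is a deliberate choice: a high EF point estimate
without a significant excess is too noisy to act on immediately.
The pipeline never downgrades a prior classification.

`apply_pp1_upgrade` folds newly observed co-segregation into a
prioritized decision: evidence is re-assigned with the meiosis count
and re-combined, and the decision upgrades only if (L)P is reached
(e.g. supporting-band PM1 + PM2 + PP3 + PP4 + PP1@moderate). The
upgrade applies on both routes, reflecting that segregation data can
rescue a gene with case excess but EF < 0.9 as well as a
constraint-screened gene.

Validation of prior (likely) pathogenic calls mirrors the same routing:
a CE/EF-route (L)P is *concordant* when its stratum has significant
case excess; a gnomAD-route (L)P when the intolerance screen passes.
Tallies are kept at unique-variant and patient level separately, and
founder-flagged discordant variants are reported as a fraction of the
CE-route total — founder variants are regionally enriched and so evade
frequency-based constraint evidence by design.

## Numerical choices

* **Exact test.** Two-sided Fisher exact test on the 2×2 carrier table
  (scipy), validated against exhaustive hypergeometric enumeration with
  exact-integer tie handling. Significance additionally requires the
  excess to be in the case direction. Default α = 0.05; no
  multiple-testing correction, since significance calls are normally
  consumed from the published studies rather than recomputed.
* **EF interval.** The Katz log interval for the risk ratio mapped
  through the monotone identity `EF = 1 − 1/RR`, truncated at 1. An
  odds-ratio interval mapped through `1 − 1/OR` was evaluated and
  rejected: `1 − 1/OR ≥ EF` with equality only as carrier frequencies
  vanish, and at a TTN-like stratum (10% case carriers) its measured
  coverage of the true EF dropped to ~86% against a 95% nominal level,
  while the risk-ratio interval stays within binomial error of nominal.
  Any zero cell leaves the interval undefined (reported missing); no
  continuity corrections are applied.
* **Rounding.** All reported percentages are recomputed from raw
  integer counts in decimal arithmetic and rounded half-up at the
  displayed precision (integers for concordance and the gnomAD-route
  fraction, one decimal for cohort-level yields). Half-up matters at
  the edges: 12/22 → 55%, 19/2002 → 1%, 113/2002 → 5.6%.
* **Missing values.** Empty cells and `NA` parse as missing; a bare `.`
  is rejected. A missing popmax AF means "absent from large population
  studies" and therefore satisfies PM2's frequency condition.
* **Determinism.** Triage is a pure function of its inputs evaluated in
  input order; serialised decision tables are byte-identical across
  runs. The simulator derives everything from one integer seed.

## The synthetic cohort generator

`generate_cohort` emulates the statistical shape of a referral-based
diagnostic cohort: 2,002 patients by default with a subtype mix of
35% HCM / 32.5% DCM / 6% ACM / 14.5% unclassified CM / 12% LVNC, 33
case-excess genes cycling over HCM/DCM/ACM with Beta(8, 1.5) EFs
(mean ≈ 0.84), an expected prior diagnostic yield of 21.5% planted
88% inside CE-analysed genes, Poisson(1) reportable VUSs per patient,
90%/70%/60% rates for the PM2/PP3/PP4 flags and a 4% founder rate.
These defaults were chosen once to mirror a realistic diagnostic
setting and are not tuned per experiment.

What the generator does **not** emulate: linkage between variants of
one patient, gene-specific variant spectra, per-variant allele
frequencies (rarity is a Bernoulli flag), pedigree structure (meiosis
counts are inputs), panel-version drift, or classification noise in
the prior labels. Tests passing on simulated cohorts therefore
demonstrate the pipeline's logic and calibration under its own
assumptions, not performance on real laboratory data.

`reference_cohort` is different in kind: a deterministic, hand-allocated
2,002-patient cohort whose pipeline outputs reproduce an exact set of
reference tallies (concordance 354/378 = 94% and 12/22 = 55%, yield
430/2002 = 21.5%, 23 unique VUSs reclassified in 28 patients, 25 new
diagnoses = 1.2%, 113 = 5.6% and 19 = 1% prioritized-undiagnosed
patients, 106 = 5.3% prioritized unique VUSs, 132 = 6.6% combined).
Variant multiplicities use the minimal allocation consistent with the
patient/unique-variant tallies; the per-patient VUS multiplicity
distribution is otherwise unconstrained. Explicit allocation rather
than simulation keeps the end-to-end checks exact.

## Estimator calibration

`parameter_recovery_experiment` simulates binomial carrier counts at a
known true EF and summarises the estimator's sampling behaviour. At
the default setting (true EF 0.9, 1,000 cases vs 60,706 reference
samples, 1% control carrier frequency, 500 replicates) the mean
estimate is unbiased within Monte-Carlo error, interval coverage is
within binomial error of 95%, and the misassignment rate across the
0.8/0.9/0.95 bands quantifies how often a gene would land in the wrong
evidence band at these sample sizes — the practical caveat for acting
on EF point estimates near band edges.

## Known limitations

* EF values are consumed as published inputs; the package does not
  re-derive them from raw population variant lists, and inherits any
  ancestry mismatch (e.g. founder effects) between the cohort and the
  reference samples.
* PP3 and PP4 are boolean input flags; no in-silico scores are
  computed.
* The constraint table carries no explicit provenance field; a gene is
  treated as CE-analysed when it has a significant excess flag or an
  EF estimate.
* Region-restricted entries are matched on protein residue only;
  transcript mapping and variant normalisation are upstream concerns.
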