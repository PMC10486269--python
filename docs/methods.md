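# Methods

## Scope and model

`phenoconv` analyses drug–drug–gene interactions for the two pharmacogenes
that dominate psychiatric pharmacotherapy, CYP2C19 and CYP2D6. The central
object is the metabolizer phenotype, an ordinal category

    PM < IM < NM < UM

(poor, intermediate, normal, ultrarapid metabolizer). Two phenotypes are
attached to every patient–gene pair:

* the **genotype-predicted** phenotype, derived from the star-allele
  diplotype, and
* the **phenoconverted** phenotype (written P-CYP2C19 / P-CYP2D6), obtained
  by shifting the predicted category according to the patient's modulating
  co-medication.

### Diplotype translation

Each star allele carries a functional activity value (reference `*1` = 1,
null alleles `*4`, `*5`, ... = 0, decreased-function alleles fractional,
duplications multiplied by copy number). The diplotype activity score is
the sum of the two allele activities, classified through per-gene interval
cut-points:

| gene    | PM  | IM        | NM           | UM      |
|---------|-----|-----------|--------------|---------|
| CYP2D6  | 0   | (0, 1]    | (1, 2.25]    | > 2.25  |
| CYP2C19 | 0   | (0, 1.5]  | (1.5, 2.5]   | > 2.5   |

For CYP2C19 the conventional description is a diplotype-class rule (two
null alleles → PM, one null → IM, `*17/*17` → UM, everything else
including `*1/*17` → NM). We give `*17` activity 1.5 so that the interval
scheme above reproduces that partition exactly over the default allele
panel; a test enumerates all diplotypes and asserts the equivalence. This
buys a single translation mechanism for both genes, with the class rule as
a verified corollary rather than a special case.

### Phenoconversion

The shift rule is ordinal arithmetic with clamping:

* moderate inhibitor: one step down, clamped at PM;
* strong inhibitor: two steps down, clamped at PM;
* inducer (CYP2C19 only — no CYP2D6 inducers are known): one step up,
  clamped at UM, **except** that PM stays PM (inducing the synthesis of
  loss-of-function protein does not change clearance);
* weak inhibitor or no modulator: no shift.

The full 4×3 shift table is stored as literal data *and* regenerated from
the rule, with a test asserting cell-for-cell equality so the two cannot
drift apart. Further deliberate choices where the method leaves room:

* **Multiple inhibitors:** the strongest wins; strengths never stack (two
  moderate inhibitors are not a strong one). This is the conservative
  reading of a single-modulator shift table.
* **Inhibitor + inducer co-occurrence** (possible for CYP2C19): there is
  no defensible net rule, so no shift is applied and the patient is
  flagged (`conflict_flag`) with a warning. Inventing a net rule would
  fabricate methodology.
* **Counting phenoconversion:** the default cohort rate counts *any shift*
  (predicted ≠ converted). An alternative `modulator_user` mode counts
  every user of a moderate/strong inhibitor or inducer, whether or not the
  category moved; the two coincide exactly when no genotype-PM (or, for
  induction, genotype-UM) uses a modulator. Both modes are exposed because
  published cohort counts cannot distinguish them.
* Structural variants enter through allele activity values only (`*5`
  deletion = 0, `xN` duplications multiply activity); there is no
  special-cased copy-number logic.

### Knowledge bases

The drug knowledge base (CSV: drug, gene, role, actionable) assigns
substrate and modulator roles per gene; a drug may hold both (fluoxetine:
strong CYP2D6 inhibitor and moderate CYP2C19 inhibitor). The shipped
default covers the psychiatric substrates with actionable DPWG-style
recommendations plus diazepam (a CYP2C19 substrate whose interaction is
supported by the literature) and modulators with FDA/Flockhart-style
strength classes. It is a documented reconstruction, not an authoritative
registry, and is fully user-replaceable; matching is case-insensitive
exact (silent fuzzy mismatches are worse than loud failures). Drugs with
no entry are reported as having no known CYP role, never silently dropped.

## UKU scoring

Each of the 39 items of the adapted scale (extrapyramidal symptoms
excluded) is rated 0–3; the total is the plain sum. Missing items are
imputed as 0 (side effect not reported) and counted per patient. Presence
of a side effect means severity ≥ 1 — the only reading consistent with a
0–3 severity scale reported as prevalence.

Totals are categorized low ≤ 11, moderate 12–21, high ≥ 22. The published
boundaries leave the total 21 unassigned (moderate printed as 12–20, high
as ≥ 22); we fold 21 into "moderate" so the categories partition all
non-negative integers, and flag that the true boundary is unknowable from
the printed intervals. Fixed cut-points are the default so that published
odds ratios are reproducible; a data-driven tertile estimator is provided
as an option.

Per-item prevalence comparisons are restricted to the 33 CYP-related items
and to users of a CYP substrate of the gene under analysis, with phenotype
groups combined NM+UM vs IM+PM (small strata). The 30 item names printed
in the source tables are used verbatim; the three items dropped there for
zero prevalence are retained (and exercised by the generator as
never-present items); the remaining six items of the adapted scale are
standard UKU psychic/autonomic items marked not CYP-related.

## Statistics

* **Crude OR:** OR = ad/bc on the 2×2 of dichotomized UKU category
  (moderate+high vs low, the unique dichotomization consistent with every
  printed crude OR) against exposure. 95% CI = exp(ln OR ± 1.96·SE),
  SE² = Σ 1/cell, with z fixed at 1.96 exactly. Any zero cell triggers the
  Haldane–Anscombe +0.5 correction with an explicit flag; a zero margin
  leaves the OR undefined rather than corrected.
* **Fisher exact (two-sided):** point-probability method — sum of
  hypergeometric probabilities, margins fixed, over all tables no more
  probable than the observed one. Implemented in exact integer arithmetic
  (numerator comparison under the common denominator), so probability ties
  are decided exactly instead of to floating tolerance. This is the
  variant that reproduces the published p = 0.033 on the 15-patient
  nausea table.
* **Test choice:** Fisher whenever any expected cell is below 5, Pearson
  chi-squared (no continuity correction) otherwise; overridable. The rule
  reflects the observation that printed small-table p-values are
  exact-test values even where the methods text says chi-squared.
* **Rank tests:** Mann-Whitney U (asymptotic, tie-corrected) for two
  groups, Kruskal-Wallis beyond.
* **Adjusted ORs:** binary logistic regression fit by IRLS (tolerance
  1e-8 on the Newton step, 50 iterations max), Wald CIs from the observed
  information. Quasi-separation (diverging coefficient, |β| > 15, or
  non-convergence) is flagged rather than reported as a finite OR —
  mirroring the practice of refusing the fit on strata too small to
  support it. On a saturated single-covariate design the fit reproduces
  the crude OR to ≥ 6 decimals (tested).
* **Multiple testing:** raw p-values by default, matching the source
  analysis (~30 per-item tests, no correction); Benjamini–Hochberg flags
  are available as an optional annotation and never change defaults.

## Concentration-dose ratios

CD-ratio = trough plasma concentration (μg/L) / daily dose (mg). Per drug,
groups NM vs IM+PM are compared with a Welch two-sample t-test (unequal
variances are evident in published group SDs; Mann-Whitney available as an
option). Drugs with fewer than two users in either group are excluded with
a logged reason. UMs are excluded from the NM group by default (their
clearance is not comparable); folding them in is a flag, since published
groupings at n(UM)=2 are ambiguous.

## Synthetic cohorts

The generator emulates the *marginal* structure of a 117-patient
psychiatric outpatient cohort; defaults are frozen to the published
margins and are study conditions, not tuning knobs:

* allele frequencies (synthetic European-ancestry-like conventions):
  CYP2C19 {*1 .63, *2 .15, *17 .22}; CYP2D6 {*1 .40, *2 .27, *4 .18,
  *5 .03, *10 .02, *41 .08, *1xN .02} — minimal panels spanning all four
  phenotypes; diplotypes drawn under Hardy-Weinberg;
* modulator-use class probabilities per gene: CYP2C19 weak 20/117,
  moderate 6/117, strong 3/117, inducer 3/117; CYP2D6 weak 15/117, strong
  11/117; substrate use 17/117 (CYP2C19) and 52/117 (CYP2D6);
* polypharmacy (≥ 5 drugs) prevalence 68/117; psychotic diagnosis 72/117;
  BMI classes 30/55/31 of 117; UKU non-response 13/117;
* side-effect presence: per-item logistic model with default baseline
  log-odds −1.0 and coefficients β(IM/PM converted CYP2D6) = 0.9,
  β(polypharmacy) = 1.5, β(non-psychotic) = 0.95 (chosen to land in the
  published crude-OR range of 2.6–4.5 for the non-genetic factors);
  severity given presence is categorical on {1,2,3} with probabilities
  0.6/0.3/0.1 (no published severity distribution exists);
* concentrations: dose × drug-specific scale / clearance(converted
  phenotype) × lognormal noise (σ = 0.3), clearance multipliers NM 1.0,
  UM 1.5, IM 0.6, PM 0.45.

When drawing medications the generator picks modulators that carry no
shift-inducing role for the *other* gene and substrates with no
moderate/strong/inducer role at all, so the configured class probabilities
stay marginally calibrated; real cohorts contain dual-role drugs
(fluoxetine, paroxetine), which the *analysis* side handles fully — only
the generator avoids them. What the generator consequently does **not**
emulate: cross-gene modulator correlation, auto-inhibition by substrates,
dose titration, within-patient correlation of side effects beyond the
shared covariates, or linkage/phase structure. Passing tests therefore
validate the pipeline's arithmetic and inferential behaviour under the
stated margins, not any joint distribution of a real population.

Identical (spec, seed) yields byte-identical tables (tested).

## Pipeline

Stage order: phenotype → score → associate → CD-ratio. Patients without a
genotype are excluded at stage 1 with a log entry; patients without UKU
data stay in phenotyping output but leave the score/association stages
(two-level inclusion). The run manifest records the config snapshot, seed,
package version, SHA-256 digests of all inputs, and per-stage counts with
the invariant analyzed = in − excluded enforced by tests. Stages
communicate only through the documented table schemas, so each can be
re-run from files via the CLI subcommands.

## Problem sizes used in checks

Simulation-based checks use cohorts of 117 (the study size) for
end-to-end runs, 1,000 patients for the CD-ratio clearance-fold recovery,
200 replicates of n = 400 for logistic CI coverage, 1,000 replicates of
two groups of 30 for the Welch type-I error, and 20,000 patients for
calibration against the analytic phenoconversion expectation; the Fisher
implementation is checked exhaustively against an exact-Fraction
enumeration over all 46,376 tables with total ≤ 30.

## Known limitations

* The default drug KB is a reconstruction from public strength
  classifications; users analysing real data should supply their own.
* Only co-medication-driven phenoconversion is modelled; smoking, hepatic
  impairment, inflammation and other non-genetic modifiers are out of
  scope.
* CYP1A2/CYP2C9/CYP3A4 are intentionally unsupported.
* The adjusted-OR stage reports a flagged non-result under separation
  instead of penalized (Firth) estimates; penalization was considered and
  rejected to keep the inferential behaviour identical to the plain MLE
  practice the analysis mirrors.
* Fisher exact is implemented for 2×2 tables only; r×c tables fall back
  to chi-squared.
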