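# Methods

## Variant triage in tumor-only CLL sequencing

Tumor-only sequencing of *ATM* yields a mixture of somatic mutations and
(mostly rare) germline variants. The classifier resolves the mixture with a
fixed, configurable hierarchy of evidence rules; the first rule that fires
decides the label, and the rule's index in the hierarchy is the variant's
evidence tier (lower = stronger evidence).

**Pre-filters** (applied before classification): VAF ≥ `min_vaf`
(default 0.05, inclusive — panels are unreliable below this); gnomAD max
population AF < `common_polymorphism_af` (default 0.01; at ≥1% a variant is
a common polymorphism, not a candidate driver); consequence restricted to
exonic non-synonymous classes plus splice (missense, nonsense, frameshift,
in-frame indel, splice). Absence from gnomAD passes the AF filters: not
being observed in ~800k individuals is itself evidence against common
germline origin.

**Default tier order**:

| tier | rule | verdict |
|---|---|---|
| 0 | `germline_blocklist` — membership in a configured germline-variant blocklist or a CLL germline dataset | germline/neutral |
| 1 | `paired_germline` — confirmed germline in a paired tumor/normal sample | germline/neutral |
| 2 | `paired_somatic` — confirmed somatic in a paired sample | somatic, *unless* both in-silico predictors call it benign (AlphaMissense likely-benign **and** CADD < cutoff), in which case it falls through |
| 3 | `gnomad_rare_germline` — gnomAD max population AF > `rare_germline_af` (default 0.001) | germline/neutral |
| 4 | `clinvar` — pathogenic/likely-pathogenic → somatic; benign/likely-benign → germline/neutral | either |
| 5 | `oncokb` — oncogenic/likely-oncogenic | somatic |
| 6 | `truncating` — nonsense, frameshift or splice | somatic |
| 7 | `insilico_predictors` — AlphaMissense likely-pathogenic **or** CADD ≥ cutoff (default phred 20, the top 1% convention) → somatic; AlphaMissense likely-benign **and** CADD < cutoff → germline/neutral | either |
| 8 | `fallback` — discordant or absent evidence | germline/neutral, flagged low-evidence |

The fallback is deliberately conservative: ambiguous missense variants do
not inflate the mutated-patient count. The `paired_somatic` escape hatch
mirrors the observation that a small number of sequencing-confirmed somatic
calls are nonetheless predicted neutral by multiple in-silico scores.
Splice variants and in-frame indels are not explicitly routed by the
literature this design follows; splice changes are treated as truncating
(tier 6) and in-frame indels as missense-like (tier 7) — both choices are
overrideable via `tier_order`.

**Cohort harmonization.** The same genomic change can be classified
differently across patients when patient-level evidence differs (paired
calls, per-center annotation). `harmonize_recurrent_variants` reassigns all
occurrences of one genomic change the verdict whose deciding rule has the
smallest tier among the occurrences. An exact tier tie between conflicting
labels resolves to the label whose first emitting rule appears earlier in
the hierarchy (with the default order: germline/neutral, which can first be
emitted at tier 0, beats somatic, first possible at tier 2) — this makes the
outcome independent of input order, and the operation idempotent.

**Per-patient status.** A patient is *mutated* iff they carry ≥1
somatic-labeled variant; patients with only germline/neutral variants are
re-categorized as wildtype. The representative variant is the somatic
variant with the smallest tier; ties break by largest VAF, then genomic
coordinate. `biallelic` = mutated + del(11q). `cnloh_flag` is raised when
the representative VAF exceeds `high_vaf_threshold` (default 0.60,
exclusive) in a patient *without* del(11q) — the signature of copy-neutral
loss of heterozygosity. VAF inequality conventions: the 5% floor is
inclusive (≥), the 60% cnLOH threshold and the 50% reference line are
exclusive (>). Patients missing a del(11q) measurement get unknown-safe
`False` flags plus a warning rather than NA propagation.

Protein positions use the *ATM* reference transcript NM_000051.3 (3056 aa,
GRCh37). The N-/C-terminal split is at the first FAT-domain residue
(default 1960, per the UniProt domain annotation; boundary inclusive on the
C-terminal side).

## Association statistics

Odds ratios are raw-count cross-product ratios (a·d)/(b·c); when any cell is
zero, 0.5 is added to every cell (Haldane–Anscombe) for both the point
estimate and the interval. Confidence intervals use the Woolf logit method,
exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)). The point estimates reproduce the
published clinicobiological tables to two decimals; published intervals were
produced by an unstated method and are not asserted.

Fisher exact tests are two-sided under the probability-mass convention (sum
of hypergeometric probabilities of all tables, with the observed margins, at
most as likely as the observed table) via `scipy.stats.fisher_exact`; the
test suite checks it against exhaustive enumeration. Chi-squared tests are
Pearson without Yates correction (a `yates` flag is provided), with an
explicit error recommending Fisher when an expected count is zero.
Benjamini–Hochberg adjustment goes through
`statsmodels.stats.multitest.multipletests` and is oracle-checked against a
literal step-up implementation. BH families: one family per association
table; one family per co-occurrence matrix (entire cohort, U-CLL and M-CLL
strata are separate families); one family per pairwise log-rank panel.

Missing data are handled by pairwise-complete deletion — each 2×2 test drops
only the patients missing one of its two features, which is why per-test
denominators differ.

## Survival analysis

TTFT runs from diagnosis to first treatment; untreated patients are
censored at the earlier of administrative censoring and death (death is
censoring, not a competing event — no competing-risk model is fit). OS runs
from diagnosis to death, censored at last follow-up. Times are stored in
years as reals, never rounded on input.

Kaplan–Meier estimation uses lifelines with the deaths-before-censorings
convention at tied times; Greenwood standard errors are computed from the
event table, and the median is the earliest time with S(t) ≤ 0.5 (absent if
unreached). Median follow-up uses the reverse Kaplan–Meier (flip event and
censoring indicators; report the median and 95% CI of the follow-up
distribution). Log-rank tests are the Cox–Mantel form with k−1 df; the
pairwise mode emits all pairs with BH-adjusted q-values.

Cox models maximize the Efron-tie-corrected partial likelihood (lifelines'
default; preferred because year-granular data produce heavy ties), with
Wald intervals and p-values. Analyses are complete-case: rows with any
missing model term are dropped and `n_used` is reported; fewer than 10
complete cases per term triggers a warning, constant covariates an error,
and non-convergence (including monotone likelihood under perfect
separation) is reported via `converged=False`. Covariate coding: IGHV
status enters as U-CLL vs. M-CLL; TP53 mutation and del(17p) are merged
into a single `tp53_aberrant` indicator (NA only when both are missing);
*NFKBIE* counts as mutated only for the p.Y254fs/p.254* hotspot.

## Synthetic cohort generator

The generator emulates the structure of a large (n = 3631 by default)
multi-center, untreated European CLL cohort.

**Markers.** Binary markers are drawn sequentially (IGHV status → FISH
lesions → gene mutations). Each marker's log-odds receives
ln(OR)·(x_j − p_j) for every already-drawn marker j with a configured
pairwise odds multiplier, and the intercept is then solved numerically so
the realized cohort-mean probability equals the configured marginal (the
raw logit intercept would overshoot: the sigmoid is convex over the
relevant range, so zero-mean log-odds noise inflates the mean). Default
marginals: male 63%, Binet A 72%, U-CLL 44%, del(13q) 41%, trisomy 12 13%,
del(11q) 12%, del(17p) 6%, *ATM*-mutated 6.8%; gene-mutation frequencies
(NOTCH1 12%, SF3B1 10%, TP53 8%, XPO1 4.5%, BIRC3/POT1 3.5%, NFKBIE
hotspot 3%, EGR2/MYD88 2.5%) follow the ordering typical of large CLL
series, with *ATM* fourth. Default odds multipliers encode the
co-occurrence structure: ATM↔del(11q) 8.07, ATM↔U-CLL 4.93, ATM↔SF3B1 2.0,
ATM↔trisomy 12 0.50, ATM↔TP53 0.50. IGHV status is masked in 6.3% and FISH
in 2.9% of emitted clinical rows; ground truth stays complete.

**Variants.** Each *ATM*-mutated patient receives one somatic variant, or
two to three with probability 0.232. Somatic missense mass sits 80% in the
C-terminal (FAT/kinase) region and truncating mass 80% in the N-terminal
region; two recurrent hotspot changes (a frameshift at residue 468 and a
missense at 3008) recur with fixed coordinates to exercise harmonization.
A configurable 3.7% of all patients carry a germline/neutral decoy variant.
Annotation evidence is generated to be *rule-consistent* with the true
origin (somatic variants are decided by paired call, ClinVar, OncoKB,
variant type or predictors, never contradicted upstream; germline decoys by
blocklist membership, rare gnomAD frequency, benign ClinVar, concordant
benign predictors, or the fallback), except at rate `annotation_noise`
(default 0, so classification recovers the generative label exactly). A
genomic change keeps one true origin cohort-wide; cross-origin coordinate
collisions are resampled, since one change being somatic in one patient and
germline in another would be contradictory evidence by construction.

**VAFs.** Germline: Normal(0.5, 0.04) truncated to (0.02, 0.98) —
heterozygous variants center on 50%. Somatic: Beta(2, 3) scaled to
(0.05, 0.50), so non-inflated somatic VAFs never exceed 50%; with del(11q)
(probability 0.33 per variant) or simulated cnLOH (5.5% of mutated patients
without del(11q), matching the proportion of high-VAF somatic calls seen in
practice) the VAF is replaced by Uniform(0.55, 0.95). High somatic VAFs
therefore occur *only* with del(11q) or cnLOH.

**Outcomes.** TTFT event times are exponential with hazard =
baseline × ∏ HR^flag; default HRs: U-CLL 2.5, del(11q) 1.8, SF3B1 1.6,
EGR2 1.5, TP53/del(17p) 1.5, trisomy 12 1.4, XPO1/NOTCH1 1.3, Binet B/C
2.2, and **ATM mutation 1.0** — the generator's central assumption is that
the apparent univariable effect of *ATM* mutation arises entirely through
linkage with del(11q) and U-CLL. Administrative censoring is uniform on
(0.25, 15) years, and the baseline rate is calibrated (closed form + root
finding) so the expected treated fraction equals 58% accounting for
death-before-treatment. The independent death process for OS has baseline
rate 0.035/yr with its own HRs and a log-linear age trend, censored at a
uniform (3, 20)-year follow-up horizon. Gene-mutation HRs are
order-of-magnitude placeholders, not estimates of published effect sizes.

All draws flow from one `numpy.random.Generator` seeded by the config, so a
config fully determines the cohort byte-for-byte.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: sequencing/calling noise and per-center
heterogeneity in annotation; linkage beyond pairwise odds; treatment-era and
center effects on outcomes; non-proportional or time-varying hazards;
clonal evolution (VAFs are cross-sectional); and the real, unknown marginal
accuracy of the flowchart on ambiguous variants (the noise-free recovery
property shows internal consistency of rules and generator, not field
accuracy).

## Problem sizes and numerical choices

The simulation-based checks use 1000 null two-group replicates (n = 200
each) for log-rank size, 200 replicates of 2500 patients for multivariable
Cox coverage and for the univariable-vs-multivariable *ATM* contrast, and
n = 2000 for single-covariate hazard recovery; the acceptance script uses
50 replicates for the contrast. Fisher tie detection uses a 1e-7 relative
tolerance; Cox fitting follows lifelines' Newton solver defaults; brentq
root-finding calibrates generator intercepts and the baseline hazard.

## Known limitations

- The evidence hierarchy is a faithful reading of the published evidence
  list, not a verbatim transcription of any one group's supplementary
  flowchart; step order and thresholds are configurable for that reason.
- ClinVar-pathogenic variants that are nonetheless rare germline (e.g. with
  del(11q) on the alternate allele) remain germline/neutral under the
  default order (tier 3 fires before tier 4 when the gnomAD AF exceeds
  0.001); treating them as mutated requires a custom `tier_order`.
- Exact conditional (hypergeometric-MLE) odds ratios, adjusted
  logistic-regression ORs, competing-risk TTFT models and
  proportional-hazards diagnostics are out of scope.
- The Woolf CI is one of several defensible interval methods and will not
  reproduce intervals computed by other conventions.
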