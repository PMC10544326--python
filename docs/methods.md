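# Methods

This note documents the models, numerical choices and limitations behind
`panelburden`, in the order the pipeline runs.

## Variant classification

Consequence terms are consumed in an ANNOVAR-style vocabulary
(`stopgain`, `frameshift_insertion`, `frameshift_deletion`, `splicing`,
`nonsynonymous_SNV`, `nonframeshift_insertion/deletion`,
`synonymous_SNV`, `intronic`, `UTR5`, `UTR3`).  Canonical ±2 splice
membership is taken as encoded by the upstream annotator in the
`splicing` term; the package never re-derives splice distances from
genomic coordinates, which keeps it independent of genome builds.

The decision procedure is strictly ordered, and each exclusion carries a
machine-readable reason so filter attrition is fully auditable:

1. gene on the excluded list (default: *PPM1D*, whose panel signal is
   attributable to somatic mosaicism) → `gene_excluded`;
2. in-frame indels, UTR, intronic and synonymous rows →
   `consequence_out_of_scope`;
3. truncating consequences: last-exon truncations → `last_exon`;
   splice variants in the penultimate exon → `penultimate_splice`,
   *unless* the gene is on the exception list where the truncated
   protein is expected damaging irrespective of exon skipping (default
   {ATM, BARD1, BRCA1, RAD51C, RAD51D, PALB2}); named splice variants of
   uncertain clinical significance (default: six *BRCA1* variants under
   expert-panel classification) → `uncertain_splice`; everything else →
   `PTV`;
4. missense: (likely) benign → `benign`; gnomAD non-Finnish-European
   allele frequency ≥ 0.001 → `common`; otherwise `RARE_MISSENSE`.

Missense variants absent from the reference population (unknown AF) are
kept as rare — absence itself implies rarity — but flagged `af_unknown`
so they can be counted or removed in sensitivity analyses.  Missense
variants classified pathogenic are retained inside `RARE_MISSENSE`
(none occurred in the emulated cohort); they can be split out by the
`clinical_class` column.

Protein domains are 1-based inclusive residue intervals; overlapping
intervals within a gene are rejected at load time.  The default domain
map ships synthetic approximations of the real UniProt domains for the
nine established genes — adequate for exercising interval membership,
not for biological interpretation; real analyses should supply a curated
TSV.

## Carrier burden and descriptive comparisons

Carrier indicators are binary per subject × unit: heterozygous and
homozygous carriers are not distinguished, and several qualifying
variants in one unit count once.  Gene-set rows (e.g. the nine
established susceptibility genes) count each subject once across member
genes.  Unique-variant counts key on (gene, variant_id) pooled over
cases and controls.  Percentages are stored at full precision and
rounded only for presentation.

Stratifications: family history (subjects with missing FH are dropped
from FH-stratified and FH-adjusted analyses and counted in the log); age
dichotomized as "< 50" vs "≥ 50" (the boundary assignment is a
convention; the cut is configurable); receptor subtype with
triple-negative defined only when ER, PR and HER2 are all observed.

Group-location comparisons use the Wilcoxon rank-sum (Mann–Whitney)
test — exact null when both samples are small and untied, normal
approximation with tie correction otherwise (identical samples give
p = 1) — or the classic equal-variance two-sample t-test.  Proportion
contrasts default to Fisher's exact test with a continuity-corrected
chi-square alternative; for the published family-history contrast
(13/158 vs 29/815) the chi-square route reproduces the reported
p ≈ 0.015.

## Firth penalized-likelihood logistic regression

Written from scratch (no Firth implementation exists in the supporting
stack).  The objective is ℓ\*(β) = ℓ(β) + ½ log det I(β) with
I(β) = XᵀWX, W = diag(πᵢ(1−πᵢ)); for the logistic link the gradient of
ℓ\* is exactly Firth's modified score
U\*ᵣ = Σᵢ (yᵢ − πᵢ + hᵢ(½ − πᵢ)) xᵢᵣ with hᵢ the hat-matrix diagonal.
This penalty guarantees a finite interior maximizer for any full-rank
design — including complete separation — and removes the O(1/n)
coefficient bias.

Numerics, chosen because no convergence recipe is standard:

* columns are standardized internally (unit SD, centered when an
  intercept column can absorb the shift).  A fixed linear
  reparameterization changes the Jeffreys penalty only by an additive
  constant, so the transform is exact; it keeps score components on
  comparable scales (ages in years otherwise dominate 0/1 carrier
  flags).
* Newton–Raphson with Fisher scoring; step-halving (≤ 25) accepts a step
  when ℓ\* increases, or — near the optimum, where the quadratic ℓ\*
  improvement falls below floating-point resolution — when the score
  norm decreases.  Convergence: max |U\*| < tol (default 10⁻⁶),
  max_iter = 100.
* if the line search stalls, a BFGS polish on −ℓ\* with the exact
  gradient runs; a residual score norm below max(tol, 4·10⁻⁹·n) after a
  stalled search is treated as convergence at numerical precision.
  This matters for quasi-separated adjusted fits (e.g. a single carrier
  control with a near-separated family-history covariate), where the
  score's cancellation noise floor can sit slightly above 10⁻⁶ even at
  the optimum; the reported `max_score_norm` stays honest.
* rank deficiency is detected by pivoted QR and reported with the names
  of the collinear columns.

Inference is Wald on the log-odds scale: exp(β̂ ± z·SE) and the normal
reference for β̂/SE.  The choice matches the convention that printed
confidence intervals in this literature are log-symmetric around the OR.
A penalized-profile-likelihood interval (`profile_ci`) is available
behind an explicit call for small-sample work; no multiple-testing
correction is applied (nominal 0.05 convention), and exclusions due to
missing covariates are listwise per fit and logged.

Association scans fit outcome ~ carrier + age + family_history per unit;
outcomes are overall, ER+, ER− and triple-negative disease (cases
restricted to the subtype, controls always the full control group), with
optional stratum filters restricting the case set.  Units with zero
carriers in both groups are skipped — they carry no information.  Age
enters continuous in years.  The age-interaction model adds
carrier×(age − 50); its exponentiated coefficient is the per-year OR
multiplier, and the model's implied OR(t) feeds the risk module.
Re-centering age changes the carrier main effect, never the multiplier.

## Cumulative risk

The constrained-incidence scheme on 5-year piecewise-constant bands:
given population incidence λ_pop(t), carrier frequency at birth f, and
age-specific relative risk RR(t) (taken equal to the OR under the
rare-disease approximation; a warning fires when band incidence × RR ×
width exceeds 0.1), the non-carrier hazard is constrained so the
survivor-weighted mixture reproduces λ_pop in every band, with
disease-free survivor fractions updated band by band.  The mixture
identity holds to machine precision by construction and is asserted in
tests; the recursion is also validated against a 10⁷-individual
discrete-time binomial simulation.  RR(t) is evaluated at band
midpoints.  Competing mortality is ignored ("risk in the absence of
other events").  Confidence bands re-run the whole recursion at the OR's
CI bounds (plug-in); when a per-year multiplier is supplied, OR(t)
varies log-linearly and the multiplier's point estimate is used for the
bounds as well — the band then reflects OR uncertainty only.  Curves
are classified against a threshold (default 30% by age 80, the NICE
surveillance criterion).

## Synthetic cohort generator

The generator emulates the published marginal structure of the MASTOS
case-control study: 990 cases / 1,094 controls; case and control ages
drawn from the published 5-band frequencies with uniform jitter within
bands (cases 26–74, controls 28–71); first-degree family history 16.2%
in cases vs 8.0% in controls with the published missingness; ER/PR/HER2
generated for cases only with independent per-marker missingness
calibrated to the published denominators (628/619/584 of 990).

The disease model is retrospective logistic sampling.  Rather than
simulating a large source population and sampling fixed numbers of cases
and controls, the generator draws the exact conditional distribution
that scheme implies: carrier status given status and covariates, with
carrier odds in cases equal to the control odds times
exp(log_or + subtype_log_or·[ER−] + log_or_per_year·(age − 50)).  Under
covariate-independent exposure the two schemes coincide and the logistic
OR is the exact estimand; tests verify agreement with a brute-force
forward simulation of the source-population scheme.  Default per-gene
parameters are the published estimates (e.g. BRCA2: control carrier
frequency 9×10⁻⁴ ≈ 1/1094, OR 9.75, 55% of carriers sharing the founder
frameshift c.8756delG).

Carriers are realized as qualifying PTV rows drawn from a deterministic
per-gene variant pool (never last-exon; splice variants never
penultimate); rare-missense carriers analogously.  A decoy stream adds
rows that must be excluded — at least one per exclusion rule per cohort,
plus a Poisson number of extras (default rate 0.05/subject) — so the
classifier is always exercised end to end without perturbing the carrier
model.  Every table has its own RNG stream spawned from the master seed;
identical config + seed gives byte-identical files.

What the generator does **not** emulate: linkage between variants,
marker correlation (real ER/PR/HER2 are strongly correlated, so the
synthetic triple-negative fraction ~8% sits below the published 11.5%),
age-matching of controls beyond marginal band frequencies, and any
sequence-level error process.  Passing tests therefore demonstrate
correctness of the statistical machinery under the stated model, not
robustness to real-data artifacts.

The synthetic incidence preset ("bc-like") rises from zero before age 25
to a plateau of 2.5/1,000 person-years in the sixties, giving a
population cumulative risk to 80 of ≈9.4% — in the range typical of
European breast-cancer registries.  It stands in for real national
incidence tables, which are consumed as CSV when available.

## Published-count reconstruction

The emulated study's individual-level data are access-controlled, but
its printed summary counts (per-gene carrier counts, family-history
margins, receptor margins) fully determine the descriptive statistics.
`panelburden.mastos.build_reference_cohort()` lays out a synthetic
subject-level dataset whose margins equal the published counts (subject
identities and joint assignments are arbitrary), so prevalence,
stratification and unadjusted 2×2 association code can be verified
against the published numbers by actually running the pipeline, not by
restating constants.  Covariate-adjusted odds ratios are *not*
reproducible this way — adjustment needs the real joint covariate
distribution — which is why the estimator is instead validated by
simulation (type-I error, CI coverage, effect and age-trend recovery).

## Operating-characteristic studies

Simulation studies (`panelburden.studies`) run at the emulated cohort
scale (990/1,094):

* **Type-I error**: null gene at 5% carrier frequency (common enough for
  the Wald normal approximation to be meaningful at this n),
  1,000 replicates; rejection rate at α = 0.05.
* **Coverage and recovery**: carrier frequency 9×10⁻⁴ and OR 9.75 (the
  high-risk-gene configuration), 500 replicates; 95% Wald CI coverage
  and median recovery.  Recovery is measured on the log-odds scale,
  where the penalty's bias reduction operates; on the OR scale the
  median estimate at these counts (~9 carrier cases, ~1 carrier
  control) sits ~20% below the generating value because the implicit
  half-cell correction is material when a cell expectation is ≈1.  This
  is a property of the estimator, not a defect of the implementation.
* **Age trend**: planted per-year multiplier 0.94 recovered in a single
  50,000-subject cohort at 1% carrier frequency; a 300-replicate null
  study checks that the interaction CI covers 1.0 ≈95% of the time.

Problem sizes (replicate counts, cohort sizes, the 10⁷-individual risk
simulation) were chosen so each study's Monte-Carlo error is small
relative to the quantity checked while the whole suite stays
desk-interactive.

## Known limitations

* The RR ≈ OR substitution overstates risk when the disease is not rare
  in some band; the warning threshold (band hazard × RR × width > 0.1)
  is a heuristic.
* Plug-in CI bands for risk curves ignore uncertainty in the carrier
  frequency and (when used) the age multiplier.
* The domain-level missense scan inherits the synthetic domain map
  unless a curated one is supplied.
* The penultimate-splice exception list and the panel gene list are
  configuration, not discoveries of this package; defaults follow the
  conventions of the emulating study and its antecedents.
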