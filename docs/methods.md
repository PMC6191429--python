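# Methods

This note documents the statistical models implemented in `metaphewas`, the
assumptions behind them, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
choices that matter for reproducibility.

## Study design being modelled

The pipeline targets the setting where a handful of GWAS-nominated SNPs
near candidate drug targets are tested against the full phenome of several
disease-agnostic cohorts. Each cohort captures binary endpoints in its own
vocabulary (self-report questionnaires, ICD registries, EHR phenotype
codes) with widely varying case:control ratios. Equivalent endpoints are
mapped to harmonized phenotypes and meta-analyzed; everything else flows
through as cohort-specific single tests. The classification layer then asks
three questions of each signal: does a known association replicate (given
adequate power), is a signal novel at FDR < q, and does its direction
support or oppose the therapeutic hypothesis for that target?

## Per-cohort association model

Each SNP–endpoint pair is tested independently under an additive genetic
model: logistic regression of case status on effect-allele dosage (0–2,
non-integer imputed dosages accepted) adjusted for age, sex and a
configurable number of principal-component covariates (categorical batch
covariates enter as generic factors). Fitting is Newton–Raphson IRLS with
step halving; convergence requires max |score| < 1e−8 or relative
log-likelihood change < 1e−10 within 50 iterations. Quasi-complete
separation (diverging coefficients, |β| > 25, or a singular information
matrix) is flagged `converged=False` and the record is retained rather than
dropped, so downstream stages can filter explicitly. Endpoints with fewer
than `min_cases = 20` cases are excluded up front and logged with a
machine-readable reason. Missing genotypes are removed listwise per test,
matching the per-test regression framing. Constant covariate columns are
dropped (they alias the intercept).

The fitter is implemented in the package rather than delegated, because the
stated convergence contract and the calibration experiments (10⁴ null
refits) are part of the tested surface; `statsmodels` serves as an
independent cross-check in the test suite, alongside a profile-likelihood
grid-search oracle.

## Harmonization

Effect-allele alignment treats the reference orientation as a per-SNP
(effect, other) pair with an optional reference frequency. Reconcilable
cases are: identity, allele swap (β → −β, EAF → 1−EAF, se and p untouched),
strand complement, and complement-plus-swap. Palindromic (A/T, C/G) SNPs
cannot be oriented by letters; they are resolved by allele frequency only
when both the record's and the reference's effect-allele frequency are more
than 0.08 away from 0.5, otherwise flagged unresolvable and excluded with a
log entry. The 0.08 margin is the conventional ambiguity guard for
palindromic variants. Alignment is idempotent: aligning an aligned record
is the identity.

Phenotype mapping is an explicit input table (cohort_id, endpoint_label,
harmonized_id); no ontology inference is attempted. A harmonized phenotype
becomes a meta-analysis group when records from ≥ 2 sources contribute;
external GWAS summary records count as one source. When several endpoints
in one cohort map to one phenotype, the endpoint with the largest case
count is selected (ties broken by lexicographically smallest label) and the
alternates are logged — the selection criterion is a design choice made
here for power and determinism. The resulting test matrix carries the exact
total test count consumed by multiple-testing control; no record appears in
two groups.

## Meta-analysis

Fixed-effect inverse-variance pooling on the log-OR scale is the primary
rule: wᵢ = 1/seᵢ², pooled β = Σwᵢβᵢ/Σwᵢ, pooled se = (Σwᵢ)^(−1/2), Wald
two-sided P. Heterogeneity is Cochran's Q = Σwᵢ(βᵢ − β̂)², df = k−1,
I² = max(0, (Q−df)/Q)·100 clamped to [0, 100]; for k = 1 heterogeneity is
*missing*, not zero, and single-record groups pass through as a "meta of
one" so cohort-specific endpoints share the code path. Results with
I² > 40% carry a heterogeneity flag for manual review.

The sample-size weighted Z combination, Wᵢ = 1/√(1/Naᵢ + 1/Nuᵢ) and
Z = ΣWᵢZᵢ/√(ΣWᵢ²), is computed alongside for every group; it is the rule of
choice when a source lacks a comparable beta scale (e.g. linear-model
summary statistics). Per-source Z scores take their sign from the aligned
beta so direction survives allele flips. When all studies share the same se
and Na = Nu, both rules reduce to Stouffer with equal weights and their
P-values coincide — a tested invariant. No random-effects model, no
meta-regression, and no sample-overlap correction are provided.

Direction strings summarise per-source betas over a canonical source order:
`+` (risk-increasing), `-` (risk-decreasing), `0` (exactly null), `?`
(source absent).

## Multiple testing and power

The Bonferroni threshold is α/m over the exact test-matrix count; BH FDR
(q = 0.1 by default) is applied jointly to the full matrix — mapped groups
and singletons together — since BH is robust to the positive dependence
this family exhibits. Adjusted p-values come from the standard step-up
procedure (statsmodels' `fdr_bh` backs the implementation; a literal
brute-force step-up is the test oracle). Discovery uses strict inequality
(adjusted p < q). Missing p-values are excluded from the family and
reported.

Analytic power for a known association is computed from (RAF, published OR,
prevalence K, realized case/control counts, α): genotype frequencies follow
Hardy–Weinberg; per-genotype risk is logistic with per-allele log-odds
log(OR) and the intercept solved so population risk equals K; expected
case/control allele frequencies follow by Bayes' rule; the two-sided
allele-count z-test's rejection region uses the pooled null variance and
the alternative distribution uses per-group variances. This construction
reduces exactly to α at OR = 1 and to 1 at α = 1, is monotone in OR, n and
α, and is validated against a Monte-Carlo oracle (binomial allele-count
draws from the same generative model) to within 0.03 at a realistic
parameter point (RAF 0.39, OR 1.037, prevalence 8%, ~57k cases / ~270k
controls) across α tiers. Default prevalences for common indications ship
with the package (e.g. type 2 diabetes 9%, psoriasis 3%, ulcerative colitis
0.24%) and are overridable per phenotype; when no prevalence is known the
realized case fraction is used as a fallback.

Classification: *powered* ⇔ power ≥ 0.8; *replicated* ⇔ powered ∧
meta P < 0.05 ∧ pooled direction (on the registry's risk allele) matches
the published risk direction. The pooled direction is used rather than
per-cohort unanimity, since accepted multi-cohort signals routinely show
mixed per-cohort strings. Registry rows whose declared discovery cohorts
overlap the sources contributing to the meta result are excluded from the
replication family (circularity guard). *Novel* ⇔ the pair is absent from
the registry ∧ adjusted p < q; its direction label compares the pooled
effect on the risk-allele orientation with the therapeutic-hypothesis
direction (concordant → repurposing candidate; discordant → potential ADE;
no hypothesis row → unclassified). Significance tiers are nested by
construction: every Bonferroni call is also an FDR call.

## Colocalization

Per-SNP evidence is the Wakefield approximate Bayes factor computed from
z = β/se and shrinkage r = W²/(W² + se²): log ABF = ½(log(1−r) + r·z²).
The effect-scale prior W is 0.2 for case-control traits and 0.15·sd(Y) for
quantitative traits. The five hypotheses (H0 none; H1/H2 one trait only;
H3 two distinct causal variants; H4 one shared variant) are scored as
H1 ∝ p1·ΣᵢABFᴬᵢ, H2 ∝ p2·ΣⱼABFᴮⱼ, H3 ∝ p1·p2·Σᵢ≠ⱼABFᴬᵢABFᴮⱼ,
H4 ∝ p12·ΣᵢABFᴬᵢABFᴮᵢ against H0 ∝ 1, with priors p1 = p2 = 1e−4,
p12 = 1e−5 (the conventional defaults; exposed as parameters). All sums run
in log space with log-sum-exp — 100-SNP regions overflow naive products.
The single-causal-variant-per-trait assumption is inherited; no
conditioning, fine-mapping or LD-matrix method is included. Posteriors are
checked against a plain-arithmetic enumeration oracle, and simulation
recovery (shared-causal median PP4 > 0.8, distinct-causal median PP3 > 0.8
at z ≈ 8, n = 5000, 100 SNPs, ρ = 0.7) is part of the acceptance surface.

## Synthetic-data generator

The simulator emulates the *statistical structure* the analysis assumes:

- genotypes drawn per SNP from Hardy–Weinberg class probabilities
  (1−p)², 2p(1−p), p²;
- LD regions from a first-order autoregressive haplotype mosaic: each
  marker copies the previous marker's allele with probability ρ, else draws
  fresh Bernoulli(p), giving corr = ρ^distance with constant marginals —
  a single-knob, analytically checkable model;
- binary endpoints from a logistic model whose per-allele effects are
  specified directly on the log-odds scale (not liability-threshold),
  which makes parameter recovery exact in expectation under the analysis
  model; the intercept is solved by root-finding on the population-averaged
  logistic mean to |realized − target prevalence| tolerance 1e−6;
- age/sex/PC covariates that by default do not affect the outcome;
  optional loadings let PC1 track genotype so tests can demonstrate that
  covariate adjustment matters;
- GWAS-style summary statistics drawn Normal(true β, se²) with se from the
  case-control score-variance approximation
  se² = (1/Na + 1/Nu)/(2p(1−p)), so P = 2Φ(−|β/se|) holds exactly;
- a truth ledger materialising every (SNP, phenotype) effect — zeros
  included — plus realized counts, so every emitted association is
  traceable.

All randomness flows from one master seed through named substreams keyed by
(purpose, cohort, endpoint/SNP), so adding an endpoint or SNP to a
configuration never perturbs existing draws, and identical configurations
are byte-identical on disk.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: imputation uncertainty (hard calls only, though
the fitter accepts dosages), relatedness, population structure beyond the
declared PC confounders, ascertainment and diagnostic misclassification,
endpoint correlation structure within the phenome, and sequence-level
realism. The cohorts' endpoint-overlap structure is configuration, not a
fixed constant, because real overlap patterns vary by study.

## Problem sizes and numerical conventions

The shipped tests and the acceptance script use desk-scale problem sizes
chosen to make the statistical claims testable with comfortable margins:
10⁴ refits (n = 800) for type-I calibration, 200 matrices of 400 tests for
FDR control, 200 replicates at n = 20,000 for OR recovery, 50 seeds of
100-SNP/5,000-individual regions for colocalization recovery, and a
two-cohort suite (9,000 + 6,000 individuals, 40 SNPs × 40 phenotypes, ORs
1.12–1.25 giving per-association power 0.84–1.0) for end-to-end
replication-rate recovery.

Output conventions: TSV is tab-separated UTF-8 with a mandatory header,
`NA` for missing, `%.6g` for floats; P-values are floored at 1e−300 and
never rendered as 0. VCF support is deliberately narrow — GT-only, diploid,
unphased, biallelic (multi-allelic records are rejected with a clear
error), matching the few-dozen-hard-called-SNPs use case. Exit codes are
0/1/2 for success/runtime/configuration errors.

## Known limitations

- Fixed-effect pooling only; strong between-cohort heterogeneity is
  flagged (I² > 40%) but not modelled.
- The analytic power formula assumes the allele-count test approximates the
  covariate-adjusted logistic Wald test; with strongly confounding
  covariates the two diverge.
- The optional external-GWAS P < 0.05 inclusion filter (off by default)
  biases meta-analyzed effects away from zero when enabled; it exists for
  compatibility with published-database workflows and is documented as such.
- Colocalization assumes at most one causal variant per trait per region.
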