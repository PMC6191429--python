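# Four cohorts of unequal size with partially overlapping endpoint
# vocabularies; one SNP carries a true asthma effect (OR ~ 1.5).
cohort_sizes:
  popgen: 8000      # large consumer-genetics-style cohort
  biobank: 4000     # national biobank
  registry_epi: 2500    # registry-linked epidemiological survey
  pediatric: 1500   # pediatric hospital cohort
snp_specs:
  - {snp_id: rs0001, maf: 0.30, effect_allele: A, other_allele: G}
  - {snp_id: rs0002, maf: 0.20, effect_allele: C, other_allele: T}
  - {snp_id: rs0003, maf: 0.45, effect_allele: G, other_allele: A}
endpoint_specs:
  - phenotype_id: asthma
    prevalence: 0.12
    cohorts: [popgen, biobank, registry_epi, pediatric]
    labels: {popgen: asthma_self_report, biobank: asthma_interview,
             registry_epi: J45, pediatric: phe_495}
  - phenotype_id: hypothyroidism
    prevalence: 0.06
    cohorts: [popgen, biobank]
    labels: {popgen: hypothyroidism_self_report, biobank: E03}
  - phenotype_id: gout
    prevalence: 0.04
    cohorts: [popgen]
  - phenotype_id: eczema_infantile
    prevalence: 0.08
    cohorts: [pediatric]
effect_specs:
  - [rs0001, asthma, 0.405]           # log(1.5)
  - [rs0002, hypothyroidism, 0.262]   # log(1.3)
covariates:
  n_pcs: 2
rng_seed: 20180417
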