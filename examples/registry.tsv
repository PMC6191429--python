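snp_id	risk_allele	phenotype_id	published_or	raf	is_hypothesis	source	discovery_cohorts
rs0001	A	asthma	1.5	0.30	True	published_gwas
rs0002	C	hypothyroidism	1.3	0.20	True	published_gwas
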