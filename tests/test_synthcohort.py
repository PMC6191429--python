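"""Simulator checks: Hardy-Weinberg sampling, LD decay, prevalence targeting,
suite emission and GWAS-style summary generation."""

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metaphewas._errors import ConfigError, InvalidParameterError
from metaphewas import synthcohort as sc
from metaphewas.assoc import fit_logistic_assoc


class TestSimulateGenotypes:
    def test_near_zero_maf_gives_all_reference(self):
        g = sc.simulate_genotypes(100, 1e-9, rng_seed=0)
        assert np.all(g == 0)

    def test_mean_dosage_matches_expectation(self):
        g = sc.simulate_genotypes(10_000, 0.3, rng_seed=1)
        expected = 2 * 0.3
        sd = np.sqrt(2 * 0.3 * 0.7 / 10_000)  # binomial SD of the mean dosage
        assert abs(g.mean() - expected) < 4 * sd

    def test_class_counts_match_hwe_multinomial(self):
        """Genotype classes follow the closed-form HWE probabilities."""
        n, p = 5000, 0.39
        g = sc.simulate_genotypes(n, p, rng_seed=7)
        observed = np.bincount(g, minlength=3)
        expected = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
        chi2 = float(((observed - expected) ** 2 / expected).sum())
        assert stats.chi2.sf(chi2, df=2) > 0.001

    @pytest.mark.parametrize("maf", [0.0, -0.1, 0.51, 1.0])
    def test_invalid_maf_rejected(self, maf):
        with pytest.raises(InvalidParameterError):
            sc.simulate_genotypes(100, maf, rng_seed=0)

    def test_reproducible_under_seed(self):
        a = sc.simulate_genotypes(500, 0.25, rng_seed=3)
        b = sc.simulate_genotypes(500, 0.25, rng_seed=3)
        assert np.array_equal(a, b)


class TestLDRegion:
    def test_single_snp_region_is_hwe(self):
        spec = sc.LDRegionSpec(n_snps=1, n_individuals=5000, rho=0.5, maf=0.3, rng_seed=2)
        geno, freqs = sc.simulate_ld_region(spec)
        assert geno.shape == (5000, 1)
        assert set(np.unique(geno)).issubset({0, 1, 2})
        observed = np.bincount(geno[:, 0], minlength=3)
        expected = 5000 * np.array([0.49, 0.42, 0.09])
        chi2 = float(((observed - expected) ** 2 / expected).sum())
        assert stats.chi2.sf(chi2, df=2) > 0.001

    def test_rho_zero_means_independence(self):
        spec = sc.LDRegionSpec(n_snps=10, n_individuals=5000, rho=0.0, maf=0.3, rng_seed=4)
        geno, _ = sc.simulate_ld_region(spec)
        corr = np.corrcoef(geno.T)
        off = corr[np.triu_indices(10, k=1)]
        assert np.mean(np.abs(off)) < 0.05

    def test_adjacent_correlation_matches_brute_force_oracle(self):
        """Adjacent-pair genotype correlation agrees with a 10x-larger
        re-simulation of the same haplotype copying model."""
        rho, maf, n = 0.9, 0.3, 5000
        spec = sc.LDRegionSpec(n_snps=8, n_individuals=n, rho=rho, maf=maf, rng_seed=3)
        geno, _ = sc.simulate_ld_region(spec)

        # independent brute-force oracle at 10x n
        rng = np.random.default_rng(12345)
        n_hap = 2 * 10 * n
        hap = np.empty((n_hap, 8), dtype=np.int8)
        hap[:, 0] = rng.random(n_hap) < maf
        for j in range(1, 8):
            fresh = (rng.random(n_hap) < maf).astype(np.int8)
            copy = rng.random(n_hap) < rho
            hap[:, j] = np.where(copy, hap[:, j - 1], fresh)
        geno_oracle = hap[0::2] + hap[1::2]

        for j in range(7):
            r_sim = np.corrcoef(geno[:, j], geno[:, j + 1])[0, 1]
            r_oracle = np.corrcoef(geno_oracle[:, j], geno_oracle[:, j + 1])[0, 1]
            assert abs(r_sim - r_oracle) < 0.1

    def test_rho_one_rejected(self):
        with pytest.raises(InvalidParameterError):
            sc.LDRegionSpec(n_snps=5, n_individuals=100, rho=1.0)

    def test_causal_index_out_of_range_rejected(self):
        with pytest.raises(InvalidParameterError):
            sc.LDRegionSpec(n_snps=5, n_individuals=100, rho=0.5, causal_a=(5,))


class TestBinaryEndpoint:
    def test_null_effect_hits_target_prevalence(self):
        g = sc.simulate_genotypes(20_000, 0.3, rng_seed=5)
        _, n_cases, n_controls = sc.simulate_binary_endpoint(g, 0.0, 0.2, rng_seed=6)
        frac = n_cases / 20_000
        assert abs(frac - 0.2) < 4 * np.sqrt(0.2 * 0.8 / 20_000)

    def test_logistic_refit_recovers_odds_ratio(self):
        """Re-estimation oracle: a logistic refit of simulated labels on
        dosage recovers the simulated OR = 2 within 10%."""
        g = sc.simulate_genotypes(50_000, 0.3, rng_seed=8)
        labels, _, _ = sc.simulate_binary_endpoint(g, np.log(2.0), 0.15, rng_seed=9)
        fit = fit_logistic_assoc(g.astype(float), labels)
        assert 0.9 * 2.0 <= np.exp(fit.beta) <= 1.1 * 2.0

    def test_huge_effect_is_monotone_in_carriers(self):
        g = sc.simulate_genotypes(5000, 0.3, rng_seed=10)
        labels, _, _ = sc.simulate_binary_endpoint(g, 5.0, 0.3, rng_seed=11)
        carrier_rate = labels[g > 0].mean()
        noncarrier_rate = labels[g == 0].mean()
        assert carrier_rate > noncarrier_rate

    @pytest.mark.parametrize("prev", [0.0, 1.0, -0.2])
    def test_degenerate_prevalence_rejected(self, prev):
        g = sc.simulate_genotypes(100, 0.3, rng_seed=0)
        with pytest.raises(InvalidParameterError):
            sc.simulate_binary_endpoint(g, 0.0, prev, rng_seed=0)

    def test_prevalence_error_shrinks_with_n(self):
        """|realized - target| decreases O(n^-1/2) over three decades of n."""
        target = 0.1
        errors = {}
        for n in (1000, 10_000, 100_000):
            errs = []
            for seed in range(8):
                g = sc.simulate_genotypes(n, 0.3, rng_seed=100 + seed)
                _, ca, co = sc.simulate_binary_endpoint(
                    g, 0.3, target, rng_seed=200 + seed
                )
                errs.append(abs(ca / n - target))
            errors[n] = np.mean(errs)
        assert errors[100_000] < errors[1000]
        # scaled errors should stay bounded if the rate is ~ n^-1/2
        assert errors[100_000] * np.sqrt(100_000) < 10 * np.sqrt(0.1 * 0.9)


class TestCohortSuite:
    def test_mapping_rows_count_shared_phenotype(self, tmp_path):
        config = sc.SimConfig(
            cohort_sizes={f"c{i}": 300 for i in range(4)},
            snp_specs=(sc.SnpSpec("rs1", 0.3),),
            endpoint_specs=(
                sc.EndpointSpec("asthma", 0.3, tuple(f"c{i}" for i in range(4))),
            ),
            rng_seed=1,
        )
        suite = sc.emit_cohort_suite(config, tmp_path / "s")
        assert len(suite.mapping) == 4
        assert suite.mapping.harmonized_id.nunique() == 1

    def test_single_cohort_phenotype_is_unmapped(self, small_suite):
        assert "gout" in small_suite.manifest["unmapped_phenotypes"]
        assert "asthma" in small_suite.manifest["mapped_phenotypes"]
        assert "gout" not in set(small_suite.mapping.harmonized_id)

    def test_manifest_endpoint_accounting(self, small_suite):
        m = small_suite.manifest
        # hand count from the fixture config: asthma in 2 cohorts + gout in 1
        assert m["total_endpoints"] == 3
        assert m["n_analysis_endpoints"] == 1 + 1  # one mapped + one cohort-specific
        per_cohort = sum(c["n_endpoints"] for c in m["cohorts"].values())
        assert m["total_endpoints"] == per_cohort

    def test_truth_ledger_complete(self, small_suite):
        effects = small_suite.truth.effects
        # every (snp, phenotype) pair materialized, zero effects included
        assert len(effects) == 3 * 2
        assert small_suite.truth.effect_of("rs1", "asthma") == pytest.approx(np.log(1.6))
        assert small_suite.truth.effect_of("rs2", "gout") == 0.0
        counts = small_suite.truth.counts
        sizes = {"cohortA": 2500, "cohortB": 1500}
        for row in counts.itertuples(index=False):
            assert row.n_cases + row.n_controls == sizes[row.cohort_id]

    def test_same_seed_byte_identical_files(self, small_config, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        sc.emit_cohort_suite(small_config, a)
        sc.emit_cohort_suite(small_config, b)
        for fa in sorted(a.iterdir()):
            ha = hashlib.sha256(fa.read_bytes()).hexdigest()
            hb = hashlib.sha256((b / fa.name).read_bytes()).hexdigest()
            assert ha == hb, fa.name

    def test_adding_endpoint_does_not_perturb_existing_draws(self, small_config, tmp_path):
        """Named substreams: extending the config leaves old files unchanged."""
        import dataclasses

        extended = dataclasses.replace(
            small_config,
            endpoint_specs=small_config.endpoint_specs
            + (sc.EndpointSpec("eczema", 0.1, ("cohortB",)),),
        )
        a = sc.emit_cohort_suite(small_config, tmp_path / "a")
        b = sc.emit_cohort_suite(extended, tmp_path / "b")
        for name in ("cohortA.dosages.tsv", "cohortA.endpoints.tsv", "cohortA.covariates.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_duplicate_local_labels_rejected(self):
        with pytest.raises(ConfigError):
            sc.SimConfig(
                cohort_sizes={"c0": 100},
                snp_specs=(sc.SnpSpec("rs1", 0.3),),
                endpoint_specs=(
                    sc.EndpointSpec("a", 0.3, ("c0",), labels={"c0": "dup"}),
                    sc.EndpointSpec("b", 0.3, ("c0",), labels={"c0": "dup"}),
                ),
                rng_seed=1,
            )

    def test_effect_referencing_unknown_snp_rejected(self):
        with pytest.raises(ConfigError):
            sc.SimConfig(
                cohort_sizes={"c0": 100},
                snp_specs=(sc.SnpSpec("rs1", 0.3),),
                endpoint_specs=(sc.EndpointSpec("a", 0.3, ("c0",)),),
                effect_specs=(("rsX", "a", 0.5),),
                rng_seed=1,
            )


class TestGwasSummary:
    def test_internal_wald_consistency(self, small_suite):
        frame = sc.emit_gwas_summary(small_suite.truth, "asthma", 5000, 20_000, rng_seed=1)
        z = frame.beta / frame.se
        expected = 2 * stats.norm.sf(np.abs(z))
        assert np.allclose(frame.p, expected, atol=1e-12)

    def test_null_pvalues_uniform(self):
        """Under a zero true effect the summary P-values are uniform."""
        truth = sc.SyntheticTruth(
            effects=pd.DataFrame(
                {"snp_id": [f"rs{i}" for i in range(2000)],
                 "phenotype_id": "pheno",
                 "beta": 0.0}
            ),
            counts=pd.DataFrame(),
            snp_frequencies=pd.DataFrame(
                {"snp_id": [f"rs{i}" for i in range(2000)],
                 "maf": 0.3, "effect_allele": "A", "other_allele": "G"}
            ),
        )
        frame = sc.emit_gwas_summary(truth, "pheno", 3000, 12_000, rng_seed=17)
        ks = stats.kstest(frame.p, "uniform")
        assert ks.pvalue > 0.001

    def test_mean_estimate_unbiased_monte_carlo(self):
        """1000 replicates at realistic case/control scale: mean estimated
        beta within 2 Monte-Carlo SEs of the true 0.1."""
        truth = sc.SyntheticTruth(
            effects=pd.DataFrame(
                {"snp_id": ["rs1"], "phenotype_id": ["pheno"], "beta": [0.1]}
            ),
            counts=pd.DataFrame(),
            snp_frequencies=pd.DataFrame(
                {"snp_id": ["rs1"], "maf": [0.39],
                 "effect_allele": ["A"], "other_allele": ["G"]}
            ),
        )
        rng = np.random.default_rng(99)
        betas = [
            sc.emit_gwas_summary(truth, "pheno", 57_101, 269_659, rng_seed=rng).beta.iloc[0]
            for _ in range(1000)
        ]
        mc_se = np.std(betas, ddof=1) / np.sqrt(len(betas))
        assert abs(np.mean(betas) - 0.1) < 2 * mc_se
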