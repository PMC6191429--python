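import numpy as np
import pandas as pd
import pytest

from metaphewas import synthcohort as sc


@pytest.fixture(scope="session")
def small_config() -> sc.SimConfig:
    """Two cohorts, three SNPs, one shared + one cohort-specific phenotype."""
    return sc.SimConfig(
        cohort_sizes={"cohortA": 2500, "cohortB": 1500},
        snp_specs=(
            sc.SnpSpec("rs1", 0.30, "A", "G"),
            sc.SnpSpec("rs2", 0.20, "C", "T"),
            sc.SnpSpec("rs3", 0.45, "A", "C"),
        ),
        endpoint_specs=(
            sc.EndpointSpec("asthma", 0.18, ("cohortA", "cohortB")),
            sc.EndpointSpec("gout", 0.06, ("cohortA",)),
        ),
        effect_specs=(("rs1", "asthma", float(np.log(1.6))),),
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def small_suite(small_config, tmp_path_factory) -> sc.CohortSuite:
    out = tmp_path_factory.mktemp("suite")
    return sc.emit_cohort_suite(small_config, out)


@pytest.fixture()
def registry_frame() -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "snp_id": "rs1",
                "risk_allele": "A",
                "phenotype_id": "asthma",
                "published_or": 1.6,
                "raf": 0.30,
                "is_hypothesis": True,
                "source": "published_gwas",
                "discovery_cohorts": "",
            }
        ]
    )
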