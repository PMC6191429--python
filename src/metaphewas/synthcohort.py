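"""Synthetic multi-cohort genotype/phenotype data with a ground-truth ledger.

The simulator emulates the data structure of a multi-cohort PheWAS of a few
dozen candidate-target SNPs: several cohorts of unequal size, each observing
a partially overlapping set of binary endpoints under its own local endpoint
vocabulary, with endpoint-specific case:control imbalance, additive per-allele
effects on the log-odds scale, age/sex/PC-like covariates, and external
GWAS-style summary statistics generated from the same truth table.

Every stochastic draw flows from a single master seed through named
substreams (cohort x endpoint x snp), so extending a configuration never
perturbs existing draws and identical configurations are byte-identical on
disk.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

from metaphewas._errors import ConfigError, InvalidParameterError
from metaphewas._rng import as_rng, substream

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SnpSpec:
    """One biallelic SNP: identifier, minor-allele frequency, allele labels.

    The effect allele is the minor allele; dosages count its copies.
    """

    snp_id: str
    maf: float
    effect_allele: str = "A"
    other_allele: str = "G"

    def __post_init__(self) -> None:
        if not 0.0 < self.maf <= 0.5:
            raise InvalidParameterError(
                f"SNP {self.snp_id}: maf must be in (0, 0.5], got {self.maf}"
            )
        if self.effect_allele == self.other_allele:
            raise ConfigError(f"SNP {self.snp_id}: alleles must differ")


@dataclass(frozen=True)
class EndpointSpec:
    """One harmonized phenotype and how the cohorts observe it.

    ``cohorts`` lists the cohort ids that capture the endpoint; ``labels``
    optionally maps cohort id -> cohort-local endpoint label (defaulting to
    ``f"{cohort}:{phenotype_id}"`` to emulate divergent vocabularies).
    ``prevalence`` is either a single float applied to all observing cohorts
    or a mapping cohort id -> prevalence.
    """

    phenotype_id: str
    prevalence: float | Mapping[str, float]
    cohorts: tuple[str, ...]
    labels: Mapping[str, str] | None = None

    def prevalence_in(self, cohort_id: str) -> float:
        if isinstance(self.prevalence, Mapping):
            prev = float(self.prevalence[cohort_id])
        else:
            prev = float(self.prevalence)
        if not 0.0 < prev < 1.0:
            raise InvalidParameterError(
                f"endpoint {self.phenotype_id}: prevalence must be in (0,1), got {prev}"
            )
        return prev

    def label_in(self, cohort_id: str) -> str:
        if self.labels and cohort_id in self.labels:
            return str(self.labels[cohort_id])
        return f"{cohort_id}:{self.phenotype_id}"


@dataclass(frozen=True)
class CovariateModel:
    """Age, sex and PC-like covariates and their (optional) outcome effects.

    Defaults are null effects: covariates exist (so the regressions adjust
    for them) but neither confound nor affect the outcome unless loadings are
    declared.  ``pc_genotype_loading`` lets PC1 correlate with genotype to
    demonstrate that covariate adjustment matters.
    """

    age_range: tuple[float, float] = (30.0, 70.0)
    female_fraction: float = 0.5
    n_pcs: int = 2
    age_beta: float = 0.0
    sex_beta: float = 0.0
    pc_betas: tuple[float, ...] = ()
    pc_genotype_loading: float = 0.0


@dataclass(frozen=True)
class SimConfig:
    """Full specification of a synthetic multi-cohort suite."""

    cohort_sizes: Mapping[str, int]
    snp_specs: tuple[SnpSpec, ...]
    endpoint_specs: tuple[EndpointSpec, ...]
    effect_specs: tuple[tuple[str, str, float], ...] = ()  # (snp, phenotype, log-odds)
    covariates: CovariateModel = field(default_factory=CovariateModel)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.cohort_sizes:
            raise ConfigError("at least one cohort required")
        for cid, n in self.cohort_sizes.items():
            if int(n) < 1:
                raise ConfigError(f"cohort {cid}: size must be >= 1")
        snp_ids = [s.snp_id for s in self.snp_specs]
        if len(set(snp_ids)) != len(snp_ids):
            raise ConfigError("duplicate snp_id in snp_specs")
        phe_ids = [e.phenotype_id for e in self.endpoint_specs]
        if len(set(phe_ids)) != len(phe_ids):
            raise ConfigError("duplicate phenotype_id in endpoint_specs")
        for e in self.endpoint_specs:
            for c in e.cohorts:
                if c not in self.cohort_sizes:
                    raise ConfigError(
                        f"endpoint {e.phenotype_id} references unknown cohort {c!r}"
                    )
        # duplicate cohort-local labels within a cohort are ambiguous
        for cid in self.cohort_sizes:
            labels = [e.label_in(cid) for e in self.endpoint_specs if cid in e.cohorts]
            if len(set(labels)) != len(labels):
                raise ConfigError(f"cohort {cid}: duplicate cohort-local endpoint labels")
        known_phe = set(phe_ids)
        known_snp = set(snp_ids)
        for snp, phe, beta in self.effect_specs:
            if snp not in known_snp:
                raise ConfigError(f"effect references undeclared SNP {snp!r}")
            if phe not in known_phe:
                raise ConfigError(f"effect references undeclared phenotype {phe!r}")

    def effects_on(self, phenotype_id: str) -> list[tuple[str, float]]:
        return [(s, b) for (s, p, b) in self.effect_specs if p == phenotype_id]


@dataclass(frozen=True)
class LDRegionSpec:
    """A region of ``n_snps`` markers with first-order autoregressive LD.

    Haplotypes follow a copying mosaic: each marker's allele equals the
    previous marker's allele with probability ``rho`` and is a fresh
    Bernoulli(maf) draw otherwise, giving corr(h_j, h_{j+d}) = rho^d while
    keeping every marginal frequency at ``maf``.
    """

    n_snps: int
    n_individuals: int
    rho: float
    maf: float = 0.3
    causal_a: tuple[int, ...] = ()
    causal_b: tuple[int, ...] = ()
    beta_a: float = 0.0
    beta_b: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise InvalidParameterError(f"rho must be in [0,1), got {self.rho}")
        if self.n_snps < 1 or self.n_individuals < 1:
            raise InvalidParameterError("n_snps and n_individuals must be >= 1")
        if not 0.0 < self.maf <= 0.5:
            raise InvalidParameterError(f"maf must be in (0,0.5], got {self.maf}")
        for idx in (*self.causal_a, *self.causal_b):
            if not 0 <= idx < self.n_snps:
                raise InvalidParameterError(f"causal index {idx} out of range")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a simulated suite.

    ``effects`` holds the true per-allele log-odds for every
    (snp, phenotype) pair — zero rows are materialised so that every emitted
    association is traceable to a truth row.  ``counts`` records the realized
    case/control counts per cohort x endpoint.
    """

    effects: pd.DataFrame  # snp_id, phenotype_id, beta
    counts: pd.DataFrame  # cohort_id, phenotype_id, endpoint_label, n_cases, n_controls
    snp_frequencies: pd.DataFrame  # snp_id, maf, effect_allele, other_allele

    def effect_of(self, snp_id: str, phenotype_id: str) -> float:
        sel = self.effects[
            (self.effects.snp_id == snp_id) & (self.effects.phenotype_id == phenotype_id)
        ]
        if sel.empty:
            raise KeyError((snp_id, phenotype_id))
        return float(sel.beta.iloc[0])


# ---------------------------------------------------------------------------
# core sampling operations
# ---------------------------------------------------------------------------


def simulate_genotypes(
    n_individuals: int, maf: float, rng_seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``n_individuals`` additive dosages in {0,1,2} under Hardy–Weinberg.

    Genotype classes are sampled with probabilities (1-p)^2, 2p(1-p), p^2
    where p is the minor-allele frequency.
    """
    if not 0.0 < maf <= 0.5:
        raise InvalidParameterError(f"maf must be in (0, 0.5], got {maf}")
    if n_individuals < 1:
        raise InvalidParameterError("n_individuals must be >= 1")
    rng = as_rng(rng_seed)
    p = float(maf)
    probs = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    return rng.choice(3, size=int(n_individuals), p=probs).astype(np.int64)


def simulate_ld_region(spec: LDRegionSpec) -> tuple[np.ndarray, np.ndarray]:
    """Simulate an (individuals x SNPs) dosage matrix with AR(1)-like LD.

    Returns the genotype matrix and the realized per-SNP minor-allele
    frequencies.  With ``n_snps == 1`` this reduces exactly to two summed
    Bernoulli haplotypes, i.e. Hardy–Weinberg sampling.
    """
    rng = substream(spec.rng_seed, "ld_region")
    n_hap = 2 * spec.n_individuals
    p = spec.maf
    hap = np.empty((n_hap, spec.n_snps), dtype=np.int8)
    hap[:, 0] = rng.random(n_hap) < p
    for j in range(1, spec.n_snps):
        fresh = (rng.random(n_hap) < p).astype(np.int8)
        copy = rng.random(n_hap) < spec.rho
        hap[:, j] = np.where(copy, hap[:, j - 1], fresh)
    geno = (hap[0::2, :] + hap[1::2, :]).astype(np.int64)
    freqs = geno.mean(axis=0) / 2.0
    return geno, freqs


def solve_intercept(
    linear_predictor: np.ndarray, prevalence: float, tol: float = 1e-6
) -> float:
    """Solve alpha so that mean(expit(alpha + eta)) equals the target prevalence.

    The population-averaged logistic mean is strictly increasing in alpha, so
    a bracketing root find converges; the bracket is widened geometrically
    from the logit of the target.
    """
    if not 0.0 < prevalence < 1.0:
        raise InvalidParameterError(f"prevalence must be in (0,1), got {prevalence}")
    eta = np.asarray(linear_predictor, dtype=float)

    def mean_risk(alpha: float) -> float:
        return float(np.mean(expit(alpha + eta))) - prevalence

    lo, hi = -40.0, 40.0
    if mean_risk(lo) > 0 or mean_risk(hi) < 0:
        raise InvalidParameterError(
            f"prevalence {prevalence} unreachable for the given linear predictor"
        )
    return float(brentq(mean_risk, lo, hi, xtol=tol))


def simulate_binary_endpoint(
    dosages: np.ndarray,
    beta: float,
    prevalence: float,
    rng_seed: int | np.random.Generator,
    covariate_predictor: np.ndarray | None = None,
) -> tuple[np.ndarray, int, int]:
    """Draw binary labels from a logistic model with a prevalence-matched intercept.

    Labels are Bernoulli(expit(alpha + beta*dosage + covariate_predictor))
    with alpha solved so the population-averaged risk equals ``prevalence``
    to 1e-6.  Returns (labels, n_cases, n_controls).
    """
    dos = np.asarray(dosages, dtype=float)
    eta = beta * dos
    if covariate_predictor is not None:
        cov = np.asarray(covariate_predictor, dtype=float)
        if cov.shape[0] != dos.shape[0]:
            raise InvalidParameterError("dosage and covariate lengths differ")
        eta = eta + cov
    alpha = solve_intercept(eta, prevalence)
    rng = as_rng(rng_seed)
    labels = (rng.random(dos.shape[0]) < expit(alpha + eta)).astype(np.int64)
    n_cases = int(labels.sum())
    return labels, n_cases, int(labels.size - n_cases)


# ---------------------------------------------------------------------------
# suite emission
# ---------------------------------------------------------------------------


def _simulate_covariates(
    n: int, model: CovariateModel, rng: np.random.Generator
) -> pd.DataFrame:
    lo, hi = model.age_range
    age = rng.uniform(lo, hi, n)
    sex = (rng.random(n) < model.female_fraction).astype(int)  # 1 = female
    cols = {"age": np.round(age, 2), "sex": sex}
    for k in range(model.n_pcs):
        cols[f"pc{k + 1}"] = np.round(rng.normal(0.0, 1.0, n), 6)
    return pd.DataFrame(cols)


def _covariate_predictor(cov: pd.DataFrame, model: CovariateModel) -> np.ndarray:
    # age enters centred so declared prevalences stay interpretable
    eta = model.age_beta * (cov["age"].to_numpy() - cov["age"].mean())
    eta = eta + model.sex_beta * cov["sex"].to_numpy()
    for k, b in enumerate(model.pc_betas):
        if k < model.n_pcs and b != 0.0:
            eta = eta + b * cov[f"pc{k + 1}"].to_numpy()
    return np.asarray(eta, dtype=float)


def count_analysis_endpoints(n_mapped_phenotypes: int, n_cohort_specific: int) -> int:
    """Total endpoints entering the analysis.

    Each multi-cohort (mapped) phenotype contributes one meta-analyzed
    endpoint regardless of how many cohorts observe it; each cohort-specific
    endpoint contributes individually.
    """
    if n_mapped_phenotypes < 0 or n_cohort_specific < 0:
        raise InvalidParameterError("endpoint counts must be non-negative")
    return int(n_mapped_phenotypes) + int(n_cohort_specific)


@dataclass
class CohortSuite:
    """Paths and in-memory handles for one emitted suite."""

    root: Path
    manifest: dict
    truth: SyntheticTruth
    mapping: pd.DataFrame


def emit_cohort_suite(config: SimConfig, out_dir: str | Path) -> CohortSuite:
    """Simulate and write the full multi-cohort suite.

    Per cohort: a dosage TSV (one row per SNP, one column per sample), an
    endpoints TSV (sample_id, endpoint_label, status) holding each observed
    endpoint under its cohort-local label, and a covariates TSV.  Suite-wide:
    a mapping TSV linking cohort-local labels of multi-cohort phenotypes to
    harmonized ids, a truth TSV, and a manifest JSON.
    """
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    seed = config.rng_seed

    effect_lookup = {(s, p): b for (s, p, b) in config.effect_specs}
    counts_rows: list[dict] = []
    mapping_rows: list[dict] = []
    manifest_cohorts: dict[str, dict] = {}

    for cid, n in config.cohort_sizes.items():
        n = int(n)
        # genotypes
        dosage_mat = {}
        for snp in config.snp_specs:
            dosage_mat[snp.snp_id] = simulate_genotypes(
                n, snp.maf, substream(seed, "geno", cid, snp.snp_id)
            )
        sample_ids = [f"{cid}_s{i:06d}" for i in range(n)]
        geno_df = pd.DataFrame(
            {
                "snp_id": [s.snp_id for s in config.snp_specs],
                "effect_allele": [s.effect_allele for s in config.snp_specs],
                "other_allele": [s.other_allele for s in config.snp_specs],
            }
        )
        geno_df = pd.concat(
            [
                geno_df,
                pd.DataFrame(
                    np.column_stack([dosage_mat[s.snp_id] for s in config.snp_specs]).T,
                    columns=sample_ids,
                ),
            ],
            axis=1,
        )

        cov = _simulate_covariates(n, config.covariates, substream(seed, "cov", cid))
        if config.covariates.pc_genotype_loading != 0.0 and config.snp_specs:
            # PC1 tracks the first SNP's standardized dosage: a stratification-like confounder
            d = dosage_mat[config.snp_specs[0].snp_id].astype(float)
            sd = d.std()
            if sd > 0:
                cov["pc1"] = np.round(
                    cov["pc1"] + config.covariates.pc_genotype_loading * (d - d.mean()) / sd,
                    6,
                )
        cov_eta = _covariate_predictor(cov, config.covariates)
        cov_out = cov.copy()
        cov_out.insert(0, "sample_id", sample_ids)

        # endpoints
        endp_frames = []
        for espec in config.endpoint_specs:
            if cid not in espec.cohorts:
                continue
            label = espec.label_in(cid)
            eta = cov_eta.copy()
            for snp_id, b in config.effects_on(espec.phenotype_id):
                eta = eta + b * dosage_mat[snp_id].astype(float)
            labels, n_ca, n_co = simulate_binary_endpoint(
                np.zeros(n),
                0.0,
                espec.prevalence_in(cid),
                substream(seed, "endpoint", cid, espec.phenotype_id),
                covariate_predictor=eta,
            )
            endp_frames.append(
                pd.DataFrame(
                    {"sample_id": sample_ids, "endpoint_label": label, "status": labels}
                )
            )
            counts_rows.append(
                {
                    "cohort_id": cid,
                    "phenotype_id": espec.phenotype_id,
                    "endpoint_label": label,
                    "n_cases": n_ca,
                    "n_controls": n_co,
                }
            )
        endp_df = (
            pd.concat(endp_frames, ignore_index=True)
            if endp_frames
            else pd.DataFrame(columns=["sample_id", "endpoint_label", "status"])
        )

        geno_path = root / f"{cid}.dosages.tsv"
        endp_path = root / f"{cid}.endpoints.tsv"
        cov_path = root / f"{cid}.covariates.tsv"
        geno_df.to_csv(geno_path, sep="\t", index=False)
        endp_df.to_csv(endp_path, sep="\t", index=False)
        cov_out.to_csv(cov_path, sep="\t", index=False)
        manifest_cohorts[cid] = {
            "n_individuals": n,
            "n_endpoints": int(endp_df["endpoint_label"].nunique()),
            "dosages": geno_path.name,
            "endpoints": endp_path.name,
            "covariates": cov_path.name,
        }

    # phenotype mapping: only phenotypes observed by >= 2 cohorts are "mapped"
    mapped, unmapped = [], []
    for espec in config.endpoint_specs:
        if len(espec.cohorts) >= 2:
            mapped.append(espec.phenotype_id)
            for cid in espec.cohorts:
                mapping_rows.append(
                    {
                        "cohort_id": cid,
                        "endpoint_label": espec.label_in(cid),
                        "harmonized_id": espec.phenotype_id,
                    }
                )
        else:
            unmapped.append(espec.phenotype_id)
    mapping_df = pd.DataFrame(
        mapping_rows, columns=["cohort_id", "endpoint_label", "harmonized_id"]
    )
    mapping_df.to_csv(root / "mapping.tsv", sep="\t", index=False)

    # truth ledger: every (snp, phenotype) pair gets a row, zero effects included
    truth_effect_rows = [
        {
            "snp_id": s.snp_id,
            "phenotype_id": e.phenotype_id,
            "beta": effect_lookup.get((s.snp_id, e.phenotype_id), 0.0),
        }
        for s in config.snp_specs
        for e in config.endpoint_specs
    ]
    effects_df = pd.DataFrame(truth_effect_rows, columns=["snp_id", "phenotype_id", "beta"])
    counts_df = pd.DataFrame(
        counts_rows,
        columns=["cohort_id", "phenotype_id", "endpoint_label", "n_cases", "n_controls"],
    )
    freq_df = pd.DataFrame(
        {
            "snp_id": [s.snp_id for s in config.snp_specs],
            "maf": [s.maf for s in config.snp_specs],
            "effect_allele": [s.effect_allele for s in config.snp_specs],
            "other_allele": [s.other_allele for s in config.snp_specs],
        }
    )
    effects_df.to_csv(root / "truth.effects.tsv", sep="\t", index=False)
    counts_df.to_csv(root / "truth.counts.tsv", sep="\t", index=False)
    freq_df.to_csv(root / "truth.snps.tsv", sep="\t", index=False)

    total_endpoints = sum(c["n_endpoints"] for c in manifest_cohorts.values())
    manifest = {
        "format_version": 1,
        "rng_seed": seed,
        "cohorts": manifest_cohorts,
        "n_snps": len(config.snp_specs),
        "mapped_phenotypes": sorted(mapped),
        "unmapped_phenotypes": sorted(unmapped),
        "n_mapped_phenotypes": len(mapped),
        "n_unmapped_phenotypes": len(unmapped),
        "total_endpoints": total_endpoints,
        "n_analysis_endpoints": count_analysis_endpoints(len(mapped), len(unmapped)),
        "files": {
            "mapping": "mapping.tsv",
            "truth_effects": "truth.effects.tsv",
            "truth_counts": "truth.counts.tsv",
            "truth_snps": "truth.snps.tsv",
        },
    }
    with open(root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    truth = SyntheticTruth(effects=effects_df, counts=counts_df, snp_frequencies=freq_df)
    return CohortSuite(root=root, manifest=manifest, truth=truth, mapping=mapping_df)


# ---------------------------------------------------------------------------
# external GWAS summary statistics
# ---------------------------------------------------------------------------


def gwas_se_approx(maf: float, n_cases: int, n_controls: int) -> float:
    """Case-control score-variance approximation to the SE of a per-allele log-OR."""
    if n_cases < 1 or n_controls < 1:
        raise InvalidParameterError("case and control counts must be >= 1")
    if not 0.0 < maf < 1.0:
        raise InvalidParameterError("maf must be in (0,1)")
    return float(np.sqrt((1.0 / n_cases + 1.0 / n_controls) / (2.0 * maf * (1.0 - maf))))


def emit_gwas_summary(
    truth: SyntheticTruth,
    phenotype_id: str,
    n_cases: int,
    n_controls: int,
    rng_seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Generate GWAS-style summary statistics for one phenotype from the truth table.

    For each SNP the estimate is drawn Normal(true beta, se^2) with se from
    the case-control score-variance approximation; P is the two-sided Wald
    P-value, so ``p == 2 * Phi(-|beta/se|)`` holds exactly by construction.
    """
    rng = as_rng(rng_seed)
    sel = truth.effects[truth.effects.phenotype_id == phenotype_id]
    if sel.empty:
        raise ConfigError(f"phenotype {phenotype_id!r} not in truth table")
    rows = []
    for _, row in sel.iterrows():
        frq = truth.snp_frequencies[truth.snp_frequencies.snp_id == row.snp_id].iloc[0]
        se = gwas_se_approx(float(frq.maf), n_cases, n_controls)
        beta_hat = float(rng.normal(row.beta, se))
        z = beta_hat / se
        rows.append(
            {
                "snp_id": row.snp_id,
                "effect_allele": frq.effect_allele,
                "other_allele": frq.other_allele,
                "eaf": float(frq.maf),
                "phenotype_id": phenotype_id,
                "beta": beta_hat,
                "se": se,
                "p": float(2.0 * norm.sf(abs(z))),
                "n_cases": int(n_cases),
                "n_controls": int(n_controls),
            }
        )
    return pd.DataFrame(rows)


def config_to_dict(config: SimConfig) -> dict:
    """JSON/YAML-serializable form of a SimConfig (inverse of config_from_dict)."""
    d = dataclasses.asdict(config)
    d["cohort_sizes"] = dict(config.cohort_sizes)
    return d


def config_from_dict(d: Mapping) -> SimConfig:
    """Build a SimConfig from a plain mapping (parsed YAML/JSON)."""
    try:
        snps = tuple(SnpSpec(**s) for s in d.get("snp_specs", ()))
        endpoints = tuple(
            EndpointSpec(
                phenotype_id=e["phenotype_id"],
                prevalence=e["prevalence"],
                cohorts=tuple(e["cohorts"]),
                labels=e.get("labels"),
            )
            for e in d.get("endpoint_specs", ())
        )
        effects = tuple(
            (str(s), str(p), float(b)) for (s, p, b) in d.get("effect_specs", ())
        )
        cov = d.get("covariates")
        cov_model = (
            CovariateModel(
                age_range=tuple(cov.get("age_range", (30.0, 70.0))),
                female_fraction=float(cov.get("female_fraction", 0.5)),
                n_pcs=int(cov.get("n_pcs", 2)),
                age_beta=float(cov.get("age_beta", 0.0)),
                sex_beta=float(cov.get("sex_beta", 0.0)),
                pc_betas=tuple(cov.get("pc_betas", ())),
                pc_genotype_loading=float(cov.get("pc_genotype_loading", 0.0)),
            )
            if cov
            else CovariateModel()
        )
        return SimConfig(
            cohort_sizes={str(k): int(v) for k, v in d["cohort_sizes"].items()},
            snp_specs=snps,
            endpoint_specs=endpoints,
            effect_specs=effects,
            covariates=cov_model,
            rng_seed=int(d.get("rng_seed", 0)),
        )
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"invalid simulation config: {exc}") from exc
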