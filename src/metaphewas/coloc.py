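"""Bayesian colocalization of two traits' association signals in one region.

Apparent pleiotropy — one locus associated with two phenotypes — can arise
from a single shared causal variant or from two distinct variants in linkage
disequilibrium.  Under the standard single-causal-variant framework, each
SNP receives a Wakefield approximate Bayes factor for association with each
trait, and the evidence is aggregated over the five causal-configuration
hypotheses:

- H0: no association with either trait;
- H1/H2: association with trait A only / trait B only;
- H3: both traits, two distinct causal variants;
- H4: both traits, one shared causal variant.

Posterior probabilities PP0..PP4 follow from per-SNP prior probabilities
p1, p2 (single-trait causality) and p12 (shared causality).  All hypothesis
sums are computed in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from metaphewas._errors import InvalidParameterError

#: Wakefield prior SD on the per-allele log-OR for case-control traits
PRIOR_SD_CC = 0.2
#: prior SD per unit trait SD for quantitative traits
PRIOR_SD_QUANT = 0.15

DEFAULT_P1 = 1e-4
DEFAULT_P2 = 1e-4
DEFAULT_P12 = 1e-5


@dataclass
class RegionalStats:
    """Per-SNP summary statistics for one trait over one region."""

    snp_ids: Sequence[str]
    beta: np.ndarray
    se: np.ndarray
    trait_type: str = "cc"  # "cc" or "quant"
    sd_y: float = 1.0  # trait SD, quantitative traits only

    def __post_init__(self) -> None:
        self.snp_ids = list(map(str, self.snp_ids))
        self.beta = np.asarray(self.beta, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if self.trait_type not in ("cc", "quant"):
            raise InvalidParameterError("trait_type must be 'cc' or 'quant'")
        if len(self.snp_ids) != self.beta.size or self.beta.size != self.se.size:
            raise InvalidParameterError("snp_ids, beta and se lengths differ")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise InvalidParameterError("duplicated SNP ids in regional stats")
        if np.any(self.se <= 0) or not np.all(np.isfinite(self.se)):
            raise InvalidParameterError("all standard errors must be finite and > 0")

    @property
    def prior_sd(self) -> float:
        return PRIOR_SD_CC if self.trait_type == "cc" else PRIOR_SD_QUANT * self.sd_y


@dataclass
class ColocPosterior:
    """Posterior probabilities over the five causal configurations."""

    pp: np.ndarray  # PP0..PP4
    log_abf_a: np.ndarray
    log_abf_b: np.ndarray
    snp_ids: list[str]
    priors: tuple[float, float, float]
    per_snp_pp4: np.ndarray = field(default=None)  # P(SNP is the shared variant | H4)

    @property
    def pp4(self) -> float:
        return float(self.pp[4])

    @property
    def pp3(self) -> float:
        return float(self.pp[3])

    def as_dict(self) -> dict:
        return {
            "pp0": float(self.pp[0]),
            "pp1": float(self.pp[1]),
            "pp2": float(self.pp[2]),
            "pp3": float(self.pp[3]),
            "pp4": float(self.pp[4]),
            "priors": {"p1": self.priors[0], "p2": self.priors[1], "p12": self.priors[2]},
            "n_snps": len(self.snp_ids),
        }


def approx_log_bf(
    beta: np.ndarray | float, se: np.ndarray | float, prior_sd: float
) -> np.ndarray | float:
    """Wakefield approximate log Bayes factor for association vs null, per SNP.

    With z = beta/se and shrinkage r = W^2 / (W^2 + se^2):
    ``log ABF = 0.5 * (log(1 - r) + r * z^2)``.  Positive values favour
    association; at beta = 0 the factor is below 1 (shrinkage penalty).
    """
    if prior_sd <= 0:
        raise InvalidParameterError("prior_sd must be > 0")
    b = np.asarray(beta, dtype=float)
    s = np.asarray(se, dtype=float)
    if np.any(s <= 0):
        raise InvalidParameterError("se must be > 0")
    z = b / s
    r = prior_sd**2 / (prior_sd**2 + s**2)
    out = 0.5 * (np.log1p(-r) + r * z**2)
    return out if out.ndim else float(out)


def coloc_posteriors(
    stats_a: RegionalStats,
    stats_b: RegionalStats,
    p1: float = DEFAULT_P1,
    p2: float = DEFAULT_P2,
    p12: float = DEFAULT_P12,
) -> ColocPosterior:
    """Posterior probabilities PP0..PP4 from two traits' regional statistics.

    SNPs are intersected by id (order of trait A); at least two shared SNPs
    are required.  Hypothesis evidence sums over per-SNP Bayes factors:
    H1 ~ p1 * sum_i ABF_A_i; H2 ~ p2 * sum_j ABF_B_j;
    H3 ~ p1*p2 * sum_{i != j} ABF_A_i ABF_B_j; H4 ~ p12 * sum_i ABF_A_i ABF_B_i;
    H0 ~ 1.  All sums run in log space via log-sum-exp.
    """
    for name, val in (("p1", p1), ("p2", p2), ("p12", p12)):
        if not 0.0 < val < 1.0:
            raise InvalidParameterError(f"{name} must be in (0,1)")
    idx_b = {s: i for i, s in enumerate(stats_b.snp_ids)}
    shared = [s for s in stats_a.snp_ids if s in idx_b]
    if len(shared) < 2:
        raise InvalidParameterError(
            f"colocalization needs >= 2 shared SNPs, found {len(shared)}"
        )
    ia = [stats_a.snp_ids.index(s) for s in shared]
    ib = [idx_b[s] for s in shared]
    labf_a = np.asarray(
        approx_log_bf(stats_a.beta[ia], stats_a.se[ia], stats_a.prior_sd)
    )
    labf_b = np.asarray(
        approx_log_bf(stats_b.beta[ib], stats_b.se[ib], stats_b.prior_sd)
    )

    ls_a = logsumexp(labf_a)
    ls_b = logsumexp(labf_b)
    ls_ab = logsumexp(labf_a + labf_b)

    lh0 = 0.0
    lh1 = np.log(p1) + ls_a
    lh2 = np.log(p2) + ls_b
    # sum_{i != j} = (sum_i)(sum_j) - sum_{i == j}; guarded in log space
    diff = ls_ab - (ls_a + ls_b)
    if diff >= 0.0:  # numerically degenerate: all cross mass on the diagonal
        lh3 = -np.inf
    else:
        lh3 = np.log(p1) + np.log(p2) + ls_a + ls_b + np.log1p(-np.exp(diff))
    lh4 = np.log(p12) + ls_ab

    lh = np.array([lh0, lh1, lh2, lh3, lh4])
    pp = np.exp(lh - logsumexp(lh))
    pp = pp / pp.sum()
    per_snp = np.exp(labf_a + labf_b - ls_ab)
    return ColocPosterior(
        pp=pp,
        log_abf_a=labf_a,
        log_abf_b=labf_b,
        snp_ids=shared,
        priors=(p1, p2, p12),
        per_snp_pp4=per_snp,
    )
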