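"""Multiple-testing control, case-control power, and signal classification.

Given the pooled meta-analysis results over the full test matrix and a
registry of known SNP-phenotype associations (risk allele, published OR,
whether the phenotype is the target's therapeutic hypothesis), this module

- controls multiple testing with Benjamini-Hochberg FDR (default q = 0.1)
  and a Bonferroni family-wise threshold over the exact test count;
- estimates analytic power of each known association to reach P < 0.05 in
  the meta-analysis, from the published OR, risk-allele frequency, disease
  prevalence and the realized case/control counts;
- classifies each known association as powered/replicated, and each
  non-registry signal as novel at FDR < q, labelling its direction relative
  to the target's therapeutic hypothesis (concordant -> repurposing
  candidate; discordant -> potential adverse-event signal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from metaphewas._errors import InvalidParameterError
from metaphewas.meta import MetaResult

#: CDC-reported US prevalences for the diseases most relevant to the
#: candidate-target set; overridable per phenotype.
DEFAULT_PREVALENCE: dict[str, float] = {
    "coronary_artery_disease": 0.058,
    "crohns_disease": 0.002,
    "inflammatory_bowel_disease": 0.0044,
    "myocardial_infarction": 0.03,
    "multiple_sclerosis": 0.0009,
    "primary_biliary_cirrhosis": 0.0004,
    "parkinsons_disease": 0.0007,
    "psoriasis": 0.03,
    "rheumatoid_arthritis": 0.006,
    "systemic_lupus_erythematosus": 0.002,
    "systemic_scleroderma": 0.0002,
    "type_1_diabetes": 0.005,
    "type_2_diabetes": 0.09,
    "ulcerative_colitis": 0.0024,
    "venous_thromboembolism": 0.004,
    "vitiligo": 0.01,
}


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise per-test threshold alpha/m."""
    if m < 1:
        raise InvalidParameterError("number of tests m must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise InvalidParameterError("alpha must be in (0,1)")
    return alpha / m


def bh_fdr(
    pvalues: Sequence[float], q: float = 0.1
) -> tuple[np.ndarray, np.ndarray, int]:
    """Benjamini-Hochberg step-up adjusted p-values and the discovery set.

    Missing (NaN) entries are excluded from the family and returned as NaN
    with ``reject=False``; their count is the third return value.  Adjusted
    values are monotone in raw-p rank order and capped at 1.  Discovery uses
    strict inequality: adjusted p < q.
    """
    p = np.asarray(pvalues, dtype=float)
    mask = ~np.isnan(p)
    valid = p[mask]
    if valid.size and (np.any(valid <= 0) or np.any(valid > 1)):
        raise InvalidParameterError("p-values must lie in (0, 1]")
    adjusted = np.full(p.shape, np.nan)
    reject = np.zeros(p.shape, dtype=bool)
    if valid.size:
        _, adj, _, _ = multipletests(valid, method="fdr_bh")
        adjusted[mask] = adj
        reject[mask] = adj < q
    return adjusted, reject, int((~mask).sum())


# ---------------------------------------------------------------------------
# power
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PowerParams:
    """Inputs to the analytic case-control power computation."""

    raf: float  # risk-allele frequency
    odds_ratio: float
    prevalence: float
    n_cases: int
    n_controls: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.raf < 1.0:
            raise InvalidParameterError("raf must be in (0,1)")
        if self.odds_ratio <= 0:
            raise InvalidParameterError("odds_ratio must be > 0")
        if not 0.0 < self.prevalence < 1.0:
            raise InvalidParameterError("prevalence must be in (0,1)")
        if self.n_cases < 1 or self.n_controls < 1:
            raise InvalidParameterError("counts must be >= 1")
        if not 0.0 < self.alpha <= 1.0:
            raise InvalidParameterError("alpha must be in (0,1]")


def expected_allele_frequencies(
    raf: float, odds_ratio: float, prevalence: float
) -> tuple[float, float]:
    """Expected risk-allele frequency in cases and in controls.

    Genotypes follow Hardy-Weinberg at frequency ``raf``; disease risk per
    genotype is logistic with per-allele odds ratio ``odds_ratio`` and the
    intercept solved so the population risk equals ``prevalence``
    (multiplicative-odds additive model).
    """
    p = raf
    g = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    dose = np.array([0.0, 1.0, 2.0])
    log_or = math.log(odds_ratio)

    def mean_risk(alpha: float) -> float:
        return float(np.sum(g * expit(alpha + log_or * dose))) - prevalence

    alpha0 = float(brentq(mean_risk, -40.0, 40.0, xtol=1e-12))
    f = expit(alpha0 + log_or * dose)
    p_case = float(np.sum(g * f * dose) / (2.0 * prevalence))
    p_ctrl = float(np.sum(g * (1 - f) * dose) / (2.0 * (1 - prevalence)))
    return p_case, p_ctrl


def power_case_control(params: PowerParams) -> float:
    """Analytic power of the two-sided allele-count test.

    The non-centrality comes from the expected case/control allele-frequency
    difference under the multiplicative-risk model; the rejection region uses
    the pooled null variance, the alternative uses per-group variances.
    Reduces exactly to ``alpha`` at OR = 1 and to 1 at ``alpha = 1``.
    """
    p_case, p_ctrl = expected_allele_frequencies(
        params.raf, params.odds_ratio, params.prevalence
    )
    na2, nu2 = 2.0 * params.n_cases, 2.0 * params.n_controls  # allele counts
    p_bar = (na2 * p_case + nu2 * p_ctrl) / (na2 + nu2)
    v0 = p_bar * (1 - p_bar) * (1.0 / na2 + 1.0 / nu2)
    v1 = p_case * (1 - p_case) / na2 + p_ctrl * (1 - p_ctrl) / nu2
    delta = p_case - p_ctrl
    if params.alpha >= 1.0:
        return 1.0
    z_crit = norm.isf(params.alpha / 2.0)
    s0, s1 = math.sqrt(v0), math.sqrt(v1)
    power = norm.sf((z_crit * s0 - delta) / s1) + norm.cdf((-z_crit * s0 - delta) / s1)
    return float(min(max(power, 0.0), 1.0))


# ---------------------------------------------------------------------------
# registry & classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KnownAssociation:
    """One registry row anchoring replication and directionality calls."""

    snp_id: str
    risk_allele: str
    phenotype_id: str
    published_or: float
    raf: float
    is_hypothesis: bool = False  # phenotype is the target's therapeutic hypothesis
    source: str = ""
    discovery_cohorts: tuple[str, ...] = ()  # sources to exclude from replication

    def __post_init__(self) -> None:
        if self.published_or <= 0:
            raise InvalidParameterError("published OR must be > 0")
        if not 0.0 < self.raf < 1.0:
            raise InvalidParameterError("raf must be in (0,1)")


def registry_from_frame(frame: pd.DataFrame) -> list[KnownAssociation]:
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            KnownAssociation(
                snp_id=str(row.snp_id),
                risk_allele=str(row.risk_allele),
                phenotype_id=str(row.phenotype_id),
                published_or=float(row.published_or),
                raf=float(row.raf),
                is_hypothesis=bool(getattr(row, "is_hypothesis", False)),
                source=str(getattr(row, "source", "")),
                discovery_cohorts=tuple(
                    str(getattr(row, "discovery_cohorts", "")).split(",")
                )
                if str(getattr(row, "discovery_cohorts", "")).strip()
                else (),
            )
        )
    return out


@dataclass
class SignalCall:
    """Classification of one meta-analysis result."""

    snp_id: str
    phenotype_id: str
    p: float
    adjusted_p: float | None
    known: bool
    powered: bool | None  # None when not a registry pair
    power: float | None
    replicated: bool | None
    novel: bool
    tier: str  # "none" | "fdr" | "bonferroni"
    direction_vs_hypothesis: str  # "concordant" | "discordant" | "unclassified"


def classify_replication(
    meta: MetaResult,
    known: KnownAssociation,
    power: float,
    alpha: float = 0.05,
    power_cutoff: float = 0.8,
) -> tuple[bool, bool]:
    """(powered, replicated) for one known association.

    Powered: analytic power >= ``power_cutoff``.  Replicated: powered, meta
    P < alpha, and the pooled effect on the registry's risk allele points the
    same way as the published OR.  The meta result must already be aligned to
    the registry's risk allele.
    """
    if (meta.snp_id, meta.phenotype_id) != (known.snp_id, known.phenotype_id):
        raise InvalidParameterError("meta result and registry row refer to different pairs")
    powered = bool(power >= power_cutoff)
    published_sign = math.copysign(1.0, math.log(known.published_or)) if known.published_or != 1.0 else 0.0
    observed_sign = math.copysign(1.0, meta.beta) if meta.beta != 0.0 else 0.0
    consistent = published_sign != 0.0 and published_sign == observed_sign
    replicated = powered and meta.p < alpha and consistent
    return powered, replicated


def classify_novelty(
    meta: MetaResult,
    adjusted_p: float,
    registry: Iterable[KnownAssociation],
    q: float = 0.1,
) -> tuple[bool, str]:
    """(novel, direction_vs_hypothesis) for one result.

    Novel: the (snp, phenotype) pair is absent from the registry and the
    FDR-adjusted p is strictly below ``q``.  The direction label compares the
    pooled effect (on the registry's risk-allele orientation) with the risk
    direction of the target's therapeutic-hypothesis phenotype: concordant
    signals suggest repurposing, discordant ones potential adverse events.
    """
    reg = list(registry)
    known_pairs = {(k.snp_id, k.phenotype_id) for k in reg}
    novel = (
        (meta.snp_id, meta.phenotype_id) not in known_pairs
        and adjusted_p is not None
        and not np.isnan(adjusted_p)
        and adjusted_p < q
    )
    hypothesis_rows = [
        k for k in reg if k.snp_id == meta.snp_id and k.is_hypothesis
    ]
    if not hypothesis_rows or meta.beta == 0.0:
        return novel, "unclassified"
    # registry orientation: the risk allele increases the hypothesis disease,
    # so a positive pooled beta on that allele is hypothesis-concordant
    direction = "concordant" if meta.beta > 0 else "discordant"
    return novel, direction


def classify_calls(
    results: Sequence[MetaResult],
    registry: Iterable[KnownAssociation],
    prevalence: Mapping[str, float] | None = None,
    q: float = 0.1,
    alpha: float = 0.05,
    replication_alpha: float = 0.05,
    power_cutoff: float = 0.8,
) -> tuple[list[SignalCall], dict]:
    """Classify every meta result; returns (calls, replication summary).

    FDR adjustment runs over the full result family.  Known pairs get a
    power estimate from the registry's published OR and RAF plus the
    phenotype prevalence (``prevalence`` mapping, falling back to
    DEFAULT_PREVALENCE, falling back to the realized case fraction); the
    replication summary counts powered and replicated known associations.
    Registry rows whose ``discovery_cohorts`` overlap the sources that
    contributed to the meta result are excluded from the replication family.
    """
    reg = list(registry)
    reg_by_pair = {(k.snp_id, k.phenotype_id): k for k in reg}
    m = len(results)
    pvals = np.array([r.p for r in results], dtype=float)
    adjusted, reject, _ = bh_fdr(pvals, q=q)
    bonf = bonferroni_threshold(alpha, m) if m else np.nan

    calls: list[SignalCall] = []
    powered_n = 0
    replicated_n = 0
    excluded_circular = 0
    for i, res in enumerate(results):
        pair = (res.snp_id, res.phenotype_id)
        known = pair in reg_by_pair
        powered = replicated = None
        power_val = None
        if known:
            k = reg_by_pair[pair]
            circular = bool(set(k.discovery_cohorts) & _sources_of(res))
            prev = _prevalence_for(res, k.phenotype_id, prevalence)
            power_val = power_case_control(
                PowerParams(
                    raf=k.raf,
                    odds_ratio=k.published_or,
                    prevalence=prev,
                    n_cases=max(res.n_cases, 1),
                    n_controls=max(res.n_controls, 1),
                    alpha=replication_alpha,
                )
            )
            powered, replicated = classify_replication(
                res, k, power_val, alpha=replication_alpha, power_cutoff=power_cutoff
            )
            if circular:
                excluded_circular += 1
                powered = replicated = None  # not in the replication family
            else:
                powered_n += int(powered)
                replicated_n += int(replicated and powered)
        novel, direction = classify_novelty(res, adjusted[i], reg, q=q)
        tier = (
            "bonferroni"
            if res.p < bonf
            else "fdr"
            if reject[i]
            else "none"
        )
        calls.append(
            SignalCall(
                snp_id=res.snp_id,
                phenotype_id=res.phenotype_id,
                p=res.p,
                adjusted_p=float(adjusted[i]) if not np.isnan(adjusted[i]) else None,
                known=known,
                powered=powered,
                power=power_val,
                replicated=replicated,
                novel=novel,
                tier=tier,
                direction_vs_hypothesis=direction,
            )
        )
    summary = {
        "n_tests": m,
        "bonferroni_threshold": float(bonf) if m else None,
        "fdr_q": q,
        "n_fdr_discoveries": int(reject.sum()),
        "n_known": sum(1 for c in calls if c.known),
        "n_powered": powered_n,
        "n_replicated": replicated_n,
        "n_excluded_circular": excluded_circular,
        "replication_rate": (replicated_n / powered_n) if powered_n else None,
        "n_novel": sum(1 for c in calls if c.novel),
    }
    return calls, summary


def _sources_of(res: MetaResult) -> set[str]:
    if res.sources:
        return set(res.sources)
    # singleton phenotype labels carry "cohort:endpoint"
    if ":" in res.phenotype_id and res.n_studies == 1:
        return {res.phenotype_id.split(":", 1)[0]}
    return set()


def _prevalence_for(
    res: MetaResult, phenotype_id: str, table: Mapping[str, float] | None
) -> float:
    if table and phenotype_id in table:
        return float(table[phenotype_id])
    if phenotype_id in DEFAULT_PREVALENCE:
        return DEFAULT_PREVALENCE[phenotype_id]
    total = res.n_cases + res.n_controls
    return res.n_cases / total if total else 0.5


def calls_to_frame(calls: Iterable[SignalCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "snp_id": c.snp_id,
                "phenotype_id": c.phenotype_id,
                "p": c.p,
                "adjusted_p": np.nan if c.adjusted_p is None else c.adjusted_p,
                "known": c.known,
                "power": np.nan if c.power is None else c.power,
                "powered": "NA" if c.powered is None else c.powered,
                "replicated": "NA" if c.replicated is None else c.replicated,
                "novel": c.novel,
                "tier": c.tier,
                "direction_vs_hypothesis": c.direction_vs_hypothesis,
            }
        )
    return pd.DataFrame(rows)
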