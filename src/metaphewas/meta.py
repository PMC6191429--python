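"""Fixed-effect and sample-size-weighted Z-score meta-analysis.

Two combination rules are always computed side by side:

- inverse-variance weighting (IVW) on the log-OR scale, with Cochran's Q and
  the I^2 heterogeneity percentage — the primary meta-PheWAS rule;
- Stouffer-type weighted Z with effective-sample-size weights
  ``W_i = 1 / sqrt(1/Na_i + 1/Nu_i)`` and
  ``Z = sum(W_i * Z_i) / sqrt(sum(W_i^2))`` — used whenever a source lacks a
  comparable beta scale (e.g. linear-model summary statistics).

Per-source effect directions are summarised as a Table-3-style string over a
canonical source order: '+' risk-increasing, '-' risk-decreasing, '0' exactly
null, '?' source absent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from metaphewas._errors import InvalidParameterError
from metaphewas.assoc import AssociationRecord

P_FLOOR = 1e-300

#: default canonical source order mirroring a four-cohort + external-GWAS design
DEFAULT_SOURCE_ORDER = ("cohortA", "cohortB", "cohortC", "cohortD", "GWAS")

#: heterogeneity worth manual review
I2_FLAG_THRESHOLD = 40.0


@dataclass(frozen=True)
class MetaResult:
    """Pooled effect for one SNP x harmonized phenotype."""

    snp_id: str
    phenotype_id: str
    beta: float
    se: float
    p: float
    or_: float
    ci_low: float
    ci_high: float
    q: float | None
    df: int | None
    i2: float | None
    direction: str
    n_studies: int
    n_cases: int
    n_controls: int
    weighted_z: float | None = None
    weighted_z_p: float | None = None
    sources: tuple[str, ...] = ()

    @property
    def heterogeneous(self) -> bool:
        return self.i2 is not None and self.i2 > I2_FLAG_THRESHOLD


def _wald_p(z: float) -> float:
    return float(max(2.0 * norm.sf(abs(z)), P_FLOOR))


def ivw_pool(betas: Sequence[float], ses: Sequence[float]) -> tuple[float, float, float]:
    """Inverse-variance pooled (beta, se, p)."""
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size == 0:
        raise InvalidParameterError("cannot meta-analyze zero studies")
    if np.any(s <= 0) or not np.all(np.isfinite(s)):
        raise InvalidParameterError("all standard errors must be finite and > 0")
    w = 1.0 / s**2
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    return beta, se, _wald_p(beta / se)


def heterogeneity(
    betas: Sequence[float], ses: Sequence[float]
) -> tuple[float, int, float] | None:
    """Cochran's Q, its degrees of freedom, and I^2 in percent.

    Returns None for a single study (heterogeneity undefined, not zero).
    I^2 = max(0, (Q - df)/Q) * 100, clamped to [0, 100].
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size < 2:
        return None
    w = 1.0 / s**2
    pooled = np.sum(w * b) / np.sum(w)
    q = float(np.sum(w * (b - pooled) ** 2))
    df = int(b.size - 1)
    i2 = 0.0 if q <= 0 else max(0.0, (q - df) / q) * 100.0
    return q, df, min(i2, 100.0)


def weighted_z_meta(
    z_scores: Sequence[float],
    n_cases: Sequence[int],
    n_controls: Sequence[int],
) -> tuple[float, float, np.ndarray]:
    """Effective-sample-size weighted Z combination.

    ``W_i = 1/sqrt(1/Na_i + 1/Nu_i)``; ``Z = sum(W_i Z_i)/sqrt(sum(W_i^2))``.
    Returns (combined Z, two-sided p, weights).
    """
    z = np.asarray(z_scores, dtype=float)
    na = np.asarray(n_cases, dtype=float)
    nu = np.asarray(n_controls, dtype=float)
    if not (z.size == na.size == nu.size):
        raise InvalidParameterError("z, case and control lists must have equal length")
    if z.size == 0:
        raise InvalidParameterError("cannot combine zero sources")
    if np.any(na < 1) or np.any(nu < 1):
        raise InvalidParameterError("case and control counts must be >= 1")
    w = 1.0 / np.sqrt(1.0 / na + 1.0 / nu)
    z_comb = float(np.sum(w * z) / math.sqrt(np.sum(w**2)))
    return z_comb, _wald_p(z_comb), w


def direction_string(
    betas_by_source: dict[str, float],
    source_order: Sequence[str] = DEFAULT_SOURCE_ORDER,
) -> str:
    """Per-source direction summary over the canonical source order.

    '+' for beta > 0, '-' for beta < 0, '0' for exactly zero, '?' for a
    source that did not contribute.
    """
    out = []
    for source in source_order:
        if source not in betas_by_source:
            out.append("?")
        else:
            b = betas_by_source[source]
            out.append("+" if b > 0 else "-" if b < 0 else "0")
    return "".join(out)


def fixed_effect_meta(
    records: Iterable[AssociationRecord],
    phenotype_id: str | None = None,
    source_order: Sequence[str] = DEFAULT_SOURCE_ORDER,
) -> MetaResult:
    """IVW meta-analysis of aligned records sharing one SNP and phenotype.

    Single-record groups pass through as a "meta of one" with heterogeneity
    missing, so cohort-specific endpoints flow through the same code path.
    The weighted-Z combination is computed alongside from the per-record
    Wald Z scores and case/control counts.
    """
    recs = list(records)
    if not recs:
        raise InvalidParameterError("cannot meta-analyze zero records")
    snp_ids = {r.snp_id for r in recs}
    if len(snp_ids) != 1:
        raise InvalidParameterError(f"records span multiple SNPs: {sorted(snp_ids)}")
    phe = phenotype_id if phenotype_id is not None else recs[0].endpoint_label

    betas = [r.beta for r in recs]
    ses = [r.se for r in recs]
    beta, se, p = ivw_pool(betas, ses)
    het = heterogeneity(betas, ses)
    q, df, i2 = het if het is not None else (None, None, None)
    z_comb, z_p, _ = weighted_z_meta(
        [r.z for r in recs], [r.n_cases for r in recs], [r.n_controls for r in recs]
    )
    return MetaResult(
        snp_id=recs[0].snp_id,
        phenotype_id=phe,
        beta=beta,
        se=se,
        p=p,
        or_=math.exp(beta),
        ci_low=math.exp(beta - 1.96 * se),
        ci_high=math.exp(beta + 1.96 * se),
        q=q,
        df=df,
        i2=i2,
        direction=direction_string({r.cohort_id: r.beta for r in recs}, source_order),
        n_studies=len(recs),
        n_cases=sum(r.n_cases for r in recs),
        n_controls=sum(r.n_controls for r in recs),
        weighted_z=z_comb,
        weighted_z_p=z_p,
        sources=tuple(r.cohort_id for r in recs),
    )


def meta_analyze_matrix(
    matrix,
    source_order: Sequence[str] = DEFAULT_SOURCE_ORDER,
) -> list[MetaResult]:
    """Run fixed_effect_meta over every test in a harmonize.TestMatrix."""
    results = []
    for snp_id, label, recs in matrix.all_tests():
        results.append(fixed_effect_meta(recs, phenotype_id=label, source_order=source_order))
    return results


def results_to_frame(results: Iterable[MetaResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "snp_id": r.snp_id,
                "phenotype_id": r.phenotype_id,
                "n_studies": r.n_studies,
                "beta": r.beta,
                "se": r.se,
                "or": r.or_,
                "ci95_low": r.ci_low,
                "ci95_high": r.ci_high,
                "p_ivw": r.p,
                "z_weighted": r.weighted_z,
                "p_weighted_z": r.weighted_z_p,
                "q": np.nan if r.q is None else r.q,
                "df": np.nan if r.df is None else r.df,
                "i2": np.nan if r.i2 is None else round(r.i2, 1),
                "direction": r.direction,
                "n_cases": r.n_cases,
                "n_controls": r.n_controls,
            }
        )
    return pd.DataFrame(rows)
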