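"""Per-cohort PheWAS: additive-model logistic regression per SNP x endpoint.

Each binary endpoint is regressed on the SNP dosage (0/1/2 copies of the
effect allele, non-integer dosages in [0,2] accepted) with age, sex and
PC-like covariates, one regression per SNP-endpoint pair.  Endpoints with
fewer than ``min_cases`` cases are excluded up front and logged.

The fitter is Newton-Raphson IRLS with step halving; convergence is declared
when the maximum absolute score drops below 1e-8 or the relative
log-likelihood change falls below 1e-10 within 50 iterations.  Quasi-complete
separation is flagged (``converged=False``) rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from metaphewas._errors import ConfigError, DegenerateInputError

MIN_CASES_DEFAULT = 20

_RECORD_COLUMNS = [
    "snp_id",
    "effect_allele",
    "other_allele",
    "eaf",
    "endpoint_label",
    "cohort_id",
    "beta",
    "se",
    "p",
    "n_cases",
    "n_controls",
    "converged",
]


@dataclass(frozen=True)
class AssociationRecord:
    """One SNP x endpoint x cohort logistic-regression result."""

    snp_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    endpoint_label: str
    cohort_id: str
    beta: float
    se: float
    p: float
    n_cases: int
    n_controls: int
    converged: bool = True

    @property
    def z(self) -> float:
        return self.beta / self.se

    def flipped(self) -> "AssociationRecord":
        """The same record expressed on the other allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            eaf=1.0 - self.eaf,
            beta=-self.beta,
        )


def records_to_frame(records: list[AssociationRecord]) -> pd.DataFrame:
    rows = [{c: getattr(r, c) for c in _RECORD_COLUMNS} for r in records]
    return pd.DataFrame(rows, columns=_RECORD_COLUMNS)


def records_from_frame(frame: pd.DataFrame) -> list[AssociationRecord]:
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            AssociationRecord(
                snp_id=str(row.snp_id),
                effect_allele=str(row.effect_allele),
                other_allele=str(row.other_allele),
                eaf=float(row.eaf),
                endpoint_label=str(row.endpoint_label),
                cohort_id=str(row.cohort_id),
                beta=float(row.beta),
                se=float(row.se),
                p=float(row.p),
                n_cases=int(row.n_cases),
                n_controls=int(row.n_controls),
                converged=bool(row.converged),
            )
        )
    return out


# ---------------------------------------------------------------------------
# logistic fit
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LogisticFit:
    beta: float  # dosage coefficient
    se: float
    p: float
    converged: bool
    n_iter: int
    coefficients: np.ndarray  # full vector incl. intercept & covariates
    loglik: float
    method: str = "mle"  # "mle" or "firth"


def _irls(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 50,
    score_tol: float = 1e-8,
    ll_tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, bool, int, float]:
    """Newton-Raphson with step halving; returns (coef, cov, converged, iters, ll)."""
    n, k = X.shape
    coef = np.zeros(k)
    coef[0] = np.log(y.mean() / (1.0 - y.mean()))  # intercept at observed odds
    eta = X @ coef
    ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    converged = False
    it = 0
    H = np.eye(k)
    for it in range(1, max_iter + 1):
        mu = expit(eta)
        w = mu * (1.0 - mu)
        score = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            break
        # step halving keeps the likelihood monotone
        new_ll = -np.inf
        for _ in range(30):
            cand = coef + step
            eta_c = X @ cand
            new_ll = float(y @ eta_c - np.logaddexp(0.0, eta_c).sum())
            if new_ll >= ll - 1e-12:
                break
            step = step / 2.0
        coef = coef + step
        eta = X @ coef
        rel = abs(new_ll - ll) / (abs(ll) + 1e-12)
        ll_prev, ll = ll, new_ll
        if np.max(np.abs(score)) < score_tol or rel < ll_tol:
            converged = True
            break
    mu = expit(eta)
    w = mu * (1.0 - mu)
    H = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
    # quasi-complete separation: diverging coefficients or vanishing curvature
    if converged and (np.max(np.abs(coef)) > 25.0 or not np.all(np.isfinite(cov))):
        converged = False
    return coef, cov, converged, it, ll


def _firth_irls(
    X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray, bool, int]:
    """Firth-penalized logistic fit (Jeffreys-prior score correction).

    The penalized score replaces (y - mu) with (y - mu + h*(1/2 - mu)) where
    h is the hat-matrix diagonal; estimates stay finite under separation.
    """
    n, k = X.shape
    coef = np.zeros(k)
    cov = np.eye(k)
    for it in range(1, max_iter + 1):
        mu = expit(X @ coef)
        w = mu * (1.0 - mu)
        H = (X * w[:, None]).T @ X
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return coef, np.full((k, k), np.nan), False, it
        h = np.einsum("ij,jk,ik->i", X, cov, X) * w
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = cov @ score
        # damp very large steps to keep the iteration stable
        norm = np.max(np.abs(step))
        if norm > 5.0:
            step = step * (5.0 / norm)
        coef = coef + step
        if np.max(np.abs(step)) < tol:
            return coef, cov, True, it
    return coef, cov, False, max_iter


def fit_logistic_assoc(
    dosages: np.ndarray,
    labels: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    separation_fallback: bool = False,
) -> LogisticFit:
    """Fit labels ~ intercept + dosage + covariates by maximum likelihood.

    Returns the dosage coefficient (per-allele log-odds), its standard error
    and two-sided Wald P-value.  Raises ``DegenerateInputError`` for
    single-class labels or constant dosage.  With ``separation_fallback``
    a non-converged (separated) fit is retried with the Firth penalty.
    """
    dos = np.asarray(dosages, dtype=float)
    y = np.asarray(labels, dtype=float)
    if dos.shape[0] != y.shape[0]:
        raise DegenerateInputError("dosage and label lengths differ")
    if not np.all((y == 0) | (y == 1)):
        raise DegenerateInputError("labels must be 0/1")
    if y.min() == y.max():
        raise DegenerateInputError("labels contain a single class")
    if dos.min() == dos.max():
        raise DegenerateInputError("dosage is constant")
    if np.any((dos < 0) | (dos > 2)):
        raise DegenerateInputError("dosages must lie in [0, 2]")

    cols = [np.ones_like(dos), dos]
    if covariates is not None:
        C = (
            covariates.to_numpy(dtype=float)
            if isinstance(covariates, pd.DataFrame)
            else np.asarray(covariates, dtype=float)
        )
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[0] != dos.shape[0]:
            raise DegenerateInputError("covariate rows do not match dosage length")
        # drop constant covariate columns (they alias the intercept)
        keep = [j for j in range(C.shape[1]) if C[:, j].min() != C[:, j].max()]
        cols.extend(C[:, j] for j in keep)
    X = np.column_stack(cols)

    coef, cov, converged, it, ll = _irls(X, y)
    method = "mle"
    if not converged and separation_fallback:
        coef_f, cov_f, ok, it_f = _firth_irls(X, y)
        if ok:
            coef, cov, converged, it, method = coef_f, cov_f, True, it_f, "firth"
            eta = X @ coef
            ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    beta = float(coef[1])
    var = float(cov[1, 1]) if np.isfinite(cov[1, 1]) else np.nan
    se = float(np.sqrt(var)) if var > 0 else np.nan
    if np.isfinite(se) and se > 0:
        p = float(max(2.0 * norm.sf(abs(beta / se)), 1e-300))
    else:
        p = np.nan
        converged = False
    return LogisticFit(
        beta=beta, se=se, p=p, converged=converged, n_iter=it,
        coefficients=coef, loglik=ll, method=method,
    )


# ---------------------------------------------------------------------------
# cohort-level PheWAS
# ---------------------------------------------------------------------------


@dataclass
class CohortData:
    """One cohort's dosages (SNP x sample), endpoints (long) and covariates."""

    cohort_id: str
    dosages: pd.DataFrame  # snp_id, effect_allele, other_allele, <sample columns>
    endpoints: pd.DataFrame  # sample_id, endpoint_label, status
    covariates: pd.DataFrame  # sample_id, age, sex, pc1, ...

    @classmethod
    def from_suite(cls, suite_dir: str | Path, cohort_id: str) -> "CohortData":
        root = Path(suite_dir)
        return cls(
            cohort_id=cohort_id,
            dosages=pd.read_csv(root / f"{cohort_id}.dosages.tsv", sep="\t"),
            endpoints=pd.read_csv(root / f"{cohort_id}.endpoints.tsv", sep="\t"),
            covariates=pd.read_csv(root / f"{cohort_id}.covariates.tsv", sep="\t"),
        )

    def sample_ids(self) -> list[str]:
        return [c for c in self.dosages.columns if c not in ("snp_id", "effect_allele", "other_allele")]


def run_phewas(
    cohort: CohortData,
    snp_ids: list[str] | None = None,
    min_cases: int = MIN_CASES_DEFAULT,
    covariate_columns: list[str] | None = None,
) -> tuple[list[AssociationRecord], list[dict]]:
    """Run the cohort PheWAS: one logistic fit per SNP x eligible endpoint.

    Endpoints with fewer than ``min_cases`` cases are excluded and reported
    in the exclusion log; non-converged fits are retained but flagged.
    Returns (records, exclusion_log).
    """
    samples = cohort.sample_ids()
    dosage_rows = cohort.dosages
    if snp_ids is not None:
        dosage_rows = dosage_rows[dosage_rows.snp_id.isin(snp_ids)]

    cov = cohort.covariates.set_index("sample_id").loc[samples]
    if covariate_columns is None:
        covariate_columns = [c for c in cov.columns]
    missing = [c for c in covariate_columns if c not in cov.columns]
    if missing:
        raise ConfigError(
            f"cohort {cohort.cohort_id}: covariate column(s) {missing} not found"
        )
    cov_mat = cov[covariate_columns]

    status = cohort.endpoints.pivot_table(
        index="sample_id", columns="endpoint_label", values="status", aggfunc="first"
    )

    exclusions: list[dict] = []
    eligible: list[str] = []
    for label in sorted(status.columns):
        n_cases = int(status[label].sum())
        if n_cases < min_cases:
            exclusions.append(
                {
                    "cohort_id": cohort.cohort_id,
                    "endpoint_label": label,
                    "reason": "min_cases",
                    "n_cases": n_cases,
                    "threshold": min_cases,
                }
            )
        else:
            eligible.append(label)

    cov_arr = cov_mat.to_numpy(dtype=float)
    records: list[AssociationRecord] = []
    for _, row in dosage_rows.iterrows():
        dos = row[samples].to_numpy(dtype=float)
        eaf = float(np.nanmean(dos) / 2.0)
        for label in eligible:
            y_series = status[label].reindex(samples)
            mask = y_series.notna().to_numpy() & np.isfinite(dos)
            y = y_series.to_numpy(dtype=float)[mask]
            d = dos[mask]
            try:
                fit = fit_logistic_assoc(d, y, cov_arr[mask])
            except DegenerateInputError as exc:
                exclusions.append(
                    {
                        "cohort_id": cohort.cohort_id,
                        "endpoint_label": label,
                        "snp_id": str(row.snp_id),
                        "reason": "degenerate",
                        "detail": str(exc),
                    }
                )
                continue
            n_cases = int(y.sum())
            records.append(
                AssociationRecord(
                    snp_id=str(row.snp_id),
                    effect_allele=str(row.effect_allele),
                    other_allele=str(row.other_allele),
                    eaf=eaf,
                    endpoint_label=label,
                    cohort_id=cohort.cohort_id,
                    beta=fit.beta,
                    se=fit.se,
                    p=fit.p,
                    n_cases=n_cases,
                    n_controls=int(y.size - n_cases),
                    converged=fit.converged,
                )
            )
    return records, exclusions
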