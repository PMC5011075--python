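"""Per-study association analysis for kidney-function GWAS.

Covers the within-study stages: eGFR from serum creatinine via the
four-variable MDRD equation, imputation-quality filtering, additive-dosage
linear regression for eGFR, logistic regression for CKD status, conditional
analysis on a lead variant, and genomic-control correction for residual
population structure.

Summary statistics move between stages as a pandas DataFrame with columns
``chrom, pos, effect_allele, other_allele, eaf, beta, se, p, n, info,
software`` (the native dialect defined in :mod:`transfine.pipeline_io`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

logger = logging.getLogger(__name__)

__all__ = [
    "GCResult",
    "mdrd_egfr",
    "qc_filter",
    "linear_assoc",
    "logistic_assoc",
    "conditional_assoc",
    "genomic_control",
    "SOFTWARE_THRESHOLDS",
]

# Quality-control thresholds by imputation-software dialect: IMPUTE2 reports
# an info score (keep >= 0.4), MaCH/Minimac report r2 (keep >= 0.3).
SOFTWARE_THRESHOLDS: dict[str, float] = {
    "IMPUTE2": 0.4,
    "MACH": 0.3,
    "MINIMAC": 0.3,
}

# Median of chi-square with 1 df; denominator of the genomic-control lambda.
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))


@dataclass(frozen=True)
class GCResult:
    """Genomic-control inflation factor and the variant count it was based on."""

    lambda_gc: float
    n_variants: int

    def __post_init__(self) -> None:
        if self.lambda_gc <= 0:
            raise ValueError("lambda_gc must be positive")


def mdrd_egfr(serum_creatinine, age, female, black):
    """Estimated GFR (mL/min/1.73 m²) from the 4-variable MDRD study equation.

    eGFR = 175 * Scr^-1.154 * age^-0.203 * 0.742^female * 1.212^black,
    with serum creatinine in mg/dL (IDMS-traceable) and age in years.
    """
    scr = np.asarray(serum_creatinine, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(scr <= 0):
        raise ValueError("serum creatinine must be positive")
    if np.any(age <= 0):
        raise ValueError("age must be positive")
    out = (
        175.0
        * scr**-1.154
        * age**-0.203
        * np.where(np.asarray(female, dtype=bool), 0.742, 1.0)
        * np.where(np.asarray(black, dtype=bool), 1.212, 1.0)
    )
    return out if out.ndim else float(out)


def qc_filter(stats_table: pd.DataFrame) -> pd.DataFrame:
    """Drop variants failing the imputation-quality threshold of their dialect.

    Requires ``info`` and ``software`` columns; thresholds are inclusive
    (info >= 0.4 for IMPUTE2, r2 >= 0.3 for MaCH/Minimac). Idempotent.
    """
    tags = stats_table["software"].astype(str).str.upper()
    unknown = sorted(set(tags) - set(SOFTWARE_THRESHOLDS))
    if unknown:
        raise ValueError(f"unknown imputation software tag(s): {unknown}")
    cutoffs = tags.map(SOFTWARE_THRESHOLDS)
    keep = stats_table["info"].to_numpy(dtype=float) >= cutoffs.to_numpy(dtype=float)
    n_removed = int((~keep).sum())
    logger.info("qc_filter: kept %d variants, removed %d", int(keep.sum()), n_removed)
    return stats_table.loc[keep].reset_index(drop=True)


def _residualize(design: np.ndarray, *arrays: np.ndarray) -> tuple[np.ndarray, ...]:
    """Project out a full-rank design (QR) from each array; returns residuals."""
    q, _ = np.linalg.qr(design)
    return tuple(a - q @ (q.T @ a) for a in arrays)


def _check_full_rank(design: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify an offending column: first one not increasing the rank
        for j in range(1, design.shape[1]):
            if np.linalg.matrix_rank(design[:, : j + 1]) <= np.linalg.matrix_rank(design[:, :j]):
                raise ValueError(f"collinear covariate column: {names[j]}")
        raise ValueError("covariate matrix not full rank")


def linear_assoc(
    dosages: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    covariate_names: list[str] | None = None,
) -> pd.DataFrame:
    """Per-variant OLS of phenotype on dosage under an additive model.

    Each variant is fitted separately with an intercept and the shared
    covariates; by Frisch-Waugh-Lovell this is done by residualizing
    phenotype and dosages on [1, covariates] once, then simple regression,
    which is exactly the full OLS solution. Returns columns
    ``beta, se, t, p`` (two-sided, Student-t with n - k - 2 df).

    A dosage column collinear with the covariates (zero residual variance)
    yields NaN estimates rather than an error.
    """
    dosages = np.atleast_2d(np.asarray(dosages, dtype=float))
    phenotype = np.asarray(phenotype, dtype=float)
    n = len(phenotype)
    if dosages.shape[0] != n:
        raise ValueError("dosage rows must match phenotype length")
    if np.any(~np.isfinite(dosages)) or np.any(~np.isfinite(phenotype)):
        raise ValueError("missing or non-finite values in dosages/phenotype")

    if covariates is None:
        covariates = np.empty((n, 0))
    covariates = np.asarray(covariates, dtype=float)
    design = np.column_stack([np.ones(n), covariates])
    names = ["intercept"] + (
        covariate_names
        if covariate_names is not None
        else [f"covariate_{j}" for j in range(covariates.shape[1])]
    )
    _check_full_rank(design, names)

    y_r, d_r = _residualize(design, phenotype, dosages)
    dss = np.einsum("ij,ij->j", d_r, d_r)
    df_resid = n - design.shape[1] - 1
    if df_resid <= 0:
        raise ValueError("not enough observations for the requested model")

    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (d_r.T @ y_r) / dss
        resid_ss = (y_r @ y_r) - beta**2 * dss
        resid_ss = np.clip(resid_ss, 0.0, None)
        sigma2 = resid_ss / df_resid
        se = np.sqrt(sigma2 / dss)
        tstat = beta / se
    # collinear-with-covariates dosages have ~zero residual sum of squares
    degenerate = dss <= max(np.max(dss), 1.0) * 1e-10
    beta[degenerate] = np.nan
    se[degenerate] = np.nan
    tstat[degenerate] = np.nan
    p = 2.0 * stats.t.sf(np.abs(tstat), df=df_resid)
    return pd.DataFrame({"beta": beta, "se": se, "t": tstat, "p": p})


def logistic_assoc(
    dosages: np.ndarray,
    case_status: np.ndarray,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-variant logistic regression of case/control status on dosage.

    Maximum-likelihood fit with intercept and covariates; Wald two-sided p.
    Complete separation (or other fit failure) marks the variant with NaN
    estimates and ``converged = False`` instead of raising.
    """
    dosages = np.atleast_2d(np.asarray(dosages, dtype=float))
    y = np.asarray(case_status, dtype=float)
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0.0, 1.0))) or len(classes) < 2:
        raise ValueError("case_status must contain both 0s and 1s")
    n = len(y)
    if covariates is None:
        covariates = np.empty((n, 0))
    base = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])

    rows = []
    for j in range(dosages.shape[1]):
        x = np.column_stack([base, dosages[:, j]])
        try:
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore")  # separation is flagged, not raised
                fit = sm.Logit(y, x).fit(disp=0, maxiter=100)
            beta = fit.params[-1]
            se = fit.bse[-1]
            converged = bool(fit.mle_retvals.get("converged", True)) and np.isfinite(se) and se < 1e3
        except (PerfectSeparationError, np.linalg.LinAlgError):
            converged = False
        if not converged:
            rows.append((np.nan, np.nan, np.nan, False))
            continue
        z = beta / se
        rows.append((beta, se, 2.0 * stats.norm.sf(abs(z)), True))
    return pd.DataFrame(rows, columns=["beta", "se", "p", "converged"])


def conditional_assoc(
    dosages: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None,
    lead_dosage: np.ndarray,
) -> pd.DataFrame:
    """Association conditioned on the lead variant's genotype dosage.

    Identical to :func:`linear_assoc` with the lead dosage appended to the
    covariates. The lead variant itself (and anything in perfect LD with
    it) comes back with NaN estimates. A lead dosage collinear with an
    existing covariate raises.
    """
    n = len(phenotype)
    if covariates is None:
        covariates = np.empty((n, 0))
    covariates = np.asarray(covariates, dtype=float)
    lead = np.asarray(lead_dosage, dtype=float).reshape(-1)
    if lead.shape[0] != n:
        raise ValueError("lead dosage length must match phenotype")
    names = [f"covariate_{j}" for j in range(covariates.shape[1])] + ["lead_dosage"]
    return linear_assoc(
        dosages,
        phenotype,
        covariates=np.column_stack([covariates, lead]),
        covariate_names=names,
    )


def genomic_control(
    stats_table: pd.DataFrame, min_variants: int = 30
) -> tuple[GCResult, pd.DataFrame]:
    """Genomic-control correction of a summary-statistics table.

    lambda = median(z²) / median(chi²₁); if lambda > 1, SEs are inflated by
    sqrt(lambda) (equivalently chi² statistics divided by lambda) and
    p-values recomputed from the rescaled z; betas are untouched. lambda is
    floored at 1 — deflation is never applied.
    """
    if len(stats_table) < min_variants:
        raise ValueError(
            f"genomic control needs >= {min_variants} variants, got {len(stats_table)}"
        )
    beta = stats_table["beta"].to_numpy(dtype=float)
    se = stats_table["se"].to_numpy(dtype=float)
    z2 = (beta / se) ** 2
    ok = np.isfinite(z2)
    lam = float(np.median(z2[ok]) / CHI2_1_MEDIAN)
    result = GCResult(lambda_gc=lam, n_variants=int(ok.sum()))
    corrected = stats_table.copy()
    factor = max(lam, 1.0)
    if factor > 1.0:
        corrected["se"] = se * np.sqrt(factor)
        z = beta / corrected["se"].to_numpy()
        corrected["p"] = 2.0 * stats.norm.sf(np.abs(z))
    logger.info("genomic_control: lambda=%.4f over %d variants", lam, result.n_variants)
    return result, corrected
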