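"""Linear-model cis-eQTL mapping with Bonferroni and FDR control.

Every SNP-target association is an ordinary-least-squares fit of
normalized expression on allele dosage with an intercept and covariates
(genotype PCs, imputation status), two-sided t-test on the dosage slope.
The batch scanner residualizes expression and dosages on the covariates
once (Frisch-Waugh-Lovell), which reproduces the full-model slope, SE and
P exactly while staying vectorized.

Multiple-testing control follows the integration pipeline's two scopes:
Bonferroni per disease per quantification type for the GWAS-anchored scan,
and Benjamini-Hochberg FDR per quantification type for the genome-wide
scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CovariateSet, ExpressionSet, GenotypeMatrix, GwasLead

logger = logging.getLogger(__name__)

#: Smallest P ever reported; underflowing P-values are floored here so that
#: log-space plots and BH adjustment stay well-defined.
MIN_P = float(np.finfo(float).tiny)

ASSOC_COLUMNS = [
    "lead_snp", "disease", "snp_id", "target_id", "gene_id", "quant_type",
    "beta", "se", "tstat", "p", "n",
]


class ConstantDosageError(ValueError):
    """The dosage vector has no variance; the association is undefined."""


@dataclass(frozen=True)
class CisWindowPolicy:
    """Window geometry of the GWAS-anchored cis scan."""

    tss_window_bp: int = 500_000
    lead_window_bp: int = 100_000
    nominal_p: float = 0.01

    def __post_init__(self) -> None:
        if min(self.tss_window_bp, self.lead_window_bp, self.nominal_p) <= 0:
            raise ValueError("window policy fields must be positive")


@dataclass(frozen=True)
class AssocStats:
    beta: float
    se: float
    tstat: float
    p: float
    n: int


def _design(covars: np.ndarray, n: int) -> np.ndarray:
    """Intercept + covariates, with collinear covariate columns dropped."""
    x = np.column_stack([np.ones(n), covars]) if covars.size else np.ones((n, 1))
    q, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    keep = diag > diag.max() * 1e-10
    if not keep.all():
        logger.warning("dropping %d collinear covariate column(s)", int((~keep).sum()))
        x = x[:, keep]
    return x


def fit_association(
    dosage: np.ndarray,
    expr: np.ndarray,
    covars: CovariateSet | np.ndarray | None = None,
) -> AssocStats:
    """OLS slope of expression on dosage with intercept and covariates.

    Returns the slope, its standard error, the t statistic and the
    two-sided P-value.  Missing values are dropped pairwise; a constant
    dosage raises :class:`ConstantDosageError`.
    """
    dosage = np.asarray(dosage, dtype=float)
    expr = np.asarray(expr, dtype=float)
    if isinstance(covars, CovariateSet):
        cov = covars.matrix.to_numpy(dtype=float)
    elif covars is None:
        cov = np.empty((dosage.size, 0))
    else:
        cov = np.asarray(covars, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    ok = ~(np.isnan(dosage) | np.isnan(expr))
    if cov.size:
        ok &= ~np.isnan(cov).any(axis=1)
    dosage, expr, cov = dosage[ok], expr[ok], cov[ok]
    n = dosage.size
    if np.ptp(dosage) == 0:
        raise ConstantDosageError("constant dosage vector")
    x = np.column_stack([_design(cov, n), dosage])
    k = x.shape[1]
    if n <= k + 1:
        raise ValueError(f"need n > k + 2 observations (n={n}, k={k - 2})")
    coef, _, _, _ = np.linalg.lstsq(x, expr, rcond=None)
    resid = expr - x @ coef
    df = n - k
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(x.T @ x)
    se = float(np.sqrt(sigma2 * xtx_inv[-1, -1]))
    beta = float(coef[-1])
    if se == 0.0:
        return AssocStats(beta, 0.0, np.inf if beta >= 0 else -np.inf, MIN_P, n)
    t = beta / se
    p = max(2.0 * stats.t.sf(abs(t), df), MIN_P)
    return AssocStats(beta, se, t, p, n)


def residualize(y: np.ndarray, covars: np.ndarray) -> np.ndarray:
    """Residuals of y on [intercept, covariates] (column-wise if 2-D)."""
    y = np.asarray(y, dtype=float)
    x = _design(np.asarray(covars, dtype=float), y.shape[0])
    coef, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ coef


def batch_association(
    dosages: np.ndarray,
    expr: np.ndarray,
    covars: np.ndarray,
) -> pd.DataFrame:
    """Vectorized OLS of one expression vector on many dosage columns.

    Residualizes both sides on the covariates (plus intercept) and fits
    each simple regression on the residuals; slope, SE, t and P are
    algebraically identical to the full multiple regression.  Constant
    dosage columns get P = 1 and beta = 0 (they carry no information).
    """
    n, m = dosages.shape
    x0 = _design(covars, n)
    k0 = x0.shape[1]
    proj = lambda a: a - x0 @ np.linalg.lstsq(x0, a, rcond=None)[0]  # noqa: E731
    dz = proj(dosages)
    yz = proj(expr)
    sxx = np.einsum("ij,ij->j", dz, dz)
    sxy = dz.T @ yz
    const = sxx <= 0
    sxx_safe = np.where(const, 1.0, sxx)
    beta = sxy / sxx_safe
    syy = float(yz @ yz)
    rss = np.maximum(syy - beta * sxy, 0.0)
    df = n - k0 - 1
    sigma2 = rss / df
    se = np.sqrt(sigma2 / sxx_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.sign(beta) * np.inf)
    p = np.clip(2.0 * stats.t.sf(np.abs(t), df), MIN_P, 1.0)
    beta[const] = 0.0
    se[const] = np.nan
    t[const] = 0.0
    p[const] = 1.0
    return pd.DataFrame({"beta": beta, "se": se, "tstat": t, "p": p, "n": n})


def select_cis_pairs(
    leads: list[GwasLead],
    targets: pd.DataFrame,
    snps: pd.DataFrame,
    policy: CisWindowPolicy = CisWindowPolicy(),
) -> pd.DataFrame:
    """Enumerate the GWAS-anchored SNP-target test universe.

    A pair (SNP, target) is tested for a lead when the SNP lies within
    ``lead_window_bp`` of the lead and the target's TSS within
    ``tss_window_bp`` of the lead.  Per-lead pair counts are logged.
    """
    rows = []
    for lead in leads:
        snp_ok = snps.index[
            (snps["chrom"].astype(str) == lead.chrom)
            & ((snps["pos"] - lead.pos).abs() <= policy.lead_window_bp)
        ]
        tgt_ok = targets.index[
            (targets["chrom"].astype(str) == lead.chrom)
            & ((targets["tss"] - lead.pos).abs() <= policy.tss_window_bp)
        ]
        if len(tgt_ok) == 0:
            logger.info("lead %s: no cis targets on chromosome %s", lead.snp_id, lead.chrom)
        for sid in snp_ok:
            for tid in tgt_ok:
                rows.append((lead.snp_id, lead.disease, sid, tid))
        logger.debug(
            "lead %s: %d SNPs x %d targets", lead.snp_id, len(snp_ok), len(tgt_ok)
        )
    return pd.DataFrame(rows, columns=["lead_snp", "disease", "snp_id", "target_id"])


def scan_pairs(
    geno: GenotypeMatrix,
    expr: ExpressionSet,
    pairs: pd.DataFrame,
    covars: CovariateSet,
) -> pd.DataFrame:
    """Fit every (snp, target) pair in ``pairs``; returns ASSOC_COLUMNS rows."""
    cov = covars.aligned(geno.samples)
    out = []
    for (lead_snp, disease, tid), grp in pairs.groupby(
        ["lead_snp", "disease", "target_id"], sort=False
    ):
        y = expr.values[tid].to_numpy(dtype=float)
        snp_ids = grp["snp_id"].tolist()
        dos = geno.dosages.loc[:, snp_ids].to_numpy(dtype=float)
        res = batch_association(dos, y, cov)
        res.insert(0, "lead_snp", lead_snp)
        res.insert(1, "disease", disease)
        res.insert(2, "snp_id", snp_ids)
        res.insert(3, "target_id", tid)
        res.insert(4, "gene_id", expr.targets.loc[tid, "gene_id"])
        res.insert(5, "quant_type", expr.quant_type)
        out.append(res)
    if not out:
        return pd.DataFrame(columns=ASSOC_COLUMNS)
    return pd.concat(out, ignore_index=True)[ASSOC_COLUMNS]


def adjust_bonferroni(
    records: pd.DataFrame, scope: tuple[str, ...] = ("disease", "quant_type")
) -> pd.DataFrame:
    """p_bf = min(1, m * p) with m = number of records in each scope group."""
    records = records.copy()
    if records.empty:
        records["p_bf"] = pd.Series(dtype=float)
        return records
    m = records.groupby(list(scope))["p"].transform("size")
    records["p_bf"] = np.minimum(1.0, records["p"] * m)
    return records


def adjust_fdr(records: pd.DataFrame, scope: tuple[str, ...] = ("quant_type",)) -> pd.DataFrame:
    """Benjamini-Hochberg step-up q-values within each scope group."""
    from statsmodels.stats.multitest import multipletests

    records = records.copy()
    if records.empty:
        records["q"] = pd.Series(dtype=float)
        return records
    q = pd.Series(np.nan, index=records.index)
    for _, grp in records.groupby(list(scope)):
        q.loc[grp.index] = multipletests(grp["p"].to_numpy(), method="fdr_bh")[1]
    records["q"] = q
    return records
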