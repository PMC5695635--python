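"""Systematic-vs-heterogeneous cis-eQTL test via a crossed-intercepts LMM.

For a gene with T expression elements measured in n individuals, the
*systematic* model is

    y_st = b0 + b1 * dosage_s + u_s + v_t + e_st

with crossed Gaussian random intercepts per individual (u_s) and per
element (v_t), and the *heterogeneous* model adds fixed dosage x element
interaction terms (T - 1 of them).  Both are fitted by maximum likelihood
(not REML: the likelihood-ratio test compares models differing in fixed
effects) and compared with chi^2_{T-1}.

Fitting exploits the balanced crossed design: with samples x elements on a
complete grid, the marginal covariance

    V = sigma_e^2 I + sigma_u^2 (I_n (x) J_T) + sigma_v^2 (J_n (x) I_T)

is diagonal in the Kronecker product of any orthonormal bases whose first
vectors are constant, with eigenvalues
sigma_e^2 + T sigma_u^2 [j=0] + n sigma_v^2 [i=0].  The profiled
log-likelihood over the two variance ratios is maximised by L-BFGS-B from
several starts; each evaluation is a weighted least-squares solve, so a
fit costs milliseconds rather than a dense-covariance factorization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

logger = logging.getLogger(__name__)

__all__ = ["HetResult", "HetFit", "HeterogeneityModel", "fit_het_test", "adjust_het_bonferroni"]

_LOG_GAMMA_BOUNDS = (-30.0, 12.0)
_STARTS = [(-2.0, -2.0), (0.0, 0.0), (-8.0, -8.0), (2.0, -4.0)]


@dataclass
class _LmmFit:
    loglik: float
    beta: np.ndarray
    sigma_e: float
    sigma_u: float            # per-sample random intercept SD
    sigma_v: float            # per-target random intercept SD
    converged: bool
    boundary: bool            # a variance ratio ended at the search boundary


def _helmert_basis(n: int) -> np.ndarray:
    """Orthonormal basis of R^n whose first column is constant."""
    return linalg.helmert(n, full=True).T


def _fit_crossed_lmm(y_grid: np.ndarray, x_cols: list[np.ndarray]) -> _LmmFit:
    """ML fit of y = X beta + u_s + v_t + e on a complete n x T grid.

    ``y_grid`` is n x T; every element of ``x_cols`` is an n x T array
    giving one fixed-effect column evaluated on the grid.
    """
    n, T = y_grid.shape
    N = n * T
    hn = _helmert_basis(n)
    ht = _helmert_basis(T)
    yt = (hn.T @ y_grid @ ht).reshape(-1)
    xt = np.column_stack([(hn.T @ c @ ht).reshape(-1) for c in x_cols])
    # weight pattern masks: entry (i, j) flattened row-major
    col0 = np.zeros((n, T), dtype=bool)
    col0[:, 0] = True
    row0 = np.zeros((n, T), dtype=bool)
    row0[0, :] = True
    mask_u = col0.reshape(-1)   # picks up T * gamma_u
    mask_v = row0.reshape(-1)   # picks up n * gamma_v

    def profile_negll(theta: np.ndarray) -> float:
        gu, gv = np.exp(theta)
        w = 1.0 + gu * T * mask_u + gv * n * mask_v
        sw = 1.0 / np.sqrt(w)
        coef, _, _, _ = np.linalg.lstsq(xt * sw[:, None], yt * sw, rcond=None)
        rss = float(np.sum(((yt - xt @ coef) ** 2) / w))
        sigma2 = rss / N
        return 0.5 * (N * (np.log(2 * np.pi * sigma2) + 1.0) + np.sum(np.log(w)))

    best = None
    for start in _STARTS:
        res = optimize.minimize(
            profile_negll,
            np.array(start),
            method="L-BFGS-B",
            bounds=[_LOG_GAMMA_BOUNDS] * 2,
            options={"ftol": 1e-12, "gtol": 1e-9},
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    assert best is not None
    gu, gv = np.exp(best.x)
    w = 1.0 + gu * T * mask_u + gv * n * mask_v
    sw = 1.0 / np.sqrt(w)
    coef, _, _, _ = np.linalg.lstsq(xt * sw[:, None], yt * sw, rcond=None)
    sigma_e2 = float(np.sum(((yt - xt @ coef) ** 2) / w)) / N
    boundary = bool(
        np.any(np.abs(best.x - _LOG_GAMMA_BOUNDS[0]) < 1e-6)
        or np.any(np.abs(best.x - _LOG_GAMMA_BOUNDS[1]) < 1e-6)
    )
    return _LmmFit(
        loglik=-float(best.fun),
        beta=coef,
        sigma_e=float(np.sqrt(sigma_e2)),
        sigma_u=float(np.sqrt(gu * sigma_e2)),
        sigma_v=float(np.sqrt(gv * sigma_e2)),
        converged=bool(best.success),
        boundary=boundary,
    )


@dataclass
class HetResult:
    """LRT outcome for one SNP-gene pair at one quantification type."""

    snp_id: str
    gene_id: str
    quant_type: str
    n_targets: int
    chisq: float
    df: int
    p: float
    p_bf: float = np.nan
    model: str = "untestable"      # systematic | heterogeneous | untestable
    converged: bool = False
    boundary: bool = False
    loglik_systematic: float = np.nan
    loglik_heterogeneous: float = np.nan


@dataclass
class HetFit:
    """Full fit bundle from :meth:`HeterogeneityModel.fit`."""

    result: HetResult
    systematic: _LmmFit | None = None
    heterogeneous: _LmmFit | None = None

    def summary(self) -> str:
        r = self.result
        lines = [
            f"Heterogeneity LRT: {r.snp_id} x {r.gene_id} [{r.quant_type}]",
            f"  targets: {r.n_targets}   chi2 = {r.chisq:.4f}  df = {r.df}  "
            f"P = {r.p:.3g}",
            f"  model call: {r.model}",
        ]
        if self.systematic:
            s = self.systematic
            lines.append(
                f"  systematic fit: logL = {s.loglik:.4f}  "
                f"sd(sample) = {s.sigma_u:.3f}  sd(target) = {s.sigma_v:.3f}  "
                f"sd(resid) = {s.sigma_e:.3f}"
            )
        if self.heterogeneous:
            lines.append(f"  heterogeneous fit: logL = {self.heterogeneous.loglik:.4f}")
        return "\n".join(lines)


class HeterogeneityModel:
    """Crossed-intercepts mixed model for one gene's expression elements.

    Parameters
    ----------
    long_data
        DataFrame with columns ``sample, target, expression, dosage``;
        each (sample, target) pair at most once, dosage constant within
        sample.  Samples missing any target are dropped (the balanced
        spectral solver needs a complete grid).
    """

    def __init__(
        self,
        long_data: pd.DataFrame,
        snp_id: str = "",
        gene_id: str = "",
        quant_type: str = "",
    ) -> None:
        req = {"sample", "target", "expression", "dosage"}
        missing = req - set(long_data.columns)
        if missing:
            raise ValueError(f"long_data lacks columns {sorted(missing)}")
        if long_data.duplicated(["sample", "target"]).any():
            raise ValueError("duplicate (sample, target) rows")
        self.snp_id, self.gene_id, self.quant_type = snp_id, gene_id, quant_type

        grid = long_data.pivot(index="sample", columns="target", values="expression")
        complete = grid.dropna()
        if len(complete) < len(grid):
            logger.info(
                "HeterogeneityModel: dropped %d incomplete samples",
                len(grid) - len(complete),
            )
        self.targets = list(complete.columns)
        self.samples = list(complete.index)
        dose = long_data.drop_duplicates("sample").set_index("sample")["dosage"]
        if long_data.groupby("sample")["dosage"].nunique().max() > 1:
            raise ValueError("dosage must be constant within sample")
        self.dosage = dose.loc[self.samples].to_numpy(dtype=float)
        self.y = complete.to_numpy(dtype=float)
        if len(self.samples) >= 10 and np.ptp(self.dosage) == 0:
            raise ValueError("constant dosage: heterogeneity test undefined")

    @classmethod
    def from_matrices(
        cls,
        expr: pd.DataFrame,
        dosage: pd.Series,
        snp_id: str = "",
        gene_id: str = "",
        quant_type: str = "",
    ) -> "HeterogeneityModel":
        long = expr.stack().rename("expression").reset_index()
        long.columns = ["sample", "target", "expression"]
        long["dosage"] = dosage.loc[long["sample"]].to_numpy()
        return cls(long, snp_id, gene_id, quant_type)

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    def fit(self) -> HetFit:
        T = self.n_targets
        if T < 2:
            return HetFit(
                HetResult(self.snp_id, self.gene_id, self.quant_type, T, 0.0, 0, np.nan)
            )
        n = len(self.samples)
        if n < 10:
            raise ValueError("need >= 10 complete samples")
        ones = np.ones((n, T))
        dose_grid = np.tile(self.dosage[:, None], (1, T))
        x_sys = [ones, dose_grid]
        x_het = list(x_sys)
        for t in range(1, T):
            col = np.zeros((n, T))
            col[:, t] = self.dosage
            x_het.append(col)
        fit0 = _fit_crossed_lmm(self.y, x_sys)
        fit1 = _fit_crossed_lmm(self.y, x_het)
        chisq = max(0.0, 2.0 * (fit1.loglik - fit0.loglik))
        df = T - 1
        p = float(stats.chi2.sf(chisq, df))
        converged = fit0.converged and fit1.converged
        result = HetResult(
            self.snp_id,
            self.gene_id,
            self.quant_type,
            T,
            chisq,
            df,
            p,
            model="untestable" if not converged else "systematic",
            converged=converged,
            boundary=fit0.boundary or fit1.boundary,
            loglik_systematic=fit0.loglik,
            loglik_heterogeneous=fit1.loglik,
        )
        return HetFit(result, fit0, fit1)


def fit_het_test(
    long_data: pd.DataFrame,
    snp_id: str = "",
    gene_id: str = "",
    quant_type: str = "",
) -> HetResult:
    """Fit both nested models and return the likelihood-ratio result."""
    model = HeterogeneityModel(long_data, snp_id, gene_id, quant_type)
    return model.fit().result


def adjust_het_bonferroni(results: list[HetResult], alpha: float = 0.05) -> list[HetResult]:
    """Bonferroni-adjust across all testable results of one pipeline run.

    m is the count of testable results over every quantification type in
    the run (recomputed per run, never a hard-coded constant); a result is
    labelled heterogeneous iff p_bf < alpha, else systematic.
    """
    testable = {id(r) for r in results if r.n_targets >= 2 and np.isfinite(r.p)}
    m = len(testable)
    for r in results:
        if id(r) not in testable:
            r.p_bf = np.nan
            r.model = "untestable"
            continue
        r.p_bf = min(1.0, r.p * m)
        r.model = "heterogeneous" if r.p_bf < alpha else "systematic"
    return results
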