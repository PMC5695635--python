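"""Genotype and expression quality control, normalization and LD pruning.

Thresholds mirror the standard common-variant pipeline for an LCL eQTL
cohort: MAF > 0.05, Hardy-Weinberg exact P > 1e-4, call rate >= 0.7 for
SNPs; detection in > 50% of individuals for expression targets; rank-based
inverse-normal transform of each target; genotype principal components as
population-structure covariates; and PLINK-style ``--indep-pairwise``
pruning (100 kb window, r^2 0.8) of GWAS lead lists.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CovariateSet, ExpressionSet, GenotypeMatrix, GwasLead

logger = logging.getLogger(__name__)

__all__ = [
    "hwe_exact_test",
    "filter_snps",
    "filter_expression",
    "inverse_normal_transform",
    "normalize_expression",
    "genotype_pca",
    "LocusSet",
    "ld_prune",
    "pairwise_r2",
]


def hwe_exact_test(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Exact Hardy-Weinberg equilibrium test on genotype counts.

    Conditional on the observed allele counts, heterozygote counts follow
    the Levene-Haldane distribution; the returned P-value sums the
    probabilities of all heterozygote counts no more likely than the
    observed one (the standard exact test used by PLINK, without the
    mid-P adjustment).
    """
    if min(n_het, n_hom_minor, n_hom_major) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_het + n_hom_minor + n_hom_major
    if n == 0:
        return 1.0
    n_minor = 2 * n_hom_minor + n_het
    n_minor = min(n_minor, 2 * n - n_minor)
    # log P(het = h | allele counts) up to a constant, h same parity as n_minor
    from scipy.special import gammaln

    hs = np.arange(n_minor % 2, n_minor + 1, 2)
    logp = (
        hs * math.log(2)
        + gammaln(n + 1)
        - gammaln(hs + 1)
        - gammaln((n_minor - hs) / 2 + 1)
        - gammaln(n - (n_minor + hs) / 2 + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    observed = probs[hs == n_het]
    if observed.size == 0:
        raise ValueError("heterozygote count inconsistent with allele counts")
    return float(np.clip(probs[probs <= observed[0] + 1e-12].sum(), 0.0, 1.0))


def _genotype_counts(dosage: np.ndarray) -> tuple[int, int, int]:
    """Hard-call (het, hom-minor, hom-major) counts, rounding fractional dosages."""
    d = dosage[~np.isnan(dosage)]
    hard = np.clip(np.round(d), 0, 2).astype(int)
    n0 = int((hard == 0).sum())
    n1 = int((hard == 1).sum())
    n2 = int((hard == 2).sum())
    if n2 <= n0:
        return n1, n2, n0
    return n1, n0, n2


@dataclass
class SnpFilterReport:
    n_input: int
    n_kept: int
    n_fail_maf: int
    n_fail_hwe: int
    n_fail_callrate: int


def filter_snps(
    geno: GenotypeMatrix,
    maf_min: float = 0.05,
    hwe_p_min: float = 1e-4,
    callrate_min: float = 0.7,
) -> tuple[GenotypeMatrix, SnpFilterReport]:
    """Apply MAF / HWE / call-rate filters; strict inequalities on MAF and HWE.

    HWE uses the exact test on hard-call genotype counts (fractional
    dosages are rounded for the test only).  An empty result is returned
    with a warning, never raised.
    """
    dos = geno.dosages.to_numpy(dtype=float)
    call_rate = 1.0 - np.isnan(dos).mean(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dos, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    hwe = np.array(
        [hwe_exact_test(*_genotype_counts(dos[:, j])) for j in range(dos.shape[1])]
    )
    pass_maf = maf > maf_min
    pass_hwe = hwe > hwe_p_min
    pass_cr = call_rate >= callrate_min
    keep = pass_maf & pass_hwe & pass_cr
    report = SnpFilterReport(
        n_input=geno.n_snps,
        n_kept=int(keep.sum()),
        n_fail_maf=int((~pass_maf).sum()),
        n_fail_hwe=int((~pass_hwe).sum()),
        n_fail_callrate=int((~pass_cr).sum()),
    )
    if report.n_kept == 0:
        logger.warning("filter_snps removed every SNP (%d input)", report.n_input)
    snps = geno.snps.copy()
    snps["maf"] = maf
    snps["hwe_p"] = hwe
    snps["call_rate"] = call_rate
    kept_ids = geno.snp_ids[keep]
    return GenotypeMatrix(geno.dosages.loc[:, kept_ids], snps.loc[kept_ids]), report


def filter_expression(
    expr: ExpressionSet, detect_fraction: float = 0.5
) -> ExpressionSet:
    """Keep targets quantified (nonzero, non-missing) in > ``detect_fraction``
    of individuals — a strict inequality, so exactly-half detection drops."""
    vals = expr.values.to_numpy(dtype=float)
    detected = (~np.isnan(vals)) & (vals != 0)
    frac = detected.mean(axis=0)
    keep = expr.target_ids[frac > detect_fraction]
    return expr.subset_targets(keep)


def inverse_normal_transform(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform, Phi^-1((rank - 0.5) / n).

    Average ranks for ties; missing values propagate as NaN and do not
    enter n.  A constant vector has no defined transform and raises.
    """
    values = np.asarray(values, dtype=float)
    out = np.full(values.shape, np.nan)
    mask = ~np.isnan(values)
    v = values[mask]
    if v.size < 3:
        raise ValueError("need >= 3 non-missing values")
    if np.all(v == v[0]):
        raise ValueError("inverse-normal transform undefined for a constant vector")
    ranks = stats.rankdata(v, method="average")
    out[mask] = stats.norm.ppf((ranks - 0.5) / v.size)
    return out


def normalize_expression(expr: ExpressionSet) -> ExpressionSet:
    """Inverse-normal transform every target (column-wise)."""
    mat = np.column_stack(
        [inverse_normal_transform(expr.values[c].to_numpy()) for c in expr.values.columns]
    ) if expr.n_targets else np.empty((len(expr.samples), 0))
    return ExpressionSet(
        pd.DataFrame(mat, index=expr.samples, columns=expr.target_ids),
        expr.targets,
        expr.quant_type,
    )


def genotype_pca(
    geno: GenotypeMatrix,
    n_components: int = 3,
    snp_subset: list[str] | None = None,
) -> CovariateSet:
    """Principal components of the standardized dosage matrix.

    Components are ordered by explained variance; sign is fixed by making
    the largest-magnitude loading of each component positive.  Degenerate
    covariance yields fewer components, with a warning.
    """
    if n_components == 0:
        return CovariateSet(pd.DataFrame(index=geno.samples), [])
    if geno.n_samples < n_components + 1:
        raise ValueError("need at least n_components + 1 individuals")
    sub = geno.subset_snps(snp_subset) if snp_subset is not None else geno
    if sub.n_snps == 0:
        raise ValueError("empty SNP subset for PCA")
    dos = sub.dosages.to_numpy(dtype=float)
    col_mean = np.nanmean(dos, axis=0)
    inds = np.where(np.isnan(dos))
    dos = dos.copy()
    dos[inds] = np.take(col_mean, inds[1])
    dos -= col_mean
    sd = dos.std(axis=0, ddof=1)
    ok = sd > 0
    dos = dos[:, ok] / sd[ok]
    u, s, vt = np.linalg.svd(dos, full_matrices=False)
    rank = int((s > s[0] * 1e-9).sum()) if s.size else 0
    k = min(n_components, rank)
    if k < n_components:
        logger.warning("genotype_pca: degenerate covariance, returning %d components", k)
    scores = u[:, :k] * s[:k]
    for j in range(k):
        i_max = np.argmax(np.abs(vt[j]))
        if vt[j, i_max] < 0:
            scores[:, j] *= -1
    labels = [f"PC{i + 1}" for i in range(k)]
    return CovariateSet(pd.DataFrame(scores, index=geno.samples, columns=labels), labels)


# ---------------------------------------------------------------------------
# LD pruning of GWAS lead lists
# ---------------------------------------------------------------------------

def pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (complete pairs)."""
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 2 or x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1] ** 2)


@dataclass
class LocusSet:
    retained: list[GwasLead]
    removed: list[tuple[str, str, float]] = field(default_factory=list)  # (snp, partner, r2)
    missing: list[str] = field(default_factory=list)


def ld_prune(
    leads: list[GwasLead],
    ref: GenotypeMatrix,
    window_bp: int = 100_000,
    r2_max: float = 0.8,
) -> LocusSet:
    """Greedy position-ordered pruning of a lead-SNP list.

    Within any pair closer than ``window_bp`` with r^2 > ``r2_max``, the
    SNP with the smaller GWAS P is retained (ties: leftmost).  Leads absent
    from the reference panel are excluded with a warning.  PLINK's own
    ``--indep-pairwise`` retention rule is missingness-based, which is
    meaningless for a lead list, hence the documented P-based rule.
    """
    result = LocusSet(retained=[])
    present = []
    for lead in leads:
        if lead.snp_id not in ref.snp_ids:
            logger.warning("ld_prune: lead %s absent from reference panel", lead.snp_id)
            result.missing.append(lead.snp_id)
        else:
            present.append(lead)
    present.sort(key=lambda g: (g.chrom, g.pos))

    retained: list[GwasLead] = []
    for lead in present:
        conflicts = []
        for other in retained:
            if other.chrom != lead.chrom or abs(other.pos - lead.pos) >= window_bp:
                continue
            r2 = pairwise_r2(ref.dosage(lead.snp_id), ref.dosage(other.snp_id))
            if r2 > r2_max:
                conflicts.append((other, r2))
        if not conflicts:
            retained.append(lead)
            continue
        # lead wins only if strictly smaller P than every conflicting partner
        # (ties favour the earlier, i.e. leftmost, SNP)
        if all(lead.assoc_p < other.assoc_p for other, _ in conflicts):
            for other, r2 in conflicts:
                retained.remove(other)
                result.removed.append((other.snp_id, lead.snp_id, r2))
            retained.append(lead)
        else:
            best = min(conflicts, key=lambda c: (c[0].assoc_p, c[0].pos))
            result.removed.append((lead.snp_id, best[0].snp_id, best[1]))
    result.retained = retained
    return result
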