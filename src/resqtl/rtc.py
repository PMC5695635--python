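"""Regulatory Trait Concordance (RTC) colocalization.

The RTC score asks whether the GWAS lead SNP and the best cis-eQTL SNP of
a recombination-hotspot interval tag the same underlying signal.  For
each of the N SNPs in the interval, expression is residualized on that
SNP (plus covariates) and the best eQTL SNP is re-tested against the
residuals; removing a SNP that tags the causal variant destroys the eQTL
(residual P near 1), removing an unrelated SNP leaves it intact.  SNPs
are ranked by how much their removal degrades the signal (rank 0 = most
destroyed, i.e. largest residual P) and

    RTC = (N - Rank_GWAS) / N

with the 0-based rank, so RTC = 1.0 exactly when removing the GWAS SNP
extinguishes the eQTL better than removing any other SNP.  Tied residual
P-values share the minimal rank of their tie group (the favourable
assignment for the GWAS SNP).

A lead SNP falling between two hotspots defines one interval bounded by
the flanking summits; a lead inside a hotspot defines both an upper and a
lower interval (split at the containing summit), which are scored
separately and reported with the maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cisscan import batch_association, _design
from .datatypes import CovariateSet, GenotypeMatrix, GwasLead

__all__ = [
    "HotspotInterval",
    "RTCResult",
    "assign_interval",
    "rtc_score",
    "rtc_for_lead",
    "classify_causal",
]


class DegenerateLDError(ValueError):
    """All interval SNPs are identical; ranking is undefined."""


@dataclass(frozen=True)
class HotspotInterval:
    """An interval between hotspot summits (coordinates in bp, half-open)."""

    chrom: str
    start: int
    end: int
    kind: str = "between"          # between | upper | lower
    edge_flagged: bool = False     # bounded by region edge, not a summit

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")
        if self.kind not in ("between", "upper", "lower"):
            raise ValueError(f"bad interval kind {self.kind!r}")

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class RTCResult:
    lead_snp: str
    target_id: str
    interval: HotspotInterval
    n_snps: int
    best_eqtl_snp: str
    rank_gwas: int
    rtc: float
    causal: bool | None = None
    residual_p: pd.Series = field(default_factory=pd.Series, repr=False)


def assign_interval(
    lead: GwasLead,
    hotspots: pd.DataFrame,
    region_bounds: tuple[int, int] | None = None,
) -> list[HotspotInterval]:
    """Map a lead SNP to its hotspot interval(s).

    ``hotspots`` is a BED-convention frame (chrom, start, end, summit).
    Returns one ``between`` interval, or the ``upper``/``lower`` pair when
    the lead sits inside a hotspot.  A lead before the first or after the
    last summit is bounded by the region edge and flagged.
    """
    hs = hotspots[hotspots["chrom"].astype(str) == lead.chrom]
    if hs.empty:
        raise ValueError(f"hotspot track does not cover chromosome {lead.chrom}")
    hs = hs.sort_values("start")
    pos = lead.pos - 1  # BED coordinates
    lo, hi = region_bounds if region_bounds else (0, int(hs["end"].max()) + 10_000_000)

    inside = hs[(hs["start"] <= pos) & (pos < hs["end"])]
    summits = hs["summit"].to_numpy()
    prev = summits[summits < pos]
    nxt = summits[summits > pos]
    prev_summit = int(prev.max()) if prev.size else lo
    next_summit = int(nxt.min()) if nxt.size else hi
    edge = (not prev.size) or (not nxt.size)

    if inside.empty:
        return [HotspotInterval(lead.chrom, prev_summit, next_summit, "between", edge)]
    summit = int(inside.iloc[0]["summit"])
    prev_out = summits[summits < summit]
    next_out = summits[summits > summit]
    upper_lo = int(prev_out.max()) if prev_out.size else lo
    lower_hi = int(next_out.min()) if next_out.size else hi
    return [
        HotspotInterval(lead.chrom, upper_lo, summit + 1, "upper", not prev_out.size),
        HotspotInterval(lead.chrom, summit, lower_hi, "lower", not next_out.size),
    ]


def _residual_destruction_p(
    dosages: np.ndarray, expr: np.ndarray, cov: np.ndarray, best_idx: int
) -> np.ndarray:
    """P-value of the best eQTL SNP against expression residualized on each SNP."""
    n, m = dosages.shape
    x0 = _design(cov, n)
    k0 = x0.shape[1]
    xb = dosages[:, best_idx]
    xb_r = xb - x0 @ np.linalg.lstsq(x0, xb, rcond=None)[0]
    sxx = float(xb_r @ xb_r)
    from scipy import stats

    out = np.empty(m)
    for k in range(m):
        xk = np.column_stack([x0, dosages[:, k]])
        coef, _, _, _ = np.linalg.lstsq(xk, expr, rcond=None)
        resid = expr - xk @ coef
        # second stage: resid ~ intercept + covars + best dosage; resid is
        # already orthogonal to [x0, snp_k], so the slope reduces to the
        # simple projection on the covariate-residualized best dosage.
        if sxx <= 0:
            out[k] = 1.0
            continue
        beta = float(xb_r @ resid) / sxx
        rss = float(resid @ resid) - beta * float(xb_r @ resid)
        df = n - k0 - 2  # intercept+covars, snp_k (stage 1), best snp (stage 2)
        sigma2 = max(rss, 0.0) / max(df, 1)
        if sigma2 == 0:
            out[k] = 1.0
            continue
        se = np.sqrt(sigma2 / sxx)
        out[k] = min(2.0 * stats.t.sf(abs(beta / se), max(df, 1)), 1.0)
    return out


def rtc_score(
    interval_geno: GenotypeMatrix,
    expr: np.ndarray,
    covars: CovariateSet,
    lead: GwasLead | str,
    target_id: str = "",
    interval: HotspotInterval | None = None,
) -> RTCResult:
    """Score one (lead, expression target) pair over an interval's SNPs."""
    lead_id = lead.snp_id if isinstance(lead, GwasLead) else lead
    if lead_id not in interval_geno.snp_ids:
        raise ValueError(f"lead SNP {lead_id} not among interval SNPs")
    n_snps = interval_geno.n_snps
    if n_snps < 2:
        raise ValueError("need >= 2 SNPs in the hotspot interval")
    dosages = interval_geno.dosages.to_numpy(dtype=float)
    if np.all(dosages == dosages[:, [0]]):
        raise DegenerateLDError("all interval SNPs are identical")
    expr = np.asarray(expr, dtype=float)
    cov = covars.aligned(interval_geno.samples)

    assoc = batch_association(dosages, expr, cov)
    best_idx = int(assoc["p"].idxmin())
    best_snp = str(interval_geno.snp_ids[best_idx])

    destroy_p = _residual_destruction_p(dosages, expr, cov, best_idx)
    lead_idx = int(interval_geno.snp_ids.get_loc(lead_id))
    # rank 0 = largest residual P (removal destroys the signal most);
    # ties share the minimal rank of the group (1e-12 relative tolerance)
    p_lead = destroy_p[lead_idx]
    tol = 1e-12 * max(p_lead, 1e-300)
    rank = int(np.sum(destroy_p > p_lead + tol))
    rtc = (n_snps - rank) / n_snps
    if interval is None:
        meta = interval_geno.snps
        interval = HotspotInterval(
            str(meta["chrom"].iloc[0]), int(meta["pos"].min()) - 1, int(meta["pos"].max()) + 1
        )
    return RTCResult(
        lead_snp=lead_id,
        target_id=target_id,
        interval=interval,
        n_snps=n_snps,
        best_eqtl_snp=best_snp,
        rank_gwas=rank,
        rtc=float(rtc),
        residual_p=pd.Series(destroy_p, index=interval_geno.snp_ids),
    )


def rtc_for_lead(
    geno: GenotypeMatrix,
    expr: np.ndarray,
    covars: CovariateSet,
    lead: GwasLead,
    hotspots: pd.DataFrame,
    target_id: str = "",
    region_bounds: tuple[int, int] | None = None,
) -> tuple[RTCResult, list[RTCResult]]:
    """Assign interval(s) for a lead, score each, return (best, all).

    When the lead sits inside a hotspot both the upper and the lower
    interval are scored and the maximum RTC is reported.
    """
    intervals = assign_interval(lead, hotspots, region_bounds)
    results = []
    for iv in intervals:
        meta = geno.snps
        in_iv = meta.index[
            (meta["chrom"].astype(str) == iv.chrom)
            & (meta["pos"] - 1 >= iv.start)
            & (meta["pos"] - 1 < iv.end)
        ]
        if lead.snp_id not in in_iv or len(in_iv) < 2:
            continue
        results.append(
            rtc_score(geno.subset_snps(in_iv), expr, covars, lead, target_id, iv)
        )
    if not results:
        raise ValueError(f"no scoreable hotspot interval for lead {lead.snp_id}")
    best = max(results, key=lambda r: r.rtc)
    return best, results


def classify_causal(
    assoc: pd.Series | dict,
    rtcres: RTCResult,
    bf_alpha: float = 0.05,
    rtc_min: float = 0.95,
) -> bool:
    """Causal call: Bonferroni-adjusted eQTL P < alpha AND RTC >= threshold.

    ``assoc`` must describe the same (lead SNP, target) pair as ``rtcres``.
    """
    if assoc["lead_snp"] != rtcres.lead_snp or assoc["target_id"] != rtcres.target_id:
        raise ValueError(
            f"mismatched pair: assoc ({assoc['lead_snp']}, {assoc['target_id']}) "
            f"vs rtc ({rtcres.lead_snp}, {rtcres.target_id})"
        )
    flag = bool(assoc["p_bf"] < bf_alpha and rtcres.rtc >= rtc_min)
    rtcres.causal = flag
    return flag
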