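"""End-to-end GWAS-eQTL integration pipeline and cross-resolution summaries.

Stage order: genotype/expression QC -> covariate construction -> LD pruning
of GWAS leads -> cis pair selection -> association scan -> Bonferroni per
disease per quantification type -> RTC colocalization -> causal calls ->
heterogeneity LRT on causal SNP-gene pairs -> annotation shift-permutation
enrichment -> summary tables.  Every stage's row counts are recorded in the
run manifest and a fixed seed yields byte-identical output tables.

The Bonferroni scope corrects the lead-SNP-vs-target associations for the
number of targets tested per disease per quantification type, matching the
per-disease, per-type correction of the number of genes / isoforms / exons
/ junctions / introns tested.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cisscan, hetmodel, qc, rtc, shiftenrich
from .datatypes import (
    CovariateSet,
    ExpressionSet,
    GenotypeMatrix,
    GwasLead,
    QUANT_TYPES,
    empty_covariates,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineInputs",
    "PipelineResult",
    "SummaryTable",
    "run_pipeline",
    "summarize",
    "compare_matched_pairs",
]


@dataclass
class PipelineConfig:
    """Thresholds and scopes of one integration run (defaults = the
    standard common-variant LCL pipeline settings)."""

    maf_min: float = 0.05
    hwe_p_min: float = 1e-4
    callrate_min: float = 0.7
    detect_fraction: float = 0.5
    nominal_p: float = 0.01
    bf_alpha: float = 0.05
    rtc_min: float = 0.95
    fdr: float = 0.05
    ld_r2: float = 0.8
    prune_window_bp: int = 100_000
    tss_window_bp: int = 500_000
    lead_window_bp: int = 100_000
    n_perm: int = 1000
    n_pcs: int = 3
    seed: int = 0
    normalize: bool = True
    quant_types: tuple[str, ...] = QUANT_TYPES
    diseases: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        for name in ("maf_min", "detect_fraction"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ValueError(f"{name}={v} outside [0, 1)")
        for name in ("nominal_p", "bf_alpha", "rtc_min", "fdr", "ld_r2"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name}={v} outside (0, 1]")
        if min(self.prune_window_bp, self.tss_window_bp, self.lead_window_bp, self.n_perm) <= 0:
            raise ValueError("window sizes and n_perm must be positive")

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        """Parse a flat key=value config file (``#`` comments allowed)."""
        kwargs: dict = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in fields:
                raise ValueError(f"unknown config key {key!r}")
            if key in ("quant_types", "diseases"):
                kwargs[key] = tuple(v.strip() for v in val.split(",") if v.strip())
            elif fields[key].type in ("int", int):
                kwargs[key] = int(val)
            elif fields[key].type in ("bool", bool):
                kwargs[key] = val.lower() in ("1", "true", "yes")
            else:
                kwargs[key] = float(val)
        return cls(**kwargs)


@dataclass
class PipelineInputs:
    """Loaded inputs of one run (from files or the synthetic generator)."""

    geno: GenotypeMatrix
    expression: dict[str, ExpressionSet]
    hotspots: pd.DataFrame
    leads: list[GwasLead]
    annotations: dict[str, pd.DataFrame] = field(default_factory=dict)
    covariates: CovariateSet | None = None
    region_bounds: tuple[int, int] | None = None


@dataclass
class SummaryTable:
    per_type: pd.DataFrame           # quant_type, n_causal_loci, pct_of_loci, ...
    combined_loci: int
    combined_genes: int
    n_total_loci: int
    per_disease: pd.DataFrame
    sharing: dict[str, frozenset] = field(default_factory=dict)


def summarize(causal_calls: pd.DataFrame, n_total_loci: int) -> SummaryTable:
    """Cross-resolution accounting of causal calls.

    A locus (lead SNP) counts once per quantification type if >= 1 of its
    targets is causal; candidate genes and expression targets are distinct
    IDs among the causal calls; the combined figures are unions over
    types.
    """
    rows = []
    sharing: dict[str, frozenset] = {}
    for qtype in QUANT_TYPES:
        sub = causal_calls[causal_calls["quant_type"] == qtype] if len(causal_calls) else causal_calls
        loci = frozenset(sub["lead_snp"]) if len(sub) else frozenset()
        sharing[qtype] = loci
        rows.append(
            {
                "quant_type": qtype,
                "n_causal_loci": len(loci),
                "pct_of_loci": 100.0 * len(loci) / n_total_loci if n_total_loci else 0.0,
                "n_candidate_genes": sub["gene_id"].nunique() if len(sub) else 0,
                "n_expression_targets": sub["target_id"].nunique() if len(sub) else 0,
            }
        )
    combined = frozenset().union(*sharing.values()) if sharing else frozenset()
    combined_genes = causal_calls["gene_id"].nunique() if len(causal_calls) else 0
    if len(causal_calls):
        per_disease = (
            causal_calls.groupby("disease")
            .agg(n_causal_loci=("lead_snp", "nunique"), n_genes=("gene_id", "nunique"))
            .reset_index()
        )
    else:
        per_disease = pd.DataFrame(columns=["disease", "n_causal_loci", "n_genes"])
    per_type = pd.DataFrame(rows)
    assert len(combined) <= int(per_type["n_causal_loci"].sum())
    return SummaryTable(
        per_type=per_type,
        combined_loci=len(combined),
        combined_genes=combined_genes,
        n_total_loci=n_total_loci,
        per_disease=per_disease,
        sharing=sharing,
    )


@dataclass
class PipelineResult:
    config: PipelineConfig
    locus_set: qc.LocusSet
    records: pd.DataFrame            # all scanned SNP-target associations
    lead_records: pd.DataFrame       # lead-vs-target rows with p_bf
    rtc_results: pd.DataFrame
    causal_calls: pd.DataFrame
    het_results: list[hetmodel.HetResult]
    enrichment: dict[str, shiftenrich.EnrichmentResult]
    summary: SummaryTable
    manifest: dict

    def het_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self.het_results])

    def write(self, out_dir: str) -> None:
        """Write all result tables (TSV) plus the run manifest (JSON)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(out / "associations.tsv", sep="\t", index=False)
        self.lead_records.to_csv(out / "lead_associations.tsv", sep="\t", index=False)
        self.rtc_results.to_csv(out / "rtc.tsv", sep="\t", index=False)
        self.causal_calls.to_csv(out / "causal_calls.tsv", sep="\t", index=False)
        self.het_frame().to_csv(out / "heterogeneity.tsv", sep="\t", index=False)
        self.summary.per_type.to_csv(out / "summary_per_type.tsv", sep="\t", index=False)
        self.summary.per_disease.to_csv(out / "summary_per_disease.tsv", sep="\t", index=False)
        enrich = pd.DataFrame(
            [
                {
                    "annotation": name,
                    "n_loci": r.n_loci,
                    "observed_overlap": r.observed_overlap,
                    "p": r.p,
                    "p_upper": r.p_upper,
                    "n_perm": r.n_perm,
                }
                for name, r in self.enrichment.items()
            ]
        )
        enrich.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2, default=str))


def run_pipeline(inputs: PipelineInputs, config: PipelineConfig) -> PipelineResult:
    """Execute every stage in order; deterministic under a fixed seed."""
    counts: dict[str, int] = {}

    geno, snp_report = qc.filter_snps(
        inputs.geno, config.maf_min, config.hwe_p_min, config.callrate_min
    )
    counts["snps_after_qc"] = geno.n_snps

    expr_sets: dict[str, ExpressionSet] = {}
    for qtype in config.quant_types:
        es = inputs.expression.get(qtype)
        if es is None:
            continue
        es = qc.filter_expression(es, config.detect_fraction)
        if config.normalize:
            es = qc.normalize_expression(es)
        expr_sets[qtype] = es
        counts[f"targets_{qtype}"] = es.n_targets

    covars = inputs.covariates
    if covars is None:
        covars = (
            qc.genotype_pca(geno, config.n_pcs) if config.n_pcs > 0
            else empty_covariates(geno.samples)
        )

    leads = inputs.leads
    if config.diseases:
        leads = [g for g in leads if g.disease in config.diseases]
    locus_set = qc.ld_prune(leads, geno, config.prune_window_bp, config.ld_r2)
    kept_leads = locus_set.retained
    counts["loci_after_prune"] = len(kept_leads)
    if not kept_leads:
        empty = pd.DataFrame()
        summary = summarize(
            pd.DataFrame(columns=["lead_snp", "disease", "gene_id", "target_id", "quant_type"]),
            0,
        )
        return PipelineResult(
            config, locus_set, empty, empty, empty, empty, [], {}, summary,
            {"counts": counts, "seed": config.seed, "config": dataclasses.asdict(config)},
        )

    policy = cisscan.CisWindowPolicy(
        config.tss_window_bp, config.lead_window_bp, config.nominal_p
    )

    all_records = []
    lead_rows = []
    for qtype, es in expr_sets.items():
        pairs = cisscan.select_cis_pairs(kept_leads, es.targets, geno.snps, policy)
        if pairs.empty:
            continue
        records = cisscan.scan_pairs(geno, es, pairs, covars)
        all_records.append(records)
        # nominal eligibility: >= 1 SNP within the lead window at P < 0.01
        min_p = records.groupby(["lead_snp", "target_id"])["p"].transform("min")
        eligible = records[min_p < config.nominal_p]
        lead_rows.append(eligible[eligible["snp_id"] == eligible["lead_snp"]])
    records = (
        pd.concat(all_records, ignore_index=True) if all_records else pd.DataFrame()
    )
    lead_records = (
        pd.concat(lead_rows, ignore_index=True) if lead_rows else pd.DataFrame()
    )
    counts["associations_scanned"] = len(records)
    counts["lead_associations"] = len(lead_records)
    lead_records = cisscan.adjust_bonferroni(lead_records)

    rtc_rows = []
    causal_rows = []
    lead_by_id = {g.snp_id: g for g in kept_leads}
    for row in lead_records.itertuples(index=False):
        if row.p_bf >= config.bf_alpha:
            continue  # cannot be causal; skip the interval regressions
        lead = lead_by_id[row.lead_snp]
        es = expr_sets[row.quant_type]
        y = es.values[row.target_id].to_numpy(dtype=float)
        try:
            best, _ = rtc.rtc_for_lead(
                geno, y, covars, lead, inputs.hotspots, row.target_id,
                inputs.region_bounds,
            )
        except ValueError as exc:
            logger.warning("RTC failed for %s x %s: %s", row.lead_snp, row.target_id, exc)
            continue
        causal = rtc.classify_causal(
            row._asdict(), best, config.bf_alpha, config.rtc_min
        )
        rtc_rows.append(
            {
                "lead_snp": row.lead_snp,
                "disease": row.disease,
                "target_id": row.target_id,
                "gene_id": row.gene_id,
                "quant_type": row.quant_type,
                "interval_start": best.interval.start,
                "interval_end": best.interval.end,
                "interval_kind": best.interval.kind,
                "n_snps": best.n_snps,
                "best_eqtl_snp": best.best_eqtl_snp,
                "rank_gwas": best.rank_gwas,
                "rtc": best.rtc,
                "p_bf": row.p_bf,
                "causal": causal,
            }
        )
        if causal:
            causal_rows.append(
                {
                    "lead_snp": row.lead_snp,
                    "disease": row.disease,
                    "gene_id": row.gene_id,
                    "target_id": row.target_id,
                    "quant_type": row.quant_type,
                    "p_bf": row.p_bf,
                    "rtc": best.rtc,
                }
            )
    rtc_results = pd.DataFrame(rtc_rows)
    causal_calls = pd.DataFrame(
        causal_rows,
        columns=["lead_snp", "disease", "gene_id", "target_id", "quant_type", "p_bf", "rtc"],
    )
    counts["rtc_tested"] = len(rtc_results)
    counts["causal_calls"] = len(causal_calls)

    # heterogeneity on causal SNP-gene pairs at sub-gene resolutions
    het_results: list[hetmodel.HetResult] = []
    if len(causal_calls):
        seen = set()
        for row in causal_calls.itertuples(index=False):
            if row.quant_type == "gene":
                continue
            key = (row.lead_snp, row.gene_id, row.quant_type)
            if key in seen:
                continue
            seen.add(key)
            es = expr_sets[row.quant_type]
            targets = es.gene_targets(row.gene_id)
            expr_grid = es.values.loc[:, targets]
            dosage = pd.Series(geno.dosage(row.lead_snp), index=geno.samples)
            model = hetmodel.HeterogeneityModel.from_matrices(
                expr_grid, dosage, row.lead_snp, row.gene_id, row.quant_type
            )
            het_results.append(model.fit().result)
        hetmodel.adjust_het_bonferroni(het_results, config.bf_alpha)
    counts["het_tests"] = len(het_results)

    enrichment: dict[str, shiftenrich.EnrichmentResult] = {}
    if len(causal_calls) and inputs.annotations:
        causal_snps = sorted(set(causal_calls["lead_snp"]))
        loci = shiftenrich.ld_expand(causal_snps, geno, config.ld_r2)
        for name, track in inputs.annotations.items():
            enrichment[name] = shiftenrich.shift_permutation(
                loci, track, config.n_perm, seed=config.seed, annotation_name=name
            )

    summary = summarize(causal_calls, n_total_loci=len(kept_leads))
    manifest = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "counts": counts,
        "snp_filter": dataclasses.asdict(snp_report),
    }
    return PipelineResult(
        config, locus_set, records, lead_records, rtc_results, causal_calls,
        het_results, enrichment, summary, manifest,
    )


# ---------------------------------------------------------------------------
# matched SNP-gene pair comparison across quantification types
# ---------------------------------------------------------------------------

@dataclass
class MatchedComparison:
    table: pd.DataFrame
    n_matched: int
    pct_shared_both: float
    pct_x_only: float
    pct_y_only: float
    pct_neither: float
    corr_coloc: float
    corr_assoc: float


def compare_matched_pairs(
    x: pd.DataFrame,
    y: pd.DataFrame,
    nominal_p: float = 0.01,
    coloc_p: float = 0.01,
) -> MatchedComparison:
    """Pairwise comparison of two quantification types on matched SNP-gene pairs.

    Each input frame carries one row per (lead_snp, gene_id, target_id)
    with the cis-eQTL association P (column ``p``) and an ascending
    colocalization score (column ``coloc_p``; smaller = more shared).
    Pairs must reach ``p < nominal_p`` in both types; among multiple
    targets of the same gene, the pair minimizing |coloc_x - coloc_y| is
    selected (ties: smaller association P in x).  Classes are shared-both
    / x-only / y-only / neither at ``coloc_p``; Pearson correlations of
    the matched coloc and association P-values are reported on the raw
    P scale.
    """
    req = {"lead_snp", "gene_id", "target_id", "p", "coloc_p"}
    for name, frame in (("x", x), ("y", y)):
        missing = req - set(frame.columns)
        if missing:
            raise ValueError(f"{name} frame lacks columns {sorted(missing)}")
    xs = x[x["p"] < nominal_p]
    ys = y[y["p"] < nominal_p]
    merged = xs.merge(ys, on=["lead_snp", "gene_id"], suffixes=("_x", "_y"))
    if merged.empty:
        logger.warning("compare_matched_pairs: no matched pairs")
        return MatchedComparison(merged, 0, *(np.nan,) * 4, np.nan, np.nan)
    merged = merged.assign(_delta=(merged["coloc_p_x"] - merged["coloc_p_y"]).abs())
    merged = (
        merged.sort_values(["_delta", "p_x"], kind="mergesort")
        .groupby(["lead_snp", "gene_id"], as_index=False)
        .first()
        .drop(columns="_delta")
    )
    shared_x = merged["coloc_p_x"] < coloc_p
    shared_y = merged["coloc_p_y"] < coloc_p
    cls = np.select(
        [shared_x & shared_y, shared_x & ~shared_y, ~shared_x & shared_y],
        ["shared_both", "x_only", "y_only"],
        default="neither",
    )
    merged["class"] = cls
    n = len(merged)
    pct = lambda label: 100.0 * float((cls == label).sum()) / n  # noqa: E731
    def _corr(a: pd.Series, b: pd.Series) -> float:
        if n <= 1 or a.std() == 0 or b.std() == 0:
            return np.nan
        return float(np.corrcoef(a, b)[0, 1])

    corr_coloc = _corr(merged["coloc_p_x"], merged["coloc_p_y"])
    corr_assoc = _corr(merged["p_x"], merged["p_y"])
    return MatchedComparison(
        merged, n,
        pct("shared_both"), pct("x_only"), pct("y_only"), pct("neither"),
        corr_coloc, corr_assoc,
    )
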