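"""Synthetic cohort generator: genotypes, hotspots, multi-resolution
expression with a planted eQTL architecture, GWAS leads and annotation
tracks.

The generator emulates a Geuvadis-style LCL eQTL cohort so every pipeline
stage is testable without external data:

* **Genotypes** — block-LD dosages produced by thresholding correlated
  Gaussian haplotypes at Hardy-Weinberg-consistent quantiles.  Within a
  block all SNPs share a base minor-allele frequency (plus jitter scaled by
  ``1 - r``): binary variables with very different frequencies cannot reach
  high phi correlation, so tight LD blocks require near-equal frequencies,
  as they do in real panels.
* **Expression** — emitted already "residualized" (roughly standard
  normal), since the pipeline consumes PEER residuals; latent-factor
  removal itself is not modelled.  Five matrices are produced (gene,
  transcript, exon, junction, intron).  Transcript signal is primary; a
  gene value is the sum of its transcript values; exons and junctions
  inherit the summed signal of the transcripts containing them; introns
  vary independently.  Residual structure is crossed Gaussian random
  intercepts (per sample within gene, per target) plus i.i.d. noise —
  exactly the covariance the heterogeneity mixed model assumes.
* **Planted eQTLs** — a *systematic* truth adds ``beta * dosage`` to every
  transcript and intron of the gene (derived elements inherit it); a
  *heterogeneous* truth adds the effect directly to an explicit subset of
  element IDs, modelling element-specific regulation that does not
  propagate to the gene total.

All randomness flows through explicit integer seeds; there is no global
RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    ExpressionSet,
    GenotypeMatrix,
    GwasLead,
    InvalidSpecificationError,
    QUANT_TYPES,
    SNP_META_COLUMNS,
    TARGET_META_COLUMNS,
)

__all__ = [
    "LDBlockSpec",
    "GeneModelSpec",
    "EqtlTruth",
    "SimulatedExpression",
    "simulate_genotypes",
    "simulate_hotspots",
    "simulate_expression",
    "simulate_annotations",
    "simulate_gwas_leads",
    "simulate_study",
]


@dataclass(frozen=True)
class LDBlockSpec:
    """Layout of the simulated LD structure.

    ``within_block_r`` is the latent (haplotype-level) correlation of SNPs
    inside a block; realized genotype correlation is slightly attenuated by
    dichotomization.  Cross-block correlation is zero by construction.
    """

    n_blocks: int = 10
    snps_per_block: int = 10
    within_block_r: float = 0.8
    maf_range: tuple[float, float] = (0.1, 0.5)
    block_span_bp: int = 50_000
    chrom: str = "1"
    start_pos: int = 1

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.snps_per_block < 1:
            raise InvalidSpecificationError("block and SNP counts must be positive")
        if not (0 <= self.within_block_r < 1):
            raise InvalidSpecificationError("within_block_r must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.05 <= lo <= hi <= 0.5):
            raise InvalidSpecificationError(
                "maf_range must satisfy 0.05 <= lo <= hi <= 0.5 (common-variant filter)"
            )
        if self.block_span_bp < self.snps_per_block:
            raise InvalidSpecificationError("block_span_bp too small for SNP count")


@dataclass(frozen=True)
class GeneModelSpec:
    """Layout of simulated gene models (meta-exons, transcripts, introns)."""

    n_genes: int = 5
    transcripts_per_gene: tuple[int, int] = (1, 3)
    exons_per_transcript: tuple[int, int] = (2, 6)
    include_intron_retention: bool = True
    tss_positions: tuple[int, ...] = ()
    chrom: str = "1"
    exon_bp: int = 200
    intron_bp: int = 2_000

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise InvalidSpecificationError("n_genes must be positive")
        if self.transcripts_per_gene[0] < 1 or self.exons_per_transcript[0] < 2:
            raise InvalidSpecificationError(
                "need >= 1 transcript per gene and >= 2 exons per transcript"
            )
        if self.tss_positions and len(self.tss_positions) != self.n_genes:
            raise InvalidSpecificationError("tss_positions length must equal n_genes")


@dataclass(frozen=True)
class EqtlTruth:
    """One planted eQTL.

    ``mode`` is ``systematic`` (effect on every element of the gene),
    ``heterogeneous`` (effect confined to ``affected_elements``, a proper
    nonempty subset of explicit element IDs) or ``none`` (negative-control
    gene).  ``beta`` is in residual-SD units per dosage unit.
    """

    snp_id: str
    gene_id: str
    mode: str = "systematic"
    affected_elements: frozenset[str] = frozenset()
    beta: float = 0.5
    sample_sd: float = 0.3
    target_sd: float = 0.3
    resid_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("systematic", "heterogeneous", "none"):
            raise InvalidSpecificationError(f"unknown eQTL mode {self.mode!r}")
        if self.mode == "heterogeneous" and not self.affected_elements:
            raise InvalidSpecificationError(
                "heterogeneous truth requires explicit affected_elements"
            )
        if min(self.sample_sd, self.target_sd, self.resid_sd) < 0:
            raise InvalidSpecificationError("SD parameters must be >= 0")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(
    spec: LDBlockSpec, n_individuals: int, seed: int
) -> GenotypeMatrix:
    """Simulate hard-call dosages with block-exchangeable LD.

    Haplotypes are built by the exchangeable-copy construction: every
    block has a core allele per haplotype, ``a0 ~ Bernoulli(p)``, and each
    SNP copies the core with probability ``sqrt(within_block_r)`` (else
    draws a fresh allele at its own frequency), so the pairwise genotype
    correlation of same-frequency SNPs equals ``within_block_r`` in
    expectation.  Dosage is the sum of two independent haplotypes, making
    genotype frequencies HWE-consistent; cross-block SNPs are independent.
    Blocks are redrawn (fresh substream) until every realized MAF is
    >= 0.01.
    """
    if n_individuals < 20:
        raise InvalidSpecificationError("n_individuals must be >= 20")
    rng = np.random.default_rng(seed)
    lo, hi = spec.maf_range
    r = spec.within_block_r
    c = float(np.sqrt(r))
    m = spec.snps_per_block

    dosage_blocks: list[np.ndarray] = []
    freqs: list[np.ndarray] = []
    for _ in range(spec.n_blocks):
        base = rng.uniform(lo, hi)
        jitter = rng.uniform(-1.0, 1.0, size=m) * (1.0 - r) * (hi - lo) / 2.0
        p = np.clip(base + jitter, 0.05, 0.5)
        for _attempt in range(50):
            core = rng.random((2, n_individuals, 1)) < base
            fresh = rng.random((2, n_individuals, m)) < p
            copy = rng.random((2, n_individuals, m)) < c
            haps = np.where(copy, core, fresh)
            dos = haps.sum(axis=0)
            maf = dos.mean(axis=0) / 2.0
            maf = np.minimum(maf, 1.0 - maf)
            if maf.min() >= 0.01:
                break
        else:  # pragma: no cover - vanishingly unlikely at MAF >= 0.05
            raise InvalidSpecificationError("could not realize MAF >= 0.01")
        dosage_blocks.append(dos.astype(float))
        freqs.append(p)

    dosages = np.concatenate(dosage_blocks, axis=1)
    n_snps = dosages.shape[1]
    # SNPs occupy the central 80% of each block so consecutive blocks stay
    # separable by a boundary (e.g. a recombination-hotspot summit)
    pos = np.concatenate(
        [
            spec.start_pos
            + b * spec.block_span_bp
            + np.linspace(0, int(spec.block_span_bp * 0.8), m).astype(int)
            for b in range(spec.n_blocks)
        ]
    )
    snp_ids = [f"rs{spec.chrom}_{p}" for p in pos]
    samples = [f"S{i:04d}" for i in range(n_individuals)]
    maf = dosages.mean(axis=0) / 2.0
    maf = np.minimum(maf, 1.0 - maf)
    snps = pd.DataFrame(
        {
            "chrom": spec.chrom,
            "pos": pos,
            "ref": "A",
            "alt": "G",
            "maf": maf,
            "hwe_p": np.nan,
            "call_rate": 1.0,
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )[SNP_META_COLUMNS]
    return GenotypeMatrix(
        pd.DataFrame(dosages, index=pd.Index(samples, name="sample"), columns=snp_ids),
        snps,
    )


# ---------------------------------------------------------------------------
# recombination hotspots
# ---------------------------------------------------------------------------

def simulate_hotspots(
    region_span: tuple[int, int],
    n_hotspots: int,
    seed: int,
    width_bp: int = 2_000,
    chrom: str = "1",
) -> pd.DataFrame:
    """Place non-overlapping hotspot intervals with summits in a region.

    Returns a BED-convention frame (0-based half-open) with columns
    ``chrom, start, end, summit`` sorted by start.  Hotspot widths must be
    smaller than the mean spacing, otherwise the region cannot hold them.
    """
    lo, hi = region_span
    if n_hotspots < 1:
        raise InvalidSpecificationError("n_hotspots must be >= 1")
    span = hi - lo
    if span <= (width_bp + 1) * (n_hotspots + 1):
        raise InvalidSpecificationError(
            f"region of {span} bp cannot hold {n_hotspots} hotspots of {width_bp} bp"
        )
    rng = np.random.default_rng(seed)
    # stratified placement: one summit per equal slice keeps spacing > width
    edges = np.linspace(lo, hi, n_hotspots + 1)
    summits = []
    half = width_bp // 2
    for a, b in zip(edges[:-1], edges[1:]):
        summits.append(int(rng.uniform(a + half + 1, b - half - 1)))
    frame = pd.DataFrame(
        {
            "chrom": chrom,
            "start": [s - half for s in summits],
            "end": [s + half for s in summits],
            "summit": summits,
        }
    ).sort_values("start", ignore_index=True)
    if (frame["start"].to_numpy()[1:] < frame["end"].to_numpy()[:-1]).any():
        raise InvalidSpecificationError("hotspots overlap; reduce width or count")
    return frame


# ---------------------------------------------------------------------------
# gene models and expression
# ---------------------------------------------------------------------------

@dataclass
class _GeneModel:
    gene_id: str
    chrom: str
    tss: int
    exons: list[tuple[int, int]]                 # meta-exon intervals, 1-based inclusive
    transcripts: dict[str, list[int]]            # transcript id -> exon indices
    introns: list[tuple[int, int]]


@dataclass
class SimulatedExpression:
    """Bundle returned by :func:`simulate_expression`.

    ``sets`` holds the five noisy :class:`ExpressionSet` matrices;
    ``prenoise`` the same matrices before i.i.d. noise injection (on which
    the gene = sum-of-transcripts identity holds exactly); ``truth`` one
    row per planted (snp, element) effect.
    """

    sets: dict[str, ExpressionSet]
    prenoise: dict[str, pd.DataFrame]
    truth: pd.DataFrame
    gene_models: list[_GeneModel] = field(default_factory=list)


def _build_gene_models(spec: GeneModelSpec, rng: np.random.Generator) -> list[_GeneModel]:
    models = []
    gene_pitch = (
        spec.exons_per_transcript[1] * (spec.exon_bp + spec.intron_bp) + 20_000
    )
    for i in range(spec.n_genes):
        gid = f"GENE{i + 1}"
        tss = (
            spec.tss_positions[i]
            if spec.tss_positions
            else 100_000 + i * gene_pitch
        )
        n_ex = int(rng.integers(spec.exons_per_transcript[0], spec.exons_per_transcript[1] + 1))
        starts = tss + np.arange(n_ex) * (spec.exon_bp + spec.intron_bp)
        exons = [(int(s), int(s + spec.exon_bp - 1)) for s in starts]
        introns = [
            (exons[k][1] + 1, exons[k + 1][0] - 1) for k in range(n_ex - 1)
        ]
        n_tr = int(rng.integers(spec.transcripts_per_gene[0], spec.transcripts_per_gene[1] + 1))
        transcripts: dict[str, list[int]] = {}
        for t in range(n_tr):
            if t == 0:
                chosen = list(range(n_ex))       # canonical transcript: all exons
            else:
                keep = rng.random(n_ex) > 0.4
                keep[0] = keep[-1] = True        # shared first/last exon
                chosen = [k for k in range(n_ex) if keep[k]]
                if len(chosen) < 2:
                    chosen = [0, n_ex - 1]
            transcripts[f"{gid}.t{t + 1}"] = chosen
        models.append(_GeneModel(gid, spec.chrom, int(tss), exons, transcripts, introns))
    return models


def _element_ids(model: _GeneModel) -> dict[str, list[tuple[str, int, int]]]:
    """Target IDs per quantification type for one gene (id, start, end)."""
    g = model.gene_id
    out: dict[str, list[tuple[str, int, int]]] = {q: [] for q in QUANT_TYPES}
    gene_span = (model.exons[0][0], model.exons[-1][1])
    out["gene"].append((g, gene_span[0], gene_span[1]))
    for tid in model.transcripts:
        out["transcript"].append((tid, gene_span[0], gene_span[1]))
    for s, e in model.exons:
        out["exon"].append((f"{g}_exon.{s}.{e}", s, e))
    junctions = set()
    for chosen in model.transcripts.values():
        for a, b in zip(chosen[:-1], chosen[1:]):
            junctions.add((model.exons[a][1], model.exons[b][0]))
    for s, e in sorted(junctions):
        out["junction"].append((f"{g}_junction.{s}.{e}", s, e))
    for s, e in model.introns:
        out["intron"].append((f"{g}_intron.{s}.{e}", s, e))
    return out


def simulate_expression(
    geno: GenotypeMatrix,
    genes: GeneModelSpec,
    truths: list[EqtlTruth],
    seed: int,
) -> SimulatedExpression:
    """Generate the five quantification-type matrices with planted eQTLs.

    See the module docstring for the signal-propagation rules.  Raises if a
    truth references an unknown SNP, gene or element.
    """
    rng = np.random.default_rng(seed)
    models = _build_gene_models(genes, rng)
    by_gene = {m.gene_id: m for m in models}
    n = geno.n_samples
    samples = geno.samples

    truth_by_gene: dict[str, list[EqtlTruth]] = {}
    for t in truths:
        if t.gene_id not in by_gene:
            raise InvalidSpecificationError(f"truth references unknown gene {t.gene_id}")
        if t.snp_id not in geno.snp_ids:
            raise InvalidSpecificationError(f"truth references unknown SNP {t.snp_id}")
        truth_by_gene.setdefault(t.gene_id, []).append(t)

    values: dict[str, dict[str, np.ndarray]] = {q: {} for q in QUANT_TYPES}
    prenoise: dict[str, dict[str, np.ndarray]] = {q: {} for q in QUANT_TYPES}
    meta: dict[str, list] = {q: [] for q in QUANT_TYPES}
    truth_rows = []

    for model in models:
        ids = _element_ids(model)
        known_ids = {tid for q in QUANT_TYPES for tid, _, _ in ids[q]}
        gtruths = truth_by_gene.get(model.gene_id, [])
        # variance components: taken from the first truth of the gene, or defaults
        sample_sd = gtruths[0].sample_sd if gtruths else 0.3
        target_sd = gtruths[0].target_sd if gtruths else 0.3
        resid_sd = gtruths[0].resid_sd if gtruths else 1.0

        # dosage effects: systematic -> every transcript and intron; the
        # heterogeneous direct effects are applied per element afterwards.
        tr_effect = {tid: np.zeros(n) for tid in model.transcripts}
        direct: dict[str, np.ndarray] = {}
        for t in gtruths:
            if t.mode == "none":
                continue
            d = geno.dosage(t.snp_id)
            d = d - d.mean()
            if t.mode == "systematic":
                for tid in model.transcripts:
                    tr_effect[tid] = tr_effect[tid] + t.beta * d
                for iid, _, _ in ids["intron"]:
                    direct[iid] = direct.get(iid, np.zeros(n)) + t.beta * d
                affected = sorted(known_ids)
            else:
                bad = t.affected_elements - known_ids
                if bad:
                    raise InvalidSpecificationError(
                        f"truth references unknown elements {sorted(bad)}"
                    )
                for el in t.affected_elements:
                    if el in model.transcripts:
                        tr_effect[el] = tr_effect[el] + t.beta * d
                    else:
                        direct[el] = direct.get(el, np.zeros(n)) + t.beta * d
                affected = sorted(t.affected_elements)
            for el in affected:
                truth_rows.append((t.snp_id, model.gene_id, t.mode, el, t.beta))

        a_s = rng.normal(0.0, sample_sd, size=n)  # per-sample intercept, this gene

        tr_signal = {}
        for tid in model.transcripts:
            b_t = rng.normal(0.0, target_sd)
            tr_signal[tid] = a_s + b_t + tr_effect[tid]

        def emit(q: str, tid: str, start: int, end: int, signal: np.ndarray) -> None:
            prenoise[q][tid] = signal
            values[q][tid] = signal + rng.normal(0.0, resid_sd, size=n)
            meta[q].append(
                (tid, model.gene_id, q, model.chrom, start, end, model.tss)
            )

        # gene = exact sum of transcript signals (identity holds pre-noise)
        g_id, g_s, g_e = ids["gene"][0]
        emit("gene", g_id, g_s, g_e, sum(tr_signal.values()) + direct.get(g_id, 0.0))
        for tid, s, e in ids["transcript"]:
            emit("transcript", tid, s, e, tr_signal[tid] + direct.get(tid, 0.0))
        for eid, s, e in ids["exon"]:
            k = [
                tid
                for tid, chosen in model.transcripts.items()
                if any(model.exons[c] == (s, e) for c in chosen)
            ]
            sig = sum(tr_signal[t] for t in k) + rng.normal(0.0, target_sd)
            emit("exon", eid, s, e, sig + direct.get(eid, 0.0))
        for jid, s, e in ids["junction"]:
            k = []
            for tid, chosen in model.transcripts.items():
                pairs = {
                    (model.exons[a][1], model.exons[b][0])
                    for a, b in zip(chosen[:-1], chosen[1:])
                }
                if (s, e) in pairs:
                    k.append(tid)
            sig = sum(tr_signal[t] for t in k) + rng.normal(0.0, target_sd)
            emit("junction", jid, s, e, sig + direct.get(jid, 0.0))
        if genes.include_intron_retention:
            for iid, s, e in ids["intron"]:
                sig = a_s + rng.normal(0.0, target_sd)
                emit("intron", iid, s, e, sig + direct.get(iid, 0.0))

    sets = {}
    pre = {}
    for q in QUANT_TYPES:
        cols = list(values[q].keys())
        vals = pd.DataFrame(
            np.column_stack([values[q][c] for c in cols]) if cols else np.empty((n, 0)),
            index=samples,
            columns=cols,
        )
        targets = pd.DataFrame(
            meta[q],
            columns=["target_id"] + TARGET_META_COLUMNS,
        ).set_index("target_id")
        sets[q] = ExpressionSet(vals, targets, q)
        pre[q] = pd.DataFrame(
            np.column_stack([prenoise[q][c] for c in cols]) if cols else np.empty((n, 0)),
            index=samples,
            columns=cols,
        )
    truth = pd.DataFrame(
        truth_rows, columns=["snp_id", "gene_id", "mode", "target_id", "beta"]
    )
    return SimulatedExpression(sets, pre, truth, models)


# ---------------------------------------------------------------------------
# annotations and GWAS leads
# ---------------------------------------------------------------------------

def simulate_annotations(
    region_span: tuple[int, int],
    n_intervals: int,
    width_bp: int,
    seed: int,
    enrich_near: list[int] | None = None,
    enrich_fraction: float = 0.8,
    chrom: str = "1",
) -> pd.DataFrame:
    """Fixed-width annotation intervals, optionally enriched near SNPs.

    Returns a BED-convention frame (``chrom, start, end, summit``) with
    every interval exactly ``width_bp`` long.  When ``enrich_near`` holds
    SNP positions, ``enrich_fraction`` of the intervals are centred within
    1 kb of a (cycled) position from that list; the rest are uniform.
    """
    if width_bp <= 0:
        raise InvalidSpecificationError("width_bp must be positive")
    lo, hi = region_span
    rng = np.random.default_rng(seed)
    half = width_bp // 2
    centers = []
    n_enriched = 0
    if enrich_near:
        n_enriched = int(round(enrich_fraction * n_intervals))
        # offset small enough that the interval always covers its anchor SNP
        # (and is always centred within 1 kb of it)
        max_off = min(1000, max(half - 1, 0))
        for i in range(n_enriched):
            anchor = enrich_near[i % len(enrich_near)]
            centers.append(int(anchor + rng.integers(-max_off, max_off + 1)))
    for _ in range(n_intervals - n_enriched):
        centers.append(int(rng.uniform(lo + half, hi - half)))
    starts = np.maximum(np.array(centers) - half, 0)
    return pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": starts + width_bp, "summit": centers}
    ).sort_values("start", ignore_index=True)


def simulate_study(
    n_loci: int = 20,
    n_causal: int = 10,
    n_individuals: int = 300,
    seed: int = 0,
    snps_per_locus: int = 15,
    locus_span_bp: int = 50_000,
    within_block_r: float = 0.9,
    beta: float = 0.8,
    mode: str = "systematic",
    disease: str = "SIM",
    n_annotation_intervals: int = 60,
    annotation_enrich_fraction: float = 0.8,
):
    """Generate a complete single-disease study bundle for pipeline runs.

    Lays ``n_loci`` LD blocks along one chromosome (one block per locus,
    ``locus_span_bp`` pitch), puts a recombination-hotspot summit at every
    block boundary (so each locus is one hotspot interval), one gene per
    locus with its TSS at the locus centre, and a GWAS lead at the central
    SNP of every block.  The first ``n_causal`` loci carry a planted eQTL
    at the lead SNP itself (shared-causal architecture); the rest are
    expression-null.  Annotations are enriched near the causal SNPs.

    Returns a dict with keys ``geno, expression, prenoise, truth,
    hotspots, leads, annotations, causal_snps, region_bounds,
    gene_models``.
    """
    if not (1 <= n_causal <= n_loci):
        raise InvalidSpecificationError("need 1 <= n_causal <= n_loci")
    spec = LDBlockSpec(
        n_blocks=n_loci,
        snps_per_block=snps_per_locus,
        within_block_r=within_block_r,
        maf_range=(0.15, 0.45),
        block_span_bp=locus_span_bp,
        start_pos=10_000,
    )
    geno = simulate_genotypes(spec, n_individuals, seed)

    # hotspot summit at every block boundary; intervals are the blocks
    boundaries = [spec.start_pos - 5_000 + b * locus_span_bp for b in range(n_loci + 1)]
    half = 100
    hotspots = pd.DataFrame(
        {
            "chrom": spec.chrom,
            "start": [b - half for b in boundaries],
            "end": [b + half for b in boundaries],
            "summit": boundaries,
        }
    )

    # lead SNP = central SNP of each block; causal loci get a planted eQTL
    lead_ids = []
    for b in range(n_loci):
        block_ids = geno.snp_ids[b * snps_per_locus : (b + 1) * snps_per_locus]
        lead_ids.append(block_ids[snps_per_locus // 2])
    centres = [int(geno.snps.loc[sid, "pos"]) for sid in lead_ids]
    genes = GeneModelSpec(
        n_genes=n_loci,
        transcripts_per_gene=(1, 1),
        exons_per_transcript=(3, 3),
        tss_positions=tuple(centres),
        chrom=spec.chrom,
        intron_bp=1_000,
    )
    truths = [
        EqtlTruth(snp_id=lead_ids[i], gene_id=f"GENE{i + 1}", mode=mode, beta=beta)
        for i in range(n_causal)
    ]
    sim = simulate_expression(geno, genes, truths, seed + 1)
    leads = simulate_gwas_leads(geno, lead_ids, disease, seed + 2)

    causal_pos = [int(geno.snps.loc[s, "pos"]) for s in lead_ids[:n_causal]]
    region = (0, spec.start_pos + n_loci * locus_span_bp + 10_000)
    annotations = simulate_annotations(
        region,
        n_annotation_intervals,
        200,
        seed + 3,
        enrich_near=causal_pos,
        enrich_fraction=annotation_enrich_fraction,
        chrom=spec.chrom,
    )
    return {
        "geno": geno,
        "expression": sim.sets,
        "prenoise": sim.prenoise,
        "truth": sim.truth,
        "hotspots": hotspots,
        "leads": leads,
        "annotations": annotations,
        "causal_snps": list(lead_ids[:n_causal]),
        "region_bounds": region,
        "gene_models": sim.gene_models,
    }


def simulate_gwas_leads(
    geno: GenotypeMatrix,
    snp_ids: list[str],
    disease: str,
    seed: int,
    p_range: tuple[float, float] = (1e-30, 5e-8),
) -> list[GwasLead]:
    """Dress a chosen set of panel SNPs up as GWAS lead SNPs."""
    rng = np.random.default_rng(seed)
    leads = []
    for sid in snp_ids:
        if sid not in geno.snp_ids:
            raise InvalidSpecificationError(f"lead SNP {sid} absent from panel")
        row = geno.snps.loc[sid]
        logp = rng.uniform(np.log10(p_range[0]), np.log10(p_range[1]))
        leads.append(
            GwasLead(sid, str(row["chrom"]), int(row["pos"]), disease, float(10 ** logp))
        )
    return leads
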