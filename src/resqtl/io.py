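"""Readers and writers for the pipeline's on-disk formats.

Formats handled: VCF v4.x (GT and optional DS) via :mod:`cyvcf2`;
tab-delimited quantification matrices (one target per row, header row of
sample IDs); BED3+ and NarrowPeak tracks; GWAS lead-SNP tables; and the
Geuvadis-style target identifier grammar
``<gene>_<class>.<start>.<end>`` (with a ``chrom:start-end`` fallback for
junctions).

Coordinate conventions: BED tracks are 0-based half-open; VCF positions
and target IDs are 1-based inclusive.  This module is the only conversion
layer.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionSet,
    GenotypeMatrix,
    GwasLead,
    QuantTarget,
    QUANT_TYPES,
    SNP_META_COLUMNS,
    TARGET_META_COLUMNS,
)

logger = logging.getLogger(__name__)


class TargetIdError(ValueError):
    """A target identifier does not match the documented grammar."""


class VcfParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# target identifier grammar
# ---------------------------------------------------------------------------

_COORD_ID = re.compile(
    r"^(?P<gene>.+?)_(?P<cls>exon|junction|intron)\.(?P<start>\d+)\.(?P<end>\d+)$"
)
_REGION_ID = re.compile(r"^(?P<chrom>[\w.]+):(?P<start>\d+)[–-](?P<end>\d+)$")
_TRANSCRIPT_SUFFIX = re.compile(r"\.t\d+$")


def parse_target_id(
    target_id: str,
    quant_type: str,
    annotation: pd.DataFrame | None = None,
    chrom: str = "",
    tss: int | None = None,
) -> QuantTarget:
    """Parse one target ID into typed metadata.

    Sub-gene IDs carry their own 1-based inclusive coordinates
    (``GENE1_exon.100.250``); junctions may also use the region dialect
    ``chr1:235915471-235916344``.  Gene and transcript IDs carry no
    coordinates, which are then taken from the companion ``annotation``
    frame (indexed by target_id with the standard metadata columns).
    """
    if quant_type not in QUANT_TYPES:
        raise TargetIdError(f"unknown quantification type {quant_type!r}")
    if annotation is not None and target_id in annotation.index:
        row = annotation.loc[target_id]
        return QuantTarget(
            target_id,
            str(row["gene_id"]),
            quant_type,
            str(row["chrom"]),
            int(row["start"]),
            int(row["end"]),
            int(row["tss"]),
        )
    m = _COORD_ID.match(target_id)
    if m:
        if m.group("cls") != quant_type:
            raise TargetIdError(
                f"{target_id!r}: ID class {m.group('cls')!r} != declared {quant_type!r}"
            )
        start, end = int(m.group("start")), int(m.group("end"))
        return QuantTarget(
            target_id, m.group("gene"), quant_type, chrom, start, end,
            tss if tss is not None else start,
        )
    m = _REGION_ID.match(target_id)
    if m and quant_type in ("junction", "exon", "intron"):
        start, end = int(m.group("start")), int(m.group("end"))
        return QuantTarget(
            target_id, "", quant_type, m.group("chrom"), start, end,
            tss if tss is not None else start,
        )
    if quant_type in ("gene", "transcript"):
        gene = (
            _TRANSCRIPT_SUFFIX.sub("", target_id)
            if quant_type == "transcript"
            else target_id
        )
        if tss is None:
            raise TargetIdError(
                f"{target_id!r}: {quant_type} IDs carry no coordinates; "
                "provide a companion annotation"
            )
        return QuantTarget(target_id, gene, quant_type, chrom, tss, tss, tss)
    raise TargetIdError(f"cannot parse target ID {target_id!r} as {quant_type}")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_genotypes(path: str) -> GenotypeMatrix:
    """Read a VCF into a dosage matrix, dropping non-biallelic-SNP records.

    Dosages come from the DS FORMAT field when present, else from GT hard
    calls (missing genotypes become NaN).  Multi-allelic and indel records
    are excluded with a logged count.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError on malformed input
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise VcfParseError(f"VCF {path} has no sample columns")

    ids, chroms, poss, refs, alts = [], [], [], [], []
    rows = []
    n_excluded = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_excluded += 1
            continue
        try:
            ds = var.format("DS")
        except KeyError:  # DS not declared in the header
            ds = None
        if ds is not None:
            dos = np.asarray(ds, dtype=float).reshape(-1)
        else:
            # gt_types: 0 hom-ref, 1 het, 3 hom-alt, 2 unknown
            gt = var.gt_types.astype(float)
            dos = np.where(gt == 3, 2.0, gt)
            dos[var.gt_types == 2] = np.nan
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        ids.append(vid)
        chroms.append(str(var.CHROM))
        poss.append(int(var.POS))
        refs.append(var.REF)
        alts.append(var.ALT[0])
        rows.append(dos)
    if n_excluded:
        logger.info("read_genotypes: excluded %d non-biallelic-SNP records", n_excluded)
    dosages = pd.DataFrame(
        np.array(rows).T if rows else np.empty((len(samples), 0)),
        index=pd.Index(samples, name="sample"),
        columns=ids,
    )
    with np.errstate(invalid="ignore"):
        maf = np.nanmean(dosages.to_numpy(), axis=0) / 2.0 if rows else np.array([])
    maf = np.minimum(maf, 1.0 - maf)
    snps = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": poss,
            "ref": refs,
            "alt": alts,
            "maf": maf,
            "hwe_p": np.nan,
            "call_rate": 1.0 - dosages.isna().mean().to_numpy()
            if rows
            else np.array([]),
        },
        index=pd.Index(ids, name="snp_id"),
    )[SNP_META_COLUMNS]
    gm = GenotypeMatrix(dosages, snps)
    gm.n_excluded = n_excluded  # type: ignore[attr-defined]
    return gm


def write_vcf(geno: GenotypeMatrix, path: str) -> None:
    """Write hard-call genotypes as a minimal VCF v4.2 (GT only)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(geno.snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.samples)
            + "\n"
        )
        order = geno.snps.sort_values(["chrom", "pos"]).index
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for sid in order:
            meta = geno.snps.loc[sid]
            dos = geno.dosages[sid]
            calls = [
                "./." if pd.isna(d) else gt_map[int(round(d))] for d in dos
            ]
            fh.write(
                f"{meta['chrom']}\t{int(meta['pos'])}\t{sid}\t{meta['ref']}\t"
                f"{meta['alt']}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


# ---------------------------------------------------------------------------
# quantification matrices
# ---------------------------------------------------------------------------

def write_quant_matrix(expr: ExpressionSet, path: str, float_fmt: str = "%.10g") -> None:
    """Write targets x samples TSV (header row = sample IDs)."""
    expr.values.T.to_csv(path, sep="\t", index_label="target_id", float_format=float_fmt)


def write_target_annotation(expr: ExpressionSet, path: str) -> None:
    expr.targets.to_csv(path, sep="\t", index_label="target_id")


def read_target_annotation(path: str) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t").set_index("target_id")
    missing = [c for c in TARGET_META_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"annotation {path} lacks columns {missing}")
    return frame


def read_quant_matrix(
    path: str,
    quant_type: str,
    annotation: pd.DataFrame | None = None,
    chrom: str = "",
) -> ExpressionSet:
    """Read a quantification TSV into an :class:`ExpressionSet`.

    Duplicate target IDs are an error.  Target metadata comes from the
    companion annotation when provided, else from the ID grammar.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0)
    dup = raw.index[raw.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate target IDs in {path}: {dup}")
    values = raw.T
    values.index.name = "sample"
    rows = []
    for tid in values.columns:
        qt = parse_target_id(str(tid), quant_type, annotation=annotation, chrom=chrom,
                             tss=0 if annotation is None and quant_type in ("gene", "transcript") else None)
        rows.append((qt.target_id, qt.gene_id, qt.element_class, qt.chrom, qt.start, qt.end, qt.tss))
    targets = pd.DataFrame(rows, columns=["target_id"] + TARGET_META_COLUMNS).set_index("target_id")
    return ExpressionSet(values, targets, quant_type)


def align_samples(
    geno: GenotypeMatrix, expr: ExpressionSet
) -> tuple[GenotypeMatrix, ExpressionSet]:
    """Restrict both containers to shared samples, in stable sorted order."""
    common = sorted(set(geno.samples) & set(expr.samples))
    if not common:
        raise ValueError("no overlapping samples between genotypes and expression")
    dropped = (len(geno.samples) - len(common), len(expr.samples) - len(common))
    if any(dropped):
        logger.info(
            "align_samples: dropped %d genotype-only and %d expression-only samples",
            *dropped,
        )
    return geno.subset_samples(common), expr.subset_samples(common)


# ---------------------------------------------------------------------------
# BED / NarrowPeak / lead tables
# ---------------------------------------------------------------------------

def write_bed(track: pd.DataFrame, path: str) -> None:
    """Write a track frame as BED (0-based half-open), extra columns after end."""
    cols = ["chrom", "start", "end"] + [
        c for c in track.columns if c not in ("chrom", "start", "end")
    ]
    track[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str, extra_columns: tuple[str, ...] = ()) -> pd.DataFrame:
    names = ["chrom", "start", "end", *extra_columns]
    frame = pd.read_csv(path, sep="\t", header=None, comment="#")
    frame = frame.iloc[:, : len(names)]
    frame.columns = names[: frame.shape[1]]
    return frame


_NARROWPEAK_COLS = [
    "chrom", "start", "end", "name", "score", "strand",
    "signal", "p_value", "q_value", "summit_offset",
]


def read_narrowpeak(path: str, q_min: float | None = None) -> pd.DataFrame:
    """Read an ENCODE NarrowPeak track (summit offset in column 10).

    ``q_min`` filters on the -log10 q-value column when given (e.g. 2.0
    keeps peaks at FDR <= 0.01); peaks with missing q (-1) are kept.
    """
    frame = pd.read_csv(path, sep="\t", header=None, names=_NARROWPEAK_COLS)
    if q_min is not None:
        keep = (frame["q_value"] >= q_min) | (frame["q_value"] < 0)
        frame = frame.loc[keep].reset_index(drop=True)
    return frame


def write_narrowpeak(frame: pd.DataFrame, path: str) -> None:
    frame[_NARROWPEAK_COLS].to_csv(path, sep="\t", header=False, index=False)


def read_gwas_leads(path: str) -> list[GwasLead]:
    """Read a lead-SNP TSV with columns snp_id, chrom, pos, disease, assoc_p."""
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        GwasLead(str(r.snp_id), str(r.chrom), int(r.pos), str(r.disease), float(r.assoc_p))
        for r in frame.itertuples(index=False)
    ]


def write_gwas_leads(leads: list[GwasLead], path: str) -> None:
    from .datatypes import leads_to_frame

    leads_to_frame(leads).to_csv(path, sep="\t", index=False)
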