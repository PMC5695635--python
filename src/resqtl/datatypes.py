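"""Core in-memory containers shared across the pipeline.

Two tabular containers carry almost everything: :class:`GenotypeMatrix`
(individuals x SNPs dosage matrix plus per-SNP metadata) and
:class:`ExpressionSet` (individuals x expression targets for one RNA-Seq
quantification type, plus per-target metadata).  Both are thin wrappers
around aligned :class:`pandas.DataFrame` objects so downstream numerics can
drop straight to numpy.

Coordinate conventions
----------------------
Target and VCF coordinates are 1-based inclusive; BED tracks are 0-based
half-open.  Conversion happens only in :mod:`resqtl.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

#: The five RNA-Seq quantification resolutions, in the conventional order.
QUANT_TYPES = ("gene", "transcript", "exon", "junction", "intron")

SNP_META_COLUMNS = ["chrom", "pos", "ref", "alt", "maf", "hwe_p", "call_rate"]
TARGET_META_COLUMNS = ["gene_id", "element_class", "chrom", "start", "end", "tss"]


class InvalidSpecificationError(ValueError):
    """A simulation or pipeline specification violates its preconditions."""


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage table with per-SNP metadata.

    Parameters
    ----------
    dosages
        DataFrame indexed by sample ID with one column per SNP ID.  Values
        are allele dosages in [0, 2]; hard calls are exactly {0, 1, 2} and
        NaN marks a missing genotype.
    snps
        DataFrame indexed by SNP ID with columns ``chrom, pos, ref, alt,
        maf, hwe_p, call_rate``.  ``maf``/``hwe_p``/``call_rate`` may be NaN
        until QC fills them in.
    """

    dosages: pd.DataFrame
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.dosages.columns.equals(self.snps.index):
            # Keep the two tables aligned; reindex metadata to dosage order.
            self.snps = self.snps.reindex(self.dosages.columns)
        missing = [c for c in ("chrom", "pos") if c not in self.snps.columns]
        if missing:
            raise ValueError(f"snps table lacks required columns: {missing}")

    @property
    def samples(self) -> pd.Index:
        return self.dosages.index

    @property
    def snp_ids(self) -> pd.Index:
        return self.dosages.columns

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def subset_snps(self, snp_ids: Iterable[str]) -> "GenotypeMatrix":
        ids = pd.Index(snp_ids)
        return GenotypeMatrix(self.dosages.loc[:, ids], self.snps.loc[ids])

    def subset_samples(self, samples: Iterable[str]) -> "GenotypeMatrix":
        idx = pd.Index(samples)
        return GenotypeMatrix(self.dosages.loc[idx], self.snps)

    def dosage(self, snp_id: str) -> np.ndarray:
        return self.dosages[snp_id].to_numpy(dtype=float)


@dataclass
class ExpressionSet:
    """Individuals x targets matrix for a single quantification type."""

    values: pd.DataFrame
    targets: pd.DataFrame
    quant_type: str

    def __post_init__(self) -> None:
        if self.quant_type not in QUANT_TYPES:
            raise ValueError(f"unknown quantification type: {self.quant_type!r}")
        if not self.values.columns.equals(self.targets.index):
            self.targets = self.targets.reindex(self.values.columns)

    @property
    def samples(self) -> pd.Index:
        return self.values.index

    @property
    def target_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_targets(self) -> int:
        return self.values.shape[1]

    def subset_targets(self, target_ids: Iterable[str]) -> "ExpressionSet":
        ids = pd.Index(target_ids)
        return ExpressionSet(self.values.loc[:, ids], self.targets.loc[ids], self.quant_type)

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionSet":
        return ExpressionSet(self.values.loc[pd.Index(samples)], self.targets, self.quant_type)

    def gene_targets(self, gene_id: str) -> pd.Index:
        return self.targets.index[self.targets["gene_id"] == gene_id]


@dataclass(frozen=True)
class QuantTarget:
    """One expression target (gene / transcript / exon / junction / intron).

    Coordinates are 1-based inclusive; ``tss`` is the transcription start
    site of the parent gene (used for cis-window tests).
    """

    target_id: str
    gene_id: str
    element_class: str
    chrom: str
    start: int
    end: int
    tss: int

    def __post_init__(self) -> None:
        if self.element_class not in QUANT_TYPES:
            raise ValueError(f"bad element_class {self.element_class!r}")
        if self.start > self.end:
            raise ValueError(f"{self.target_id}: start {self.start} > end {self.end}")


@dataclass(frozen=True)
class GwasLead:
    """A GWAS lead SNP for one disease."""

    snp_id: str
    chrom: str
    pos: int
    disease: str
    assoc_p: float

    def __post_init__(self) -> None:
        if not (0 < self.assoc_p <= 1):
            raise ValueError(f"{self.snp_id}: assoc_p {self.assoc_p} outside (0, 1]")


def leads_to_frame(leads: Iterable[GwasLead]) -> pd.DataFrame:
    rows = [(g.snp_id, g.chrom, g.pos, g.disease, g.assoc_p) for g in leads]
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "disease", "assoc_p"])


def frame_to_leads(frame: pd.DataFrame) -> list[GwasLead]:
    return [
        GwasLead(str(r.snp_id), str(r.chrom), int(r.pos), str(r.disease), float(r.assoc_p))
        for r in frame.itertuples(index=False)
    ]


@dataclass
class CovariateSet:
    """Individuals x k covariate matrix (genotype PCs, imputation status...)."""

    matrix: pd.DataFrame
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.labels:
            self.labels = [str(c) for c in self.matrix.columns]

    @property
    def k(self) -> int:
        return self.matrix.shape[1]

    def aligned(self, samples: pd.Index) -> np.ndarray:
        """Covariate array aligned to a sample order (empty -> (n, 0))."""
        if self.k == 0:
            return np.empty((len(samples), 0))
        return self.matrix.loc[samples].to_numpy(dtype=float)


def empty_covariates(samples: pd.Index) -> CovariateSet:
    return CovariateSet(pd.DataFrame(index=samples), [])
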