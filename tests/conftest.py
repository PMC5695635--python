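import numpy as np
import pandas as pd
import pytest

from resqtl.datatypes import GwasLead, empty_covariates
from resqtl.simulate import (
    EqtlTruth,
    GeneModelSpec,
    LDBlockSpec,
    simulate_expression,
    simulate_genotypes,
    simulate_study,
)


@pytest.fixture(scope="session")
def small_geno():
    """Two 10-SNP LD blocks (r = 0.9), 200 individuals."""
    spec = LDBlockSpec(n_blocks=2, snps_per_block=10, within_block_r=0.9,
                       maf_range=(0.15, 0.45))
    return simulate_genotypes(spec, 200, seed=42)


@pytest.fixture(scope="session")
def study_bundle():
    """10-locus single-disease study, 5 shared-causal loci, n = 250."""
    return simulate_study(n_loci=10, n_causal=5, n_individuals=250, seed=17)


@pytest.fixture(scope="session")
def expression_bundle(small_geno):
    """Three genes on the small panel: one systematic eQTL, one
    heterogeneous (single exon), one null."""
    genes = GeneModelSpec(
        n_genes=3, transcripts_per_gene=(1, 1), exons_per_transcript=(3, 3),
        tss_positions=(5_000, 15_000, 30_000),
    )
    lead = small_geno.snp_ids[4]
    sim0 = simulate_expression(small_geno, genes, [], seed=1)
    het_exon = sim0.sets["exon"].gene_targets("GENE2")[0]
    truths = [
        EqtlTruth(snp_id=lead, gene_id="GENE1", mode="systematic", beta=1.0),
        EqtlTruth(snp_id=small_geno.snp_ids[14], gene_id="GENE2",
                  mode="heterogeneous", affected_elements=frozenset({het_exon}),
                  beta=1.0),
    ]
    return simulate_expression(small_geno, genes, truths, seed=2), truths, lead


@pytest.fixture()
def no_covars(small_geno):
    return empty_covariates(small_geno.samples)


def make_lead(geno, snp_id, disease="SIM", p=1e-9) -> GwasLead:
    return GwasLead(snp_id, str(geno.snps.loc[snp_id, "chrom"]),
                    int(geno.snps.loc[snp_id, "pos"]), disease, p)
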