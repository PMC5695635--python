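"""Synthetic-data generator: LD structure, gene-model identities, planted
effects, determinism."""

import numpy as np
import pandas as pd
import pytest

from resqtl.datatypes import InvalidSpecificationError, QUANT_TYPES
from resqtl.simulate import (
    EqtlTruth,
    GeneModelSpec,
    LDBlockSpec,
    simulate_annotations,
    simulate_expression,
    simulate_genotypes,
    simulate_hotspots,
)


class TestGenotypes:
    def test_tight_block_reaches_high_r2(self):
        spec = LDBlockSpec(n_blocks=1, snps_per_block=2, within_block_r=0.99,
                           maf_range=(0.2, 0.4))
        g = simulate_genotypes(spec, 200, seed=1)
        d = g.dosages.to_numpy()
        assert np.corrcoef(d[:, 0], d[:, 1])[0, 1] ** 2 > 0.8

    def test_cross_block_independence(self):
        spec = LDBlockSpec(n_blocks=2, snps_per_block=2, within_block_r=0.0)
        g = simulate_genotypes(spec, 500, seed=2)
        c = np.corrcoef(g.dosages.to_numpy().T)
        assert np.abs(c[:2, 2:]).max() < 0.2

    def test_dosages_are_hard_calls_with_common_maf(self, small_geno):
        d = small_geno.dosages.to_numpy()
        assert set(np.unique(d)) <= {0.0, 1.0, 2.0}
        assert small_geno.snps["maf"].min() >= 0.01

    def test_deterministic_under_fixed_seed(self):
        spec = LDBlockSpec(n_blocks=2, snps_per_block=5)
        a = simulate_genotypes(spec, 50, seed=7)
        b = simulate_genotypes(spec, 50, seed=7)
        pd.testing.assert_frame_equal(a.dosages, b.dosages)
        pd.testing.assert_frame_equal(a.snps, b.snps)

    @pytest.mark.parametrize("bad", [0, 5, 19])
    def test_too_few_individuals_rejected(self, bad):
        with pytest.raises(InvalidSpecificationError):
            simulate_genotypes(LDBlockSpec(), bad, seed=0)

    def test_invalid_specs_rejected(self):
        with pytest.raises(InvalidSpecificationError):
            LDBlockSpec(n_blocks=0)
        with pytest.raises(InvalidSpecificationError):
            LDBlockSpec(within_block_r=1.0)
        with pytest.raises(InvalidSpecificationError):
            LDBlockSpec(maf_range=(0.01, 0.3))  # below the common-variant floor


class TestHotspots:
    def test_partition_of_region(self):
        hs = simulate_hotspots((0, 1_000_000), 4, seed=3)
        assert len(hs) == 4
        assert (hs["start"].to_numpy()[1:] >= hs["end"].to_numpy()[:-1]).all()
        assert ((hs["start"] <= hs["summit"]) & (hs["summit"] <= hs["end"])).all()
        # 4 disjoint hotspots cut the span into 5 inter-hotspot intervals
        assert len(hs) + 1 == 5

    def test_deterministic(self):
        a = simulate_hotspots((0, 500_000), 3, seed=9)
        b = simulate_hotspots((0, 500_000), 3, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_capacity_error(self):
        with pytest.raises(InvalidSpecificationError):
            simulate_hotspots((0, 10_000), 10, seed=0, width_bp=2_000)


class TestExpression:
    def test_five_sets_emitted(self, expression_bundle):
        sim, _, _ = expression_bundle
        assert set(sim.sets) == set(QUANT_TYPES)
        for q in QUANT_TYPES:
            assert sim.sets[q].quant_type == q

    def test_gene_equals_sum_of_transcripts_prenoise(self, small_geno):
        genes = GeneModelSpec(n_genes=3, transcripts_per_gene=(2, 3),
                              exons_per_transcript=(3, 5))
        sim = simulate_expression(small_geno, genes, [], seed=5)
        tmeta = sim.sets["transcript"].targets
        for gid in sim.sets["gene"].target_ids:
            tr_cols = tmeta.index[tmeta["gene_id"] == gid]
            np.testing.assert_allclose(
                sim.prenoise["gene"][gid].to_numpy(),
                sim.prenoise["transcript"][tr_cols].sum(axis=1).to_numpy(),
                atol=1e-10,
            )

    def test_systematic_truth_slope_recovered(self, expression_bundle, small_geno):
        """Single-transcript gene, systematic beta = 1: every element's OLS
        slope on dosage is within 3 SE of 1 (intron included)."""
        sim, truths, lead = expression_bundle
        d = small_geno.dosage(lead)
        for q in QUANT_TYPES:
            for tid in sim.sets[q].gene_targets("GENE1"):
                y = sim.sets[q].values[tid].to_numpy()
                x = np.column_stack([np.ones_like(d), d])
                coef, res_ss, _, _ = np.linalg.lstsq(x, y, rcond=None)
                resid = y - x @ coef
                se = np.sqrt(resid @ resid / (len(y) - 2)
                             / np.sum((d - d.mean()) ** 2))
                assert abs(coef[1] - 1.0) < 3 * se, (q, tid)

    def test_heterogeneous_truth_confined_to_affected_element(
        self, expression_bundle, small_geno
    ):
        sim, truths, _ = expression_bundle
        het = truths[1]
        d = small_geno.dosage(het.snp_id)
        dc = d - d.mean()
        sxx = dc @ dc
        affected = next(iter(het.affected_elements))
        for tid in sim.sets["exon"].gene_targets("GENE2"):
            y = sim.sets["exon"].values[tid].to_numpy()
            slope = dc @ y / sxx
            if tid == affected:
                assert slope > 0.5
            else:
                assert abs(slope) < 0.5

    def test_null_mode_type_one_error_near_nominal(self, small_geno):
        """With no planted effect, SNP-target regressions reject at ~5%."""
        from resqtl.cisscan import batch_association

        genes = GeneModelSpec(n_genes=8, transcripts_per_gene=(1, 2),
                              exons_per_transcript=(3, 5))
        sim = simulate_expression(small_geno, genes, [], seed=11)
        dos = small_geno.dosages.to_numpy()
        cov = np.empty((len(small_geno.samples), 0))
        ps = []
        for q in ("gene", "exon", "intron"):
            for tid in sim.sets[q].target_ids:
                y = sim.sets[q].values[tid].to_numpy()
                # one SNP per block keeps the tests near-independent
                ps.extend(batch_association(dos[:, [0, 10]], y, cov)["p"])
        ps = np.asarray(ps)
        m = len(ps)
        bound = 3 * np.sqrt(0.05 * 0.95 / m)
        assert abs((ps < 0.05).mean() - 0.05) < bound + 0.02  # LD between tests

    def test_unknown_references_rejected(self, small_geno):
        genes = GeneModelSpec(n_genes=1)
        with pytest.raises(InvalidSpecificationError):
            simulate_expression(
                small_geno, genes,
                [EqtlTruth(snp_id="rs_nowhere", gene_id="GENE1")], seed=0,
            )
        with pytest.raises(InvalidSpecificationError):
            simulate_expression(
                small_geno, genes,
                [EqtlTruth(snp_id=small_geno.snp_ids[0], gene_id="GENE99")], seed=0,
            )
        with pytest.raises(InvalidSpecificationError):
            simulate_expression(
                small_geno, genes,
                [EqtlTruth(snp_id=small_geno.snp_ids[0], gene_id="GENE1",
                           mode="heterogeneous",
                           affected_elements=frozenset({"GENE1_exon.1.2"}))],
                seed=0,
            )

    def test_heterogeneous_requires_explicit_elements(self):
        with pytest.raises(InvalidSpecificationError):
            EqtlTruth(snp_id="a", gene_id="g", mode="heterogeneous")

    def test_deterministic(self, small_geno):
        genes = GeneModelSpec(n_genes=2)
        a = simulate_expression(small_geno, genes, [], seed=3)
        b = simulate_expression(small_geno, genes, [], seed=3)
        for q in QUANT_TYPES:
            pd.testing.assert_frame_equal(a.sets[q].values, b.sets[q].values)


class TestAnnotations:
    def test_exact_width(self):
        ann = simulate_annotations((0, 500_000), 50, 200, seed=1)
        assert ((ann["end"] - ann["start"]) == 200).all()

    def test_full_enrichment_overlaps_every_anchor(self):
        anchors = [10_000, 50_000, 90_000]
        ann = simulate_annotations((0, 100_000), 30, 200, seed=2,
                                   enrich_near=anchors, enrich_fraction=1.0)
        for pos in anchors:
            p0 = pos - 1
            assert ((ann["start"] <= p0) & (p0 < ann["end"])).any()

    def test_deterministic(self):
        a = simulate_annotations((0, 100_000), 20, 200, seed=5)
        b = simulate_annotations((0, 100_000), 20, 200, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_width_rejected(self):
        with pytest.raises(InvalidSpecificationError):
            simulate_annotations((0, 1000), 5, 0, seed=0)
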