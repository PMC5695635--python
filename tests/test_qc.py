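"""QC thresholds, the exact HWE test against an enumeration oracle, the
inverse-normal transform, genotype PCA, and lead-SNP pruning."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from resqtl.datatypes import GenotypeMatrix, GwasLead
from resqtl.qc import (
    filter_expression,
    filter_snps,
    genotype_pca,
    hwe_exact_test,
    inverse_normal_transform,
    ld_prune,
    normalize_expression,
)


def hwe_oracle(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Independent Levene-Haldane enumeration using exact rational counts."""
    n = n_het + n_hom_minor + n_hom_major
    na = 2 * n_hom_minor + n_het
    na = min(na, 2 * n - na)
    probs = {}
    for h in range(na % 2, na + 1, 2):
        a = (na - h) // 2
        b = n - h - a
        logp = (
            h * math.log(2)
            + math.lgamma(n + 1)
            - math.lgamma(h + 1)
            - math.lgamma(a + 1)
            - math.lgamma(b + 1)
        )
        probs[h] = math.exp(logp)
    z = sum(probs.values())
    obs = probs[n_het] / z
    return min(1.0, sum(p / z for p in probs.values() if p / z <= obs * (1 + 1e-12)))


def _geno_from_dosages(dosages: np.ndarray, pos=None) -> GenotypeMatrix:
    n, m = dosages.shape
    ids = [f"s{j}" for j in range(m)]
    snps = pd.DataFrame(
        {"chrom": "1", "pos": pos if pos is not None else np.arange(m) * 1000 + 1,
         "ref": "A", "alt": "G", "maf": np.nan, "hwe_p": np.nan, "call_rate": np.nan},
        index=pd.Index(ids, name="snp_id"),
    )
    return GenotypeMatrix(
        pd.DataFrame(dosages, index=[f"I{i}" for i in range(n)], columns=ids), snps
    )


class TestHwe:
    @pytest.mark.parametrize(
        "counts",
        [(0, 0, 100), (50, 25, 25), (10, 45, 45), (0, 10, 90), (57, 14, 50),
         (1, 0, 1), (20, 0, 80), (100, 0, 0)],
    )
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(hwe_oracle(*counts), rel=1e-9)

    def test_extreme_homozygote_excess_fails_threshold(self):
        # (AA=90, Aa=0, aa=10): all minor alleles in homozygotes
        assert hwe_exact_test(0, 10, 90) < 1e-4

    def test_equilibrium_counts_pass(self):
        # p = 0.5, n = 100 at exact HWE proportions
        assert hwe_exact_test(50, 25, 25) > 0.5


class TestFilterSnps:
    def test_maf_boundary(self):
        rng = np.random.default_rng(0)
        # MAF 0.04 (removed, strict >0.05) and 0.06 (kept); counts at HWE
        def col(p, n=1000):
            return rng.binomial(2, p, n).astype(float)

        d = np.column_stack([col(0.04), col(0.06)])
        kept, report = filter_snps(_geno_from_dosages(d))
        assert list(kept.snp_ids) == ["s1"]
        assert report.n_fail_maf == 1

    def test_hwe_failure_removed(self):
        d = np.array([[0.0] * 90 + [2.0] * 10, [0.0] * 50 + [1.0] * 50]).T
        kept, report = filter_snps(_geno_from_dosages(d))
        assert "s0" not in kept.snp_ids
        assert report.n_fail_hwe >= 1
        assert kept.snps.loc["s1", "hwe_p"] > 1e-4

    def test_callrate_boundary(self):
        rng = np.random.default_rng(1)
        d = rng.binomial(2, 0.3, (100, 2)).astype(float)
        d[:31, 0] = np.nan   # 69% typed -> fails callrate_min = 0.7
        d[:30, 1] = np.nan   # exactly 70% typed -> passes (>=)
        kept, report = filter_snps(_geno_from_dosages(d))
        assert "s0" not in kept.snp_ids
        assert "s1" in kept.snp_ids

    def test_all_removed_warns_not_raises(self, caplog):
        d = np.zeros((50, 2))
        d[:1, :] = 1.0       # MAF = 0.01, below threshold
        kept, report = filter_snps(_geno_from_dosages(d))
        assert kept.n_snps == 0 and report.n_kept == 0

    def test_no_survivor_violates_any_threshold(self, small_geno):
        kept, _ = filter_snps(small_geno)
        assert (kept.snps["maf"] > 0.05).all()
        assert (kept.snps["hwe_p"] > 1e-4).all()
        assert (kept.snps["call_rate"] >= 0.7).all()


class TestFilterExpression:
    def _es(self, col):
        from resqtl.datatypes import ExpressionSet

        n = len(col)
        vals = pd.DataFrame({"t": col}, index=[f"I{i}" for i in range(n)])
        targets = pd.DataFrame(
            {"gene_id": ["g"], "element_class": ["gene"], "chrom": ["1"],
             "start": [1], "end": [2], "tss": [1]},
            index=pd.Index(["t"], name="target_id"),
        )
        return ExpressionSet(vals, targets, "gene")

    def test_strictly_above_half_kept(self):
        col = [1.0] * 187 + [0.0] * 186          # 187/373 = 50.1%
        assert filter_expression(self._es(col)).n_targets == 1
        col = [1.0] * 186 + [0.0] * 187          # 186/373 = 49.9%
        assert filter_expression(self._es(col)).n_targets == 0

    def test_all_zero_dropped(self):
        assert filter_expression(self._es([0.0] * 50)).n_targets == 0

    def test_zero_fraction_keeps_any_detected(self):
        col = [0.0] * 49 + [1.0]
        assert filter_expression(self._es(col), detect_fraction=0).n_targets == 1


class TestInverseNormal:
    def test_closed_form_quantiles(self):
        out = inverse_normal_transform(np.array([1.0, 2.0, 3.0]))
        expected = stats.norm.ppf([1 / 6, 3 / 6, 5 / 6])
        np.testing.assert_allclose(out, expected, atol=1e-12)
        assert out[0] == pytest.approx(-0.9674, abs=1e-4)

    def test_ties_share_average_rank(self):
        out = inverse_normal_transform(np.array([5.0, 5.0, 9.0]))
        assert out[0] == out[1]

    def test_monotone_rank_preserving(self):
        rng = np.random.default_rng(2)
        x = rng.gamma(2, 1, 100)
        out = inverse_normal_transform(x)
        assert stats.spearmanr(x, out).statistic == pytest.approx(1.0)

    def test_moments(self):
        rng = np.random.default_rng(3)
        x = rng.exponential(1, 200)
        out = inverse_normal_transform(x)
        assert abs(out.mean()) < 1e-12 * len(x)
        assert 0.9 < out.std(ddof=1) < 1.1

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            inverse_normal_transform(np.ones(10))

    def test_normalize_expression_per_target(self, expression_bundle):
        sim, _, _ = expression_bundle
        es = normalize_expression(sim.sets["exon"])
        means = es.values.mean(axis=0)
        assert np.abs(means).max() < 1e-10


class TestPca:
    def test_separates_divergent_subpopulations(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(4)
        a = rng.binomial(2, 0.05, (60, 40)).astype(float)
        b = rng.binomial(2, 0.8, (60, 40)).astype(float)
        geno = _geno_from_dosages(np.vstack([a, b]))
        cov = genotype_pca(geno, 3)
        labels = [0] * 60 + [1] * 60
        assert silhouette_score(cov.matrix.iloc[:, :1], labels) > 0.9

    def test_zero_components_empty(self, small_geno):
        assert genotype_pca(small_geno, 0).k == 0

    def test_permutation_equivariance(self, small_geno):
        cov = genotype_pca(small_geno, 2)
        perm = list(small_geno.samples[::-1])
        cov_p = genotype_pca(small_geno.subset_samples(perm), 2)
        np.testing.assert_allclose(
            cov.matrix.loc[perm].to_numpy(), cov_p.matrix.to_numpy(), atol=1e-8
        )


class TestLdPrune:
    def _panel(self, r2_pairs, n=400, seed=0):
        """Panel with controllable pairwise correlation via shared alleles."""
        rng = np.random.default_rng(seed)
        base = rng.binomial(1, 0.5, (2, n))
        cols = []
        for share in r2_pairs:
            copy = rng.random((2, n)) < np.sqrt(share)
            fresh = rng.binomial(1, 0.5, (2, n))
            cols.append(np.where(copy, base, fresh).sum(axis=0).astype(float))
        return np.column_stack(cols)

    def test_window_and_p_rule(self):
        d = self._panel([0.95, 0.95, 0.95])
        geno = _geno_from_dosages(d, pos=[100_000, 150_000, 260_000])
        leads = [
            GwasLead("s0", "1", 100_000, "D", 1e-12),
            GwasLead("s1", "1", 150_000, "D", 1e-8),    # 50 kb, high r2: pruned
            GwasLead("s2", "1", 260_000, "D", 1e-8),    # 160 kb away: kept
        ]
        res = ld_prune(leads, geno)
        assert [g.snp_id for g in res.retained] == ["s0", "s2"]
        assert res.removed[0][0] == "s1" and res.removed[0][1] == "s0"

    def test_chain_matches_greedy_independent_set(self):
        # A-B and B-C in LD, A-C not; equal P -> leftmost survives each clash
        rng = np.random.default_rng(5)
        a = rng.binomial(1, 0.5, (2, 600))
        c = rng.binomial(1, 0.5, (2, 600))
        mix = rng.random((2, 600)) < 0.5
        b = np.where(mix, a, c)  # correlated with both A and C
        d = np.column_stack([a.sum(0), b.sum(0), c.sum(0)]).astype(float)
        geno = _geno_from_dosages(d, pos=[10_000, 40_000, 70_000])
        from resqtl.qc import pairwise_r2

        # construction check: the chain is real
        assert pairwise_r2(d[:, 0], d[:, 1]) > 0.8 * 0.25  # ~0.25 each way
        leads = [GwasLead(s, "1", p, "D", 1e-8)
                 for s, p in zip(["s0", "s1", "s2"], [10_000, 40_000, 70_000])]
        res = ld_prune(leads, geno, r2_max=0.2)
        kept = [g.snp_id for g in res.retained]
        # brute force under the stated greedy order: keep A; B clashes with A
        # (equal P, leftmost wins); C clashes only with B which is gone
        assert kept == ["s0", "s2"]

    def test_absent_lead_excluded_with_warning(self, small_geno):
        leads = [GwasLead("rs_missing", "1", 123, "D", 1e-8)]
        res = ld_prune(leads, small_geno)
        assert res.retained == [] and res.missing == ["rs_missing"]

    def test_no_retained_pair_violates_threshold(self, study_bundle):
        geno, leads = study_bundle["geno"], study_bundle["leads"]
        from resqtl.qc import pairwise_r2

        res = ld_prune(leads, geno, window_bp=100_000, r2_max=0.8)
        kept = res.retained
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                if abs(kept[i].pos - kept[j].pos) < 100_000:
                    r2 = pairwise_r2(geno.dosage(kept[i].snp_id),
                                     geno.dosage(kept[j].snp_id))
                    assert r2 <= 0.8
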