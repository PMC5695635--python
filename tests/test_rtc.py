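"""RTC: hotspot interval assignment, rank/score semantics, brute-force
oracle agreement and shared-vs-independent discrimination."""

import numpy as np
import pandas as pd
import pytest

from resqtl.datatypes import GwasLead, empty_covariates
from resqtl.rtc import (
    DegenerateLDError,
    HotspotInterval,
    assign_interval,
    classify_causal,
    rtc_for_lead,
    rtc_score,
)
from resqtl.simulate import LDBlockSpec, simulate_genotypes

HOTSPOTS = pd.DataFrame(
    {
        "chrom": ["1", "1", "1"],
        "start": [45_000, 95_000, 295_000],
        "end": [55_000, 105_000, 305_000],
        "summit": [50_000, 100_000, 300_000],
    }
)


def _lead(pos, chrom="1"):
    return GwasLead("rsL", chrom, pos, "D", 1e-9)


class TestAssignInterval:
    def test_between_hotspots(self):
        ivs = assign_interval(_lead(200_000), HOTSPOTS)
        assert len(ivs) == 1
        iv = ivs[0]
        assert (iv.start, iv.end, iv.kind) == (100_000, 300_000, "between")
        assert not iv.edge_flagged

    def test_inside_hotspot_yields_upper_and_lower(self):
        ivs = assign_interval(_lead(100_000), HOTSPOTS)
        kinds = {iv.kind: iv for iv in ivs}
        assert set(kinds) == {"upper", "lower"}
        assert kinds["upper"].start == 50_000 and kinds["upper"].end == 100_001
        assert kinds["lower"].start == 100_000 and kinds["lower"].end == 300_000

    def test_edge_lead_flagged(self):
        ivs = assign_interval(_lead(10_000), HOTSPOTS, region_bounds=(0, 400_000))
        assert ivs[0].edge_flagged and ivs[0].start == 0

    def test_uncovered_chromosome_is_error(self):
        with pytest.raises(ValueError, match="chromosome"):
            assign_interval(_lead(100, chrom="2"), HOTSPOTS)


def brute_force_rtc(geno, expr, lead_id):
    """Independent enumeration with statsmodels: per-SNP association, then
    per-SNP removal and re-test of the best eQTL against the residuals."""
    import statsmodels.api as sm

    ids = list(geno.snp_ids)
    dos = {s: geno.dosage(s) for s in ids}
    assoc_p = {}
    for s in ids:
        x = sm.add_constant(dos[s])
        assoc_p[s] = sm.OLS(expr, x).fit().pvalues[-1]
    best = min(ids, key=lambda s: assoc_p[s])
    destroy = {}
    for s in ids:
        resid = sm.OLS(expr, sm.add_constant(dos[s])).fit().resid
        destroy[s] = sm.OLS(resid, sm.add_constant(dos[best])).fit().pvalues[-1]
    p_lead = destroy[lead_id]
    rank = sum(1 for s in ids if destroy[s] > p_lead * (1 + 1e-12))
    n = len(ids)
    return best, rank, (n - rank) / n


class TestRtcScore:
    def _locus(self, seed, shared=True, n=373):
        spec = LDBlockSpec(n_blocks=2, snps_per_block=20, within_block_r=0.9,
                           maf_range=(0.15, 0.45))
        g = simulate_genotypes(spec, n, seed)
        rng = np.random.default_rng(seed + 1000)
        lead_id = g.snp_ids[10]
        causal = lead_id if shared else g.snp_ids[30]
        d = g.dosage(causal)
        y = 0.7 * (d - d.mean()) + rng.standard_normal(n)
        lead = GwasLead(lead_id, "1", int(g.snps.loc[lead_id, "pos"]), "D", 1e-9)
        return g, y, lead

    def test_lead_equals_best_gives_rtc_one(self):
        g, y, lead = self._locus(seed=0, shared=True)
        res = rtc_score(g, y, empty_covariates(g.samples), lead)
        assert res.best_eqtl_snp == lead.snp_id
        assert res.rank_gwas == 0 and res.rtc == 1.0

    def test_formula_and_bounds(self):
        for seed in range(5):
            g, y, lead = self._locus(seed, shared=(seed % 2 == 0), n=200)
            res = rtc_score(g, y, empty_covariates(g.samples), lead)
            assert 0 < res.rtc <= 1
            assert res.rtc == pytest.approx((res.n_snps - res.rank_gwas) / res.n_snps)
            assert 0 <= res.rank_gwas <= res.n_snps - 1

    def test_matches_brute_force_oracle(self):
        for seed in range(8):
            g, y, lead = self._locus(seed + 50, shared=(seed % 2 == 0), n=150)
            res = rtc_score(g, y, empty_covariates(g.samples), lead)
            best, rank, rtc = brute_force_rtc(g, y, lead.snp_id)
            assert res.best_eqtl_snp == best
            assert res.rank_gwas == rank
            assert res.rtc == pytest.approx(rtc)

    def test_independent_causal_scores_low(self):
        hits = 0
        for seed in range(10):
            g, y, lead = self._locus(seed + 200, shared=False)
            res = rtc_score(g, y, empty_covariates(g.samples), lead)
            hits += res.rtc < 0.95
        assert hits >= 9

    def test_lead_absent_is_error(self):
        g, y, lead = self._locus(seed=3)
        sub = g.subset_snps(g.snp_ids[:5])  # lead (index 10) excluded
        with pytest.raises(ValueError, match="not among"):
            rtc_score(sub, y, empty_covariates(g.samples), lead)

    def test_identical_snps_degenerate(self):
        g, y, lead = self._locus(seed=4)
        dup = g.dosages.copy()
        for c in dup.columns:
            dup[c] = g.dosages[g.snp_ids[10]]
        from resqtl.datatypes import GenotypeMatrix

        with pytest.raises(DegenerateLDError):
            rtc_score(GenotypeMatrix(dup, g.snps.copy()), y,
                      empty_covariates(g.samples), lead)


class TestRtcForLead:
    def test_inside_hotspot_scores_both_and_reports_max(self, study_bundle):
        geno = study_bundle["geno"]
        hotspots = study_bundle["hotspots"]
        lead_id = study_bundle["causal_snps"][0]
        lead = GwasLead(lead_id, "1", int(geno.snps.loc[lead_id, "pos"]), "SIM", 1e-9)
        es = study_bundle["expression"]["gene"]
        y = es.values[es.gene_targets("GENE1")[0]].to_numpy()
        best, all_res = rtc_for_lead(
            geno, y, empty_covariates(geno.samples), lead, hotspots,
            region_bounds=study_bundle["region_bounds"],
        )
        assert best.rtc == max(r.rtc for r in all_res)
        assert best.rtc >= 0.95  # planted shared-causal locus


class TestClassifyCausal:
    def _pair(self, p_bf, rtc_value):
        assoc = {"lead_snp": "rsL", "target_id": "t1", "p_bf": p_bf}
        res = type("R", (), {})()
        iv = HotspotInterval("1", 0, 10)
        from resqtl.rtc import RTCResult

        rtcres = RTCResult("rsL", "t1", iv, 20, "rsB", 0, rtc_value)
        return assoc, rtcres

    @pytest.mark.parametrize(
        "p_bf,rtc_value,expected",
        [(0.04, 0.96, True), (0.04, 0.94, False), (0.06, 1.0, False)],
    )
    def test_conjunction_rule(self, p_bf, rtc_value, expected):
        assoc, rtcres = self._pair(p_bf, rtc_value)
        assert classify_causal(assoc, rtcres) is expected

    def test_mismatched_pair_is_error(self):
        assoc, rtcres = self._pair(0.01, 1.0)
        assoc["target_id"] = "other"
        with pytest.raises(ValueError, match="mismatched"):
            classify_causal(assoc, rtcres)
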