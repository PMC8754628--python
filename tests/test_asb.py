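"""Allele-specific binding: beta-binomial test, rho estimation, calling, negatives."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from turf.asb import (
    AllelicSite,
    CnvRegion,
    asb_non_allelic,
    asb_positives,
    beta_binomial_pvalue,
    build_negative_set,
    call_asb,
    estimate_overdispersion,
)
from turf.genomic import GenomicInterval, IntervalIndex, Variant


def _site(pos, ref_count, alt_count, dataset="d1", in_peak=True, chrom="chr1"):
    v = Variant(chrom, pos, "A", "G", f"s{chrom}_{pos}")
    return AllelicSite(v, dataset, ref_count, alt_count, in_peak)


class TestBetaBinomialPvalue:
    def test_balanced_counts_give_one(self):
        assert beta_binomial_pvalue(5, 5, 0.0) == 1.0

    def test_fully_imbalanced_binomial_tail(self):
        # two-sided exact binomial: 2 * (0.5)^10
        assert beta_binomial_pvalue(10, 0, 0.0) == pytest.approx(0.001953125, abs=1e-15)

    def test_overdispersion_widens_the_null(self):
        # oracle: the beta-binomial CDF from scipy at alpha=beta=(1/rho-1)/2
        rho = 0.3
        a = (1 / rho - 1) / 2
        oracle = min(1.0, 2.0 * stats.betabinom(10, a, a).sf(9))
        assert beta_binomial_pvalue(10, 0, rho) == pytest.approx(oracle, rel=1e-12)
        assert beta_binomial_pvalue(10, 0, rho) > beta_binomial_pvalue(10, 0, 0.0)

    @pytest.mark.parametrize("rho", [-0.1, 1.0, 1.5])
    def test_rho_domain(self, rho):
        with pytest.raises(ValueError):
            beta_binomial_pvalue(3, 3, rho)

    @given(
        a=st.integers(min_value=0, max_value=40),
        b=st.integers(min_value=0, max_value=40),
        rho=st.sampled_from([0.0, 0.1, 0.4]),
    )
    @settings(max_examples=200, deadline=None)
    def test_symmetry(self, a, b, rho):
        if a + b == 0:
            return
        assert beta_binomial_pvalue(a, b, rho) == pytest.approx(
            beta_binomial_pvalue(b, a, rho), abs=1e-12
        )

    @pytest.mark.parametrize("rho", [0.0, 0.2])
    def test_monotone_in_imbalance(self, rho):
        n = 30
        ps = [beta_binomial_pvalue(k, n - k, rho) for k in range(n // 2, n + 1)]
        assert all(ps[i + 1] <= ps[i] + 1e-12 for i in range(len(ps) - 1))


class TestEstimateOverdispersion:
    def test_binomial_sites_give_near_zero_rho(self, rng):
        ks = rng.binomial(20, 0.5, size=1000)
        sites = [_site(i + 1, int(k), 20 - int(k)) for i, k in enumerate(ks)]
        assert abs(estimate_overdispersion(sites)) < 0.05

    @pytest.mark.parametrize("true_rho", [0.1, 0.2])
    def test_recovers_planted_rho(self, rng, true_rho):
        a = (1 / true_rho - 1) / 2
        n = 40
        ps = rng.beta(a, a, size=1000)
        ks = rng.binomial(n, ps)
        sites = [_site(i + 1, int(k), n - int(k)) for i, k in enumerate(ks)]
        assert estimate_overdispersion(sites) == pytest.approx(true_rho, abs=0.05)

    def test_identical_balanced_ratios_give_zero(self):
        sites = [_site(i + 1, 10, 10) for i in range(60)]
        assert estimate_overdispersion(sites) == 0.0

    def test_too_few_sites_suggests_default(self):
        with pytest.raises(ValueError, match="default rho"):
            estimate_overdispersion([_site(1, 5, 5)])


class TestCallAsb:
    def test_cnv_region_excluded_before_testing(self):
        inside = _site(500, 30, 2)
        outside = _site(5000, 30, 2)
        cnv = [CnvRegion(GenomicInterval("chr1", 0, 1000), 0.3)]
        res = call_asb([inside, outside], cnv, fdr=0.05)
        assert list(res["pos"]) == [5000]

    def test_normal_depth_cnv_region_kept(self):
        cnv = [CnvRegion(GenomicInterval("chr1", 0, 1000), 1.0)]
        res = call_asb([_site(500, 30, 2)], cnv, fdr=0.05)
        assert len(res) == 1

    def test_strong_imbalance_called_positive(self):
        # exact binomial p ~ 1.2e-7 for (30, 2), the only test performed
        res = call_asb([_site(100, 30, 2)], fdr=0.05)
        assert res["significant"].tolist() == [True]
        assert [v.pos for v in asb_positives(res)] == [100]

    def test_equal_counts_fall_into_non_allelic(self):
        res = call_asb([_site(100, 7, 7)], fdr=0.05)
        assert not res["significant"].any()
        assert res["non_allelic"].tolist() == [True]
        assert [v.pos for v in asb_non_allelic(res)] == [100]

    def test_out_of_peak_and_shallow_sites_not_tested(self):
        res = call_asb([_site(1, 30, 2, in_peak=False), _site(2, 3, 1)], fdr=0.05)
        assert not res["tested"].any()

    def test_variant_positive_if_significant_in_any_dataset(self):
        sites = [_site(100, 30, 2, dataset="d1"), _site(100, 8, 8, dataset="d2")]
        res = call_asb(sites, fdr=0.05)
        assert len(asb_positives(res)) == 1

    def test_fdr_domain(self):
        with pytest.raises(ValueError):
            call_asb([_site(1, 5, 5)], fdr=1.5)


class TestBuildNegativeSet:
    def _peaks(self):
        return IntervalIndex([GenomicInterval("chr1", 890, 910)])

    def test_nearest_outside_peak_chosen(self):
        pos = Variant("chr1", 1000, "A", "G", "p1")
        cand_in = Variant("chr1", 900, "C", "T", "c_in")  # inside the peak
        cand_out = Variant("chr1", 1200, "C", "T", "c_out")
        ts = build_negative_set([pos], [], [pos, cand_in, cand_out], self._peaks(),
                                has_annotation=lambda v: True, seed=0)
        assert [v.key for v in ts.nearest_outside_peak] == ["c_out"]

    def test_shared_neighbour_deduplicated(self):
        p1 = Variant("chr1", 1000, "A", "G", "p1")
        p2 = Variant("chr1", 1400, "A", "G", "p2")
        shared = Variant("chr1", 1200, "C", "T", "shared")
        ts = build_negative_set([p1, p2], [], [p1, p2, shared], IntervalIndex(),
                                has_annotation=lambda v: True, seed=0)
        assert [v.key for v in ts.nearest_outside_peak] == ["shared"]

    def test_equal_thirds_weighting(self):
        # sublists of sizes 10 / 5 / 20 weigh 1/30, 1/15, 1/60 per example
        positives = [Variant("chr2", i + 1, "A", "G", f"p{i}") for i in range(3)]
        non_allelic = [Variant("chr1", 10_000 + i, "A", "G", f"na{i}") for i in range(10)]
        neighbours = [Variant("chr2", i + 10, "C", "T", f"nb{i}") for i in range(5)]
        randoms = [Variant("chr3", i + 1, "C", "T", f"r{i}") for i in range(20)]
        all_vars = positives + neighbours + randoms
        # craft nearest-neighbour structure: each positive's neighbour is unique
        ts = build_negative_set(
            positives, non_allelic, all_vars, IntervalIndex(),
            has_annotation=lambda v: not v.key.startswith("r"), n_random=20, seed=1,
        )
        assert len(ts.non_allelic) == 10 and len(ts.random_no_hit) == 20
        got = {
            "non_allelic": ts.weights[ts.non_allelic[0].key],
            "random": ts.weights[ts.random_no_hit[0].key],
        }
        assert got["non_allelic"] == pytest.approx(1 / 30)
        assert got["random"] == pytest.approx(1 / 60)
        for sub in ts.negative_sublists().values():
            assert sum(ts.weights[v.key] for v in sub) == pytest.approx(1 / 3)

    def test_positives_absent_from_negatives(self):
        pos = [Variant("chr1", 100, "A", "G", "p")]
        ts = build_negative_set(pos, pos, pos + [Variant("chr1", 50, "C", "T", "n")],
                                IntervalIndex(), has_annotation=lambda v: False, seed=0)
        neg_keys = {v.key for sub in ts.negative_sublists().values() for v in sub}
        assert "p" not in neg_keys


def test_call_asb_empty_input_warns_and_returns_empty():
    res = call_asb([_site(1, 5, 5, in_peak=False)], fdr=0.05)
    assert asb_positives(res) == [] and asb_non_allelic(res) == []
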