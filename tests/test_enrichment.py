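"""Trait-organ enrichment: pruning, U test, Holm-Sidak, z-scores."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from turf.enrichment import (
    TraitSet,
    cluster_organs,
    eligible_traits,
    holm_sidak,
    mann_whitney_one_sided,
    prune_by_distance,
    run_enrichment,
)


def _scored(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "score"])


def permutation_u_oracle(x, y):
    """Full enumeration of P(U >= U_obs) over pooled-value reassignments."""
    pooled = list(x) + list(y)
    n1 = len(x)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
        total += 1
        hits += u >= u_obs - 1e-12
    return hits / total


class TestPruneByDistance:
    def test_greedy_score_ordered_rule(self):
        df = _scored(
            [("chr1", 1_000_000, 0.9), ("chr1", 1_500_000, 0.8), ("chr1", 2_200_000, 0.7)]
        )
        kept = prune_by_distance(df)
        assert sorted(kept["pos"]) == [1_000_000, 2_200_000]

    def test_chromosomes_are_independent(self):
        df = _scored([("chr1", 100, 0.9), ("chr2", 101, 0.8)])
        assert len(prune_by_distance(df)) == 2

    def test_deterministic_tie_break(self):
        df = _scored([("chr1", 500, 0.5), ("chr1", 400, 0.5)])
        kept = prune_by_distance(df)
        assert kept["pos"].tolist() == [400]  # ascending (chrom, pos) wins the tie

    def test_pairwise_gap_property(self, rng):
        for _ in range(20):
            df = _scored(
                [
                    (f"chr{rng.integers(1, 3)}", int(p), float(rng.random()))
                    for p in rng.integers(0, 10_000_000, size=60)
                ]
            )
            kept = prune_by_distance(df)
            for chrom, grp in kept.groupby("chrom"):
                pos = np.sort(grp["pos"].to_numpy())
                assert np.all(np.diff(pos) > 1_000_000)

    def test_empty_input_passthrough(self):
        df = _scored([])
        assert prune_by_distance(df).empty


class TestMannWhitney:
    def test_two_vs_two_exact(self):
        # all C(4,2)=6 rank splits; trait holding both top ranks has p = 1/6
        assert mann_whitney_one_sided([0.9, 0.8], [0.1, 0.2]) == pytest.approx(1 / 6)

    def test_identical_samples_near_half(self):
        p = mann_whitney_one_sided([1, 2, 3, 4], [1, 2, 3, 4])
        assert 0.4 <= p <= 0.7

    def test_wrong_direction_large_p(self):
        assert mann_whitney_one_sided([0.1, 0.2], [0.8, 0.9]) >= 0.9

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_one_sided([], [1.0])

    def test_matches_permutation_oracle_small_samples(self, rng):
        for n1 in range(1, 6):
            for n2 in range(1, 11 - n1):
                x = rng.random(n1).round(1)  # rounding forces ties
                y = rng.random(n2).round(1)
                assert mann_whitney_one_sided(x, y) == pytest.approx(
                    permutation_u_oracle(x, y), abs=1e-12
                )

    def test_asymptotic_path_matches_scipy(self, rng):
        x, y = rng.random(30), rng.random(25)
        expected = stats.mannwhitneyu(x, y, alternative="greater", method="asymptotic")
        assert mann_whitney_one_sided(x, y) == pytest.approx(float(expected.pvalue))


class TestHolmSidak:
    def test_single_small_p_rejected(self):
        assert holm_sidak([0.001], 0.05).tolist() == [True]

    def test_all_large_p_kept(self):
        assert holm_sidak([0.3, 0.4], 0.05).tolist() == [False, False]

    def test_step_down_thresholds(self):
        # m=3: thresholds 1-0.95^(1/3), 1-0.95^(1/2), 0.05 for the sorted p
        flags = holm_sidak([0.01, 0.02, 0.04], 0.05)
        assert flags.tolist() == [True, True, True]

    def test_step_down_stops_at_first_failure(self):
        # sorted p: 0.001 rejected; 0.03 > 1-0.95^(1/2) ≈ 0.0253 stops the walk
        flags = holm_sidak([0.03, 0.001, 0.04], 0.05)
        assert flags.tolist() == [False, True, False]

    def test_empty_input(self):
        assert holm_sidak([], 0.05).size == 0

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    @settings(max_examples=200, deadline=None)
    def test_matches_direct_step_down_evaluation(self, pvals):
        flags = holm_sidak(pvals, 0.05)
        order = np.argsort(pvals)
        m = len(pvals)
        expected = np.zeros(m, dtype=bool)
        for rank, idx in enumerate(order):
            threshold = 1 - (1 - 0.05) ** (1 / (m - rank))
            if pvals[idx] <= threshold:
                expected[idx] = True
            else:
                break
        assert flags.tolist() == expected.tolist()


class TestEligibleTraits:
    def _catalog(self, trait_sizes):
        rows = []
        for trait, size in trait_sizes.items():
            for i in range(size):
                rows.append((f"{trait}_{i}", "chr1", 1000 + i, trait))
        return pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "trait"])

    def test_small_traits_excluded(self):
        cat = self._catalog({"small": 10, "big": 25})
        scores = {v: 0.9 for v in cat["variant_id"]}
        ld = pd.DataFrame(columns=["snp_a", "snp_b", "r2"])
        kept = eligible_traits(cat, ld, scores)
        assert [t.trait for t in kept] == ["big"]

    def test_low_scoring_traits_excluded(self):
        cat = self._catalog({"dull": 25, "sharp": 25})
        scores = {v: (0.9 if v.startswith("sharp_0") else 0.1) for v in cat["variant_id"]}
        # sharp_0 alone is 1/25 = 4% < 5%; give sharp one more high scorer
        scores["sharp_1"] = 0.95
        ld = pd.DataFrame(columns=["snp_a", "snp_b", "r2"])
        kept = eligible_traits(cat, ld, scores)
        assert [t.trait for t in kept] == ["sharp"]


class TestZScoresAndRun:
    def test_population_z_example(self):
        # organs with -log p of (3, 1, 2): z = (1.2247, -1.2247, 0)
        vals = np.array([3.0, 1.0, 2.0])
        z = (vals - vals.mean()) / vals.std(ddof=0)
        assert z == pytest.approx([1.224745, -1.224745, 0.0], abs=1e-6)

    def _toy_inputs(self, rng, planted=True):
        n = 40
        rows = []
        scores = {}
        for i in range(n):
            vid = f"rs{i}"
            chrom = f"chr{i % 4 + 1}"
            rows.append((vid, chrom, (i // 4) * 2_000_000 + 1, "t1" if i < 20 else "t2"))
            base = rng.random() * 0.2
            boost = 0.7 if (planted and i < 20) else 0.0
            scores[vid] = (base + boost, base)
        catalog = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "trait"])
        organ_scores = pd.DataFrame(
            {
                "chrom": catalog.set_index("variant_id")["chrom"],
                "pos": catalog.set_index("variant_id")["pos"],
                "liver": [scores[v][0] for v in catalog["variant_id"]],
                "brain": [scores[v][1] for v in catalog["variant_id"]],
                "lung": [scores[v][1] * 0.9 for v in catalog["variant_id"]],
            },
            index=catalog["variant_id"],
        )
        ld = pd.DataFrame(columns=["snp_a", "snp_b", "r2"])
        traits = [TraitSet("t1", tuple(catalog[catalog.trait == "t1"]["variant_id"]))]
        return traits, catalog, ld, organ_scores

    def test_planted_organ_wins_and_z_sums_to_zero(self, rng):
        traits, catalog, ld, organ_scores = self._toy_inputs(rng, planted=True)
        result = run_enrichment(traits, catalog, ld, organ_scores, iterations=20, seed=5)
        assert result.top_organs.iloc[0]["top_organ"] == "liver"
        z = result.mean_z_matrix.loc["t1"]
        assert z.sum() == pytest.approx(0.0, abs=1e-9)

    def test_deterministic_given_seed(self, rng):
        traits, catalog, ld, organ_scores = self._toy_inputs(rng)
        r1 = run_enrichment(traits, catalog, ld, organ_scores, iterations=5, seed=9)
        r2 = run_enrichment(traits, catalog, ld, organ_scores, iterations=5, seed=9)
        pd.testing.assert_frame_equal(r1.pairs, r2.pairs)

    def test_cluster_organs_returns_permutation(self, rng):
        matrix = pd.DataFrame(
            rng.random((5, 4)), columns=["a", "b", "c", "d"],
            index=[f"t{i}" for i in range(5)],
        )
        order = cluster_organs(matrix)
        assert sorted(order) == ["a", "b", "c", "d"]
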