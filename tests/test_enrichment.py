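import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fetalcortex.enrichment import (
    associate_batch,
    expression_scaling_association,
    hypergeometric_enrichment,
    permutation_median_test,
    proportion_odds_ratio,
    split_allometric_sets,
)
from fetalcortex.synthetic import (
    AnnotationConfig,
    ExpressionDesign,
    gen_annotation_resources,
    gen_expression_dataset,
)


def kendall_brute_force(x, y):
    """All-pairs tau-b oracle with tie correction."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        dx, dy = x[j] - x[i], y[j] - y[i]
        if dx == 0 and dy == 0:
            tx += 1; ty += 1
        elif dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            conc += 1
        else:
            disc += 1
    n0 = n * (n - 1) / 2
    return (conc - disc) / np.sqrt((n0 - tx) * (n0 - ty))


class TestAssociation:
    def test_expression_equal_to_beta_gives_tau_one(self):
        beta = pd.Series([0.8, 0.9, 1.0, 1.1, 1.2],
                         index=[f"r{i}" for i in range(5)])
        expr = pd.DataFrame([beta.to_numpy()], index=["G1"],
                            columns=beta.index)
        out = expression_scaling_association(expr, beta)
        assert out.loc[0, "tau"] == pytest.approx(1.0)

    def test_hand_enumerated_tau(self):
        # x=[1,2,3,4], y=[1,3,2,4]: 5 concordant, 1 discordant -> 4/6
        beta = pd.Series([1.0, 3.0, 2.0, 4.0, 5.0],
                         index=[f"r{i}" for i in range(5)])
        expr = pd.DataFrame([[1.0, 2.0, 3.0, 4.0, 5.0]], index=["G1"],
                            columns=beta.index)
        tau = expression_scaling_association(expr, beta).loc[0, "tau"]
        assert tau == pytest.approx(
            kendall_brute_force([1, 2, 3, 4, 5], [1, 3, 2, 4, 5]))

    def test_tau_matches_brute_force_with_ties(self, rng):
        for _ in range(10):
            x = rng.integers(0, 6, 12).astype(float)
            y = rng.integers(0, 6, 12).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            expected = kendall_brute_force(x, y)
            got, _ = stats.kendalltau(x, y)
            assert got == pytest.approx(expected)

    def test_constant_expression_excluded(self):
        beta = pd.Series(np.linspace(0.8, 1.2, 6),
                         index=[f"r{i}" for i in range(6)])
        expr = pd.DataFrame([[1.0] * 6], index=["G1"], columns=beta.index)
        out = expression_scaling_association(expr, beta)
        assert np.isnan(out.loc[0, "tau"])

    def test_too_few_regions_raises(self):
        beta = pd.Series([1.0, 1.1], index=["r0", "r1"])
        expr = pd.DataFrame([[1.0, 2.0]], index=["G1"], columns=beta.index)
        with pytest.raises(ValueError):
            expression_scaling_association(expr, beta)

    def test_planted_monotone_genes_recovered(self):
        d = ExpressionDesign(n_genes=300, n_regions=12, noise_sd=0.1,
                            monotone_region_fraction=0.05, effect_size=1.0,
                            zone_fraction=0.0, time_fraction=0.0,
                            region_fraction=0.0)
        sim = gen_expression_dataset(d, seed=11)
        beta = pd.Series(np.linspace(0.7, 1.3, 12), index=sim.regions)
        expr = pd.DataFrame(sim.values[:, :2].mean(axis=1)[:, :, 0],
                            index=sim.genes, columns=sim.regions)
        rec = expression_scaling_association(expr, beta, zone="CP",
                                             timepoint="early")
        batch = associate_batch([rec], alpha=0.01)
        planted = set(sim.monotone_genes)
        sig = set(batch.loc[batch["significant"], "gene"])
        sens = len(planted & sig) / len(planted)
        assert sens >= 0.8

    def test_region_subset_restricts_regions(self):
        beta = pd.Series(np.linspace(0.8, 1.2, 8),
                         index=[f"r{i}" for i in range(8)])
        expr = pd.DataFrame([np.arange(8.0)], index=["G1"],
                            columns=beta.index)
        out = expression_scaling_association(
            expr, beta, region_subset=[f"r{i}" for i in range(5)])
        assert out.loc[0, "n_regions"] == 5


class TestSplitSets:
    def test_empty_when_nothing_significant(self):
        rec = pd.DataFrame({"gene": ["a"], "zone": ["CP"],
                            "timepoint": ["early"], "tau": [0.5],
                            "p": [0.5], "q": [0.9]})
        sets = split_allometric_sets(rec)
        assert sets["hyper"] == [] and sets["hypo"] == []

    def test_gene_significant_in_two_zones_deduplicated(self):
        rec = pd.DataFrame({
            "gene": ["a", "a", "b"], "zone": ["CP", "IZ", "CP"],
            "timepoint": ["early"] * 3, "tau": [0.9, 0.8, -0.7],
            "p": [1e-5] * 3, "q": [1e-4] * 3})
        sets = split_allometric_sets(rec)
        assert sets["pooled"] == ["a", "b"]
        assert sets["hyper"] == ["a"] and sets["hypo"] == ["b"]
        assert sets["n_significant_records"] == 3


class TestHypergeometric:
    def test_geneset_equal_to_background(self):
        bg = [f"g{i}" for i in range(20)]
        res = hypergeometric_enrichment(bg[:5], bg, bg)
        assert res.enrichment_ratio == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_worked_example_by_enumeration(self):
        # M=10, K=4, N=5, x=3 -> p = 66/252
        bg = [f"g{i}" for i in range(10)]
        geneset = bg[:4]
        interest = bg[1:4] + bg[8:10]        # overlap {g1,g2,g3} = 3
        res = hypergeometric_enrichment(interest, geneset, bg)
        assert res.x == 3
        count = 0
        for draw in itertools.combinations(range(10), 5):
            if len(set(draw) & {0, 1, 2, 3}) >= 3:
                count += 1
        from math import comb
        assert res.p == pytest.approx(count / comb(10, 5))
        assert res.p == pytest.approx(66 / 252)

    def test_exhaustive_enumeration_all_small_instances(self):
        from math import comb
        bg = [f"g{i}" for i in range(12)]
        rng = np.random.default_rng(3)
        for _ in range(30):
            M = int(rng.integers(4, 13))
            K = int(rng.integers(1, M + 1))
            N = int(rng.integers(1, M + 1))
            universe = bg[:M]
            geneset = list(rng.choice(universe, K, replace=False))
            interest = list(rng.choice(universe, N, replace=False))
            res = hypergeometric_enrichment(interest, geneset, universe)
            gs = set(geneset)
            count = sum(1 for draw in itertools.combinations(universe, N)
                        if len(set(draw) & gs) >= res.x)
            assert res.p == pytest.approx(count / comb(M, N), rel=1e-12)

    def test_monte_carlo_agreement_on_larger_instances(self, rng):
        n_mc = 20_000
        for _ in range(2):
            M = int(rng.integers(200, 600))
            K = int(rng.integers(20, M // 2))
            N = int(rng.integers(20, M // 2))
            bg = np.arange(M)
            geneset = rng.choice(bg, K, replace=False)
            interest = rng.choice(bg, N, replace=False)
            res = hypergeometric_enrichment(
                [str(g) for g in interest], [str(g) for g in geneset],
                [str(g) for g in bg])
            gs = set(geneset)
            hits = np.array([
                len(set(rng.choice(bg, N, replace=False)) & gs) >= res.x
                for _ in range(n_mc)])
            p_mc = hits.mean()
            se = np.sqrt(max(res.p * (1 - res.p), 1e-12) / n_mc)
            assert abs(p_mc - res.p) <= 3 * se + 1e-9

    def test_p_monotone_nonincreasing_in_overlap(self):
        M, K, N = 100, 30, 20
        ps = [float(stats.hypergeom.sf(x - 1, M, K, N))
              for x in range(0, min(K, N) + 1)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_uniform_geneset_ratio_expectation_one(self, annotation_sim):
        cfg, _ = annotation_sim
        rng = np.random.default_rng(12)
        bg = [f"g{i}" for i in range(400)]
        interest = list(rng.choice(bg, 80, replace=False))
        ratios = []
        for _ in range(1000):
            gs = rng.choice(bg, 40, replace=False)
            ratios.append(hypergeometric_enrichment(interest, gs, bg)
                          .enrichment_ratio)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.02)

    def test_empty_sets_degenerate(self):
        bg = ["a", "b", "c"]
        res = hypergeometric_enrichment([], ["a"], bg)
        assert res.p == 1.0 and np.isnan(res.enrichment_ratio)


class TestOddsRatio:
    def test_equal_proportions_or_one(self):
        assert proportion_odds_ratio(0.3, 0.3)["odds_ratio"] == \
            pytest.approx(1.0)

    def test_printed_proportions(self):
        out = proportion_odds_ratio(0.201, 0.083)
        assert out["odds_ratio"] == pytest.approx(2.78, abs=0.01)
        assert out["p"] is None

    def test_counts_against_enumeration_oracle(self):
        from math import comb
        out = proportion_odds_ratio(counts=(3, 10, 1, 10))
        assert out["odds_ratio"] == pytest.approx((3 / 7) / (1 / 9))
        # Fisher p by enumerating all tables with fixed margins
        x1, n1, x2, n2 = 3, 10, 1, 10
        row = x1 + x2
        def table_p(a):
            return (comb(n1, a) * comb(n2, row - a)) / comb(n1 + n2, row)
        p_obs = table_p(x1)
        total = sum(table_p(a) for a in range(max(0, row - n2),
                                              min(row, n1) + 1)
                    if table_p(a) <= p_obs + 1e-12)
        assert out["p"] == pytest.approx(total)

    def test_degenerate_proportion_symbolic(self):
        out = proportion_odds_ratio(1.0, 0.4)
        assert out["symbolic"] == "inf"


class TestPermutationTest:
    def test_planted_low_median_hits_floor(self):
        cfg = AnnotationConfig(score_sd=0.0, shifted_size=50,
                               score_shift=-0.3)
        t = gen_annotation_resources(cfg, seed=21)
        res = permutation_median_test(t.shifted_genes, t.score_table,
                                      n_perm=1000, seed=1, side="low")
        assert res.p == pytest.approx(1 / 1001)

    def test_seed_reproducibility(self, annotation_sim):
        _, t = annotation_sim
        r1 = permutation_median_test(t.shifted_genes, t.score_table,
                                     n_perm=1000, seed=5)
        r2 = permutation_median_test(t.shifted_genes, t.score_table,
                                     n_perm=1000, seed=5)
        assert r1.p == r2.p

    def test_whole_universe_geneset_central_p(self, annotation_sim):
        _, t = annotation_sim
        res = permutation_median_test(list(t.score_table["gene"]),
                                      t.score_table, n_perm=1000, seed=2)
        assert 0.4 <= res.p <= 1.0

    def test_p_has_support_floor(self, annotation_sim):
        _, t = annotation_sim
        res = permutation_median_test(t.shifted_genes, t.score_table,
                                      n_perm=1000, seed=3, side="high")
        assert res.p >= 1 / 1001

    def test_small_geneset_raises(self, annotation_sim):
        _, t = annotation_sim
        with pytest.raises(ValueError):
            permutation_median_test([t.score_table["gene"].iloc[0]],
                                    t.score_table, n_perm=1000, seed=0)

    def test_null_p_uniform_on_support(self):
        # under a uniformly drawn gene set the permutation p is uniform
        rng = np.random.default_rng(31)
        scores = pd.DataFrame({"gene": [f"g{i}" for i in range(200)],
                               "score": rng.normal(size=200)})
        ps = []
        for rep in range(300):
            gs = rng.choice(scores["gene"], 15, replace=False)
            res = permutation_median_test(gs, scores, n_perm=1000,
                                          seed=1000 + rep)
            ps.append(res.p)
        stat = stats.kstest(ps, "uniform")
        assert stat.pvalue > 1e-3
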