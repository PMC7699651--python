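"""Influence scores, precision-recall, overlap tests and damage analysis."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mlcascade.influence import (
    degree_bins,
    degree_matched_null_overlap,
    density_vs_rank,
    hypergeometric_overlap,
    influence_scores,
    influence_table,
    mannwhitney_less,
    pr_curve,
    second_round_counts,
    targeted_damage,
)
from mlcascade.synth import ERBenchmarkSpec, generate_er_multilayer


# ------------------------------------------------------------------- scores


class TestInfluenceScores:
    def test_t1_coupled_hand_values(self, t1):
        s = influence_scores(t1)
        assert s["g1"] == pytest.approx(0.8)
        assert s["g4"] == pytest.approx(0.6)

    def test_t1_uncoupled_hand_value(self, t1):
        s = influence_scores(t1, "uncoupled")
        assert s["g1"] == pytest.approx(0.2)

    def test_unpaired_genes_absent(self, t1):
        t1.grn.graph.add_node("g_orphan")
        s = influence_scores(t1)
        assert "g_orphan" not in s.index
        assert set(s.index) == {"g1", "g2", "g3", "g4"}

    def test_scores_within_unit_interval(self, small_er):
        table = influence_table(small_er).table
        assert ((0 <= table["influence"]) & (table["influence"] <= 1)).all()
        assert (table["influence"] + 1e-12 >= table["uncoupled"]).all()

    def test_second_round_counts(self, t1, t2):
        assert second_round_counts(t1, ["g1"])["g1"] == 0
        assert second_round_counts(t2, ["g4"])["g4"] == 2
        # g3 has no regulatory targets and its protein's removal does not
        # fragment the interactome: every failure lands in round 1
        assert second_round_counts(t1, ["g3"])["g3"] == 0


# ------------------------------------------------------------------ PR / APS


class TestPRCurve:
    def test_perfect_ranking(self):
        scores = {f"g{i}": 10 - i for i in range(10)}
        res = pr_curve(scores, {"g0", "g1", "g2"}, tie_shuffles=5, random_baselines=0)
        assert res.aps == pytest.approx(1.0)

    def test_stepwise_hand_value(self):
        scores = dict(zip("abcde", (5, 4, 3, 2, 1)))
        res = pr_curve(scores, {"a", "c"}, tie_shuffles=1, random_baselines=0)
        assert res.aps == pytest.approx((1 + 2 / 3) / 2)

    def test_all_tied_equals_random_ranking(self):
        """With every score tied, shuffle-averaged APS equals the expected
        average precision of a fully random ranking (which exceeds the raw
        base rate at finite list length -- the hit itself counts in its own
        precision), estimated here with an independent Monte-Carlo oracle."""
        n, npos = 50, 10
        scores = {f"g{i}": 1.0 for i in range(n)}
        pos = {f"g{i}" for i in range(npos)}
        res = pr_curve(scores, pos, tie_shuffles=800, random_baselines=0, seed=1)

        rng = np.random.default_rng(99)
        flags = np.zeros(n, dtype=bool)
        flags[:npos] = True
        aps = []
        for _ in range(4000):
            f = rng.permutation(flags)
            prec = np.cumsum(f) / np.arange(1, n + 1)
            aps.append(prec[f].sum() / npos)
        assert res.aps == pytest.approx(np.mean(aps), abs=0.01)
        assert res.aps > npos / n  # strictly above the base rate

    def test_inverted_ranking_worst_case(self):
        n, npos = 12, 4
        scores = {f"g{i}": i for i in range(n)}  # positives get lowest scores
        pos = {f"g{i}" for i in range(npos)}
        res = pr_curve(scores, pos, tie_shuffles=1, random_baselines=0)
        expected = sum(i / (n - npos + i) for i in range(1, npos + 1)) / npos
        assert res.aps == pytest.approx(expected)

    def test_tie_group_permutation_invariance(self):
        rng = np.random.default_rng(0)
        base = {f"g{i}": (i // 5) for i in range(30)}  # heavy ties
        pos = set(rng.choice(sorted(base), size=8, replace=False).tolist())
        a = pr_curve(base, pos, tie_shuffles=600, random_baselines=0, seed=4).aps
        shuffled = dict(base)  # same scores, different insertion order
        for k in sorted(shuffled, reverse=True):
            shuffled[k] = base[k]
        b = pr_curve(shuffled, pos, tie_shuffles=600, random_baselines=0, seed=9).aps
        assert a == pytest.approx(b, abs=0.02)

    def test_empty_positives_rejected(self):
        with pytest.raises(ValueError):
            pr_curve({"a": 1.0}, {"zz"})

    def test_random_baseline_band(self):
        scores = {f"g{i}": float(i) for i in range(40)}
        pos = {f"g{i}" for i in range(0, 40, 4)}
        res = pr_curve(scores, pos, tie_shuffles=1, random_baselines=50, seed=3)
        assert res.aps_random.shape == (50,)
        assert res.aps_random.mean() == pytest.approx(len(pos) / 40, abs=0.1)


class TestDensityVsRank:
    def test_top1_density_binary(self):
        scores = dict(zip("abcd", (4, 3, 2, 1)))
        comparator = dict(zip("abcd", (1, 2, 3, 4)))
        df = density_vs_rank(scores, {"a"}, comparator, shuffles=1)
        assert df["density_score"].iloc[0] == 1.0
        assert df["density_comparator"].iloc[0] == 0.0

    def test_five_gene_worked_case(self):
        scores = dict(zip("abcde", (5, 4, 3, 2, 1)))
        df = density_vs_rank(scores, {"a", "c"}, scores, shuffles=1)
        assert df["density_score"].iloc[1] == pytest.approx(1 / 2)

    def test_uniform_scores_approach_base_rate(self):
        scores = {f"g{i}": 0.0 for i in range(60)}
        pos = {f"g{i}" for i in range(12)}
        df = density_vs_rank(scores, pos, scores, shuffles=300, seed=5)
        assert df["density_score"].iloc[-1] == pytest.approx(0.2, abs=1e-12)
        assert df["density_score"].iloc[29] == pytest.approx(0.2, abs=0.05)


# ------------------------------------------------------- overlap significance


class TestHypergeometric:
    def test_disjoint_sets_not_significant(self):
        uni = {f"g{i}" for i in range(1000)}
        p = hypergeometric_overlap({f"g{i}" for i in range(5)},
                                   {f"g{i}" for i in range(500, 505)}, uni)
        assert p > 0.9

    def test_closed_form_value(self):
        # N=10, K=5, n=4, k=4: p = C(5,4)C(5,0)/C(10,4) = 5/210
        uni = {f"g{i}" for i in range(10)}
        top = {f"g{i}" for i in range(4)}
        query = {f"g{i}" for i in range(5)}
        assert hypergeometric_overlap(top, query, uni) == pytest.approx(5 / 210)

    def test_matches_exhaustive_enumeration(self):
        """Brute-force enumeration of all draws from a tiny universe."""
        uni = [f"g{i}" for i in range(9)]
        query = set(uni[:4])
        top = set(uni[2:6])
        k_obs = len(top & query)
        total = 0
        hits = 0
        for combo in itertools.combinations(uni, len(top)):
            total += 1
            if len(set(combo) & query) >= k_obs:
                hits += 1
        assert hypergeometric_overlap(top, query, set(uni)) == pytest.approx(hits / total)

    def test_empty_universe(self):
        with pytest.raises(ValueError):
            hypergeometric_overlap(set(), set(), set())


class TestDegreeMatchedNull:
    def test_self_set_hits_floor(self):
        degrees = {f"g{i}": i for i in range(100)}
        top = {f"g{i}" for i in range(10)}
        p, _ = degree_matched_null_overlap(top, top, degrees, n_sets=200, min_bin=100)
        # single bin of 100 distinct degrees: overlap can tie but the observed
        # full overlap is never exceeded and rarely equalled
        assert p <= 0.05

    def test_uniform_degree_matches_hypergeometric(self):
        """With a single shared degree, bin resampling is uniform resampling:
        the empirical p matches the hypergeometric tail within MC error."""
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(120)]
        degrees = {g: 3 for g in genes}
        top = set(rng.choice(genes, size=30, replace=False).tolist())
        gene_set = set(rng.choice(genes, size=15, replace=False).tolist())
        p_emp, null = degree_matched_null_overlap(
            gene_set, top, degrees, n_sets=4000, min_bin=1, seed=2
        )
        k_obs = len(top & gene_set)
        # oracle: resampling-with-possible-duplicates makes sets of size <= 15;
        # approximate with the hypergeometric tail at n=15
        p_hyp = float(stats.hypergeom.sf(k_obs - 1, 120, 30, 15))
        assert p_emp == pytest.approx(p_hyp, abs=0.05)

    def test_zero_null_sets_rejected(self):
        with pytest.raises(ValueError):
            degree_matched_null_overlap({"a"}, {"a"}, {"a": 1}, n_sets=0)

    def test_bins_hold_min_distinct_values(self):
        degrees = {f"g{i}": i % 37 for i in range(500)}
        g2b = degree_bins(degrees, min_bin=10)
        vals_per_bin = {}
        for g, b in g2b.items():
            vals_per_bin.setdefault(b, set()).add(degrees[g])
        for b, vals in vals_per_bin.items():
            assert len(vals) >= 10


# ------------------------------------------------------------- Mann-Whitney


class TestMannWhitney:
    def test_matches_exact_enumeration_small_samples(self):
        """Enumeration of the exact U null distribution for n <= 8."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            nx_, ny = rng.integers(3, 7, size=2)
            x = rng.normal(size=nx_)
            y = rng.normal(size=ny)
            p = mannwhitney_less(x, y)
            # oracle: enumerate all label assignments of the pooled sample;
            # U counts the (x > y) pairs, and "less" is its lower tail
            pooled = np.concatenate([x, y])
            u_obs = sum(1 for xi in x for yi in y if xi > yi)
            us = []
            for idx in itertools.combinations(range(nx_ + ny), nx_):
                xs = pooled[list(idx)]
                ys = np.delete(pooled, list(idx))
                us.append(sum(1 for xi in xs for yi in ys if xi > yi))
            us = np.array(us)
            expected = (us <= u_obs).mean()
            assert p == pytest.approx(expected, abs=1e-12)

    def test_identical_distributions_near_half(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        y = rng.normal(size=200)
        assert 0.1 < mannwhitney_less(x, y) < 0.95


@pytest.fixture(scope="module")
def damage_net():
    return generate_er_multilayer(
        ERBenchmarkSpec(n_g=150, n_p=150, n_m=40, c_p=6), seed=21
    )


class TestTargetedDamage:
    def test_identical_target_and_control_universe(self, damage_net):
        """When the 'disease' set is degree-generic, targeted and random
        perturbations are exchangeable and the test is not significant."""
        rng = np.random.default_rng(4)
        genes = set(rng.choice(sorted(damage_net.grn.nodes), size=25, replace=False).tolist())
        summary, dists = targeted_damage(
            damage_net, genes, ps_grid=[0.5], f_p2m_grid=[1.0], reps=80, seed=5, min_bin=100
        )
        assert summary["p_value"].iloc[0] > 0.01
        assert set(dists) == {(0.5, 1.0)}

    def test_empty_set_rejected(self, damage_net):
        with pytest.raises(ValueError):
            targeted_damage(damage_net, [], [1.0], [1.0], reps=5)
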