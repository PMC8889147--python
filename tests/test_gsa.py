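"""Directional gene-set analysis: statistics, permutation nulls, five
directionality classes, consensus ranking, and the exhaustive-enumeration
oracle for the mean statistic on tiny universes."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sigrepo.gsa import (
    ALL_METHODS,
    CLASSES,
    DirectionalGSA,
    classify_directionality,
    consensus_rank,
    permutation_class_p,
    set_statistic,
    significant_pathways,
)
from sigrepo.datatypes import GeneSetCollection


def _table(t_values, df=10.0):
    """Gene-stat table with given moderated t values; p from t(df)."""
    t = np.asarray(t_values, dtype=float)
    p = 2 * stats.t.sf(np.abs(t), df)
    return pd.DataFrame({"t_mod": t, "p": p},
                        index=[f"g{i}" for i in range(t.size)])


class TestSetStatistic:
    def test_mean_of_constant_t(self):
        tab = _table([2.0, 2.0, 2.0, 0.0])
        assert set_statistic(tab, ["g0", "g1", "g2"], "mean") == pytest.approx(2.0)

    def test_fisher_hand_value_and_chi_square_reference(self):
        tab = _table([1.0, 1.0])
        tab["p"] = [0.01, 0.04]
        stat = set_statistic(tab, ["g0", "g1"], "fisher")
        assert stat == pytest.approx(-2 * (np.log(0.01) + np.log(0.04)), abs=1e-3)
        assert stat == pytest.approx(15.648, abs=0.01)
        assert stats.chi2.sf(stat, 4) == pytest.approx(0.0035, abs=0.0005)

    def test_stouffer_at_half_is_zero(self):
        tab = _table([0.5, -0.5, 3.0])
        tab["p"] = [0.5, 0.5, 0.01]
        assert set_statistic(tab, ["g0", "g1"], "stouffer") == pytest.approx(0.0, abs=1e-12)

    def test_unknown_method_lists_valid_names(self):
        with pytest.raises(ValueError, match="mean"):
            set_statistic(_table([1.0]), ["g0"], "bogus")

    def test_unresolvable_member_raises(self):
        with pytest.raises(KeyError, match="missing"):
            set_statistic(_table([1.0]), ["nope"], "mean")


class TestPermutationClassP:
    def test_planted_all_up_set_floors_distinct_up(self):
        rng = np.random.default_rng(0)
        t = rng.normal(0, 1, 200)
        t[:8] = rng.uniform(3.5, 5.0, 8)  # extreme all-up set
        tab = _table(t)
        res = permutation_class_p(tab, [f"g{i}" for i in range(8)], B=999, seed=1,
                                  set_name="planted")
        assert np.allclose(res["distinct up"].to_numpy(), 1 / 1000)
        assert (res["distinct down"] > 0.5).all()

    def test_balanced_set_is_non_directional(self):
        rng = np.random.default_rng(1)
        t = rng.normal(0, 1, 300)
        t[:4] = 5.0
        t[4:8] = -5.0
        tab = _table(t)
        res = permutation_class_p(tab, [f"g{i}" for i in range(8)], B=9999, seed=2,
                                  set_name="balanced")
        assert (res["non-directional"] <= 0.01).all()
        assert (res.loc["mean", ["distinct up", "distinct down"]] > 0.1).all()
        assert classify_directionality(res.median(axis=0)) == "non-directional"

    def test_sign_flip_swaps_directional_p_exactly(self):
        rng = np.random.default_rng(3)
        t = rng.normal(0.3, 1.2, 120)
        tab = _table(t)
        members = [f"g{i}" for i in rng.choice(120, 15, replace=False)]
        res = permutation_class_p(tab, members, B=499, seed=5, set_name="s")
        flipped = tab.copy()
        flipped["t_mod"] = -flipped["t_mod"]
        res_f = permutation_class_p(flipped, members, B=499, seed=5, set_name="s")
        for m in ALL_METHODS:
            assert res.loc[m, "distinct up"] == res_f.loc[m, "distinct down"]
            assert res.loc[m, "distinct down"] == res_f.loc[m, "distinct up"]
            assert res.loc[m, "mixed up"] == res_f.loc[m, "mixed down"]
            assert res.loc[m, "mixed down"] == res_f.loc[m, "mixed up"]
            assert res.loc[m, "non-directional"] == res_f.loc[m, "non-directional"]

    def test_p_floor_and_range(self):
        tab = _table(np.linspace(-2, 2, 50))
        res = permutation_class_p(tab, [f"g{i}" for i in range(45, 50)], B=199,
                                  seed=0, set_name="x")
        assert (res.to_numpy() >= 1 / 200).all()
        assert (res.to_numpy() <= 1.0).all()

    def test_unstable_b_rejected(self):
        tab = _table(np.ones(30))
        with pytest.raises(ValueError, match="B"):
            permutation_class_p(tab, ["g0"], B=10)

    def test_exhaustive_mean_matches_brute_force(self):
        # tiny universe: enumerate every k-subset by hand and compare
        rng = np.random.default_rng(7)
        t = rng.normal(0, 1, 11)
        tab = _table(t)
        members = ["g0", "g3", "g7"]
        res = permutation_class_p(tab, members, B=999, seed=0, methods=("mean",),
                                  exhaustive=True, set_name="tiny")
        obs = t[[0, 3, 7]].mean()
        null = np.array([t[list(c)].mean() for c in combinations(range(11), 3)])
        assert res.loc["mean", "distinct up"] == pytest.approx(np.mean(null >= obs))
        assert res.loc["mean", "distinct down"] == pytest.approx(np.mean(null <= obs))
        null_abs = np.array([np.abs(t)[list(c)].mean() for c in combinations(range(11), 3)])
        assert res.loc["mean", "non-directional"] == pytest.approx(
            np.mean(null_abs >= np.abs(t)[[0, 3, 7]].mean()))


class TestClassification:
    def test_argmin_rule(self):
        p = pd.Series([0.001, 0.2, 0.3, 0.9, 0.9], index=list(CLASSES))
        assert classify_directionality(p) == "distinct up"

    def test_all_equal_is_non_directional(self):
        p = pd.Series(0.25, index=list(CLASSES))
        assert classify_directionality(p) == "non-directional"

    def test_one_sided_floor_tie_resolves_to_distinct(self):
        p = pd.Series([0.001, 0.001, 0.001, 0.9, 1.0], index=list(CLASSES))
        assert classify_directionality(p) == "distinct up"

    def test_bidirectional_floor_tie_resolves_to_non_directional(self):
        p = pd.Series([0.9, 0.001, 0.001, 0.001, 0.9], index=list(CLASSES))
        assert classify_directionality(p) == "non-directional"


class TestConsensus:
    def _frames(self, p_values_per_method):
        # one set per entry; build method x class frames for two sets
        return p_values_per_method

    def test_single_method_rank_is_method_rank(self):
        f = {
            "A": pd.DataFrame({c: [0.01] for c in CLASSES}, index=["mean"]),
            "B": pd.DataFrame({c: [0.50] for c in CLASSES}, index=["mean"]),
        }
        cons_p, cons_r = consensus_rank(f)
        assert cons_r.loc["A", "distinct up"] == 1.0
        assert cons_r.loc["B", "distinct up"] == 2.0
        assert cons_p.loc["A", "distinct up"] == 0.01

    def test_median_rank_across_three_methods(self):
        methods = ["mean", "median", "sum"]
        # set A ranked 1,2,3 across methods -> consensus rank 2
        pa = {"mean": 0.01, "median": 0.05, "sum": 0.2}
        pb = {"mean": 0.02, "median": 0.01, "sum": 0.1}
        pc = {"mean": 0.03, "median": 0.1, "sum": 0.01}
        f = {name: pd.DataFrame({c: [p[m] for m in methods] for c in CLASSES},
                                index=methods)
             for name, p in (("A", pa), ("B", pb), ("C", pc))}
        _, cons_r = consensus_rank(f)
        assert cons_r.loc["A", "distinct up"] == 2.0

    def test_unanimous_first_rank(self):
        methods = list(ALL_METHODS)
        f = {
            "A": pd.DataFrame({c: [0.001] * 9 for c in CLASSES}, index=methods),
            "B": pd.DataFrame({c: [0.5] * 9 for c in CLASSES}, index=methods),
        }
        _, cons_r = consensus_rank(f)
        assert cons_r.loc["A", "distinct up"] == 1.0


class TestSignificantPathways:
    def test_alpha_zero_selects_nothing(self):
        cons = pd.DataFrame(0.001, index=["A", "B"], columns=list(CLASSES))
        assert significant_pathways(cons, alpha=0.0).empty

    def test_null_collection_selects_at_most_alpha(self, gene_stats):
        rng = np.random.default_rng(11)
        genes = list(gene_stats.index[500:])  # avoid planted genes
        sets = {f"S{i}": list(rng.choice(genes, 20, replace=False)) for i in range(25)}
        col = GeneSetCollection(sets=sets)
        est = DirectionalGSA(B=199, seed=3).fit(gene_stats, col)
        assert len(est.significant_) / len(col) <= 0.05 + 0.1


class TestDirectionalGSA:
    def test_whole_universe_set_skipped_with_warning(self, gene_stats):
        col = GeneSetCollection(sets={"ALL": list(gene_stats.index)})
        with pytest.warns(UserWarning, match="skipping"):
            est = DirectionalGSA(B=99, seed=0).fit(gene_stats, col)
        assert est.skipped_ and est.consensus_p_.empty

    def test_unknown_method_rejected(self, gene_stats):
        col = GeneSetCollection(sets={"S": list(gene_stats.index[:10])})
        with pytest.raises(ValueError, match="unknown methods"):
            DirectionalGSA(methods=("mean", "bogus")).fit(gene_stats, col)

    def test_planted_pathways_recovered_with_direction(self, universe, gene_stats):
        est = DirectionalGSA(B=999, seed=17).fit(gene_stats, universe["collection"])
        planted = universe["truth"].planted_pathways
        for name in planted:
            members = universe["collection"].members(name)
            effects = [universe["truth"].planted_genes.get(g, 0.0) for g in members]
            direction = "distinct up" if sum(effects) > 0 else "distinct down"
            assert est.assigned_class_[name] == direction
            assert est.consensus_p_.loc[name].min() <= 0.01
        assert set(planted) <= est.significant_sets()
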