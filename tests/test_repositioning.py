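"""Pathway-group intersection, candidate selection, toxicity exclusion,
network export, and the screening summary with its floor convention."""

import numpy as np
import pandas as pd
import pytest

from sigrepo.datatypes import CompoundKB, GeneSetCollection
from sigrepo.repositioning import (
    apply_tox_filter,
    build_pathway_groups,
    compound_pathways,
    export_network,
    screening_summary,
    select_candidates,
)


@pytest.fixture
def small_world():
    sets = GeneSetCollection(sets={
        "PW1": ["g1", "g2", "g3"],
        "PW2": ["g4", "g5"],
        "PW3": ["g6", "g7"],
    })
    kb = CompoundKB(
        targets={"drugA": ["g1"], "drugB": ["g4", "g6"], "drugC": ["g99"],
                 "stea1": ["g2"], "stea2": ["g5"]},
        tox={"drugB": True},
    )
    return sets, kb


def _screen(rows):
    return pd.DataFrame(rows, columns=["compound", "es_up", "es_down", "score",
                                       "p", "selected"])


class TestCompoundPathways:
    def test_membership_rule(self, small_world):
        sets, kb = small_world
        assert compound_pathways(kb, sets, "drugA") == {"PW1"}
        assert compound_pathways(kb, sets, "drugB") == {"PW2", "PW3"}

    def test_unresolvable_targets_drop_to_empty(self, small_world):
        sets, kb = small_world
        with pytest.warns(UserWarning, match="not in any gene set"):
            assert compound_pathways(kb, sets, "drugC") == set()

    def test_unknown_compound_rejected(self, small_world):
        sets, kb = small_world
        with pytest.raises(KeyError, match="ghost"):
            compound_pathways(kb, sets, "ghost")


class TestPathwayGroups:
    def test_intersection_is_p_target(self, small_world):
        sets, kb = small_world
        groups = build_pathway_groups([{"PW1", "PW2"}], kb, sets, ["stea1"])
        assert groups.p_stea == {"PW1"}
        assert groups.p_target == {"PW1"}

    def test_union_vs_intersection_policy(self, small_world):
        sets, kb = small_world
        clin = [{"PW1"}, {"PW2"}]
        union = build_pathway_groups(clin, kb, sets, ["stea1", "stea2"])
        inter = build_pathway_groups(clin, kb, sets, ["stea1", "stea2"],
                                     clin_policy="intersection")
        assert union.p_clin == {"PW1", "PW2"}
        assert inter.p_clin == set()

    def test_disjoint_groups_warn_empty_target(self, small_world):
        sets, kb = small_world
        with pytest.warns(UserWarning, match="no pathways-to-target"):
            groups = build_pathway_groups([{"PW3"}], kb, sets, ["stea1"])
        assert groups.p_target == set()

    def test_planted_universe_recovers_eleven(self, universe, gene_stats):
        from sigrepo.gsa import DirectionalGSA

        est = DirectionalGSA(B=499, seed=5).fit(gene_stats, universe["collection"])
        truth = universe["truth"]
        steatogens = [c for c, r in truth.compound_roles.items() if r == "mimicker"]
        groups = build_pathway_groups([est.significant_sets()], universe["kb"],
                                      universe["collection"], steatogens)
        assert groups.p_target == set(truth.planted_pathways)
        assert len(groups.p_target) == 11


class TestSelectCandidates:
    def test_selected_without_overlap_is_rejected(self, small_world):
        sets, kb = small_world
        groups = build_pathway_groups([{"PW1"}], kb, sets, ["stea1"])
        screen = _screen([("drugB", 0.5, -0.5, 0.5, 0.01, True)])
        table = select_candidates([screen], kb, sets, groups)
        assert table.loc[0, "status"] == "rejected"

    def test_candidate_requires_overlap_and_selection(self, small_world):
        sets, kb = small_world
        groups = build_pathway_groups([{"PW1"}], kb, sets, ["stea1"])
        screen = _screen([
            ("drugA", -0.6, 0.6, -0.6, 0.001, True),
            ("drugB", 0.9, -0.9, 0.9, 0.001, False),  # not selected
        ])
        table = select_candidates([screen], kb, sets, groups)
        assert list(table["compound"]) == ["drugA"]
        assert table.loc[0, "status"] == "candidate"
        assert table.loc[0, "overlap"] == "PW1"

    def test_empty_target_empties_table(self, small_world):
        sets, kb = small_world
        with pytest.warns(UserWarning):
            groups = build_pathway_groups([{"PW3"}], kb, sets, ["stea1"])
        screen = _screen([("drugA", -0.6, 0.6, -0.6, 0.001, True)])
        table = select_candidates([screen], kb, sets, groups)
        assert (table["status"] == "rejected").all()

    def test_ranking_keys(self, small_world):
        sets, kb = small_world
        kb.targets["drugD"] = ["g3"]
        groups = build_pathway_groups([{"PW1", "PW2", "PW3"}], kb, sets,
                                      ["stea1", "stea2"])
        screen = _screen([
            ("drugA", -0.4, 0.4, -0.4, 0.01, True),
            ("drugD", 0.8, -0.8, 0.8, 0.001, True),
        ])
        table = select_candidates([screen], kb, sets, groups)
        assert list(table["compound"]) == ["drugD", "drugA"]  # |score| first

    def test_p_target_invariant_to_library_growth(self, small_world):
        sets, kb = small_world
        groups1 = build_pathway_groups([{"PW1"}], kb, sets, ["stea1"])
        kb.targets["new_compound"] = ["g6"]
        groups2 = build_pathway_groups([{"PW1"}], kb, sets, ["stea1"])
        assert groups1.p_target == groups2.p_target


class TestToxFilter:
    def test_worked_example_46_minus_25(self):
        table = pd.DataFrame({
            "compound": [f"c{i}" for i in range(46)],
            "tox_flag": [i < 25 for i in range(46)],
            "status": ["candidate"] * 46,
        })
        out, n_excluded = apply_tox_filter(table)
        assert n_excluded == 25
        assert (out["status"] == "candidate").sum() == 21
        assert (out["status"] == "excluded-tox").sum() == 25

    def test_no_flags_all_retained(self):
        table = pd.DataFrame({"compound": ["a", "b"], "tox_flag": [False, False],
                              "status": ["candidate"] * 2})
        out, n = apply_tox_filter(table)
        assert n == 0 and (out["status"] == "candidate").all()

    def test_all_flagged_warns(self):
        table = pd.DataFrame({"compound": ["a"], "tox_flag": [True],
                              "status": ["candidate"]})
        with pytest.warns(UserWarning, match="every candidate"):
            out, n = apply_tox_filter(table)
        assert n == 1 and (out["status"] == "excluded-tox").all()


class TestNetworkExport:
    def test_minimal_network_counts(self, small_world):
        sets, kb = small_world
        groups = build_pathway_groups([{"PW1"}], kb, sets, ["stea1"])
        table = pd.DataFrame({
            "compound": ["drugA"], "score": [-0.6], "sign": [-1], "p": [0.001],
            "overlap": ["PW1"], "n_overlap": [1], "tox_flag": [False],
            "status": ["candidate"],
        })
        net = export_network(table, kb, sets, groups)
        # 1 compound + 1 gene + 1 pathway; compound->gene and gene->pathway
        assert len(net["nodes"]) == 3
        assert len(net["edges"]) == 2

    def test_empty_candidates_keep_target_pathways(self, small_world):
        sets, kb = small_world
        groups = build_pathway_groups([{"PW1"}], kb, sets, ["stea1"])
        empty = pd.DataFrame(columns=["compound", "score", "sign", "p", "overlap",
                                      "n_overlap", "tox_flag", "status"])
        net = export_network(empty, kb, sets, groups)
        assert [n["type"] for n in net["nodes"]] == ["pathway"]
        assert net["edges"] == []

    def test_candidates_reachable_from_target_pathways(self, tmp_path, small_world):
        sets, kb = small_world
        groups = build_pathway_groups([{"PW1", "PW2", "PW3"}], kb, sets,
                                      ["stea1", "stea2"])
        screen = _screen([("drugA", -0.6, 0.6, -0.6, 0.001, True),
                          ("drugB", 0.7, -0.7, 0.7, 0.001, True)])
        table = select_candidates([screen], kb, sets, groups)
        net = export_network(table, kb, sets, groups,
                             path_json=tmp_path / "n.json", path_sif=tmp_path / "n.sif")
        compounds = {n["id"] for n in net["nodes"] if n["type"] == "compound"}
        reachable = set()
        for e1 in net["edges"]:
            if e1["type"] == "member-of":
                for e2 in net["edges"]:
                    if e2["type"] == "targets" and e2["target"] == e1["source"]:
                        reachable.add(e2["source"])
        assert compounds == reachable
        assert (tmp_path / "n.json").exists() and (tmp_path / "n.sif").exists()


class TestScreeningSummary:
    def test_worked_example_hit_rate(self):
        outcomes = {f"c{i}": "positive" for i in range(6)}
        outcomes.update({f"n{i}": "negative" for i in range(12)})
        outcomes.update({f"a{i}": "aggravating" for i in range(3)})
        s = screening_summary(outcomes)
        assert s["n_screened"] == 21
        assert s["positive"] == 6
        assert s["hit_rate_percent"] == 28.5  # floored, not rounded (28.57)

    @pytest.mark.parametrize("n_pos,n_tot,expected", [(0, 10, 0.0), (10, 10, 100.0)])
    def test_rate_extremes(self, n_pos, n_tot, expected):
        outcomes = {f"p{i}": "positive" for i in range(n_pos)}
        outcomes.update({f"n{i}": "negative" for i in range(n_tot - n_pos)})
        assert screening_summary(outcomes)["hit_rate_percent"] == expected

    def test_zero_screened_rejected(self):
        with pytest.raises(ValueError, match="no screened"):
            screening_summary({})

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="unknown outcome"):
            screening_summary({"c": "meh"})
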