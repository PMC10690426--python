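"""RED normalisation, clade evaluation, synonym calling, proposal ranking."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from taxogen import (
    OGRIMatrix,
    TaxonTree,
    call_synonyms,
    default_red_interval,
    evaluate_clades,
    proposal_report,
    red_values,
)
from taxogen.signature import PhylogroupAssignment

from conftest import random_binary_tree


def red_by_label(tree: TaxonTree) -> dict:
    reds = red_values(tree)
    out = {}
    for node, v in reds.items():
        key = node.taxon.label if node.is_leaf() else (node.label or "root")
        out.setdefault(key, []).append(v)
    return out


def sym_matrix(values: dict, genomes: list[str], kind="AAI") -> OGRIMatrix:
    df = pd.DataFrame(np.nan, index=genomes, columns=genomes, dtype=float)
    np.fill_diagonal(df.values, 100.0)
    for (a, b), v in values.items():
        df.loc[a, b] = df.loc[b, a] = v
    return OGRIMatrix(kind=kind, df=df)


class TestRed:
    def test_two_leaf_tree(self):
        tree = TaxonTree.from_newick("(A:1,B:2);")
        reds = red_values(tree)
        assert reds[tree.tree.seed_node] == 0.0
        for leaf in ("A", "B"):
            assert reds[tree.leaf(leaf)] == 1.0

    def test_three_leaf_hand_value(self):
        tree = TaxonTree.from_newick("((A:1,B:1)n1:1,C:2);")
        reds = red_values(tree)
        internal = tree.mrca(["A", "B"])
        # p=0, d=1, u = 1 + mean(1,1) = 2 -> RED = 0 + (1/2)(1-0) = 0.5
        assert reds[internal] == pytest.approx(0.5)

    def test_ultrametric_symmetry(self):
        nw = "(((a:1,b:1):1,(c:1,d:1):1):1,((e:1,f:1):1,(g:1,h:1):1):1);"
        tree = TaxonTree.from_newick(nw)
        reds = red_values(tree)
        by_depth = {}
        for node, v in reds.items():
            by_depth.setdefault(tree.node_depth(node), set()).add(round(v, 12))
        for depth, vals in by_depth.items():
            assert len(vals) == 1, f"depth {depth} has distinct REDs {vals}"

    def test_scaling_invariance(self):
        rng = np.random.default_rng(3)
        nw = random_binary_tree(10, rng)
        t1 = TaxonTree.from_newick(nw)
        t2 = TaxonTree.from_newick(nw)
        for e in t2.tree.preorder_edge_iter():
            if e.length is not None:
                e.length *= 7.3
        r1 = sorted(red_values(t1).values())
        r2 = sorted(red_values(t2).values())
        assert np.allclose(r1, r2)

    def test_monotone_along_paths(self):
        rng = np.random.default_rng(4)
        tree = TaxonTree.from_newick(random_binary_tree(14, rng))
        reds = red_values(tree)
        for node in tree.tree.preorder_node_iter():
            if node.parent_node is not None:
                assert reds[node] >= reds[node.parent_node] - 1e-12

    def test_zero_length_terminal_branch_rejected(self):
        tree = TaxonTree.from_newick("((A:0.0,B:1):1,C:2);")
        with pytest.raises(ValueError, match="terminal"):
            red_values(tree)

    def test_default_interval_is_median_centred(self):
        lo, hi = default_red_interval([0.3, 0.5, 0.9])
        assert (lo, hi) == (0.4, 0.6)


class TestEvaluateClades:
    def _setup(self):
        tree = TaxonTree.from_newick(
            "((g1:1,g2:1)100:1,(g3:1,g4:1)95:1);"
        )
        assignment = PhylogroupAssignment(
            representatives={"A": "g1", "B": "g3"},
            assignment={"g1": "A", "g2": "A", "g3": "B", "g4": "B"},
        )
        return tree, assignment

    def test_hand_matrix_matches_enumeration(self):
        tree, assignment = self._setup()
        genomes = ["g1", "g2", "g3", "g4"]
        vals = {
            ("g1", "g2"): 92.0, ("g3", "g4"): 88.0,
            ("g1", "g3"): 70.0, ("g1", "g4"): 71.0,
            ("g2", "g3"): 75.0, ("g2", "g4"): 73.0,
        }
        m = sym_matrix(vals, genomes)
        ev = evaluate_clades(tree, assignment, [m])
        # brute force over the explicit pair lists
        a = ev.clades["A"].stats["AAI"]
        assert a.min_intra == 92.0
        assert a.max_inter == max(70, 71, 75, 73)
        assert a.overlap_count == 0
        b = ev.clades["B"].stats["AAI"]
        assert b.min_intra == 88.0
        assert b.overlap_count == 0
        assert ev.global_min_intra["AAI"] == 88.0

    def test_overlap_counted_when_inter_reaches_min_intra(self):
        tree, assignment = self._setup()
        genomes = ["g1", "g2", "g3", "g4"]
        vals = {
            ("g1", "g2"): 80.0, ("g3", "g4"): 90.0,
            ("g1", "g3"): 85.0, ("g1", "g4"): 60.0,
            ("g2", "g3"): 60.0, ("g2", "g4"): 60.0,
        }
        ev = evaluate_clades(tree, assignment, [sym_matrix(vals, genomes)])
        assert ev.clades["A"].stats["AAI"].overlap_count == 1  # 85 >= 80
        assert ev.clades["B"].stats["AAI"].overlap_count == 0  # 85 < 90

    def test_non_contiguous_clade_not_monophyletic(self):
        tree = TaxonTree.from_newick("((g1:1,g3:1)100:1,(g2:1,g4:1)100:1);")
        assignment = PhylogroupAssignment(
            representatives={"A": "g1", "B": "g3"},
            assignment={"g1": "A", "g2": "A", "g3": "B", "g4": "B"},
        )
        ev = evaluate_clades(tree, assignment, [])
        assert not ev.clades["A"].monophyletic

    def test_support_and_red_reported(self):
        tree, assignment = self._setup()
        ev = evaluate_clades(
            tree, assignment, [], red_interval=(0.0, 0.4)
        )
        assert ev.clades["A"].support == 100.0
        assert ev.clades["B"].support == 95.0
        assert ev.clades["A"].red == pytest.approx(0.5)
        assert ev.clades["A"].red_in_interval is False

    def test_singleton_clade_stats_undefined(self):
        tree = TaxonTree.from_newick("((g1:1,g2:1)100:1,g3:2);")
        assignment = PhylogroupAssignment(
            representatives={"A": "g1", "B": "g3"},
            assignment={"g1": "A", "g2": "A", "g3": "B"},
        )
        m = sym_matrix(
            {("g1", "g2"): 90.0, ("g1", "g3"): 70.0, ("g2", "g3"): 70.0},
            ["g1", "g2", "g3"],
        )
        ev = evaluate_clades(tree, assignment, [m])
        st_b = ev.clades["B"].stats["AAI"]
        assert st_b.min_intra is None
        assert st_b.overlap_count is None
        assert st_b.max_inter == 70.0


class TestCallSynonyms:
    def _matrices(self, genomes, ani_vals, dddh_vals):
        ani_df = pd.DataFrame(np.nan, index=genomes, columns=genomes)
        np.fill_diagonal(ani_df.values, 100.0)
        for (a, b), (v1, v2) in ani_vals.items():
            ani_df.loc[a, b], ani_df.loc[b, a] = v1, v2
        ddf = pd.DataFrame(np.nan, index=genomes, columns=genomes)
        np.fill_diagonal(ddf.values, 100.0)
        for (a, b), v in dddh_vals.items():
            ddf.loc[a, b] = ddf.loc[b, a] = v
        return (
            OGRIMatrix(kind="ANI", df=ani_df, directional=True),
            OGRIMatrix(kind="dDDH", df=ddf),
        )

    def test_conjunction_required(self):
        ani, dddh = self._matrices(
            ["a", "b"], {("a", "b"): (97.0, 97.0)}, {("a", "b"): 60.0}
        )
        call = call_synonyms(ani, dddh)
        assert call.synonym_sets == []

    def test_both_ani_directions_required(self):
        ani, dddh = self._matrices(
            ["a", "b"], {("a", "b"): (97.0, 95.0)}, {("a", "b"): 80.0}
        )
        call = call_synonyms(ani, dddh)
        assert call.synonym_sets == []

    def test_chain_forms_triple_via_components(self):
        genomes = ["a", "b", "c"]
        ani, dddh = self._matrices(
            genomes,
            {("a", "b"): (97.0, 97.5), ("b", "c"): (96.5, 96.2)},
            {("a", "b"): 75.0, ("b", "c"): 71.0},
        )
        with pytest.warns(UserWarning, match="missing"):
            call = call_synonyms(ani, dddh)
        assert call.synonym_sets == [{"a", "b", "c"}]

    def test_order_invariance(self):
        genomes = ["a", "b", "c", "d"]
        ani_vals = {("a", "b"): (98.0, 98.0), ("c", "d"): (97.0, 97.0)}
        dddh_vals = {("a", "b"): 80.0, ("c", "d"): 75.0,
                     ("a", "c"): 20.0, ("a", "d"): 20.0,
                     ("b", "c"): 20.0, ("b", "d"): 20.0}
        ani_full = {}
        for (a, b), v in ani_vals.items():
            ani_full[(a, b)] = v
        for pair in itertools.combinations(genomes, 2):
            ani_full.setdefault(pair, (80.0, 80.0))
        ani, dddh = self._matrices(genomes, ani_full, dddh_vals)
        call1 = call_synonyms(ani, dddh)
        rev = genomes[::-1]
        ani_r = OGRIMatrix(kind="ANI", df=ani.df.loc[rev, rev], directional=True)
        dddh_r = OGRIMatrix(kind="dDDH", df=dddh.df.loc[rev, rev])
        call2 = call_synonyms(ani_r, dddh_r)
        assert sorted(map(sorted, call1.synonym_sets)) == sorted(
            map(sorted, call2.synonym_sets)
        )

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        seed=st.integers(min_value=0, max_value=5000),
        ani_min=st.floats(min_value=90, max_value=99),
        dddh_min=st.floats(min_value=50, max_value=90),
    )
    def test_lowering_thresholds_never_removes_edges(self, seed, ani_min, dddh_min):
        rng = np.random.default_rng(seed)
        genomes = [f"g{i}" for i in range(5)]
        ani_df = pd.DataFrame(
            rng.uniform(85, 100, (5, 5)), index=genomes, columns=genomes
        )
        dddh_df = pd.DataFrame(
            rng.uniform(40, 100, (5, 5)), index=genomes, columns=genomes
        )
        dddh_df = (dddh_df + dddh_df.T) / 2
        np.fill_diagonal(ani_df.values, 100.0)
        np.fill_diagonal(dddh_df.values, 100.0)
        ani = OGRIMatrix(kind="ANI", df=ani_df, directional=True)
        dddh = OGRIMatrix(kind="dDDH", df=dddh_df)
        strict = call_synonyms(ani, dddh, ani_min=ani_min, dddh_min=dddh_min)
        loose = call_synonyms(
            ani, dddh, ani_min=ani_min - 2, dddh_min=dddh_min - 5
        )
        strict_pairs = {(a, b) for a, b, *_ in strict.pairs}
        loose_pairs = {(a, b) for a, b, *_ in loose.pairs}
        assert strict_pairs <= loose_pairs


class TestProposalReport:
    def _evaluation(self, tree_nw, proposal):
        tree = TaxonTree.from_newick(tree_nw)
        reps = {label: sorted(m)[0] for label, m in proposal.items()}
        assignment = PhylogroupAssignment(
            representatives=reps,
            assignment={
                g: label for label, ms in proposal.items() for g in ms
            },
        )
        return evaluate_clades(tree, assignment, [])

    def test_merging_jointly_supported_clades_ranks_first(self):
        nw = "(((a1:1,a2:1)100:1,(b1:1,b2:1)100:1)100:1,(c1:1,c2:1)100:1);"
        proposals = {
            "split": {"A": {"a1", "a2"}, "B": {"b1", "b2"}, "C": {"c1", "c2"}},
            "mergeAB": {"AB": {"a1", "a2", "b1", "b2"}, "C": {"c1", "c2"}},
            "mergeAll": {"ABC": {"a1", "a2", "b1", "b2", "c1", "c2"}},
        }
        evaluations = {p: self._evaluation(nw, prop)
                       for p, prop in proposals.items()}
        # planted content: joint signature for A+B, private ones for C only
        signature_counts = {
            "split": {"A": 0, "B": 0, "C": 4},
            "mergeAB": {"AB": 1, "C": 4},
            "mergeAll": {"ABC": 0},
        }
        # mergeAll's single clade covers the whole tree -> not comparable as
        # a genus proposal, but the report must still rank deterministically
        report = proposal_report(proposals, evaluations, signature_counts)
        assert report[0]["proposal"] == "mergeAB"
        assert report[0]["rank"] == 1
        split_row = next(r for r in report if r["proposal"] == "split")
        assert split_row["multi_species_clades_without_signatures"] == ["A", "B"]

    def test_non_monophyletic_proposal_fails_despite_signatures(self):
        nw = "((a1:1,b1:1)100:1,(a2:1,b2:1)100:1);"
        proposal = {"A": {"a1", "a2"}, "B": {"b1", "b2"}}
        ev = self._evaluation(nw, proposal)
        report = proposal_report(
            {"p": proposal}, {"p": ev}, {"p": {"A": 10, "B": 10}}
        )
        assert report[0]["constraint_failures"]

    def test_identical_proposals_tie(self):
        nw = "((a1:1,a2:1)100:1,(b1:1,b2:1)100:1);"
        proposal = {"A": {"a1", "a2"}, "B": {"b1", "b2"}}
        ev1 = self._evaluation(nw, proposal)
        ev2 = self._evaluation(nw, proposal)
        counts = {"A": 2, "B": 2}
        report = proposal_report(
            {"p1": proposal, "p2": proposal},
            {"p1": ev1, "p2": ev2},
            {"p1": counts, "p2": counts},
        )
        assert report[0]["rank"] == report[1]["rank"] == 1
        assert all(r["tied"] for r in report)
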