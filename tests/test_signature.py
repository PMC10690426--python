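"""Signature genes, MRCA phylogroup assignment, pattern tables."""

import numpy as np
import pandas as pd
import pytest

from taxogen import (
    PangenomeMatrix,
    TaxonTree,
    assign_phylogroups,
    build_pattern_table,
    count_signatures_per_proposal,
    find_signature_genes,
)
from taxogen.signature import InvalidCladeError, MrcaTieError

from conftest import random_binary_tree


def toy_matrix(rows: dict[str, list[int]], genomes: list[str]) -> PangenomeMatrix:
    df = pd.DataFrame.from_dict(rows, orient="index", dtype=int)
    df.columns = genomes
    return PangenomeMatrix(df=df)


class TestAssignPhylogroups:
    def test_representative_assigned_to_itself(self):
        tree = TaxonTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        out = assign_phylogroups(tree, {"P1": "A", "P2": "C"})
        assert out.assignment["A"] == "P1"
        assert out.assignment["C"] == "P2"

    def test_root_split(self):
        tree = TaxonTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        out = assign_phylogroups(tree, {"P1": "A", "P2": "C"})
        assert out.assignment == {"A": "P1", "B": "P1", "C": "P2", "D": "P2"}

    def test_representative_not_in_tree_fatal(self):
        tree = TaxonTree.from_newick("((A:1,B:1):1,C:1);")
        with pytest.raises(ValueError, match="not a tree leaf"):
            assign_phylogroups(tree, {"P1": "Z"})

    def test_tie_raises_naming_the_leaf(self):
        # C's MRCA with both representatives is the root (depth 0)
        tree = TaxonTree.from_newick("((A:1,B:1):1,C:1);")
        with pytest.raises(MrcaTieError, match="C"):
            assign_phylogroups(tree, {"P1": "A", "P2": "B"})

    def test_exclusion_list_respected(self):
        tree = TaxonTree.from_newick("((A:1,B:1):1,(C:1,OUT:1):1);")
        out = assign_phylogroups(tree, {"P1": "A", "P2": "C"}, exclude={"OUT"})
        assert "OUT" not in out.assignment

    def test_matches_exhaustive_oracle_on_random_trees(self):
        rng = np.random.default_rng(31)
        for trial in range(20):
            tree = TaxonTree.from_newick(random_binary_tree(12, rng))
            leaves = tree.leaf_labels
            reps = {
                f"P{i}": leaf
                for i, leaf in enumerate(rng.choice(leaves, 3, replace=False))
            }
            # oracle: ancestor-set intersection, deepest shared node wins
            ancestors = {}
            for leaf in leaves:
                node = tree.leaf(leaf)
                path = []
                while node is not None:
                    path.append(id(node))
                    node = node.parent_node
                ancestors[leaf] = path  # leaf-to-root order
            depth_of = {}
            for node in tree.tree.preorder_node_iter():
                depth_of[id(node)] = tree.node_depth(node)
            try:
                got = assign_phylogroups(tree, reps).assignment
            except MrcaTieError:
                continue  # oracle would tie too; nothing to compare
            for leaf in leaves:
                best_label, best_depth = None, -1
                for label, rep in reps.items():
                    if leaf == rep:
                        shared = depth_of[ancestors[leaf][0]]
                    else:
                        shared = max(
                            depth_of[a]
                            for a in ancestors[leaf]
                            if a in set(ancestors[rep])
                        )
                    if shared > best_depth:
                        best_label, best_depth = label, shared
                assert got[leaf] == best_label, f"trial {trial} leaf {leaf}"


class TestFindSignatureGenes:
    def test_planted_signatures_recovered_exactly(
        self, pangenome_products, default_dataset
    ):
        _genomes, truth = default_dataset
        _g, families, matrix, _core = pangenome_products
        for clade, members in truth.clades().items():
            found = find_signature_genes(matrix, members)
            found_planted = {
                truth.gene_map[min(families.families[f])] for f in found
            }
            assert found_planted == truth.signature_families[clade]

    def test_outsider_presence_excludes(self):
        m = toy_matrix({"F0": [1, 1, 1, 0], "F1": [1, 1, 0, 0]},
                       ["a", "b", "c", "d"])
        assert find_signature_genes(m, {"a", "b"}) == ["F1"]

    def test_missing_member_excludes(self):
        m = toy_matrix({"F0": [1, 0, 0, 0]}, ["a", "b", "c", "d"])
        assert find_signature_genes(m, {"a", "b"}) == []

    def test_invalid_clades_rejected(self):
        m = toy_matrix({"F0": [1, 1]}, ["a", "b"])
        with pytest.raises(InvalidCladeError):
            find_signature_genes(m, set())
        with pytest.raises(InvalidCladeError):
            find_signature_genes(m, {"a", "b"})

    def test_invariant_to_row_and_column_order(self):
        m1 = toy_matrix(
            {"F0": [1, 1, 0, 0], "F1": [0, 0, 1, 1]}, ["a", "b", "c", "d"]
        )
        m2 = PangenomeMatrix(
            df=m1.df.loc[["F1", "F0"], ["d", "c", "b", "a"]]
        )
        assert find_signature_genes(m1, {"a", "b"}) == find_signature_genes(
            m2, {"a", "b"}
        )

    def test_nested_clades_have_disjoint_signatures(
        self, pangenome_products, default_dataset
    ):
        _genomes, truth = default_dataset
        _g, _families, matrix, _core = pangenome_products
        clades = truth.clades()
        inner = set(sorted(clades["C1"])[:2])
        outer = clades["C1"]
        s_inner = set(find_signature_genes(matrix, inner))
        s_outer = set(find_signature_genes(matrix, outer))
        assert not (s_inner & s_outer)


class TestPatternTable:
    def test_trivial_patterns_give_empty_table(self):
        m = toy_matrix(
            {"F0": [1, 1, 1], "F1": [1, 1, 1], "F2": [1, 0, 0]},
            ["a", "b", "c"],
        )
        table = build_pattern_table(m)
        assert table.table.empty

    def test_hand_counted_toy(self):
        genomes = ["a", "b", "c", "d"]
        m = toy_matrix(
            {
                "F0": [1, 1, 0, 0], "F1": [1, 1, 0, 0], "F2": [1, 1, 0, 0],
                "F3": [0, 0, 1, 1], "F4": [0, 0, 1, 1],
                "F5": [1, 0, 1, 0],
            },
            genomes,
        )
        table = build_pattern_table(m, clades={"AB": {"a", "b"}})
        assert list(table.table["pattern"]) == ["1100", "0011", "1010"]
        assert list(table.table["count"]) == [3, 2, 1]
        assert list(table.table["signature_of"]) == ["AB", "", ""]

    def test_counts_account_for_all_families(
        self, pangenome_products, default_dataset
    ):
        _genomes, _truth = default_dataset
        _g, _families, matrix, _core = pangenome_products
        table = build_pattern_table(matrix)
        pres = matrix.presence.sum(axis=1)
        n = len(matrix.genomes)
        n_trivial = int(((pres == n) | (pres <= 1)).sum())
        assert table.table["count"].sum() == len(matrix.df) - n_trivial

    def test_planted_signature_rows_carry_clade_label(
        self, pangenome_products, default_dataset
    ):
        _genomes, truth = default_dataset
        _g, _families, matrix, _core = pangenome_products
        table = build_pattern_table(matrix, clades=truth.clades())
        labelled = set(table.table.loc[table.table["signature_of"] != "",
                                       "signature_of"])
        assert labelled == set(truth.clades())


class TestProposalCounts:
    def test_planted_proposal_counts(self, pangenome_products, default_dataset):
        _genomes, truth = default_dataset
        _g, _families, matrix, _core = pangenome_products
        counts = count_signatures_per_proposal(matrix, truth.clades())
        assert counts == {"C1": 3, "C2": 3, "C3": 3}

    def test_merged_clade_without_joint_signature(self):
        # each sub-clade has a private signature, nothing spans both
        genomes = ["a", "b", "c", "d", "e"]
        m = toy_matrix(
            {"F0": [1, 1, 0, 0, 0], "F1": [0, 0, 1, 1, 0],
             "F2": [1, 0, 1, 0, 1]},
            genomes,
        )
        split = count_signatures_per_proposal(
            m, {"AB": {"a", "b"}, "CD": {"c", "d"}, "E": {"e"}}
        )
        assert split == {"AB": 1, "CD": 1, "E": 0}
        merged = count_signatures_per_proposal(
            m, {"ABCD": {"a", "b", "c", "d"}, "E": {"e"}}
        )
        assert merged["ABCD"] == 0

    def test_merged_clade_with_joint_signature(self):
        # one family spans exactly the merged clade, mirroring the case
        # where a fused phylogroup gains a signature its halves lack
        m = toy_matrix(
            {"F0": [1, 1, 0, 0, 0], "F1": [0, 0, 1, 1, 0],
             "F2": [1, 1, 1, 1, 0]},
            ["a", "b", "c", "d", "e"],
        )
        merged = count_signatures_per_proposal(
            m, {"ABCD": {"a", "b", "c", "d"}, "E": {"e"}}
        )
        assert merged["ABCD"] == 1

    def test_overlapping_clades_fatal(self):
        m = toy_matrix({"F0": [1, 0, 1]}, ["a", "b", "c"])
        with pytest.raises(ValueError, match="overlap"):
            count_signatures_per_proposal(
                m, {"X": {"a", "b"}, "Y": {"b", "c"}}
            )

    def test_upset_style_plot_export(self, tmp_path):
        m = toy_matrix(
            {"F0": [1, 1, 0, 0], "F1": [1, 1, 0, 0], "F2": [0, 1, 1, 0]},
            ["a", "b", "c", "d"],
        )
        from taxogen.signature import plot_pattern_table

        table = build_pattern_table(m, clades={"AB": {"a", "b"}})
        out = plot_pattern_table(table, tmp_path / "patterns.png")
        assert out.exists() and out.stat().st_size > 0

    def test_outgroup_kept_in_vectors_but_not_clades(self):
        genomes = ["a", "b", "out"]
        m = toy_matrix({"F0": [1, 1, 0], "F1": [1, 1, 1]}, genomes)
        counts = count_signatures_per_proposal(
            m, {"AB": {"a", "b"}}, exclude={"out"}
        )
        # F0 is exclusive to AB; F1 leaks into the outgroup so is excluded
        assert counts == {"AB": 1}
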