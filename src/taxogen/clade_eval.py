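"""Genus-proposal evaluation and heterotypic-synonym calling.

Three decision layers:

* relative evolutionary divergence (RED) — a [0,1] normalisation of node
  depth (root 0, extant leaves 1) used to calibrate the genus rank: an
  internal node's RED is ``p + (d/u)(1-p)`` where ``p`` is the parent's RED,
  ``d`` the branch to the parent and ``u`` the mean branch-length distance
  from the parent to the node's descendant leaves;
* clade evaluation — monophyly, bootstrap support of the clade's MRCA, RED
  against a genus interval, and the intra- vs inter-clade distributions of
  any OGRI (min intra, max inter, and the count of inter pairs reaching the
  clade's minimum intra value — a well-delimited genus shows zero overlap);
* synonym calling — two genomes are conspecific when both directional ANI
  values reach 96% and dDDH reaches 70%; synonym sets are the connected
  components of the resulting graph, so pairwise evidence chains into
  larger sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from statistics import median

import networkx as nx
import numpy as np

from .ogri import OGRIMatrix
from .signature import PhylogroupAssignment
from .tree import TaxonTree


# ---------------------------------------------------------------------------
# RED
# ---------------------------------------------------------------------------

def red_values(tree: TaxonTree) -> dict:
    """RED per node (keyed by dendropy node; leaves 1.0, root 0.0)."""
    root = tree.tree.seed_node
    # mean distance from each node to its descendant leaves
    mean_leaf_dist: dict = {}
    n_leaves: dict = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            if node.parent_node is not None and not (node.edge.length or 0) > 0:
                raise ValueError(
                    f"zero-length terminal branch at {node.taxon.label}"
                )
            mean_leaf_dist[node] = 0.0
            n_leaves[node] = 1
        else:
            tot = n = 0.0
            for child in node.child_nodes():
                n += n_leaves[child]
                tot += n_leaves[child] * (mean_leaf_dist[child] + (child.edge.length or 0.0))
            n_leaves[node] = int(n)
            mean_leaf_dist[node] = tot / n
    red: dict = {root: 0.0}
    for node in tree.tree.preorder_node_iter():
        if node is root:
            continue
        if node.is_leaf():
            red[node] = 1.0
            continue
        p = red[node.parent_node]
        d = node.edge.length or 0.0
        u = d + mean_leaf_dist[node]
        if u <= 0:
            raise ValueError("non-positive mean node-to-leaf distance")
        red[node] = min(1.0, p + (d / u) * (1.0 - p))
    return red


def default_red_interval(clade_reds, width: float = 0.1) -> tuple[float, float]:
    """Genus RED interval as the median clade RED +/- ``width``."""
    m = median(clade_reds)
    return (m - width, m + width)


# ---------------------------------------------------------------------------
# clade evaluation
# ---------------------------------------------------------------------------

@dataclass
class IndexStats:
    n_intra_pairs: int
    n_inter_pairs: int
    min_intra: float | None
    max_inter: float | None
    overlap_count: int | None  # inter pairs with value >= min_intra


@dataclass
class CladeReport:
    label: str
    members: list[str]
    monophyletic: bool
    support: float | None
    red: float
    red_in_interval: bool | None
    stats: dict[str, IndexStats] = field(default_factory=dict)


@dataclass
class CladeEvaluation:
    clades: dict[str, CladeReport]
    global_min_intra: dict[str, float | None]
    params: dict = field(default_factory=dict)


def _pair_values(matrix: OGRIMatrix, pairs) -> list[float]:
    vals = []
    for a, b in pairs:
        v = matrix.symmetric_value(a, b)
        if not np.isnan(v):
            vals.append(v)
    return vals


def evaluate_clades(
    tree: TaxonTree,
    assignment: PhylogroupAssignment,
    matrices: list[OGRIMatrix],
    support_min: float = 100.0,
    red_interval: tuple[float, float] | None = None,
    exclude: set[str] | None = None,
) -> CladeEvaluation:
    """Monophyly, support, RED and intra/inter OGRI statistics per clade.

    Directional matrices contribute the mean of their two directions per
    unordered pair; missing cells are skipped, never counted as zero.
    Single-member clades have undefined intra statistics (``None``).
    """
    exclude = set(exclude or ())
    clades = assignment.clades()
    reds = red_values(tree)
    all_assigned = sorted(set(assignment.assignment) - exclude)
    reports: dict[str, CladeReport] = {}
    for label, members_set in sorted(clades.items()):
        members = sorted(members_set - exclude)
        if not members:
            continue
        mrca = tree.mrca(members)
        desc = tree.leaves_under(mrca) - exclude
        mono = desc == set(members)
        report = CladeReport(
            label=label,
            members=members,
            monophyletic=mono,
            support=tree.support(mrca),
            red=reds[mrca],
            red_in_interval=(
                None if red_interval is None
                else red_interval[0] <= reds[mrca] <= red_interval[1]
            ),
        )
        others = [g for g in all_assigned if g not in members_set]
        intra_pairs = [
            (a, b) for i, a in enumerate(members) for b in members[i + 1 :]
        ]
        inter_pairs = [(a, b) for a in members for b in others]
        for matrix in matrices:
            intra = _pair_values(matrix, intra_pairs)
            inter = _pair_values(matrix, inter_pairs)
            if len(members) < 2 or not intra:
                stats = IndexStats(
                    n_intra_pairs=0, n_inter_pairs=len(inter),
                    min_intra=None,
                    max_inter=max(inter) if inter else None,
                    overlap_count=None,
                )
            else:
                mi = min(intra)
                stats = IndexStats(
                    n_intra_pairs=len(intra),
                    n_inter_pairs=len(inter),
                    min_intra=mi,
                    max_inter=max(inter) if inter else None,
                    overlap_count=sum(1 for v in inter if v >= mi),
                )
            report.stats[matrix.kind] = stats
        reports[label] = report
    global_min: dict[str, float | None] = {}
    for matrix in matrices:
        vals = [
            r.stats[matrix.kind].min_intra
            for r in reports.values()
            if r.stats[matrix.kind].min_intra is not None
        ]
        global_min[matrix.kind] = min(vals) if vals else None
    return CladeEvaluation(
        clades=reports,
        global_min_intra=global_min,
        params={"support_min": support_min, "red_interval": red_interval},
    )


# ---------------------------------------------------------------------------
# synonym calling
# ---------------------------------------------------------------------------

@dataclass
class SynonymCall:
    pairs: list[tuple[str, str, float, float, float]]  # a, b, ANI a->b, ANI b->a, dDDH
    synonym_sets: list[set[str]]
    params: dict = field(default_factory=dict)


def call_synonyms(
    ani: OGRIMatrix,
    dddh: OGRIMatrix,
    ani_min: float = 96.0,
    dddh_min: float = 70.0,
) -> SynonymCall:
    """Conspecificity by the 'both ANI >= 96% and dDDH >= 70%' rule.

    An edge joins two genomes when both directional ANI values and the dDDH
    value all reach their thresholds; synonym sets are connected components
    of size >= 2.  Pairs with missing values are skipped with a warning and
    never treated as passing.
    """
    genomes = ani.genomes
    if set(genomes) != set(dddh.genomes):
        raise ValueError("ANI and dDDH matrices cover different genomes")
    graph = nx.Graph()
    graph.add_nodes_from(genomes)
    passing = []
    for i, a in enumerate(genomes):
        for b in genomes[i + 1 :]:
            v_ab, v_ba = ani.value(a, b), ani.value(b, a)
            v_dd = dddh.symmetric_value(a, b)
            if np.isnan(v_ab) or np.isnan(v_ba) or np.isnan(v_dd):
                warnings.warn(f"synonym rule: missing values for ({a},{b}); skipped")
                continue
            if v_ab >= ani_min and v_ba >= ani_min and v_dd >= dddh_min:
                graph.add_edge(a, b)
                passing.append((a, b, v_ab, v_ba, v_dd))
    sets = [
        set(c) for c in nx.connected_components(graph) if len(c) >= 2
    ]
    sets.sort(key=lambda s: sorted(s)[0])
    return SynonymCall(
        pairs=passing,
        synonym_sets=sets,
        params={"ani_min": ani_min, "dddh_min": dddh_min},
    )


# ---------------------------------------------------------------------------
# proposal adjudication
# ---------------------------------------------------------------------------

def proposal_report(
    proposals: dict[str, dict[str, set[str]]],
    evaluations: dict[str, CladeEvaluation],
    signature_counts: dict[str, dict[str, int]],
) -> list[dict]:
    """Deterministic ranking of genus proposals with a justification trail.

    A proposal fails outright when any clade is non-monophyletic, falls
    below the support floor, or lies outside the RED interval (when those
    checks were computed).  Among proposals, fewer multi-species clades
    without any signature gene is better; then more clades (keeping
    well-supported sub-clades separate) is better; then more total signature
    genes.  Equal keys are reported as an explicit tie.
    """
    rows = []
    for pid in sorted(proposals):
        ev = evaluations[pid]
        sigs = signature_counts[pid]
        failures = []
        for label, rep in ev.clades.items():
            if not rep.monophyletic:
                failures.append(f"{label}: not monophyletic")
            smin = ev.params.get("support_min")
            if (
                smin is not None and rep.support is not None
                and len(rep.members) > 1 and rep.support < smin
            ):
                failures.append(f"{label}: support {rep.support:g} < {smin:g}")
            if rep.red_in_interval is False:
                failures.append(f"{label}: RED {rep.red:.3f} outside genus interval")
        multi_zero = [
            label
            for label, rep in ev.clades.items()
            if len(rep.members) > 1 and sigs.get(label, 0) == 0
        ]
        rows.append(
            {
                "proposal": pid,
                "n_clades": len(ev.clades),
                "constraint_failures": failures,
                "multi_species_clades_without_signatures": sorted(multi_zero),
                "signature_counts": dict(sigs),
                "total_signatures": sum(sigs.values()),
            }
        )

    def key(row):
        return (
            len(row["constraint_failures"]),
            len(row["multi_species_clades_without_signatures"]),
            -row["n_clades"],
            -row["total_signatures"],
        )

    rows.sort(key=lambda r: (key(r), r["proposal"]))
    rank = 0
    prev_key = None
    for i, row in enumerate(rows):
        k = key(row)
        if k != prev_key:
            rank = i + 1
            prev_key = k
        row["rank"] = rank
        row["tied"] = False
    for i, row in enumerate(rows):
        row["tied"] = any(
            other["rank"] == row["rank"] and other is not row for other in rows
        )
        reasons = []
        if row["constraint_failures"]:
            reasons.append("fails constraints: " + "; ".join(row["constraint_failures"]))
        else:
            reasons.append("all clades monophyletic, supported, within RED interval")
        if row["multi_species_clades_without_signatures"]:
            reasons.append(
                "multi-species clades without signature genes: "
                + ", ".join(row["multi_species_clades_without_signatures"])
            )
        else:
            reasons.append("every multi-species clade backed by signature genes")
        row["justification"] = "; ".join(reasons)
    return rows
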