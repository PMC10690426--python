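"""Clade-specific signature genes and MRCA-based phylogroup assignment.

A signature gene family of a clade is present (copy >= 1) in every member of
the clade and absent from every other genome in the matrix.  Phylogroups are
defined by representative species: each genome joins the phylogroup of the
representative with which it shares the most recent common ancestor, where
"most recent" is measured by node depth from the root in edge count.  Ties
are an error, never a silent choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .pangenome import PangenomeMatrix
from .tree import TaxonTree


class MrcaTieError(ValueError):
    pass


class InvalidCladeError(ValueError):
    pass


@dataclass
class PhylogroupAssignment:
    representatives: dict[str, str]     # phylogroup label -> representative genome
    assignment: dict[str, str]          # genome -> phylogroup label

    def clades(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {label: set() for label in self.representatives}
        for g, label in self.assignment.items():
            out[label].add(g)
        return out

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# genome\tphylogroup\trepresentative\n")
            for g in sorted(self.assignment):
                label = self.assignment[g]
                fh.write(f"{g}\t{label}\t{self.representatives[label]}\n")


def assign_phylogroups(
    tree: TaxonTree,
    representatives: dict[str, str],
    exclude: set[str] | None = None,
) -> PhylogroupAssignment:
    """Assign every non-excluded leaf to its deepest-MRCA representative."""
    exclude = set(exclude or ())
    leaves = set(tree.leaf_labels)
    for label, rep in representatives.items():
        if rep not in leaves:
            raise ValueError(f"representative {rep!r} ({label}) is not a tree leaf")
    assignment: dict[str, str] = {}
    rep_of = {rep: label for label, rep in representatives.items()}
    for leaf in sorted(leaves - exclude):
        if leaf in rep_of:
            assignment[leaf] = rep_of[leaf]
            continue
        depths: dict[str, int] = {}
        for label, rep in representatives.items():
            depths[label] = tree.node_depth(tree.mrca([leaf, rep]))
        best = max(depths.values())
        winners = sorted(lbl for lbl, d in depths.items() if d == best)
        if len(winners) > 1:
            raise MrcaTieError(
                f"leaf {leaf!r}: MRCA depth tie between {winners} (depth {best})"
            )
        assignment[leaf] = winners[0]
    return PhylogroupAssignment(
        representatives=dict(representatives), assignment=assignment
    )


def find_signature_genes(
    matrix: PangenomeMatrix, clade: set[str]
) -> list[str]:
    """Families whose presence vector equals the clade indicator exactly."""
    genomes = set(matrix.genomes)
    if not clade or not clade < genomes:
        raise InvalidCladeError(
            "clade must be a non-empty proper subset of the matrix genomes"
        )
    pres = matrix.presence
    indicator = pd.Series(
        [g in clade for g in matrix.genomes], index=matrix.genomes
    )
    mask = (pres == indicator).all(axis=1)
    return sorted(matrix.df.index[mask])


@dataclass
class PatternTable:
    """Presence/absence patterns ordered for UpSet-style display."""

    table: pd.DataFrame  # columns: pattern (0/1 string), count, signature_of
    genomes: list[str] = field(default_factory=list)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "# pattern (0/1 over genomes: "
                + ",".join(self.genomes)
                + ")\tn_families\tsignature_of\n"
            )
            self.table.to_csv(fh, sep="\t", index=False, header=False)


def build_pattern_table(
    matrix: PangenomeMatrix, clades: dict[str, set[str]] | None = None
) -> PatternTable:
    """Group families by presence pattern, drop trivial patterns, sort.

    Trivial patterns are the all-present (core) pattern and single-genome
    (singleton) patterns.  Rows are sorted by descending family count, ties
    by lexicographic pattern string; a row is annotated as the signature
    pattern of a clade when it equals that clade's indicator.
    """
    clades = clades or {}
    genomes = matrix.genomes
    pres = matrix.presence.astype(int)
    patterns = pres.apply(lambda row: "".join(map(str, row)), axis=1)
    counts = patterns.value_counts()
    indicator_of = {
        "".join("1" if g in members else "0" for g in genomes): label
        for label, members in clades.items()
    }
    rows = []
    for pattern, count in counts.items():
        ones = pattern.count("1")
        if ones == len(genomes) or ones <= 1:
            continue
        rows.append(
            (pattern, int(count), indicator_of.get(pattern, ""))
        )
    rows.sort(key=lambda r: (-r[1], r[0]))
    return PatternTable(
        table=pd.DataFrame(rows, columns=["pattern", "count", "signature_of"]),
        genomes=genomes,
    )


def count_signatures_per_proposal(
    matrix: PangenomeMatrix,
    proposal: dict[str, set[str]],
    exclude: set[str] | None = None,
) -> dict[str, int]:
    """Signature-gene counts per clade of a proposal (merged clades allowed).

    The proposal must partition the non-excluded genomes; outgroup genomes
    stay in the presence vectors but belong to no clade.
    """
    exclude = set(exclude or ())
    seen: set[str] = set()
    for label, members in proposal.items():
        overlap = seen & members
        if overlap:
            raise ValueError(f"clade {label} overlaps another: {sorted(overlap)}")
        seen |= members
    expected = set(matrix.genomes) - exclude
    if seen != expected:
        raise ValueError(
            "proposal does not partition the in-family genomes: "
            f"missing {sorted(expected - seen)}, extra {sorted(seen - expected)}"
        )
    return {
        label: len(find_signature_genes(matrix, members))
        for label, members in proposal.items()
    }


def plot_pattern_table(table: PatternTable, path: str | Path, max_patterns: int = 40):
    """Minimal UpSet-style export: count bars over a presence dot matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = table.table.head(max_patterns)
    n = len(sub)
    fig, (ax_bar, ax_dots) = plt.subplots(
        2, 1, figsize=(max(4, n * 0.3), 6),
        gridspec_kw={"height_ratios": [1, 2]}, sharex=True,
    )
    ax_bar.bar(range(n), sub["count"], color="steelblue")
    ax_bar.set_ylabel("gene families")
    for x, (pattern, sig) in enumerate(zip(sub["pattern"], sub["signature_of"])):
        for y, bit in enumerate(pattern):
            if bit == "1":
                ax_dots.plot(
                    x, y, "o",
                    color="darkblue" if sig else "lightsteelblue", ms=4,
                )
    ax_dots.set_yticks(range(len(table.genomes)))
    ax_dots.set_yticklabels(table.genomes, fontsize=6)
    ax_dots.invert_yaxis()
    ax_dots.set_xlabel("presence/absence pattern")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
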