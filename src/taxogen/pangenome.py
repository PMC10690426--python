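"""Gene families by Markov clustering of all-vs-all protein similarity.

The similarity search is exhaustive pairwise local alignment (BLOSUM62
Smith-Waterman behind a shared-k-mer prefilter); edges carry percent
identity, which is also the weight fed to MCL.  Clustering follows the
classic Markov Cluster algorithm on the column-stochastic identity matrix
with self-loops: alternate expansion (matrix squaring) and inflation
(entrywise power, column renormalisation), prune tiny entries, stop when
successive iterates agree, and read clusters off the converged matrix's
nonzero structure.  Isolated genes become singleton families.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .align import align_protein_pair, shares_kmers
from .io import DuplicateIdError, GenomeRecord, genome_of


class MclConvergenceError(RuntimeError):
    pass


@dataclass
class GeneFamilySet:
    """A partition of the gene universe into families."""

    families: dict[str, frozenset[str]]

    def __post_init__(self):
        self.gene_to_family: dict[str, str] = {}
        for fam, genes in self.families.items():
            for g in genes:
                if g in self.gene_to_family:
                    raise ValueError(f"gene {g} in two families")
                self.gene_to_family[g] = fam

    @property
    def n_genes(self) -> int:
        return len(self.gene_to_family)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# gene\tfamily\n")
            for gene in sorted(self.gene_to_family):
                fh.write(f"{gene}\t{self.gene_to_family[gene]}\n")


@dataclass
class PangenomeMatrix:
    """Gene-family x genome copy-number matrix with a boolean presence view."""

    df: pd.DataFrame  # rows: families, columns: genomes, int copy numbers

    @property
    def presence(self) -> pd.DataFrame:
        return self.df > 0

    @property
    def genomes(self) -> list[str]:
        return list(self.df.columns)

    def to_tsv(self, path: str | Path) -> None:
        from .io import write_tsv

        write_tsv(self.df, path, "gene family copy numbers; rows=family, cols=genome")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PangenomeMatrix":
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        return cls(df=df.astype(int))


def _gene_universe(proteomes) -> dict[str, str]:
    """Flatten proteomes (GenomeRecords or {genome: {gene: seq}}) to gene->seq."""
    genes: dict[str, str] = {}
    for item in proteomes.values() if isinstance(proteomes, dict) else proteomes:
        prot = item.proteins if isinstance(item, GenomeRecord) else item
        for gid, seq in prot.items():
            if gid in genes:
                raise DuplicateIdError(f"duplicate gene ID across proteomes: {gid}")
            if not seq:
                raise ValueError(f"empty sequence for gene {gid}")
            genes[gid] = seq
    return genes


def score_protein_pairs(
    proteomes,
    min_identity: float = 40.0,
    min_coverage: float = 0.5,
    aligner=align_protein_pair,
    prefilter_k: int = 4,
    prefilter_min_shared: int = 2,
) -> nx.Graph:
    """All-vs-all protein similarity graph.

    Nodes are genome-scoped gene IDs (every gene appears, connected or not);
    edges exist where the local alignment reaches ``min_identity`` percent
    and covers at least ``min_coverage`` of the shorter sequence, and carry
    ``identity``, ``coverage`` and ``score``.
    """
    genes = _gene_universe(proteomes)
    ids = sorted(genes)
    graph = nx.Graph()
    for gid in ids:
        graph.add_node(gid, genome=genome_of(gid))
    for i, a in enumerate(ids):
        sa = genes[a]
        for b in ids[i + 1 :]:
            sb = genes[b]
            if not shares_kmers(sa, sb, k=prefilter_k, min_shared=prefilter_min_shared):
                continue
            hit = aligner(sa, sb)
            if hit is None:
                continue
            if hit.identity >= min_identity and hit.coverage >= min_coverage:
                graph.add_edge(
                    a, b,
                    identity=hit.identity,
                    coverage=hit.coverage,
                    score=hit.score,
                )
    return graph


def mcl_cluster(
    graph: nx.Graph,
    inflation: float = 5.0,
    min_identity: float = 40.0,
    pruning_floor: float = 1e-6,
    tolerance: float = 1e-8,
    max_iterations: int = 200,
) -> GeneFamilySet:
    """Markov clustering of the similarity graph into gene families.

    Edges below ``min_identity`` are dropped first; each node gets a
    self-loop equal to its largest incident weight (1 for isolated nodes).
    Family IDs are ``F`` + index, assigned in order of each family's
    lexicographically smallest member so the labelling is deterministic.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    nodes = sorted(graph.nodes)
    n = len(nodes)
    pos = {g: i for i, g in enumerate(nodes)}
    W = np.zeros((n, n))
    for a, b, data in graph.edges(data=True):
        if data["identity"] < min_identity:
            continue
        W[pos[a], pos[b]] = W[pos[b], pos[a]] = data["identity"]
    for i in range(n):
        mx = W[i].max()
        W[i, i] = mx if mx > 0 else 1.0

    M = W / W.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iterations):
        nxt = np.linalg.matrix_power(M, 2)
        np.power(nxt, inflation, out=nxt)
        nxt[nxt < pruning_floor] = 0.0
        colsum = nxt.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        nxt /= colsum
        delta = np.abs(nxt - M).max()
        M = nxt
        if delta < tolerance:
            converged = True
            break
    if not converged:
        raise MclConvergenceError(
            f"MCL did not converge within {max_iterations} iterations"
        )

    comp_graph = nx.Graph()
    comp_graph.add_nodes_from(range(n))
    for i, j in np.argwhere(M > pruning_floor):
        comp_graph.add_edge(int(i), int(j))
    clusters = [
        frozenset(nodes[i] for i in comp)
        for comp in nx.connected_components(comp_graph)
    ]
    clusters.sort(key=lambda fs: min(fs))
    width = max(5, int(math.log10(max(len(clusters), 1)) + 1))
    families = {f"F{i:0{width}d}": fs for i, fs in enumerate(clusters)}
    return GeneFamilySet(families=families)


def presence_matrix(
    families: GeneFamilySet, genomes: list[str]
) -> PangenomeMatrix:
    """Per-family per-genome copy numbers from the family partition."""
    known = set(genomes)
    counts = {fam: {g: 0 for g in genomes} for fam in families.families}
    for fam, genes in families.families.items():
        for gid in genes:
            g = genome_of(gid)
            if g not in known:
                raise ValueError(f"gene {gid} maps to unknown genome {g!r}")
            counts[fam][g] += 1
    df = pd.DataFrame.from_dict(counts, orient="index", dtype=int)
    df = df.reindex(columns=list(genomes)).sort_index()
    return PangenomeMatrix(df=df)


def extract_core(
    matrix: PangenomeMatrix, fraction: float = 0.9
) -> list[str]:
    """Single-copy families present in at least ``fraction`` of genomes.

    Presence uses ceil(fraction * n_genomes); single-copy means copy number
    <= 1 in every genome (absence allowed).  Returned in lexicographic order.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = len(matrix.genomes)
    need = math.ceil(fraction * n)
    pres = matrix.presence.sum(axis=1)
    single = (matrix.df <= 1).all(axis=1)
    return sorted(matrix.df.index[(pres >= need) & single])
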