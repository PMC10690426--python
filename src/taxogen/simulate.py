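"""Synthetic comparative-genomics datasets with planted ground truth.

The generator emulates the data regime the analysis stages assume: a
clade-structured species tree; gene families that are universal single-copy
(core), clade-exclusive (signatures), patchy (accessory) or genome-unique
(singletons); protein divergence that grows with tree distance under a
uniform-exchange amino-acid process; nucleotide loci back-translated through
the standard codon table with neutral synonymous-site noise; and
near-identical genome pairs planted as cherries to stand in for heterotypic
synonyms.  Every random draw flows from the single config seed, so identical
configs give byte-identical outputs.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GenomeRecord, write_fasta
from .tree import TaxonTree

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# standard genetic code grouped by residue (stop codons excluded); the codon
# chosen for a residue is a uniform draw over this list, which is what makes
# nucleotide identity decay faster than protein identity.
_CODONS_OF: dict[str, list[str]] = {}
from Bio.Data.CodonTable import standard_dna_table as _SDT  # noqa: E402

for _codon, _aa in _SDT.forward_table.items():
    _CODONS_OF.setdefault(_aa, []).append(_codon)
for _aa in _CODONS_OF:
    _CODONS_OF[_aa].sort()

_N_CODONS = np.array([len(_CODONS_OF[a]) for a in AA_ALPHABET])


class InvalidConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Branch lengths are in expected substitutions per site divided by
    ``substitution_rate``, so the realised amino-acid divergence between two
    leaves at path length ``d`` is ``(19/20) * (1 - exp(-d * rate))``.
    """

    n_genomes: int = 12
    clade_sizes: tuple[int, ...] = (4, 4, 4)
    n_core_families: int = 12
    n_signature_per_clade: int = 3
    n_accessory_families: int = 24
    accessory_presence_prob: float = 0.3
    n_singletons_per_genome: int = 2
    protein_length_mean: int = 150
    substitution_rate: float = 1.0
    genome_fragment_length: int = 0   # >0 forces a fixed per-locus bp length
    synonym_pairs: int = 1
    synonym_divergence: float = 0.005
    seed: int = 0
    spacer_length: int = 100          # intergenic spacer bound to each locus, bp
    synonymous_rate: float | None = None  # per-codon; defaults to substitution_rate
    rearrangement_rate: float = 30.0  # gene-order events per unit branch length

    def __post_init__(self):
        if sum(self.clade_sizes) != self.n_genomes:
            raise InvalidConfigError("clade_sizes must sum to n_genomes")
        if any(s < 1 for s in self.clade_sizes):
            raise InvalidConfigError("every clade must have at least one genome")
        for name in (
            "n_core_families", "n_signature_per_clade", "n_accessory_families",
            "n_singletons_per_genome", "synonym_pairs", "spacer_length",
        ):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")
        if self.substitution_rate < 0 or self.synonym_divergence < 0:
            raise InvalidConfigError("rates must be >= 0")
        if not 0.0 < self.accessory_presence_prob < 1.0:
            if self.n_accessory_families > 0:
                raise InvalidConfigError("accessory_presence_prob must be in (0,1)")
        if self.protein_length_mean < 10 and self.genome_fragment_length <= 0:
            raise InvalidConfigError("protein_length_mean too small")
        hosts = sum(s // 2 for s in self.clade_sizes)
        if self.synonym_pairs > hosts:
            raise InvalidConfigError("too many synonym pairs for the clade sizes")

    @property
    def syn_rate(self) -> float:
        return (
            self.substitution_rate
            if self.synonymous_rate is None
            else self.synonymous_rate
        )


@dataclass
class SyntheticTruth:
    """Planted ground truth: the oracle for every downstream stage."""

    clade_of: dict[str, str] = field(default_factory=dict)
    signature_families: dict[str, set[str]] = field(default_factory=dict)
    synonym_sets: list[set[str]] = field(default_factory=list)
    # family -> genome -> ordered (site, ancestral, derived) events, root to leaf
    mutation_log: dict[str, dict[str, list[tuple[int, str, str]]]] = field(
        default_factory=dict
    )
    root_proteins: dict[str, str] = field(default_factory=dict)
    gene_map: dict[str, str] = field(default_factory=dict)  # gene ID -> family
    presence: pd.DataFrame | None = None
    tree: TaxonTree | None = None

    def clades(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for g, c in self.clade_of.items():
            out.setdefault(c, set()).add(g)
        return out

    def replay(self, family: str, genome: str) -> str:
        """Replay the mutation log to rebuild a leaf protein from the root."""
        seq = list(self.root_proteins[family])
        for site, anc, der in self.mutation_log[family][genome]:
            if seq[site] != anc:
                raise AssertionError(
                    f"log corrupt at {family}/{genome} site {site}"
                )
            seq[site] = der
        return "".join(seq)

    # -- (de)serialisation -------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "clade_of": self.clade_of,
                "signature_families": {
                    c: sorted(f) for c, f in self.signature_families.items()
                },
                "synonym_sets": [sorted(s) for s in self.synonym_sets],
                "mutation_log": self.mutation_log,
                "root_proteins": self.root_proteins,
                "gene_map": self.gene_map,
                "presence": (
                    None if self.presence is None
                    else self.presence.to_dict(orient="index")
                ),
                "tree": None if self.tree is None else self.tree.to_newick(),
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        presence = (
            None if d["presence"] is None
            else pd.DataFrame.from_dict(d["presence"], orient="index").sort_index()
        )
        return cls(
            clade_of=d["clade_of"],
            signature_families={
                c: set(f) for c, f in d["signature_families"].items()
            },
            synonym_sets=[set(s) for s in d["synonym_sets"]],
            mutation_log={
                fam: {
                    g: [(int(s), a, b) for s, a, b in ev] for g, ev in gm.items()
                }
                for fam, gm in d["mutation_log"].items()
            },
            root_proteins=d["root_proteins"],
            gene_map=d["gene_map"],
            presence=presence,
            tree=None if d["tree"] is None else TaxonTree.from_newick(d["tree"]),
        )


# ---------------------------------------------------------------------------
# stage 1: species tree
# ---------------------------------------------------------------------------

def _draw(rng, lo, hi, scale):
    return rng.uniform(lo, hi) * scale


def simulate_tree(config: SimulationConfig) -> tuple[TaxonTree, SyntheticTruth]:
    """Rooted binary species tree with planted monophyletic clades.

    Synonym pairs are cherries whose two pendant edges each measure
    ``synonym_divergence / substitution_rate``, so the leaf-to-leaf path is
    twice that.  All internal nodes carry support 100.
    """
    rng = np.random.default_rng([config.seed, 1])
    rate = config.substitution_rate
    scale = 1.0 / rate if rate > 0 else 1.0
    truth = SyntheticTruth()

    labels = [f"g{i:02d}" for i in range(config.n_genomes)]
    clades: list[list[str]] = []
    i = 0
    for ci, size in enumerate(config.clade_sizes):
        members = labels[i : i + size]
        clade = f"C{ci + 1}"
        for g in members:
            truth.clade_of[g] = clade
        clades.append(members)
        i += size

    # one synonym pair per hosting clade, round-robin over clades able to host
    syn_len = config.synonym_divergence * scale
    pair_host: dict[int, int] = {}
    hostable = [ci for ci, m in enumerate(clades) if len(m) >= 2]
    for p in range(config.synonym_pairs):
        placed = False
        for ci in itertools.islice(itertools.cycle(hostable), p, p + len(hostable)):
            if (len(clades[ci]) - 2 * pair_host.get(ci, 0)) >= 2:
                pair_host[ci] = pair_host.get(ci, 0) + 1
                placed = True
                break
        if not placed:
            raise InvalidConfigError("cannot place all synonym pairs")

    subtrees: list[str] = []
    for ci, members in enumerate(clades):
        units: list[tuple[str, str]] = []  # (newick fragment, kind)
        rest = list(members)
        for _ in range(pair_host.get(ci, 0)):
            a, b = rest[-2], rest[-1]
            rest = rest[:-2]
            units.append((f"({a}:{syn_len:.6g},{b}:{syn_len:.6g})100", "cherry"))
            truth.synonym_sets.append({a, b})
        units = [(g, "leaf") for g in rest] + units
        while len(units) > 1:
            j, k = sorted(rng.choice(len(units), size=2, replace=False))
            (u1, k1), (u2, k2) = units[j], units[k]
            l1 = _draw(rng, 0.04, 0.05, scale) if k1 != "internal" else _draw(rng, 0.01, 0.02, scale)
            l2 = _draw(rng, 0.04, 0.05, scale) if k2 != "internal" else _draw(rng, 0.01, 0.02, scale)
            merged = (f"({u1}:{l1:.6g},{u2}:{l2:.6g})100", "internal")
            units = [u for idx, u in enumerate(units) if idx not in (j, k)]
            units.append(merged)
        subtrees.append(units[0][0])

    if len(subtrees) == 1:
        newick = subtrees[0] + ";"
    else:
        stem = lambda: _draw(rng, 0.08, 0.10, scale)  # noqa: E731
        spine = lambda: _draw(rng, 0.015, 0.03, scale)  # noqa: E731
        comb = f"({subtrees[0]}:{stem():.6g},{subtrees[1]}:{stem():.6g})100"
        for sub in subtrees[2:]:
            comb = f"({comb}:{spine():.6g},{sub}:{stem():.6g})100"
        newick = comb + ";"

    tree = TaxonTree.from_newick(newick)
    truth.tree = tree
    return tree, truth


# ---------------------------------------------------------------------------
# stage 2: gene content
# ---------------------------------------------------------------------------

def simulate_gene_content(
    tree: TaxonTree, config: SimulationConfig, truth: SyntheticTruth
) -> pd.DataFrame:
    """Family presence plan (families x genomes copy numbers, all 0/1).

    Core families are universal single-copy; each clade receives exactly
    ``n_signature_per_clade`` exclusive families; accessory families are
    present per genome with independent probability
    ``accessory_presence_prob`` (vectors colliding with a clade indicator,
    the all-present vector or the empty vector are redrawn, so planted
    signatures stay the only clade-exclusive patterns); singletons are
    genome-unique.
    """
    rng = np.random.default_rng([config.seed, 2])
    genomes = sorted(tree.leaf_labels)
    clades = truth.clades()
    indicator = {
        c: frozenset(m) for c, m in clades.items() if 0 < len(m) < len(genomes)
    }

    rows: dict[str, dict[str, int]] = {}
    for i in range(config.n_core_families):
        rows[f"core_{i:03d}"] = {g: 1 for g in genomes}
    for c in sorted(clades):
        fams = set()
        for i in range(config.n_signature_per_clade):
            fam = f"sig_{c}_{i:02d}"
            fams.add(fam)
            rows[fam] = {g: int(g in clades[c]) for g in genomes}
        truth.signature_families[c] = fams
    forbidden = set(indicator.values()) | {frozenset(genomes)}
    for i in range(config.n_accessory_families):
        while True:
            mask = rng.random(len(genomes)) < config.accessory_presence_prob
            present = frozenset(g for g, m in zip(genomes, mask) if m)
            if present and present not in forbidden:
                break
        rows[f"acc_{i:03d}"] = {g: int(g in present) for g in genomes}
    for g in genomes:
        for i in range(config.n_singletons_per_genome):
            rows[f"sng_{g}_{i:02d}"] = {h: int(h == g) for h in genomes}

    plan = pd.DataFrame.from_dict(rows, orient="index", dtype=int)
    plan = plan.reindex(columns=genomes).sort_index()
    truth.presence = plan
    return plan


# ---------------------------------------------------------------------------
# stage 3: sequence evolution
# ---------------------------------------------------------------------------

_NT = "ACGT"
_REVCOMP = str.maketrans("ACGT", "TGCA")


def _evolve_order(rng, order: list[tuple[str, int]], n_events: int):
    """Apply block inversions / transpositions to a gene order (in place)."""
    for _ in range(n_events):
        if len(order) < 2:
            return
        width = int(rng.integers(1, 4))
        i = int(rng.integers(0, len(order)))
        block = order[i : i + width]
        if rng.random() < 0.5:  # inversion: reverse block, flip strands
            order[i : i + width] = [(f, -s) for f, s in reversed(block)]
        else:  # transposition: move block elsewhere
            del order[i : i + width]
            j = int(rng.integers(0, len(order) + 1))
            order[j:j] = block


def _evolve_spacer(rng, spacer: "np.ndarray", p: float) -> "np.ndarray":
    """Neutral nucleotide substitutions on a spacer (base indices 0-3)."""
    out = spacer.copy()
    hit = rng.random(out.size) < p
    for site in np.flatnonzero(hit):
        out[site] = (out[site] + int(rng.integers(1, 4))) % 4
    return out


def _evolve_branch(rng, aa, codon_idx, p_aa, p_syn):
    """One branch of the uniform-exchange process; returns events."""
    n = aa.size
    events = []
    hit = rng.random(n) < p_aa
    if hit.any():
        for site in np.flatnonzero(hit):
            old = int(aa[site])
            new = (old + int(rng.integers(1, 20))) % 20
            aa[site] = new
            codon_idx[site] = int(rng.integers(0, _N_CODONS[new]))
            events.append((int(site), AA_ALPHABET[old], AA_ALPHABET[new]))
    syn = (rng.random(n) < p_syn) & ~hit & (_N_CODONS[aa] > 1)
    for site in np.flatnonzero(syn):
        ncod = int(_N_CODONS[aa[site]])
        codon_idx[site] = (int(codon_idx[site]) + int(rng.integers(1, ncod))) % ncod
    return events


def evolve_sequences(
    tree: TaxonTree,
    plan: pd.DataFrame,
    config: SimulationConfig,
    truth: SyntheticTruth,
) -> dict[str, GenomeRecord]:
    """Evolve proteins and nucleotide loci down the tree, then assemble genomes.

    Per branch each protein site mutates with probability
    ``1 - exp(-rate * length)`` to a uniformly chosen different residue; the
    codon of a mutated site is redrawn uniformly among the new residue's
    codons, and unmutated sites take synonymous codon switches at the
    (per-codon) synonymous rate.  Contigs concatenate a genome's loci in
    shuffled order and random strand, separated by random spacer DNA.
    """
    rng = np.random.default_rng([config.seed, 3])
    rate = config.substitution_rate
    genomes = list(plan.columns)
    leaf_prot: dict[str, dict[str, str]] = {g: {} for g in genomes}
    leaf_dna: dict[str, dict[str, str]] = {g: {} for g in genomes}
    root = tree.tree.seed_node

    # gene order and strand evolve along the tree by block inversions and
    # transpositions, so close genomes stay collinear (synteny) while
    # distant ones drift apart
    all_fams = list(plan.index)
    root_order = [
        (all_fams[i], 1 if rng.random() < 0.5 else -1)
        for i in rng.permutation(len(all_fams))
    ]
    leaf_order: dict[str, list[tuple[str, int]]] = {}
    stack = [(root, root_order)]
    while stack:
        node, order = stack.pop()
        if node.is_leaf():
            leaf_order[node.taxon.label] = order
            continue
        for child in node.child_nodes():
            length_b = child.edge.length or 0.0
            child_order = list(order)
            _evolve_order(
                rng, child_order,
                int(rng.poisson(config.rearrangement_rate * length_b)),
            )
            stack.append((child, child_order))

    leaf_spacer: dict[str, dict[str, str]] = {g: {} for g in genomes}
    for family in plan.index:
        if config.genome_fragment_length > 0:
            length = max(10, config.genome_fragment_length // 3 - 1)
        else:
            length = max(30, int(rng.poisson(config.protein_length_mean)))
        if length == 0:
            raise InvalidConfigError("zero-length protein")
        root_aa = rng.integers(0, 20, size=length)
        root_codon = np.array(
            [int(rng.integers(0, _N_CODONS[a])) for a in root_aa]
        )
        truth.root_proteins[family] = "".join(AA_ALPHABET[a] for a in root_aa)
        truth.mutation_log[family] = {}
        present = set(plan.columns[plan.loc[family] > 0])
        root_spacer = rng.integers(0, 4, size=config.spacer_length)

        # iterative preorder walk carrying (node, aa, codons, spacer, events)
        stack = [(root, root_aa, root_codon, root_spacer, [])]
        while stack:
            node, aa, cod, spc, events = stack.pop()
            if node.is_leaf():
                g = node.taxon.label
                if g in present:
                    truth.mutation_log[family][g] = events
                    leaf_prot[g][family] = "".join(AA_ALPHABET[a] for a in aa)
                    leaf_dna[g][family] = (
                        "".join(
                            _CODONS_OF[AA_ALPHABET[a]][c] for a, c in zip(aa, cod)
                        )
                        + "TAA"
                    )
                    leaf_spacer[g][family] = "".join(_NT[b] for b in spc)
                continue
            for child in node.child_nodes():
                length_b = child.edge.length or 0.0
                p_aa = 1.0 - np.exp(-rate * length_b)
                p_syn = 1.0 - np.exp(-config.syn_rate * length_b)
                caa, ccod = aa.copy(), cod.copy()
                ev = _evolve_branch(rng, caa, ccod, p_aa, p_syn)
                cspc = _evolve_spacer(rng, spc, p_aa)
                stack.append((child, caa, ccod, cspc, events + ev))

    records: dict[str, GenomeRecord] = {}
    for g in genomes:
        proteins: dict[str, str] = {}
        parts: list[str] = []
        k = 0
        for family, strand in leaf_order[g]:
            if family not in leaf_prot[g]:
                continue
            gene_id = f"{g}|g{k:03d}"
            k += 1
            proteins[gene_id] = leaf_prot[g][family]
            truth.gene_map[gene_id] = family
            piece = leaf_spacer[g][family] + leaf_dna[g][family]
            if strand < 0:
                piece = piece.translate(_REVCOMP)[::-1]
            parts.append(piece)
        records[g] = GenomeRecord(
            genome_id=g, contigs={f"{g}_ctg1": "".join(parts)}, proteins=proteins
        )
    return records


# ---------------------------------------------------------------------------
# stage 4: convenience + on-disk dataset
# ---------------------------------------------------------------------------

def simulate_dataset(
    config: SimulationConfig,
) -> tuple[dict[str, GenomeRecord], SyntheticTruth]:
    tree, truth = simulate_tree(config)
    plan = simulate_gene_content(tree, config, truth)
    genomes = evolve_sequences(tree, plan, config, truth)
    return genomes, truth


def write_dataset(
    genomes: dict[str, GenomeRecord],
    truth: SyntheticTruth,
    outdir: str | Path,
    overwrite: bool = False,
) -> list[Path]:
    """Write per-genome FASTA pairs, the tree and the truth record.

    Refuses to clobber existing files unless ``overwrite`` is set.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    targets = [outdir / "truth.json", outdir / "tree.nwk"]
    for g in genomes:
        targets += [outdir / f"{g}.fna", outdir / f"{g}.faa"]
    if not overwrite:
        clashes = [p for p in targets if p.exists()]
        if clashes:
            raise FileExistsError(f"refusing to overwrite: {clashes[0]} (+{len(clashes)-1} more)")
    for g, rec in genomes.items():
        write_fasta(rec.contigs, outdir / f"{g}.fna")
        write_fasta(rec.proteins, outdir / f"{g}.faa")
        paths += [outdir / f"{g}.fna", outdir / f"{g}.faa"]
    (outdir / "truth.json").write_text(truth.to_json())
    if truth.tree is not None:
        truth.tree.write(outdir / "tree.nwk")
    return paths + [outdir / "truth.json", outdir / "tree.nwk"]


def read_dataset(
    indir: str | Path,
) -> tuple[dict[str, GenomeRecord], SyntheticTruth]:
    from .io import read_fasta

    indir = Path(indir)
    truth = SyntheticTruth.from_json((indir / "truth.json").read_text())
    genomes = {}
    for fna in sorted(indir.glob("*.fna")):
        g = fna.stem
        genomes[g] = GenomeRecord(
            genome_id=g,
            contigs=read_fasta(fna),
            proteins=read_fasta(indir / f"{g}.faa"),
        )
    return genomes, truth
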