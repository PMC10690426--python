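"""Core-family alignment, column trimming, and supermatrix concatenation.

Trimming is two-staged, per family, before concatenation: first columns with
strictly more than ``max_gap_fraction`` gaps are dropped, then the
``floor(prune_fraction x surviving)`` least conserved columns are removed,
where conservation is scored by the chi-squared deviation of a column's
residue counts from the alignment-wide residue frequencies (gaps excluded on
both sides).  A column dominated by one residue deviates strongly from the
background and scores high; a maximally mixed column scores near zero, so
"least conserved" means lowest chi-squared.  Ties at the cut are broken by
column index, left to right.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import biotite.sequence as bseq
import biotite.sequence.align as balign

GAP = "-"

_MATRIX = balign.SubstitutionMatrix.std_protein_matrix()


@dataclass
class FamilyAlignment:
    family_id: str
    rows: dict[str, str]  # genome (or sequence name) -> aligned residues

    def __post_init__(self):
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment for {self.family_id}")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def column(self, j: int) -> list[str]:
        return [s[j] for s in self.rows.values()]

    def ungapped(self, name: str) -> str:
        return self.rows[name].replace(GAP, "")


@dataclass
class SuperAlignment:
    """Concatenated trimmed family alignments over a shared genome set."""

    rows: dict[str, str]
    spans: list[tuple[str, int, int]]  # (family, start, end), 1-based inclusive

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def slice_family(self, family_id: str) -> FamilyAlignment:
        for fam, start, end in self.spans:
            if fam == family_id:
                return FamilyAlignment(
                    family_id=fam,
                    rows={g: s[start - 1 : end] for g, s in self.rows.items()},
                )
        raise KeyError(family_id)

    def write(self, fasta_path: str | Path, partition_path: str | Path) -> None:
        from .io import write_fasta

        write_fasta(self.rows, fasta_path)
        with open(partition_path, "w") as fh:
            fh.write("# family\tstart\tend (1-based inclusive columns)\n")
            for fam, start, end in self.spans:
                fh.write(f"{fam}\t{start}\t{end}\n")


def _biotite_msa(named: list[tuple[str, str]]) -> list[str]:
    seqs = [bseq.ProteinSequence(s) for _n, s in named]
    if len(seqs) == 2:
        aln = balign.align_optimal(
            seqs[0], seqs[1], _MATRIX, gap_penalty=(-11, -1),
            terminal_penalty=False, max_number=1,
        )[0]
        return list(aln.get_gapped_sequences())
    aln, _order, _tree, _dist = balign.align_multiple(
        seqs, _MATRIX, gap_penalty=(-11, -1)
    )
    return list(aln.get_gapped_sequences())


def align_family(
    sequences: dict[str, str], family_id: str = "", aligner=_biotite_msa
) -> FamilyAlignment:
    """Multiple alignment of one family (progressive, guide-tree based).

    ``aligner`` may be replaced by any callable taking ``[(name, seq), ...]``
    and returning equal-length gapped strings in input order.
    """
    if len(sequences) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    if any(not s for s in sequences.values()):
        raise ValueError("empty sequence in family " + family_id)
    named = list(sequences.items())
    if len({s for _n, s in named}) == 1:
        gapped = [s for _n, s in named]  # identical: trivially aligned
    else:
        gapped = aligner(named)
    aln = FamilyAlignment(
        family_id=family_id,
        rows={n: g for (n, _s), g in zip(named, gapped)},
    )
    for name, seq in sequences.items():
        if aln.ungapped(name) != seq:
            raise AssertionError(f"aligner corrupted sequence {name}")
    return aln


def chi2_column_scores(aln: FamilyAlignment, columns: list[int]) -> list[float]:
    """Chi-squared conservation score per column against background frequencies.

    The background is the residue composition of the listed columns, gaps
    excluded.  Residues absent from the background contribute nothing (their
    expected count is zero).
    """
    background: Counter = Counter()
    for j in columns:
        for c in aln.column(j):
            if c != GAP:
                background[c] += 1
    total = sum(background.values())
    freqs = {r: cnt / total for r, cnt in background.items()}
    scores = []
    for j in columns:
        obs = Counter(c for c in aln.column(j) if c != GAP)
        n = sum(obs.values())
        chi2 = 0.0
        for r, f in freqs.items():
            e = n * f
            if e > 0:
                chi2 += (obs.get(r, 0) - e) ** 2 / e
        scores.append(chi2)
    return scores


def trim_alignment(
    aln: FamilyAlignment,
    max_gap_fraction: float = 0.5,
    prune_fraction: float = 0.2,
) -> tuple[FamilyAlignment, dict]:
    """Two-stage column trim; returns the trimmed alignment and a report.

    Stage 1 removes columns whose gap fraction strictly exceeds
    ``max_gap_fraction``; stage 2 removes exactly
    ``floor(prune_fraction x surviving)`` lowest-chi-squared columns.
    The report maps removed original column indices to their stage.
    """
    nrow = len(aln.rows)
    survivors = []
    removed: dict[int, str] = {}
    for j in range(aln.n_columns):
        gaps = sum(1 for c in aln.column(j) if c == GAP)
        if gaps / nrow > max_gap_fraction:
            removed[j] = "gap"
        else:
            survivors.append(j)
    scores = chi2_column_scores(aln, survivors) if survivors else []
    k = int(prune_fraction * len(survivors))
    # lowest score first; ties broken by original column index (stable sort)
    order = sorted(range(len(survivors)), key=lambda i: (scores[i], survivors[i]))
    for i in order[:k]:
        removed[survivors[i]] = "chi2"
    kept = [j for j in survivors if removed.get(j) != "chi2"]
    if not kept:
        raise ValueError(f"trimming removed every column of {aln.family_id}")
    trimmed = FamilyAlignment(
        family_id=aln.family_id,
        rows={g: "".join(s[j] for j in kept) for g, s in aln.rows.items()},
    )
    report = {
        "kept_columns": kept,
        "removed": removed,
        "chi2_scores": dict(zip(survivors, scores)),
    }
    return trimmed, report


def concatenate(
    alignments: list[FamilyAlignment], genome_ids: list[str]
) -> SuperAlignment:
    """Concatenate family alignments; absent genomes get all-gap blocks."""
    covered = set()
    for aln in alignments:
        covered |= set(aln.rows)
    missing = set(genome_ids) - covered
    if missing:
        raise ValueError(f"genomes present in no family: {sorted(missing)}")
    parts = {g: [] for g in genome_ids}
    spans = []
    start = 1
    for aln in alignments:
        w = aln.n_columns
        for g in genome_ids:
            parts[g].append(aln.rows.get(g, GAP * w))
        spans.append((aln.family_id, start, start + w - 1))
        start += w
    return SuperAlignment(
        rows={g: "".join(p) for g, p in parts.items()}, spans=spans
    )
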