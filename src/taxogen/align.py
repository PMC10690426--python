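"""Pluggable pairwise local alignment.

Two built-in backends cover every similarity search in the package:

* proteins — biotite's affine-gap Smith-Waterman (BLOSUM62, gap open/extend
  11/1), guarded by a shared-k-mer prefilter so unrelated pairs are never
  aligned;
* nucleotide fragments — a seed-and-extend scheme: exact k-mer seeds on
  either strand locate a candidate subject window, the fragment is aligned
  to the window with edlib's banded edit-distance aligner, and the highest
  scoring run of the resulting alignment path is kept as the local hit
  (Smith-Waterman restricted to the edlib path).

Both report percent identity as identical columns over alignment columns and
coverage as the aligned fraction of the relevant sequence.  Either backend
can be replaced by any callable with the same signature.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import biotite.sequence as bseq
import biotite.sequence.align as balign
import edlib

_PROTEIN_MATRIX = balign.SubstitutionMatrix.std_protein_matrix()  # BLOSUM62

_COMPLEMENT = str.maketrans("ACGTRYKMBDHVN", "TGCAYRMKVHDBN")

# column scores used when extracting the best local run from an edlib path;
# the breakeven identity is 1/(1-match/mismatch) = 2/3, above the ~55-60%
# identity an optimal edit-distance alignment reaches on random DNA, so
# non-homologous stretches score negative and are clipped from the run
_NT_MATCH, _NT_MISMATCH, _NT_GAP = 1.0, -2.0, -2.5

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PairwiseHit:
    """Local alignment summary for one sequence pair (or fragment)."""

    identity: float        # percent, identical columns / alignment columns
    coverage: float        # aligned fraction of the query (or shorter) sequence
    score: float
    matches: int           # identical columns
    columns: int           # alignment columns (incl. gap columns)


# ---------------------------------------------------------------------------
# protein local alignment
# ---------------------------------------------------------------------------

def kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def shares_kmers(a: str, b: str, k: int = 4, min_shared: int = 2) -> bool:
    """Cheap homology prefilter: do the sequences share >= min_shared k-mers?"""
    ka, kb = kmer_set(a, k), kmer_set(b, k)
    if len(ka) > len(kb):
        ka, kb = kb, ka
    n = 0
    for m in ka:
        if m in kb:
            n += 1
            if n >= min_shared:
                return True
    return False


def align_protein_pair(
    a: str, b: str, gap_open: int = -11, gap_extend: int = -1
) -> PairwiseHit | None:
    """Smith-Waterman local alignment of two protein sequences.

    Returns ``None`` when no positively scoring local alignment exists.
    """
    if not a or not b:
        raise ValueError("empty protein sequence")
    sa, sb = bseq.ProteinSequence(a), bseq.ProteinSequence(b)
    alns = balign.align_optimal(
        sa, sb, _PROTEIN_MATRIX, gap_penalty=(gap_open, gap_extend),
        local=True, max_number=1,
    )
    if not alns:
        return None
    aln = alns[0]
    if aln.trace.shape[0] == 0 or aln.score <= 0:
        return None
    trace = aln.trace
    both = (trace[:, 0] >= 0) & (trace[:, 1] >= 0)
    matches = int(
        sum(
            1
            for i in range(trace.shape[0])
            if both[i] and a[trace[i, 0]] == b[trace[i, 1]]
        )
    )
    columns = int(trace.shape[0])
    shorter = min(len(a), len(b))
    cov_a = int((trace[:, 0] >= 0).sum())
    cov_b = int((trace[:, 1] >= 0).sum())
    coverage = (cov_a if len(a) <= len(b) else cov_b) / shorter
    return PairwiseHit(
        identity=100.0 * matches / columns,
        coverage=coverage,
        score=float(aln.score),
        matches=matches,
        columns=columns,
    )


# ---------------------------------------------------------------------------
# nucleotide fragment alignment (seed-and-extend)
# ---------------------------------------------------------------------------

class SubjectIndex:
    """Exact k-mer index over a genome's contigs, for fragment seeding."""

    def __init__(self, contigs: dict[str, str], k: int = 12):
        self.k = k
        self.contigs = dict(contigs)
        self.index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in self.contigs.items():
            for i in range(len(seq) - k + 1):
                self.index.setdefault(seq[i : i + k], []).append((name, i))

    def _seed_windows(self, fragment: str, min_seeds: int):
        """Diagonal-binned seed counts -> candidate (contig, window) list."""
        k = self.k
        bins: dict[tuple[str, int], list[tuple[int, int]]] = {}
        for q in range(0, len(fragment) - k + 1):
            for name, pos in self.index.get(fragment[q : q + k], ()):
                diag = pos - q
                for b in (diag // 200, diag // 200 + 1):
                    bins.setdefault((name, b), []).append((q, pos))
        out = []
        for (name, _b), seeds in bins.items():
            if len(seeds) < min_seeds:
                continue
            lo = max(0, min(p for _q, p in seeds) - min(q for q, _p in seeds) - 64)
            hi = min(
                len(self.contigs[name]),
                max(p for _q, p in seeds) + (len(fragment) - max(q for q, _p in seeds)) + 64,
            )
            out.append((len(seeds), name, lo, hi))
        out.sort(reverse=True)
        return out[:3]


def _best_local_run(cigar: str, fragment_len: int) -> tuple[int, int, int, float]:
    """Best scoring contiguous run of an edlib extended-CIGAR alignment.

    Returns (matches, columns, query_cols, score) of the maximal scoring
    segment under match/mismatch/gap column scores — i.e. the local core of
    the end-to-end path.
    """
    cols: list[tuple[str, int]] = []
    for num, op in _CIGAR_RE.findall(cigar):
        cols.extend([(op, 1)] * int(num))
    best = (0, 0, 0, 0.0)  # matches, columns, query columns, score
    cur_score = 0.0
    cur = [0, 0, 0]  # matches, columns, query columns
    best_score = 0.0
    for op, _ in cols:
        sc = _NT_MATCH if op == "=" else (_NT_MISMATCH if op in "XM" else _NT_GAP)
        if cur_score <= 0:
            cur_score = 0.0
            cur = [0, 0, 0]
        cur_score += sc
        cur[1] += 1
        if op == "=":
            cur[0] += 1
        if op in "=XMI":  # columns consuming query ('I' = insertion to target)
            cur[2] += 1
        if cur_score > best_score:
            best_score = cur_score
            best = (cur[0], cur[1], cur[2], cur_score)
    return best


def align_fragment(
    fragment: str,
    index: SubjectIndex,
    min_seeds: int = 2,
) -> PairwiseHit | None:
    """Best local alignment of a nucleotide fragment against an indexed subject.

    Both strands are attempted; the better one is reported.  Returns ``None``
    when no candidate window attracts at least ``min_seeds`` co-diagonal
    seeds on either strand.
    """
    best: PairwiseHit | None = None
    for strand_seq in (fragment, revcomp(fragment)):
        for _n, name, lo, hi in index._seed_windows(strand_seq, min_seeds):
            window = index.contigs[name][lo:hi]
            res = edlib.align(strand_seq, window, mode="HW", task="path")
            if res["editDistance"] < 0 or not res.get("cigar"):
                continue
            matches, columns, qcols, score = _best_local_run(
                res["cigar"], len(strand_seq)
            )
            if columns == 0:
                continue
            hit = PairwiseHit(
                identity=100.0 * matches / columns,
                coverage=qcols / len(fragment),
                score=score,
                matches=matches,
                columns=columns,
            )
            if best is None or hit.score > best.score:
                best = hit
    return best
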