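"""Overall genome relatedness indexes.

* ``anib`` — fragment-based average nucleotide identity: the query assembly
  is cut into consecutive fixed-length fragments (1,020 bp by default, final
  short fragment kept), each fragment is locally aligned to the subject, and
  fragments below the identity or coverage floors are discarded; ANI is the
  mean identity of retained fragments.  Directional by construction.
* ``aai`` — mean percent identity over reciprocal-best-hit protein pairs.
* ``caai`` — the same statistic restricted to shared core orthologous
  families (one best cross-genome pair per family), an index designed to be
  less sensitive to horizontally transferred accessory genes.
* ``dddh_formula2`` — digital DNA-DNA hybridisation: the fragment HSPs are
  pooled and the distance is d = 1 - (sum of identities / sum of HSP
  lengths); a monotone decreasing transform maps d to a dDDH percentage.
  The raw distance is always reported alongside the transformed value.

Missing values are explicit ``None``/NaN, never 0.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .align import PairwiseHit, SubjectIndex, align_fragment, align_protein_pair, shares_kmers
from .io import GenomeRecord


class OgriWarning(UserWarning):
    pass


@dataclass
class OGRIMatrix:
    """Pairwise index values with their parameters."""

    kind: str                      # ANI | AAI | cAAI | dDDH
    df: pd.DataFrame               # float values in [0,100]; NaN = missing
    params: dict = field(default_factory=dict)
    directional: bool = False

    @property
    def genomes(self) -> list[str]:
        return list(self.df.index)

    def value(self, a: str, b: str) -> float:
        return float(self.df.loc[a, b])

    def symmetric_value(self, a: str, b: str) -> float:
        """Mean of the two directions (equals either one when symmetric)."""
        vals = [
            v for v in (self.df.loc[a, b], self.df.loc[b, a]) if not np.isnan(v)
        ]
        return float(np.mean(vals)) if vals else float("nan")

    def to_tsv(self, path: str | Path) -> None:
        from .io import write_tsv

        path = Path(path)
        write_tsv(self.df, path, f"{self.kind} values (percent); rows=query")
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps(
                {"kind": self.kind, "directional": self.directional,
                 "params": self.params},
                indent=1, sort_keys=True,
            )
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OGRIMatrix":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        meta = {}
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        return cls(
            kind=meta.get("kind", "?"), df=df.astype(float),
            params=meta.get("params", {}),
            directional=meta.get("directional", False),
        )


# ---------------------------------------------------------------------------
# ANIb
# ---------------------------------------------------------------------------

def _fragments(record: GenomeRecord, length: int) -> list[str]:
    frags = []
    for seq in record.contigs.values():
        for i in range(0, len(seq), length):
            frags.append(seq[i : i + length])
    return frags


def anib(
    query: GenomeRecord,
    subject: GenomeRecord,
    fragment_length: int = 1020,
    min_identity: float = 30.0,
    min_coverage: float = 70.0,
    subject_index: SubjectIndex | None = None,
) -> tuple[float | None, pd.DataFrame]:
    """Directional fragment-based ANI (query -> subject).

    Returns the ANI value (or ``None`` with a warning when no fragment is
    retained) plus a per-fragment report of identity, coverage and retention.
    """
    if fragment_length < 100:
        raise ValueError("fragment_length must be >= 100")
    if not query.contigs or not subject.contigs:
        raise ValueError("empty assembly")
    index = subject_index or SubjectIndex(subject.contigs)
    rows = []
    for fid, frag in enumerate(_fragments(query, fragment_length)):
        hit = align_fragment(frag, index)
        if hit is None:
            rows.append((fid, len(frag), np.nan, 0.0, False))
            continue
        keep = hit.identity >= min_identity and 100.0 * hit.coverage >= min_coverage
        rows.append((fid, len(frag), hit.identity, hit.coverage, keep))
    report = pd.DataFrame(
        rows, columns=["fragment", "length", "identity", "coverage", "retained"]
    )
    retained = report[report["retained"]]
    if retained.empty:
        warnings.warn(
            f"anib({query.genome_id},{subject.genome_id}): no retained fragments",
            OgriWarning,
        )
        return None, report
    return float(retained["identity"].mean()), report


# ---------------------------------------------------------------------------
# AAI / cAAI
# ---------------------------------------------------------------------------

def _proteins(x) -> dict[str, str]:
    return x.proteins if isinstance(x, GenomeRecord) else dict(x)


def _best_hits(
    qa: dict[str, str], qb: dict[str, str]
) -> dict[str, tuple[str, PairwiseHit]]:
    """Best-scoring hit in B for each A gene (k-mer prefiltered)."""
    out = {}
    for ga, sa in qa.items():
        best = None
        for gb, sb in qb.items():
            if not shares_kmers(sa, sb):
                continue
            hit = align_protein_pair(sa, sb)
            if hit is None:
                continue
            if best is None or hit.score > best[1].score:
                best = (gb, hit)
        if best is not None:
            out[ga] = best
    return out


def aai(
    proteome_a, proteome_b, min_coverage: float = 0.7
) -> tuple[float | None, int]:
    """Symmetric AAI over reciprocal best hits; returns (value, n_pairs)."""
    pa, pb = _proteins(proteome_a), _proteins(proteome_b)
    if not pa or not pb:
        raise ValueError("empty proteome")
    fwd = _best_hits(pa, pb)
    rev = _best_hits(pb, pa)
    idents = []
    for ga, (gb, hit) in fwd.items():
        if rev.get(gb, (None,))[0] == ga and hit.coverage >= min_coverage:
            idents.append(hit.identity)
    if not idents:
        warnings.warn("aai: no reciprocal best-hit pairs", OgriWarning)
        return None, 0
    return float(np.mean(idents)), len(idents)


def caai(
    proteome_a,
    proteome_b,
    core_families: list[str],
    family_map: dict[str, str],
    min_coverage: float = 0.7,
) -> tuple[float | None, int]:
    """AAI restricted to shared core families (one best pair per family)."""
    pa, pb = _proteins(proteome_a), _proteins(proteome_b)
    if not pa or not pb:
        raise ValueError("empty proteome")
    core = set(core_families)
    by_family_a: dict[str, list[str]] = {}
    by_family_b: dict[str, list[str]] = {}
    for g in pa:
        fam = family_map.get(g)
        if fam in core:
            by_family_a.setdefault(fam, []).append(g)
    for g in pb:
        fam = family_map.get(g)
        if fam in core:
            by_family_b.setdefault(fam, []).append(g)
    idents = []
    for fam in sorted(set(by_family_a) & set(by_family_b)):
        best = None
        for ga in by_family_a[fam]:
            for gb in by_family_b[fam]:
                hit = align_protein_pair(pa[ga], pb[gb])
                if hit is None or hit.coverage < min_coverage:
                    continue
                if best is None or hit.score > best.score:
                    best = hit
        if best is not None:
            idents.append(best.identity)
    if not idents:
        warnings.warn("caai: no shared core families aligned", OgriWarning)
        return None, 0
    return float(np.mean(idents)), len(idents)


# ---------------------------------------------------------------------------
# dDDH (formula 2)
# ---------------------------------------------------------------------------

def formula2_distance_from_hsps(identities, lengths) -> float:
    """d = 1 - (sum of identical columns / sum of HSP lengths)."""
    identities = np.asarray(identities, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if lengths.sum() <= 0:
        raise ValueError("no HSPs")
    return float(1.0 - identities.sum() / lengths.sum())


def default_dddh_transform(distance: float, exponent: float = 10.5) -> float:
    """Monotone decreasing map from formula-2 distance to dDDH percent.

    ``100 * (1 - d) ** exponent``: exact 100 at distance 0, strictly
    decreasing, and calibrated so the 70% dDDH species boundary falls near
    distance 0.033 (~96.7% summed identity), matching published ANI-dDDH
    correspondences.
    """
    return 100.0 * (1.0 - distance) ** exponent


@dataclass
class DdhResult:
    distance: float | None
    dddh: float | None
    n_hsps: int


def dddh_formula2(
    query: GenomeRecord,
    subject: GenomeRecord,
    transform=default_dddh_transform,
    fragment_length: int = 1020,
    min_hsp_columns: int = 50,
    subject_index: SubjectIndex | None = None,
) -> DdhResult:
    """Formula-2 dDDH between two assemblies.

    HSPs are the per-fragment local alignments of the same seed-and-extend
    aligner ANIb uses; runs shorter than ``min_hsp_columns`` are ignored as
    spurious seed matches.
    """
    index = subject_index or SubjectIndex(subject.contigs)
    identities, lengths = [], []
    for frag in _fragments(query, fragment_length):
        hit = align_fragment(frag, index)
        if hit is None or hit.columns < min_hsp_columns:
            continue
        identities.append(hit.matches)
        lengths.append(hit.columns)
    if not lengths:
        warnings.warn(
            f"dddh({query.genome_id},{subject.genome_id}): no HSPs", OgriWarning
        )
        return DdhResult(distance=None, dddh=None, n_hsps=0)
    d = formula2_distance_from_hsps(identities, lengths)
    return DdhResult(distance=d, dddh=float(transform(d)), n_hsps=len(lengths))


# ---------------------------------------------------------------------------
# assembly statistics
# ---------------------------------------------------------------------------

def genome_stats(genome: GenomeRecord) -> tuple[int, float]:
    """(assembly size in bp, G+C mol%); ambiguous bases excluded from G+C."""
    if not genome.contigs:
        raise ValueError("empty assembly")
    size = genome.assembly_size
    gc = at = 0
    for seq in genome.contigs.values():
        gc += seq.count("G") + seq.count("C")
        at += seq.count("A") + seq.count("T")
    mol = 100.0 * gc / (gc + at) if (gc + at) else float("nan")
    return size, mol


# ---------------------------------------------------------------------------
# all-vs-all matrices
# ---------------------------------------------------------------------------

def pairwise_matrix(
    index_kind: str,
    genomes: list[GenomeRecord],
    core_families: list[str] | None = None,
    family_map: dict[str, str] | None = None,
    cache: dict | None = None,
    **params,
) -> OGRIMatrix:
    """All-vs-all OGRI matrix.

    ANI is computed in both directions; AAI and cAAI once per unordered
    pair; dDDH once per unordered pair and mirrored (treated as symmetric).
    ``cache`` maps (kind, query, subject, frozen params) to values and makes
    reruns resume without new alignments.
    """
    kind = index_kind.lower()
    if len(genomes) < 2:
        raise ValueError("need at least 2 genomes")
    ids = [g.genome_id for g in genomes]
    by_id = {g.genome_id: g for g in genomes}
    df = pd.DataFrame(np.nan, index=ids, columns=ids, dtype=float)
    np.fill_diagonal(df.values, 100.0)
    cache = cache if cache is not None else {}
    key_params = tuple(sorted(params.items()))
    indexes: dict[str, SubjectIndex] = {}

    def subject_index(gid: str) -> SubjectIndex:
        if gid not in indexes:
            indexes[gid] = SubjectIndex(by_id[gid].contigs)
        return indexes[gid]

    def cached(a: str, b: str, fn):
        key = (kind, a, b, key_params)
        if key not in cache:
            cache[key] = fn()
        return cache[key]

    directional = kind in ("ani", "anib")
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if kind in ("ani", "anib"):
                df.loc[a, b] = cached(
                    a, b,
                    lambda: anib(by_id[a], by_id[b],
                                 subject_index=subject_index(b), **params)[0],
                )
                df.loc[b, a] = cached(
                    b, a,
                    lambda: anib(by_id[b], by_id[a],
                                 subject_index=subject_index(a), **params)[0],
                )
            elif kind == "aai":
                df.loc[a, b] = df.loc[b, a] = cached(
                    a, b, lambda: aai(by_id[a], by_id[b], **params)[0]
                )
            elif kind == "caai":
                if core_families is None or family_map is None:
                    raise ValueError("caai needs core_families and family_map")
                df.loc[a, b] = df.loc[b, a] = cached(
                    a, b,
                    lambda: caai(by_id[a], by_id[b], core_families,
                                 family_map, **params)[0],
                )
            elif kind == "dddh":
                df.loc[a, b] = df.loc[b, a] = cached(
                    a, b,
                    lambda: dddh_formula2(
                        by_id[a], by_id[b],
                        subject_index=subject_index(b), **params
                    ).dddh,
                )
            else:
                raise ValueError(f"unknown index kind {index_kind!r}")
    label = {"ani": "ANI", "anib": "ANI", "aai": "AAI",
             "caai": "cAAI", "dddh": "dDDH"}[kind]
    return OGRIMatrix(
        kind=label, df=df, params=dict(params), directional=directional
    )
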