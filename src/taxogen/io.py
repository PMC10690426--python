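"""FASTA / table input-output and the GenomeRecord container.

Conventions used throughout the package:

* gene IDs are genome-scoped, written ``<genome>|<gene>``;
* sequences are stored uppercase; mixed-case input is uppercased with a warning;
* tabular outputs are TSV with a single ``#``-prefixed header line naming the
  columns.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class DuplicateIdError(ValueError):
    """Two records in one file (or one gene universe) share an ID."""


@dataclass
class GenomeRecord:
    """One genome: assembly contigs, predicted proteome, identifiers."""

    genome_id: str
    contigs: dict[str, str] = field(default_factory=dict)
    proteins: dict[str, str] = field(default_factory=dict)

    @property
    def assembly_size(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def gene_ids(self) -> list[str]:
        return list(self.proteins)


def genome_of(gene_id: str) -> str:
    """Genome part of a ``<genome>|<gene>`` scoped gene ID."""
    if "|" not in gene_id:
        raise ValueError(f"gene ID {gene_id!r} is not genome-scoped (<genome>|<gene>)")
    return gene_id.split("|", 1)[0]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping.

    Duplicate IDs and empty files are fatal; mixed-case sequence is
    uppercased with a warning.
    """
    path = Path(path)
    records: dict[str, str] = {}
    warned = False
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise DuplicateIdError(f"duplicate record ID {rec.id!r} in {path}")
        s = str(rec.seq)
        if not s.isupper():
            if not warned:
                warnings.warn(f"mixed-case sequence in {path}; uppercasing")
                warned = True
            s = s.upper()
        records[rec.id] = s
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: dict[str, str], path: str | Path, width: int = 80) -> None:
    path = Path(path)
    seqrecs = [
        SeqRecord(Seq(s), id=name, description="") for name, s in records.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


def write_tsv(df, path: str | Path, header_comment: str) -> None:
    """Write a DataFrame as TSV with a one-line ``#`` header naming columns."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
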