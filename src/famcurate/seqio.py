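"""Sequence and alignment I/O.

Readers and writers for the plain-text formats the pipeline touches —
multi-record FASTA, PHYLIP (sequential, strict or relaxed names), and
tab-separated gene-order tables — plus frame-1 CDS translation.

FASTA parsing is delegated to :mod:`Bio.SeqIO`.  PHYLIP is read by a
tolerant reader that accepts both the strict 10-character-name dialect and
the relaxed whitespace-delimited dialect (sequential layout in either
case), because gene-family alignments routinely carry taxon labels far
longer than ten characters.  Alignments are written back as relaxed
sequential PHYLIP, so write-then-read is the identity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "SequenceRecord",
    "Alignment",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_phylip",
    "write_phylip",
    "translate_cds",
    "read_gene_order",
]

GAP = "-"
# '.' is an alternative gap convention in some alignment tools; normalised on read.
_ALT_GAPS = "."

_PROTEIN_LETTERS = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*-")
_NUC_LETTERS = set("ACGTUNRYSWKMBDHV-")


class FormatError(ValueError):
    """A file violated the expected format; the message names the offending spot."""


@dataclass(frozen=True)
class SequenceRecord:
    """One sequence with provenance.

    Parameters
    ----------
    id : str
        Unique label within a collection.
    residues : str
        Protein or nucleotide residues (no gaps).
    taxon : str, optional
        Source organism, when known.
    source : str
        Provenance tag: ``genome``, ``transcriptome`` or ``synthetic``.
    """

    id: str
    residues: str
    taxon: str | None = None
    source: str = "genome"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Alignment:
    """A rectangular character matrix of aligned sequences.

    ``rows`` is an ordered list of ``(id, aligned_residues)`` pairs; every
    row has identical length and ids are unique.  ``gap`` is the single
    gap symbol (default ``'-'``).
    """

    rows: list[tuple[str, str]]
    gap: str = GAP

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment must contain at least one row")
        length = len(self.rows[0][1])
        if length < 1:
            raise ValueError("alignment length must be >= 1")
        ids = set()
        for rid, seq in self.rows:
            if len(seq) != length:
                raise ValueError(
                    f"row {rid!r} has length {len(seq)}, expected {length}"
                )
            if rid in ids:
                raise ValueError(f"duplicate row id {rid!r}")
            ids.add(rid)

    @property
    def length(self) -> int:
        """Number of aligned sites."""
        return len(self.rows[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def row(self, rid: str) -> str:
        for r, seq in self.rows:
            if r == rid:
                return seq
        raise KeyError(rid)

    def degap(self) -> list[SequenceRecord]:
        """Strip gaps row-wise, recovering the unaligned sequences."""
        return [
            SequenceRecord(rid, seq.replace(self.gap, ""))
            for rid, seq in self.rows
        ]


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly line-wrapped) multi-record FASTA file.

    Raises
    ------
    FormatError
        If the file does not start with a header, a record is empty, or
        ids are duplicated.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(">"):
            raise FormatError(f"{path}: line 1 is not a FASTA header")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        if not rec.id:
            raise FormatError(f"{path}: record {i} has an empty id")
        if len(rec.seq) == 0:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def _normalise_gaps(seq: str) -> str:
    for alt in _ALT_GAPS:
        seq = seq.replace(alt, GAP)
    return seq


def read_phylip(path: str | Path) -> Alignment:
    """Read a sequential PHYLIP alignment (strict or relaxed names).

    The first line must carry the taxon count and site count.  Each
    subsequent row is a name followed by its residues; residues may wrap
    over several lines and contain spaces, and a row is complete once it
    reaches the site count from the header.  Strict files whose names abut
    the sequence at column 10 are also handled.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) < 2:
            raise FormatError(f"{path}: first line must hold taxon and site counts")
        try:
            n_taxa, n_sites = int(header[0]), int(header[1])
        except ValueError:
            raise FormatError(f"{path}: non-integer PHYLIP header {header!r}") from None
        rows: list[tuple[str, str]] = []
        name: str | None = None
        seq_parts: list[str] = []

        def flush() -> None:
            nonlocal name, seq_parts
            if name is not None:
                seq = _normalise_gaps("".join(seq_parts))
                if len(seq) != n_sites:
                    raise FormatError(
                        f"{path}: row {name!r} has {len(seq)} sites, header says {n_sites}"
                    )
                rows.append((name, seq))
            name, seq_parts = None, []

        for line in fh:
            if not line.strip():
                continue
            if name is None or sum(map(len, seq_parts)) >= n_sites:
                flush()
                # new row: name is the first whitespace-delimited token;
                # strict 10-column names with no separating space are split at 10
                stripped = line.rstrip("\n")
                m = re.match(r"(\S+)\s+(.*)$", stripped)
                if m:
                    name = m.group(1)
                    seq_parts = [m.group(2).replace(" ", "")]
                else:
                    name = stripped[:10].strip()
                    seq_parts = [stripped[10:].replace(" ", "")]
                if not name:
                    raise FormatError(f"{path}: row with empty taxon name")
            else:
                seq_parts.append(line.strip().replace(" ", ""))
        flush()
    if len(rows) != n_taxa:
        raise FormatError(
            f"{path}: header declares {n_taxa} sequences but body holds {len(rows)}"
        )
    return Alignment(rows)


def write_phylip(aln: Alignment, path: str | Path) -> None:
    """Write relaxed sequential PHYLIP; round-trips through :func:`read_phylip`."""
    for rid, _ in aln.rows:
        if re.search(r"\s", rid):
            raise ValueError(
                f"id {rid!r} contains whitespace and cannot be encoded in PHYLIP"
            )
    width = max(len(rid) for rid, _ in aln.rows) + 2
    with open(path, "w") as fh:
        fh.write(f"{aln.n_rows} {aln.length}\n")
        for rid, seq in aln.rows:
            fh.write(f"{rid:<{width}}{seq}\n")


def translate_cds(cds: str, frame: int = 1) -> str:
    """Translate a frame-1 CDS with the standard genetic code.

    Trailing incomplete codons are dropped, stops are rendered ``*`` and
    codons that do not resolve to a single amino acid become ``X``.
    """
    if frame != 1:
        raise ValueError("only frame 1 is supported")
    cds = cds.upper().replace("U", "T")
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    usable = len(cds) - len(cds) % 3
    return str(Seq(cds[:usable]).translate())


def read_gene_order(path: str | Path):
    """Read a tab-separated gene-order table into a :class:`~famcurate.synteny.GeneOrder`.

    Columns: contig, start, end, strand, gene id.  Coordinates are 1-based
    inclusive; genes are ranked 0-based along each contig by start.
    """
    from .synteny import GeneOrder  # local import avoids a cycle at module load

    per_contig: dict[str, list[tuple[int, str]]] = {}
    seen: set[str] = set()
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise FormatError(f"{path}: line {lineno}: expected 5 columns")
            contig, start, end, strand, gene = fields[:5]
            try:
                s, e = int(start), int(end)
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-numeric coordinates {start!r}/{end!r}"
                ) from None
            if s > e:
                raise FormatError(f"{path}: line {lineno}: start > end")
            if gene in seen:
                raise FormatError(f"{path}: line {lineno}: duplicate gene id {gene!r}")
            seen.add(gene)
            per_contig.setdefault(contig, []).append((s, gene))
    contigs = {
        contig: [g for _, g in sorted(entries)]
        for contig, entries in per_contig.items()
    }
    return GeneOrder(contigs)
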