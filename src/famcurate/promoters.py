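"""Promoter extraction and cis-regulatory element counting.

Promoters are taken as the 1.5 kb immediately upstream of each gene's
transcription start site (TSS), reverse-complemented for minus-strand
genes so that scanning always reads away from the gene.  Cis-elements
(e.g. the AuxRE auxin-response core, or type-B ARR binding sites) are
matched as IUPAC consensus patterns on both strands of the promoter, and
overlapping sites of the same motif are counted only once: hits whose
footprints share at least one promoter position (either strand) collapse
into a single cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from Bio.Seq import Seq

from .motifs import MotifHit

__all__ = [
    "DnaMotif",
    "PromoterRegion",
    "MotifCountRow",
    "extract_upstream",
    "scan_dna_motif",
    "count_once",
    "presence_matrix",
    "load_dna_library",
    "default_dna_library",
    "IUPAC",
]

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"), "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
               "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D",
               "N": "N"}


@dataclass(frozen=True)
class DnaMotif:
    """A named IUPAC consensus pattern for a cis-regulatory element."""

    name: str
    consensus: str

    def __post_init__(self) -> None:
        bad = set(self.consensus.upper()) - set(IUPAC)
        if bad:
            raise ValueError(
                f"motif {self.name!r}: non-IUPAC characters {sorted(bad)}"
            )

    @property
    def positions(self) -> list[frozenset[str]]:
        return [IUPAC[c] for c in self.consensus.upper()]

    @property
    def reverse_positions(self) -> list[frozenset[str]]:
        rc = "".join(_COMPLEMENT[c] for c in reversed(self.consensus.upper()))
        return [IUPAC[c] for c in rc]

    def __len__(self) -> int:
        return len(self.consensus)


@dataclass(frozen=True)
class PromoterRegion:
    """A strand-aware upstream region.

    ``interval`` is the 1-based inclusive genomic span on ``contig``;
    ``sequence`` reads 5'->3' away from the TSS (reverse-complemented for
    minus-strand genes).  ``truncated`` marks clipping at contig bounds.
    """

    gene: str
    contig: str
    interval: tuple[int, int]
    strand: str
    sequence: str
    truncated: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.interval
        if len(self.sequence) != hi - lo + 1:
            raise ValueError(
                f"promoter {self.gene!r}: sequence length {len(self.sequence)} "
                f"does not match interval {self.interval}"
            )
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class MotifCountRow:
    gene: str
    motif: str
    raw_count: int
    deduplicated_count: int
    present: bool

    def __post_init__(self) -> None:
        if self.deduplicated_count > self.raw_count:
            raise ValueError("deduplicated count cannot exceed raw count")
        if self.present != (self.deduplicated_count >= 1):
            raise ValueError("presence flag inconsistent with deduplicated count")


def extract_upstream(
    genome: Mapping[str, str],
    tss: Mapping[str, tuple[str, int, str]],
    length: int = 1500,
) -> list[PromoterRegion]:
    """Extract the ``length`` bp upstream of each TSS (1-based positions).

    Plus-strand genes take [TSS-length, TSS-1]; minus-strand genes take
    [TSS+1, TSS+length] reverse-complemented.  Regions are clipped at
    contig bounds and flagged truncated.
    """
    regions: list[PromoterRegion] = []
    for gene, (contig, pos, strand) in tss.items():
        if contig not in genome:
            raise KeyError(f"gene {gene!r}: contig {contig!r} not in genome")
        contig_seq = genome[contig].upper()
        n = len(contig_seq)
        if not 1 <= pos <= n:
            raise ValueError(f"gene {gene!r}: TSS {pos} outside contig of length {n}")
        if strand == "+":
            lo, hi = pos - length, pos - 1
        elif strand == "-":
            lo, hi = pos + 1, pos + length
        else:
            raise ValueError(f"gene {gene!r}: bad strand {strand!r}")
        truncated = lo < 1 or hi > n
        lo, hi = max(1, lo), min(n, hi)
        if hi < lo:
            raise ValueError(f"gene {gene!r}: no upstream sequence inside the contig")
        seq = contig_seq[lo - 1 : hi]
        if strand == "-":
            seq = str(Seq(seq).reverse_complement())
        regions.append(PromoterRegion(gene, contig, (lo, hi), strand, seq, truncated))
    return regions


def _scan_positions(seq: str, positions: list[frozenset[str]]) -> list[int]:
    n, k = len(seq), len(positions)
    if n < k:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    ok = np.ones(n - k + 1, dtype=bool)
    for j, allowed in enumerate(positions):
        ok &= np.isin(arr[j : j + n - k + 1], [c.encode("ascii") for c in allowed])
    return [int(i) for i in np.flatnonzero(ok)]


def scan_dna_motif(region: PromoterRegion, motif: DnaMotif) -> list[MotifHit]:
    """All matches of a motif on both strands of a promoter.

    Coordinates are promoter-local (0-based half-open on the extracted
    sequence), ordered by start; reverse-strand hits carry strand '-'.
    """
    seq = region.sequence
    k = len(motif)
    hits = [
        MotifHit(motif.name, region.gene, (i, i + k), seq[i : i + k], "+")
        for i in _scan_positions(seq, motif.positions)
    ]
    hits += [
        MotifHit(motif.name, region.gene, (i, i + k), seq[i : i + k], "-")
        for i in _scan_positions(seq, motif.reverse_positions)
    ]
    hits.sort(key=lambda h: (h.span, h.strand))
    return hits


def count_once(hits: Sequence[MotifHit]) -> int:
    """Number of non-overlapping site clusters for one (gene, motif) pair.

    Hits whose footprints share at least one position — regardless of
    strand — are merged into a single cluster; the result is invariant to
    the input order of hits.
    """
    if not hits:
        return 0
    spans = sorted(h.span for h in hits)
    clusters = 1
    _, end = spans[0]
    for lo, hi in spans[1:]:
        if lo >= end:  # half-open: touching intervals share no position
            clusters += 1
            end = hi
        else:
            end = max(end, hi)
    return clusters


def presence_matrix(
    regions: Sequence[PromoterRegion],
    motifs: Sequence[DnaMotif],
) -> list[MotifCountRow]:
    """Per-gene, per-motif raw and deduplicated counts plus a presence flag."""
    if not regions or not motifs:
        raise ValueError("regions and motifs must be non-empty")
    rows: list[MotifCountRow] = []
    for region in regions:
        for motif in motifs:
            hits = scan_dna_motif(region, motif)
            dedup = count_once(hits)
            rows.append(
                MotifCountRow(region.gene, motif.name, len(hits), dedup, dedup >= 1)
            )
    return rows


def load_dna_library(path: str | Path) -> list[DnaMotif]:
    """Load a cis-element library from YAML (list of {name, consensus})."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, list) or not data:
        raise ValueError(f"{path}: cis-element library must be a non-empty list")
    return [DnaMotif(e["name"], e["consensus"]) for e in data]


def default_dna_library() -> list[DnaMotif]:
    """The shipped cis-element consensus placeholders (``data/cis_elements.yaml``)."""
    ref = resources.files("famcurate.data").joinpath("cis_elements.yaml")
    with resources.as_file(ref) as path:
        return load_dna_library(path)
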