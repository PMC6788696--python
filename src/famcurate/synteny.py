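"""Windowed microsynteny scoring between two gene orders.

Synteny is assessed on ranked gene lists: for an anchor gene, a vicinity
window of the anchor plus its 20 upstream and 20 downstream neighbours
(41 genes, truncated at contig ends) is compared against candidate
windows in a target genome.  The **syntenic score** of a window pair is
the number of target-window genes with at least one homolog in the query
window (each target gene counted once, which keeps tandem paralogs from
inflating the score); a score of at least 4 calls the region syntenic.
A syntenic region lacking a homolog of the anchor gene itself is flagged
a **syntenic proxy** — the anchor was lost there, but its neighbourhood
survives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "GeneOrder",
    "HomologyMap",
    "SyntenyCall",
    "extract_window",
    "syntenic_score",
    "call_synteny",
    "find_syntenic_regions",
]

DEFAULT_WINDOW = 20
DEFAULT_THRESHOLD = 4


@dataclass
class GeneOrder:
    """Ordered gene lists per contig, with a gene -> (contig, rank) index."""

    contigs: dict[str, list[str]]
    index: dict[str, tuple[str, int]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.index = {}
        for contig, genes in self.contigs.items():
            for rank, gene in enumerate(genes):
                if gene in self.index:
                    raise ValueError(f"gene {gene!r} appears more than once")
                self.index[gene] = (contig, rank)

    def locate(self, gene: str) -> tuple[str, int]:
        try:
            return self.index[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not present in gene order") from None

    @property
    def genes(self) -> set[str]:
        return set(self.index)


class HomologyMap:
    """A symmetric, irreflexive homology relation over gene ids."""

    def __init__(self, pairs: Iterable[tuple[str, str]] = ()):
        self._adj: dict[str, set[str]] = {}
        for a, b in pairs:
            self.add(a, b)

    def add(self, a: str, b: str) -> None:
        if a == b:
            raise ValueError(f"homology relation is irreflexive; got ({a!r}, {a!r})")
        self._adj.setdefault(a, set()).add(b)
        self._adj.setdefault(b, set()).add(a)

    def homologs(self, gene: str) -> set[str]:
        return self._adj.get(gene, set())

    def are_homologs(self, a: str, b: str) -> bool:
        return b in self._adj.get(a, ())

    def __len__(self) -> int:
        return sum(len(v) for v in self._adj.values()) // 2

    @classmethod
    def from_tsv(cls, path) -> "HomologyMap":
        """Read gene pairs from a two-column TSV."""
        hm = cls()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                a, b = line.split("\t")[:2]
                if not hm.are_homologs(a, b):
                    hm.add(a, b)
        return hm


@dataclass(frozen=True)
class SyntenyCall:
    anchor: str
    target_contig: str
    target_span: tuple[int, int]  # rank span, 0-based half-open
    score: int
    is_syntenic: bool
    is_proxy: bool

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("syntenic score must be non-negative")
        if self.is_proxy and not self.is_syntenic:
            raise ValueError("a proxy call must be syntenic")


def extract_window(
    order: GeneOrder,
    anchor: str,
    up: int = DEFAULT_WINDOW,
    down: int = DEFAULT_WINDOW,
) -> list[str]:
    """The anchor gene plus its ``up``/``down`` rank neighbours, truncated at contig ends."""
    contig, rank = order.locate(anchor)
    genes = order.contigs[contig]
    lo = max(0, rank - up)
    hi = min(len(genes), rank + down + 1)
    return genes[lo:hi]


def syntenic_score(
    query_window: Sequence[str],
    target_window: Sequence[str],
    homology: HomologyMap,
) -> int:
    """Number of target-window genes with >= 1 homolog in the query window."""
    if not query_window or not target_window:
        raise ValueError("windows must be non-empty")
    qset = set(query_window)
    return sum(1 for t in target_window if homology.homologs(t) & qset)


def call_synteny(score: int, threshold: int = DEFAULT_THRESHOLD) -> bool:
    """True iff ``score >= threshold`` (default 4)."""
    if score < 0:
        raise ValueError("score must be non-negative")
    return score >= threshold


def find_syntenic_regions(
    anchor: str,
    query_order: GeneOrder,
    target_order: GeneOrder,
    homology: HomologyMap,
    up: int = DEFAULT_WINDOW,
    down: int = DEFAULT_WINDOW,
    threshold: int = DEFAULT_THRESHOLD,
) -> list[SyntenyCall]:
    """Syntenic target regions for one anchor gene.

    Candidate windows are centred on every target gene homologous to any
    gene of the anchor's query window, scored with
    :func:`syntenic_score`, and kept when the score reaches the
    threshold.  Overlapping candidate windows on the same contig are
    merged, keeping the best-scoring one (leftmost on ties).  A call is a
    proxy when the winning window holds no homolog of the anchor itself.
    """
    qwin = extract_window(query_order, anchor, up, down)
    qset = set(qwin)
    centers: set[str] = set()
    for g in qwin:
        centers |= homology.homologs(g) & target_order.genes
    anchor_homs = homology.homologs(anchor)

    candidates: list[SyntenyCall] = []
    for center in sorted(centers):
        contig, rank = target_order.locate(center)
        genes = target_order.contigs[contig]
        lo = max(0, rank - up)
        hi = min(len(genes), rank + down + 1)
        twin = genes[lo:hi]
        score = syntenic_score(qwin, twin, homology)
        if not call_synteny(score, threshold):
            continue
        proxy = not any(t in anchor_homs for t in twin)
        candidates.append(SyntenyCall(anchor, contig, (lo, hi), score, True, proxy))

    # merge overlapping windows per contig, keep max score (leftmost on ties)
    merged: list[SyntenyCall] = []
    by_contig: dict[str, list[SyntenyCall]] = {}
    for c in candidates:
        by_contig.setdefault(c.target_contig, []).append(c)
    for contig in sorted(by_contig):
        calls = sorted(by_contig[contig], key=lambda c: c.target_span)
        cluster: list[SyntenyCall] = []
        cluster_end = -1
        for c in calls:
            if cluster and c.target_span[0] < cluster_end:
                cluster.append(c)
                cluster_end = max(cluster_end, c.target_span[1])
            else:
                if cluster:
                    merged.append(max(cluster, key=lambda c: (c.score, -c.target_span[0])))
                cluster = [c]
                cluster_end = c.target_span[1]
        if cluster:
            merged.append(max(cluster, key=lambda c: (c.score, -c.target_span[0])))
    return merged
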