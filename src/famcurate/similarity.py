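"""Desk-scale homolog retrieval by optimal local alignment.

Replaces a heuristic BLAST stage for small query/database sets: every
query is Smith-Waterman-aligned (affine gaps, BLOSUM62 by default) against
every database sequence and hits are kept when their Karlin-Altschul
E-value passes a cutoff (default 1e-5, inclusive).

The gap convention is BLAST-like: a gap run of length *k* costs
``gap_open + k * gap_extend``.  E-values use the ungapped formula
``E = K * m * n * exp(-lambda * S)`` with documented ungapped-BLOSUM62
defaults for K and lambda; no on-the-fly parameter estimation is done.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import SequenceRecord, translate_cds

__all__ = [
    "ScoringScheme",
    "HomologyHit",
    "local_align",
    "evalue",
    "search_homologs",
    "write_hits_tsv",
]

# Published Karlin-Altschul parameters for ungapped BLOSUM62.
_UNGAPPED_BLOSUM62_K = 0.134
_UNGAPPED_BLOSUM62_LAMBDA = 0.3176


@lru_cache(maxsize=8)
def _load_matrix(name: str):
    return substitution_matrices.load(name)


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties and E-value parameters.

    ``gap_open`` is the gap-existence cost and ``gap_extend`` the
    per-residue cost, so a gap of length k costs ``gap_open + k*gap_extend``.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    karlin_k: float = _UNGAPPED_BLOSUM62_K
    karlin_lambda: float = _UNGAPPED_BLOSUM62_LAMBDA

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.karlin_k <= 0 or self.karlin_lambda <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")

    @property
    def matrix(self):
        return _load_matrix(self.matrix_name)

    @property
    def alphabet(self) -> str:
        return str(self.matrix.alphabet)

    def score_pair(self, a: str, b: str) -> int:
        return int(self.matrix[a, b])

    def _aligner(self, mode: str) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = self.matrix
        aligner.mode = mode
        # PairwiseAligner charges open on the first gapped position only.
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner


DEFAULT_SCHEME = ScoringScheme()


@dataclass(frozen=True)
class HomologyHit:
    """A best local alignment between one query and one subject."""

    query_id: str
    subject_id: str
    score: int
    evalue: float
    query_span: tuple[int, int]  # 0-based half-open
    subject_span: tuple[int, int]

    def __post_init__(self) -> None:
        if self.score < 0 or self.evalue < 0:
            raise ValueError("score and evalue must be non-negative")


def _check_alphabet(seq: str, scheme: ScoringScheme) -> None:
    bad = set(seq) - set(scheme.alphabet)
    if bad:
        raise ValueError(
            f"residues {sorted(bad)} are outside the {scheme.matrix_name} alphabet"
        )


def local_align(
    a: str, b: str, scheme: ScoringScheme = DEFAULT_SCHEME
) -> tuple[int, tuple[int, int], tuple[int, int]]:
    """Optimal Smith-Waterman local alignment score and spans.

    Returns ``(score, a_span, b_span)`` with 0-based half-open spans that
    achieve the score.  When no alignment scores above zero (all pairwise
    substitution scores negative) the score is 0 with empty spans.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    _check_alphabet(a, scheme)
    _check_alphabet(b, scheme)
    aligner = scheme._aligner("local")
    score = aligner.score(a, b)
    if score <= 0:
        return 0, (0, 0), (0, 0)
    aln = next(iter(aligner.align(a, b)))
    a_blocks, b_blocks = aln.aligned
    a_span = (int(a_blocks[0][0]), int(a_blocks[-1][1]))
    b_span = (int(b_blocks[0][0]), int(b_blocks[-1][1]))
    return int(score), a_span, b_span


def evalue(score: int, m: int, n: int, scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """Karlin-Altschul expected number of chance hits at or above ``score``.

    ``E = K * m * n * exp(-lambda * score)`` for query length *m* against a
    database of *n* total residues; strictly decreasing in score.
    """
    if m < 1 or n < 1:
        raise ValueError("sequence lengths must be >= 1")
    return scheme.karlin_k * m * n * math.exp(-scheme.karlin_lambda * score)


def search_homologs(
    queries: Sequence[SequenceRecord],
    database: Sequence[SequenceRecord],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    cutoff: float = 1e-5,
    translate: bool = False,
) -> list[HomologyHit]:
    """All-vs-all local-alignment search with an E-value cutoff.

    Reports every (query, subject) pair whose best local alignment has
    ``evalue <= cutoff`` (inclusive, matching a pass-at-threshold reading
    of the cutoff), one hit per pair.  ``translate=True`` translates a CDS
    database to protein first.  An empty database yields an empty result.
    """
    if translate:
        database = [
            SequenceRecord(r.id, translate_cds(r.residues), r.taxon, r.source)
            for r in database
        ]
    n_db = sum(len(r) for r in database)
    hits: list[HomologyHit] = []
    for q in queries:
        for s in database:
            score, q_span, s_span = local_align(q.residues, s.residues, scheme)
            if score == 0:
                continue
            e = evalue(score, len(q), n_db, scheme)
            if e <= cutoff:
                hits.append(HomologyHit(q.id, s.id, score, e, q_span, s_span))
    return hits


def write_hits_tsv(hits: Iterable[HomologyHit], path) -> None:
    """Write hits as TSV: query, subject, score, evalue, qstart, qend, sstart, send."""
    with open(path, "w") as fh:
        fh.write("query\tsubject\tscore\tevalue\tqstart\tqend\tsstart\tsend\n")
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.score}\t{h.evalue:.3g}\t"
                f"{h.query_span[0]}\t{h.query_span[1]}\t"
                f"{h.subject_span[0]}\t{h.subject_span[1]}\n"
            )
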