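"""Iterative alignment-occupancy curation of a gene family to a fixed point.

Large homolog sets assembled from mixed genome and transcriptome sources
are dominated by fragmentary sequences.  The curation loop implemented
here alternates alignment with two occupancy filters until it reaches a
fixed point:

1. **Column filter** — aligned columns with *more than* a configured
   fraction of missing data (gap symbols; default 50%) are removed.
2. **Sequence filter** — sequences retaining *fewer than* a configured
   fraction of the column-filtered alignment length in actual residues
   (default one half) are removed.

The surviving sequences are degapped and realigned, and the procedure
repeats until an iteration removes no sequences.  Because every iteration
can only shrink the sequence set, the loop always terminates.

The aligner is pluggable: any callable mapping a list of
:class:`~famcurate.seqio.SequenceRecord` to an
:class:`~famcurate.seqio.Alignment` whose degapped rows equal its input
may be used.  The built-in default is a progressive aligner (3-mer
distances, neighbor-joining guide tree, profile-profile merge).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .seqio import GAP, Alignment, SequenceRecord
from .similarity import DEFAULT_SCHEME, ScoringScheme

__all__ = [
    "FilterConfig",
    "IterationLog",
    "CurationResult",
    "DegenerateCurationError",
    "length_prefilter",
    "global_align_pair",
    "kmer_distance",
    "nj_tree",
    "progressive_align",
    "filter_columns",
    "filter_sequences",
    "curate_to_fixed_point",
    "gap_fraction",
    "root_with_outgroup",
]


class DegenerateCurationError(ValueError):
    """All columns or all sequences were removed by a filter pass."""


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the length prefilter and the two occupancy filters.

    Defaults follow the study conditions: protein lengths 120–971 aa
    (inclusive), columns dropped above 50% missing, sequences dropped
    below half of the alignment length, and a safety bound of 20
    iterations on the fixed-point loop.
    """

    min_length: int = 120
    max_length: int = 971
    max_column_missing: float = 0.5
    min_sequence_fraction: float = 0.5
    max_iterations: int = 20

    def __post_init__(self) -> None:
        if self.min_length > self.max_length:
            raise ValueError("min_length must be <= max_length")
        for frac in (self.max_column_missing, self.min_sequence_fraction):
            if not 0 < frac < 1:
                raise ValueError("fractions must lie strictly between 0 and 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass(frozen=True)
class IterationLog:
    iteration: int
    n_seqs_in: int
    n_cols_removed: int
    n_seqs_removed: int


@dataclass
class CurationResult:
    """Final alignment plus the audit trail of the fixed-point loop."""

    alignment: Alignment
    iterations: list[IterationLog]
    converged: bool
    gap_fraction: float


def length_prefilter(
    seqs: Sequence[SequenceRecord], cfg: FilterConfig = FilterConfig()
) -> list[SequenceRecord]:
    """Keep sequences with min_length <= len <= max_length (both inclusive)."""
    return [s for s in seqs if cfg.min_length <= len(s) <= cfg.max_length]


# ---------------------------------------------------------------------------
# pairwise and progressive alignment


def global_align_pair(
    a: str, b: str, scheme: ScoringScheme = DEFAULT_SCHEME, ids: tuple[str, str] = ("a", "b")
) -> Alignment:
    """Optimal Needleman-Wunsch global alignment with affine gaps."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    for seq in (a, b):
        bad = set(seq) - set(scheme.alphabet)
        if bad:
            raise ValueError(f"residues {sorted(bad)} outside the matrix alphabet")
    aligner = scheme._aligner("global")
    aln = next(iter(aligner.align(a, b)))
    return Alignment([(ids[0], str(aln[0])), (ids[1], str(aln[1]))])


def kmer_distance(a: str, b: str, k: int = 3) -> float:
    """1 minus the shared k-mer fraction (shared / smaller set size)."""
    ka = {a[i : i + k] for i in range(len(a) - k + 1)} or {a}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)} or {b}
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def nj_tree(d: np.ndarray | Sequence[Sequence[float]], labels: Sequence[str]) -> TreeNode:
    """Neighbor-joining tree from a symmetric distance matrix.

    On additive matrices the returned topology matches the generating tree.
    """
    d = np.asarray(d, dtype=float)
    if d.shape[0] != d.shape[1] or d.shape[0] != len(labels):
        raise ValueError("matrix must be square and match the label count")
    if d.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    if np.any(np.diag(d) != 0):
        raise ValueError("distance matrix diagonal must be zero")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    return nj(DistanceMatrix(d, list(labels)))


_GAP_VS_RESIDUE = -4.0  # profile column score against a gap, linear gap model


def _profile_align(
    p: list[tuple[str, str]], q: list[tuple[str, str]], scheme: ScoringScheme
) -> list[tuple[str, str]]:
    """Needleman-Wunsch on two profiles with mean-of-pairs column scoring."""
    mat = scheme.matrix
    alpha = scheme.alphabet
    idx = {c: i for i, c in enumerate(alpha)}
    n_alpha = len(alpha)

    def columns(rows: list[tuple[str, str]]) -> np.ndarray:
        # frequency vector per column; last slot counts gaps
        length = len(rows[0][1])
        freq = np.zeros((length, n_alpha + 1))
        for _, seq in rows:
            for j, c in enumerate(seq):
                freq[j, idx.get(c, idx.get("X", 0)) if c != GAP else n_alpha] += 1
        return freq / len(rows)

    sub = np.zeros((n_alpha + 1, n_alpha + 1))
    for i, ci in enumerate(alpha):
        for j, cj in enumerate(alpha):
            sub[i, j] = mat[ci, cj]
    sub[n_alpha, :] = _GAP_VS_RESIDUE
    sub[:, n_alpha] = _GAP_VS_RESIDUE
    sub[n_alpha, n_alpha] = 0.0

    fp, fq = columns(p), columns(q)
    m, n = fp.shape[0], fq.shape[0]
    pair = fp @ sub @ fq.T  # (m, n) expected column-vs-column score
    gap_col = _GAP_VS_RESIDUE

    score = np.full((m + 1, n + 1), -np.inf)
    ptr = np.zeros((m + 1, n + 1), dtype=np.int8)  # 0 diag, 1 up (gap in q), 2 left
    score[0, 0] = 0.0
    score[1:, 0] = gap_col * np.arange(1, m + 1)
    score[0, 1:] = gap_col * np.arange(1, n + 1)
    ptr[1:, 0] = 1
    ptr[0, 1:] = 2
    for i in range(1, m + 1):
        diag = score[i - 1, : n] + pair[i - 1, :]
        up = score[i - 1, 1:] + gap_col
        prev = score[i, : n]  # filled progressively for the left move
        row = score[i]
        for j in range(1, n + 1):
            best, move = diag[j - 1], 0
            if up[j - 1] > best:
                best, move = up[j - 1], 1
            left = row[j - 1] + gap_col
            if left > best:
                best, move = left, 2
            row[j] = best
            ptr[i, j] = move

    # traceback
    i, j = m, n
    ops: list[int] = []
    while i > 0 or j > 0:
        move = ptr[i, j]
        ops.append(move)
        if move == 0:
            i, j = i - 1, j - 1
        elif move == 1:
            i -= 1
        else:
            j -= 1
    ops.reverse()

    out: list[tuple[str, list[str]]] = [(rid, []) for rid, _ in p] + [
        (rid, []) for rid, _ in q
    ]
    np_rows = len(p)
    pi = qi = 0
    for move in ops:
        take_p = move in (0, 1)
        take_q = move in (0, 2)
        for r, (rid, buf) in enumerate(out):
            if r < np_rows:
                buf.append(p[r][1][pi] if take_p else GAP)
            else:
                buf.append(q[r - np_rows][1][qi] if take_q else GAP)
        if take_p:
            pi += 1
        if take_q:
            qi += 1
    return [(rid, "".join(buf)) for rid, buf in out]


def progressive_align(
    seqs: Sequence[SequenceRecord], scheme: ScoringScheme = DEFAULT_SCHEME
) -> Alignment:
    """Progressive multiple alignment along a neighbor-joining guide tree.

    Pairwise 3-mer distances feed :func:`nj_tree`; profiles are merged
    leaf-to-root with :func:`_profile_align`.  Row order follows the input
    order, and degapping the result recovers the input sequences exactly
    (the merge only ever inserts gap columns).
    """
    seqs = list(seqs)
    if not seqs:
        raise ValueError("no sequences to align")
    if len(seqs) == 1:
        return Alignment([(seqs[0].id, seqs[0].residues)])
    by_id = {s.id: s for s in seqs}
    if len(by_id) != len(seqs):
        raise ValueError("sequence ids must be unique")
    if len(seqs) == 2:
        a, b = seqs
        return global_align_pair(a.residues, b.residues, scheme, ids=(a.id, b.id))

    ids = [s.id for s in seqs]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = kmer_distance(seqs[i].residues, seqs[j].residues)
    guide = nj_tree(d, ids)

    def merge(node: TreeNode) -> list[tuple[str, str]]:
        if node.is_tip():
            rec = by_id[node.name]
            return [(rec.id, rec.residues)]
        profiles = [merge(child) for child in node.children]
        acc = profiles[0]
        for prof in profiles[1:]:
            acc = _profile_align(acc, prof, scheme)
        return acc

    rows = dict(merge(guide))
    return Alignment([(rid, rows[rid]) for rid in ids])


# ---------------------------------------------------------------------------
# occupancy filters and the fixed-point loop


def _matrix(aln: Alignment) -> np.ndarray:
    return np.array([list(seq) for _, seq in aln.rows])


def filter_columns(
    aln: Alignment, cfg: FilterConfig = FilterConfig()
) -> tuple[Alignment, list[int]]:
    """Drop columns whose missing-data fraction strictly exceeds the threshold.

    Missing means the gap symbol; 'X' counts as present.  A column with a
    missing fraction exactly at the threshold is retained.
    """
    m = _matrix(aln)
    missing_frac = (m == aln.gap).mean(axis=0)
    removed = np.flatnonzero(missing_frac > cfg.max_column_missing)
    if len(removed) == aln.length:
        raise DegenerateCurationError("column filter removed every column")
    if len(removed) == 0:
        return aln, []
    keep = np.flatnonzero(missing_frac <= cfg.max_column_missing)
    rows = [(rid, "".join(m[i, keep])) for i, (rid, _) in enumerate(aln.rows)]
    return Alignment(rows, aln.gap), [int(c) for c in removed]


def filter_sequences(
    aln: Alignment, cfg: FilterConfig = FilterConfig()
) -> tuple[Alignment, list[str]]:
    """Drop rows with fewer residues than the fraction of the alignment length.

    A row is removed iff its non-gap count is *strictly less than*
    ``min_sequence_fraction * alignment_length``, measured on the
    column-filtered alignment.
    """
    m = _matrix(aln)
    residues = (m != aln.gap).sum(axis=1)
    threshold = cfg.min_sequence_fraction * aln.length
    removed = [aln.rows[i][0] for i in np.flatnonzero(residues < threshold)]
    if len(removed) == aln.n_rows:
        raise DegenerateCurationError("sequence filter removed every sequence")
    if not removed:
        return aln, []
    gone = set(removed)
    rows = [(rid, seq) for rid, seq in aln.rows if rid not in gone]
    return Alignment(rows, aln.gap), removed


Aligner = Callable[[Sequence[SequenceRecord]], Alignment]


def curate_to_fixed_point(
    seqs: Sequence[SequenceRecord],
    aligner: Aligner | None = None,
    cfg: FilterConfig = FilterConfig(),
) -> CurationResult:
    """Alternate alignment and occupancy filtering until nothing is removed.

    Each iteration realigns the degapped surviving set from scratch, then
    applies :func:`filter_columns` and :func:`filter_sequences`.  The loop
    stops when an iteration removes zero sequences (``converged=True``) or
    after ``cfg.max_iterations`` iterations (``converged=False``).  The
    result is a fixed point of the filter pair: when converged, one
    further filter pass removes nothing.
    """
    if aligner is None:
        aligner = progressive_align
    current = list(seqs)
    if len(current) < 2:
        raise ValueError("curation needs at least 2 sequences")
    log: list[IterationLog] = []
    final: Alignment | None = None
    converged = False
    for it in range(1, cfg.max_iterations + 1):
        try:
            aln = aligner(current)
            aln, removed_cols = filter_columns(aln, cfg)
            aln, removed_ids = filter_sequences(aln, cfg)
        except DegenerateCurationError as exc:
            raise DegenerateCurationError(f"iteration {it}: {exc}") from exc
        log.append(IterationLog(it, len(current), len(removed_cols), len(removed_ids)))
        final = aln
        current = aln.degap()
        if not removed_ids:
            converged = True
            break
    assert final is not None
    return CurationResult(final, log, converged, gap_fraction(final))


def gap_fraction(aln: Alignment) -> float:
    """Fraction of gap characters in the alignment matrix, in [0, 1]."""
    m = _matrix(aln)
    return float((m == aln.gap).mean())


def format_gap_percent(fraction: float) -> str:
    return f"{100 * fraction:.2f}%"


# ---------------------------------------------------------------------------
# tree utilities


def root_with_outgroup(tree: TreeNode, outgroup: Sequence[str]) -> TreeNode:
    """Root a tree on the branch separating the outgroup from the ingroup.

    Raises ``ValueError`` when the outgroup is not monophyletic in the
    unrooted tree, listing the smallest clade that contains it.
    """
    outgroup = list(outgroup)
    tips = {t.name for t in tree.tips()}
    missing = set(outgroup) - tips
    if missing:
        raise ValueError(f"outgroup labels not in tree: {sorted(missing)}")
    if set(outgroup) == tips:
        raise ValueError("outgroup cannot contain every leaf")
    try:
        return tree.root_by_outgroup(outgroup)
    except Exception:
        lca = tree.lca(outgroup) if len(outgroup) > 1 else tree.find(outgroup[0])
        clade = sorted(t.name for t in lca.tips()) if not lca.is_tip() else [lca.name]
        raise ValueError(
            "outgroup is not monophyletic: smallest containing clade is "
            f"{clade} versus requested {sorted(outgroup)}"
        ) from None
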