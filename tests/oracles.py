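"""Independent oracles used by the test suite.

These deliberately avoid the library's implementation paths: alignment
scores come from a memoised exhaustive recursion over edit operations,
and the curation loop from a plain-Python replay of the filter rules.
"""

from __future__ import annotations

from functools import lru_cache


def oracle_global_score(a: str, b: str, scheme) -> int:
    """Max global alignment score by exhaustive recursion over operations.

    A gap run of length k costs gap_open + k*gap_extend.
    """
    mat = scheme.matrix
    go, ge = scheme.gap_open, scheme.gap_extend
    m, n = len(a), len(b)

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, last: str) -> float:
        if i == m and j == n:
            return 0.0
        best = float("-inf")
        if i < m and j < n:
            best = max(best, mat[a[i], b[j]] + rec(i + 1, j + 1, "m"))
        if i < m:
            cost = ge if last == "d" else go + ge
            best = max(best, -cost + rec(i + 1, j, "d"))
        if j < n:
            cost = ge if last == "i" else go + ge
            best = max(best, -cost + rec(i, j + 1, "i"))
        return best

    return int(rec(0, 0, "s"))


def oracle_local_score(a: str, b: str, scheme) -> int:
    """Max local alignment score: best suffix alignment over all start pairs."""
    mat = scheme.matrix
    go, ge = scheme.gap_open, scheme.gap_extend
    m, n = len(a), len(b)

    @lru_cache(maxsize=None)
    def ext(i: int, j: int, last: str) -> float:
        # best score of an alignment starting at (i, j); may end at any point
        best = 0.0
        if i < m and j < n:
            best = max(best, mat[a[i], b[j]] + ext(i + 1, j + 1, "m"))
        if i < m:
            cost = ge if last == "d" else go + ge
            best = max(best, -cost + ext(i + 1, j, "d"))
        if j < n:
            cost = ge if last == "i" else go + ge
            best = max(best, -cost + ext(i, j + 1, "i"))
        return best

    return int(
        max(ext(i, j, "s") for i in range(m + 1) for j in range(n + 1))
    )


def replay_filter_loop(master_rows, max_col_missing=0.5, min_seq_frac=0.5, max_iter=50):
    """Plain-Python replay of the fixed-point curation loop.

    ``master_rows`` is a list of (id, aligned string) — the fixed master
    alignment that stands in for realignment: each iteration restricts
    the master to the surviving ids (dropping columns that are all-gap
    over them), drops columns with missing fraction strictly above
    ``max_col_missing``, then rows with residue count strictly below
    ``min_seq_frac`` times the new length.  Stops when an iteration
    removes no rows.  Returns (rows, n_iterations, converged).
    """
    ids = [rid for rid, _ in master_rows]
    master = dict(master_rows)
    length = len(master_rows[0][1])
    final = None
    for it in range(1, max_iter + 1):
        rows = [(rid, master[rid]) for rid in ids]
        n = len(rows)
        occupied = [
            j for j in range(length) if any(seq[j] != "-" for _, seq in rows)
        ]
        keep_cols = []
        for j in occupied:
            gaps = sum(1 for _, seq in rows if seq[j] == "-")
            if gaps / n <= max_col_missing:
                keep_cols.append(j)
        if not keep_cols:
            raise ValueError("degenerate: all columns removed")
        rows = [(rid, "".join(seq[j] for j in keep_cols)) for rid, seq in rows]
        new_len = len(keep_cols)
        survivors = []
        for rid, seq in rows:
            residues = sum(1 for c in seq if c != "-")
            if residues >= min_seq_frac * new_len:
                survivors.append((rid, seq))
        if not survivors:
            raise ValueError("degenerate: all sequences removed")
        removed = len(rows) - len(survivors)
        ids = [rid for rid, _ in survivors]
        final = survivors
        if removed == 0:
            return final, it, True
    return final, max_iter, False


def brute_force_syntenic_score(query_window, target_window, pairs) -> int:
    """Count target genes sharing a homolog with the query window (set oracle)."""
    related = set()
    for a, b in pairs:
        related.add((a, b))
        related.add((b, a))
    count = 0
    for t in target_window:
        if any((t, q) in related for q in query_window):
            count += 1
    return count
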