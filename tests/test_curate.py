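import itertools

import numpy as np
import pytest

from famcurate.curate import (
    DegenerateCurationError,
    FilterConfig,
    curate_to_fixed_point,
    filter_columns,
    filter_sequences,
    gap_fraction,
    global_align_pair,
    kmer_distance,
    length_prefilter,
    nj_tree,
    progressive_align,
    root_with_outgroup,
)
from famcurate.seqio import Alignment, SequenceRecord
from famcurate.simulate import SimConfig, fragment_transcripts, simulate_family

from oracles import oracle_global_score, replay_filter_loop

AA = list("ACDEFGHIKLMNPQRSTVWY")


def random_alignment(rng, max_rows=12, max_cols=30, gap_p=0.35):
    n = int(rng.integers(2, max_rows + 1))
    length = int(rng.integers(2, max_cols + 1))
    rows = []
    for i in range(n):
        chars = [
            "-" if rng.random() < gap_p else str(rng.choice(AA)) for _ in range(length)
        ]
        if all(c == "-" for c in chars):
            chars[int(rng.integers(length))] = "M"
        rows.append((f"s{i}", "".join(chars)))
    return Alignment(rows)


def restriction_aligner(master: Alignment):
    """Aligner that restricts a fixed master alignment to the surviving ids.

    Satisfies the aligner contract used by the fixed-point loop for
    degapped inputs drawn from the master's rows: all-gap columns over
    the selected rows are dropped so degapping recovers the inputs.
    """

    def align(seqs):
        wanted = [s.id for s in seqs]
        rows = [(rid, master.row(rid)) for rid in wanted]
        cols = [
            j
            for j in range(master.length)
            if any(seq[j] != "-" for _, seq in rows)
        ]
        return Alignment([(rid, "".join(seq[j] for j in cols)) for rid, seq in rows])

    return align


class TestLengthPrefilter:
    def test_boundaries_inclusive(self):
        seqs = [SequenceRecord(f"s{n}", "A" * n) for n in (119, 120, 971, 972)]
        kept = length_prefilter(seqs, FilterConfig())
        assert sorted(len(s) for s in kept) == [120, 971]

    def test_empty_input(self):
        assert length_prefilter([], FilterConfig()) == []

    def test_in_range_identity(self):
        seqs = [SequenceRecord(f"s{i}", "A" * (150 + i)) for i in range(5)]
        assert length_prefilter(seqs, FilterConfig()) == seqs


class TestGlobalAlign:
    def test_identity_gapless(self, scheme):
        aln = global_align_pair("MKV", "MKV", scheme)
        assert aln.rows == [("a", "MKV"), ("b", "MKV")]

    def test_single_gap_column(self, scheme):
        aln = global_align_pair("MKV", "MV", scheme)
        assert aln.length == 3
        assert aln.rows[0][1] == "MKV"
        assert aln.rows[1][1].count("-") == 1

    def test_degap_recovers_inputs(self, scheme):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = "".join(rng.choice(AA, size=int(rng.integers(1, 15))))
            b = "".join(rng.choice(AA, size=int(rng.integers(1, 15))))
            aln = global_align_pair(a, b, scheme)
            assert aln.rows[0][1].replace("-", "") == a
            assert aln.rows[1][1].replace("-", "") == b

    def test_matches_recursion_oracle(self, scheme):
        strings = ["".join(p) for n in (1, 2, 3) for p in itertools.product("ACDW", repeat=n)]
        rng = np.random.default_rng(9)
        aligner = scheme._aligner("global")
        for _ in range(150):
            a = strings[int(rng.integers(len(strings)))]
            b = strings[int(rng.integers(len(strings)))]
            assert int(aligner.score(a, b)) == oracle_global_score(a, b, scheme)


class TestGuideTree:
    def test_three_taxa_unique_topology(self):
        t = nj_tree([[0, 2, 3], [2, 0, 3], [3, 3, 0]], ["a", "b", "c"])
        assert sorted(x.name for x in t.tips()) == ["a", "b", "c"]

    def test_additive_four_taxon_topology(self):
        # tree ((a,b),(c,d)) with internal branch 4: the four-point condition
        # d(a,b)+d(c,d) < d(a,c)+d(b,d) = d(a,d)+d(b,c) identifies the split
        d = [
            [0, 5, 9, 9],
            [5, 0, 10, 10],
            [9, 10, 0, 8],
            [9, 10, 8, 0],
        ]
        t = nj_tree(d, ["a", "b", "c", "d"])
        ab = t.lca(["a", "b"])
        assert sorted(x.name for x in ab.tips()) in (["a", "b"], ["c", "d"])

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree([[0, 1, 2], [9, 0, 3], [2, 3, 0]], ["a", "b", "c"])

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            nj_tree([[1, 1, 2], [1, 0, 3], [2, 3, 0]], ["a", "b", "c"])


class TestProgressiveAlign:
    def test_identical_sequences_gapless(self, scheme):
        seqs = [SequenceRecord(f"s{i}", "MKVLIAWGH") for i in range(4)]
        aln = progressive_align(seqs, scheme)
        assert aln.length == 9
        assert all(seq == "MKVLIAWGH" for _, seq in aln.rows)

    def test_degap_identity_random(self, scheme):
        rng = np.random.default_rng(4)
        for _ in range(5):
            seqs = [
                SequenceRecord(
                    f"s{i}", "".join(rng.choice(AA, size=int(rng.integers(10, 30))))
                )
                for i in range(int(rng.integers(2, 7)))
            ]
            aln = progressive_align(seqs, scheme)
            degapped = {r.id: r.residues for r in aln.degap()}
            for s in seqs:
                assert degapped[s.id] == s.residues

    def test_rows_in_input_order(self, scheme):
        rng = np.random.default_rng(6)
        seqs = [
            SequenceRecord(f"s{i}", "".join(rng.choice(AA, size=20))) for i in range(5)
        ]
        assert progressive_align(seqs, scheme).ids == [s.id for s in seqs]

    def test_single_sequence(self, scheme):
        aln = progressive_align([SequenceRecord("only", "MKV")], scheme)
        assert aln.rows == [("only", "MKV")]

    def test_conserved_core_columns_aligned(self, scheme):
        fam, truth = simulate_family(SimConfig(seed=8, substitution_rate=0.05))
        members = [r for r in fam if truth.clade_labels[r.id][0] == "T1"][:8]
        aln = progressive_align(members, scheme)
        # the planted HD signature occupies the same core in every member;
        # majority identity at its columns should be essentially perfect
        sig_cols = []
        anchor = truth.motif_spans[members[0].id]
        sig_span = next((s, e) for name, s, e in anchor if name == "hd_signature")
        # map residue positions to alignment columns via the first row
        row = aln.rows[0][1]
        residue_idx = -1
        for col, c in enumerate(row):
            if c != "-":
                residue_idx += 1
                if sig_span[0] <= residue_idx < sig_span[1]:
                    sig_cols.append(col)
        assert len(sig_cols) == 9
        for col in sig_cols:
            column = [seq[col] for _, seq in aln.rows]
            top = max(column.count(c) for c in set(column) if c != "-")
            assert top / len(column) >= 0.9

    def test_kmer_distance_bounds(self):
        assert kmer_distance("MKVLIA", "MKVLIA") == 0.0
        assert kmer_distance("MKVLIA", "WWWWWW") == 1.0


class TestFilterColumns:
    def test_majority_gap_column_removed(self):
        aln = Alignment([("a", "M-"), ("b", "M-"), ("c", "M-"), ("d", "MK")])
        out, removed = filter_columns(aln, FilterConfig())
        assert removed == [1]
        assert out.length == 1

    def test_exactly_half_retained(self):
        aln = Alignment([("a", "M-"), ("b", "M-"), ("c", "MK"), ("d", "MK")])
        out, removed = filter_columns(aln, FilterConfig())
        assert removed == []
        assert out.length == 2

    def test_gapless_identity(self):
        aln = Alignment([("a", "MKV"), ("b", "WGH")])
        out, removed = filter_columns(aln, FilterConfig())
        assert out is aln and removed == []

    def test_all_columns_removed_is_degenerate(self):
        aln = Alignment([("a", "--"), ("b", "--"), ("c", "MK")])
        with pytest.raises(DegenerateCurationError):
            filter_columns(aln, FilterConfig())

    def test_idempotent(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            aln = random_alignment(rng)
            try:
                once, _ = filter_columns(aln, FilterConfig())
            except DegenerateCurationError:
                continue
            twice, removed = filter_columns(once, FilterConfig())
            assert removed == [] and twice.rows == once.rows


class TestFilterSequences:
    def test_below_half_removed(self):
        # 70 residues over 145 columns: 70 < 72.5
        full = "M" * 145
        sparse = "M" * 70 + "-" * 75
        aln = Alignment([("full", full), ("sparse", sparse)])
        out, removed = filter_sequences(aln, FilterConfig())
        assert removed == ["sparse"]
        assert out.ids == ["full"]

    def test_exactly_half_retained(self):
        half = "M" * 50 + "-" * 50
        aln = Alignment([("full", "M" * 100), ("half", half)])
        out, removed = filter_sequences(aln, FilterConfig())
        assert removed == []
        assert out.n_rows == 2

    def test_gapless_all_retained(self):
        aln = Alignment([("a", "MKV"), ("b", "WGH")])
        out, removed = filter_sequences(aln, FilterConfig())
        assert removed == [] and out.n_rows == 2

    def test_all_rows_removed_is_degenerate(self):
        aln = Alignment([("a", "M---"), ("b", "-M--")])
        with pytest.raises(DegenerateCurationError):
            filter_sequences(aln, FilterConfig())

    def test_idempotent(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            aln = random_alignment(rng)
            try:
                once, _ = filter_sequences(aln, FilterConfig())
            except DegenerateCurationError:
                continue
            twice, removed = filter_sequences(once, FilterConfig())
            assert removed == [] and twice.rows == once.rows


class TestFixedPointLoop:
    def test_immediate_fixed_point(self):
        aln = Alignment([("a", "MKV"), ("b", "MKW"), ("c", "MKH")])
        seqs = aln.degap()
        res = curate_to_fixed_point(
            seqs, restriction_aligner(aln), FilterConfig(min_length=1)
        )
        assert res.converged and len(res.iterations) == 1
        assert res.alignment.rows == aln.rows

    def test_cascading_removal_needs_multiple_iterations(self):
        # iteration 1: columns 5-11 are >50% missing (fragments A and B both
        # absent) and go; on the 5 surviving columns fragment A falls below
        # half-occupancy and is removed.  Realignment without A restores the
        # full 12 columns (now only half-missing), which dooms fragment B in
        # iteration 2; iteration 3 confirms the fixed point.
        master = Alignment(
            [
                ("full", "MKVLWGHAMKVL"),
                ("fragA", "MK----------"),
                ("fragB", "MKVLW-------"),
            ]
        )
        res = curate_to_fixed_point(
            master.degap(),
            restriction_aligner(master),
            FilterConfig(min_length=1),
        )
        assert res.converged
        assert len(res.iterations) == 3
        assert res.alignment.ids == ["full"]
        # the independently coded replay agrees step for step
        rows, n_iter, converged = replay_filter_loop(master.rows)
        assert converged and n_iter == 3
        assert [rid for rid, _ in rows] == ["full"]

    def test_matches_brute_force_replay(self):
        rng = np.random.default_rng(17)
        checked = 0
        for _ in range(200):
            master = random_alignment(rng)
            impl_error = replay_error = False
            res = expected = None
            try:
                res = curate_to_fixed_point(
                    master.degap(),
                    restriction_aligner(master),
                    FilterConfig(min_length=1, max_iterations=50),
                )
            except DegenerateCurationError:
                impl_error = True
            try:
                expected = replay_filter_loop(master.rows)
            except ValueError:
                replay_error = True
            assert impl_error == replay_error
            if impl_error:
                continue
            expected_rows, n_iter, converged = expected
            assert res.converged == converged
            assert len(res.iterations) == n_iter
            assert res.alignment.rows == expected_rows
            checked += 1
        assert checked >= 50

    def test_sequence_count_monotone_nonincreasing(self):
        rng = np.random.default_rng(18)
        for _ in range(50):
            master = random_alignment(rng)
            try:
                res = curate_to_fixed_point(
                    master.degap(),
                    restriction_aligner(master),
                    FilterConfig(min_length=1, max_iterations=50),
                )
            except (DegenerateCurationError, ValueError):
                continue
            counts = [it.n_seqs_in for it in res.iterations]
            assert all(x >= y for x, y in zip(counts, counts[1:]))

    def test_output_is_fixed_point_of_filters(self):
        rng = np.random.default_rng(19)
        for _ in range(50):
            master = random_alignment(rng)
            try:
                res = curate_to_fixed_point(
                    master.degap(),
                    restriction_aligner(master),
                    FilterConfig(min_length=1, max_iterations=50),
                )
            except (DegenerateCurationError, ValueError):
                continue
            if not res.converged:
                continue
            aln1, cols = filter_columns(res.alignment, FilterConfig())
            aln2, seqs_removed = filter_sequences(aln1, FilterConfig())
            assert cols == [] and seqs_removed == []

    def test_planted_fragments_removed_full_length_kept(self, scheme):
        cfg = SimConfig(seed=21, substitution_rate=0.03, fragment_fraction=0.3,
                        fragment_length_range=(40, 80))
        fam, _ = simulate_family(cfg)
        subset = fam[:18]
        frags, truth = fragment_transcripts(subset, cfg)
        res = curate_to_fixed_point(
            frags,
            lambda s: progressive_align(s, scheme),
            FilterConfig(min_length=30),
        )
        assert res.converged
        retained = set(res.alignment.ids)
        for sid, is_frag in truth.fragments.items():
            if is_frag:
                assert sid not in retained
            else:
                assert sid in retained


class TestGapFraction:
    def test_gapless_zero(self):
        assert gap_fraction(Alignment([("a", "MK"), ("b", "VL")])) == 0.0

    def test_one_gap_in_two_by_two(self):
        assert gap_fraction(Alignment([("a", "M-"), ("b", "VL")])) == 0.25


class TestRooting:
    def _tree(self):
        # ((a,b),(c,d)) unrooted with an obvious outgroup pendant
        d = np.array(
            [
                [0, 2, 7, 7, 12],
                [2, 0, 7, 7, 12],
                [7, 7, 0, 2, 9],
                [7, 7, 2, 0, 9],
                [12, 12, 9, 9, 0],
            ],
            dtype=float,
        )
        return nj_tree(d, ["a", "b", "c", "d", "out"])

    @staticmethod
    def _leafset(node):
        return [node.name] if node.is_tip() else sorted(t.name for t in node.tips())

    def test_single_leaf_outgroup(self):
        rooted = root_with_outgroup(self._tree(), ["out"])
        assert len(rooted.children) == 2
        sides = [self._leafset(child) for child in rooted.children]
        assert ["out"] in sides
        ingroup = next(s for s in sides if s != ["out"])
        assert ingroup == ["a", "b", "c", "d"]

    def test_outgroup_cannot_be_everything(self):
        with pytest.raises(ValueError, match="every leaf"):
            root_with_outgroup(self._tree(), ["a", "b", "c", "d", "out"])

    def test_missing_label_rejected(self):
        with pytest.raises(ValueError, match="not in tree"):
            root_with_outgroup(self._tree(), ["nope"])

    def test_non_monophyletic_outgroup_rejected(self):
        with pytest.raises(ValueError, match="not monophyletic"):
            root_with_outgroup(self._tree(), ["a", "c"])

    def test_ingroup_clades_monophyletic_after_rooting(self):
        rooted = root_with_outgroup(self._tree(), ["out"])
        ab = rooted.lca(["a", "b"])
        assert sorted(t.name for t in ab.tips()) == ["a", "b"]
        cd = rooted.lca(["c", "d"])
        assert sorted(t.name for t in cd.tips()) == ["c", "d"]
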