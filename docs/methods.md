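# Methods

This note documents the models and procedures the package implements,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Iterative alignment-occupancy curation

Gene-family datasets pooled from genomes and transcriptomes contain many
truncated sequences.  The curation loop removes them jointly with the
alignment columns they degrade:

1. align the current sequence set;
2. remove every column whose fraction of missing characters is
   **strictly greater** than `max_column_missing` (default 0.5);
3. remove every sequence whose non-gap residue count is **strictly
   less** than `min_sequence_fraction` (default 0.5) times the
   column-filtered alignment length;
4. degap the survivors and repeat until an iteration removes no
   sequences, or `max_iterations` (default 20) is reached.

Interpretation decisions, each of which is testable and tested:

* *Missing data* means gap symbols only; `X` counts as present.
  Fragmentary transcripts manifest as gaps after alignment, which is
  what the column filter is meant to see.
* Criterion (3) measures a row's residues against the **post**-column-
  filter length.  The sequence filter is defined downstream of the
  column filter, so the length it references is the one that filter
  produced.
* Both thresholds are strict inequalities: a column with exactly half
  missing is kept, a sequence with exactly half occupancy is kept.
* Each iteration realigns the degapped survivors from scratch rather
  than trimming the previous alignment.  Removing sequences changes
  what an aligner would do, so alignment belongs inside the loop.
* The length prefilter bounds (120 and 971 aa) are inclusive.

Because each iteration either removes at least one sequence or
terminates the loop, termination within the initial sequence count is
guaranteed.  The converged output is a fixed point: one further pass of
both filters removes nothing.  The per-iteration audit trail (sequences
in, columns removed, sequences removed) is part of the result object and
of the CLI's `curation.tsv`.

Degenerate inputs (a filter pass removing every column or every
sequence) raise an error naming the iteration rather than returning an
empty alignment.

## Pairwise and progressive alignment

Pairwise global (Needleman-Wunsch) and local (Smith-Waterman) alignment
use affine gap costs — a gap run of length *k* costs
`gap_open + k*gap_extend` (defaults 11 + k·1) — with BLOSUM62 scores,
delegated to Biopython's `PairwiseAligner`.  The test suite checks both
kernels against an exhaustive recursion over edit operations on short
strings, so the gap-cost convention is pinned down, not assumed.

The built-in multiple aligner is deliberately simple and deterministic:

* pairwise distances: `1 − shared 3-mer fraction`, with the shared
  fraction taken over the smaller 3-mer set;
* guide tree: neighbor joining (scikit-bio) on that matrix;
* profiles merged leaf-to-root with profile-profile Needleman-Wunsch
  using mean-of-pairs column scores and a linear gap penalty of −4 per
  inserted column.  A linear penalty suffices here because the merge
  only decides where to insert whole gap columns; affine bookkeeping
  would add state without changing the property that matters, which is
  that degapping the output recovers the inputs exactly.

Any callable with that degap-identity property can replace the built-in
aligner in the curation loop (e.g. a wrapper around an external
aligner); ties in traceback are broken diagonal-first, so repeated runs
are byte-identical.

`nj_tree` validates symmetry and a zero diagonal and recovers the
generating topology on additive matrices.  `root_with_outgroup` places
the root on the branch separating a monophyletic outgroup from the
ingroup and reports the smallest containing clade when the outgroup is
not monophyletic.

## Homolog retrieval statistics

E-values use the ungapped Karlin-Altschul formula
`E = K·m·n·exp(−λ·S)` with the published ungapped-BLOSUM62 parameters
K = 0.134, λ = 0.3176 as documented defaults; there is no on-the-fly
parameter estimation, which keeps desk-scale searches deterministic.
`n` is the total residue count of the database.  The cutoff comparison
is inclusive (`E ≤ cutoff` passes, default 1e-5), and only the
best-scoring pair per (query, subject) is reported — this stage is a
retrieval filter, not an alignment statistics engine.

## Peptide-signature classification

The three WOX superclades are diagnosed by homeodomain nonapeptides:
`NVYNWFQNR` (T1), `NVFYWFQNR` (T2), `NVFYWFQNH` (T3).  Patterns are
exact-match consensi with per-position character classes; the optional
mismatch budget is 0 by default because the nonapeptides are treated as
exact diagnostics.

The signatures are known to be imperfect separators — the T2
nonapeptide also occurs in some T3 proteins — so classification
surfaces conflicts instead of resolving them: multiple distinct
signatures, or the T2 signature co-occurring with a T3-wide motif
(WUS-box), set `ambiguous=True` while keeping the leftmost signature as
the nominal call.  Clade-level calls require clade-motif evidence whose
position is consistent with a region hint (upstream of the
homeodomain, inside it, downstream of it, or within the C-terminal
window); evidence pointing at a clade of a different superclade flags
the assignment ambiguous and suppresses the clade call.

Homeodomain localisation anchors on the shared core
`NV[YF][YN]WFQN[RH]` and extends 50 residues upstream of the anchor
start and 7 downstream of its end — a 66-aa span, at the upper edge of
the canonical 60–66 range.  The exact placement of the domain boundary
relative to the core is not settled, so both offsets are configuration,
not fact.  The C-terminal window for EAR-motif scanning is the last 30
residues, likewise configurable.

The shipped library (`data/wox_motifs.yaml`) encodes the printed
diagnostics exactly (three nonapeptides, EAR variants `L[DE]LRLS` for
WOX5/7 and `L[DE]L[ST]LN` for WUS).  The remaining clade motifs —
WUS-box, T1WOX, T2WOX, WOX2, WOX1/6, WOX4 — are published only as
sequence logos, so the library ships clearly labelled synthetic
placeholder patterns for them, intended to be replaced by users with
consensi derived from their own alignments.

## Microsynteny scoring

Windows are 41 genes (anchor ± 20 by rank, truncated at contig ends,
not renormalised).  The syntenic score counts **target-window genes**
with at least one homolog in the query window, each target gene counted
once; counting genes rather than homologous pairs prevents tandem
paralogs from inflating scores.  One consequence worth stating: the
target-window size bounds the score in general, while the
min-of-both-windows bound additionally requires injective homology.
The anchor's own homolog, when present in the window, counts — it is
part of the vicinity by definition.  A score of at least 4 calls the
region syntenic; candidate windows are centred on every target-genome
homolog of a query-window gene, and overlapping candidates on a contig
are merged keeping the best score (leftmost on ties).  A passing window
with no homolog of the anchor itself is reported as a syntenic proxy.

## Promoter cis-element counting

Promoters are the 1500 bp upstream of the TSS (1-based coordinates):
`[TSS−L, TSS−1]` on the plus strand, `[TSS+1, TSS+L]`
reverse-complemented on the minus strand, clipped at contig bounds and
flagged truncated.  Motifs are IUPAC consensus patterns scanned on both
strands of the promoter, with coordinates reported on the promoter
itself.  Overlapping sites of a motif are counted once: footprints
sharing at least one position — strand-agnostic, so a near-palindromic
element's reverse-strand twin collapses onto its forward hit — merge
into clusters, and the deduplicated count is the cluster count.  The
shipped library holds consensus stand-ins (the AuxRE core `TGTCTC` and
a degenerate type-B ARR core `RGATTN`); the matrix collections used by
promoter databases are not redistributed, so presence calls on real
promoters depend on the library the user supplies.

## The synthetic-data generator

The generator's role is to plant exact, recorded truth:

* **Families**: an ancestral core of 200 random residues evolves down a
  fixed balanced 8-leaf tree with uniform per-site substitution
  (default 5%/site/branch); each member then has its clade's signature
  written at position 80 and its clade motifs written at
  region-consistent offsets.  Planting happens after mutation, so
  planted spans are never mutated, and truth records label every
  sequence.  Default family: 3 superclades × 20 members.
* **Fragments**: a configurable fraction (default 0.3) of sequences is
  replaced by contiguous subsequences (default 40–80 aa, i.e. below
  half of the core), emulating transcriptome-derived truncation.
* **Neighbourhoods**: each anchor gets a 61-gene query contig and a
  61-gene target contig; positives share 6 window genes by default
  (the anchor homolog deleted with probability 0.25, planting a
  proxy), negatives share 3, background genes are unshared.
* **Promoters**: cluster plans (singles, plus overlapping same-motif
  pairs where the consensus admits a self-overlap, e.g. `RGATTN` at
  offset 5) are placed disjointly with ≥2 bp spacing; the random
  background is then scrubbed by point mutation until scanning the
  finished promoter finds exactly the planted footprints.  Truth is
  therefore exact, not probabilistic.  Fully specified consensi such as
  `TGTCTC` cannot self-overlap consistently and receive only disjoint
  plants.  Plants of different motifs never share positions, because a
  cross-motif merge would leave per-motif cluster truth undefined.

What the generator does **not** emulate: indels outside fragmentation,
empirical substitution matrices or rate heterogeneity, codon-level
evolution, gene birth/death, inversions or transpositions within
syntenic blocks, and dinucleotide composition of real promoters.
Passing truth-recovery tests therefore demonstrates the correctness of
the implemented rules under the assumptions above — clean planted
signals on neutral backgrounds — not the sensitivity of the rules on
real genomes, where motif decay, paralog interference and compositional
bias all reduce signal.

## Problem sizes and numerical choices

The test and acceptance runs use: 1,000 random alignments (≤ 12 × 30)
checked against an independently coded replay of the curation loop;
exhaustive alignment-kernel checks on all string pairs of lengths ≤ 3
over a 4-letter alphabet plus a seeded sample at lengths 4–6; 20
simulated-family runs of 60 proteins per noise level; 100 planted
positive and 100 negative synteny anchors; 500 simulated promoters.
These sizes give exact expectations (planted truth or an independent
oracle) while keeping a full run inside a few minutes on one core.

All randomness flows through seeded `numpy` generators; fixed seeds
reproduce outputs byte for byte.  Traceback ties in alignment prefer
the diagonal move; NJ tie-breaking follows scikit-bio's deterministic
implementation.  Gap symbols `-` and `.` are both accepted on input and
normalised to `-`.

## Known limitations

* The progressive aligner is a correctness-first reference, quadratic
  in sequence count and length; for families of thousands of sequences
  an external aligner should be plugged into the curation loop.
* Homolog search is exhaustive Smith-Waterman without heuristic
  seeding; it is meant for hundreds, not millions, of comparisons, and
  its E-values use ungapped statistics with gapped alignments, which is
  conservative for retrieval but not publication-grade statistics.
* Superclade classification is only as good as the signature library;
  proteins whose homeodomain diverges from the three nonapeptides
  return `unclassified` rather than a phylogenetic placement.
* Synteny scoring ignores gene order and orientation within the window
  (no collinearity chaining) and treats truncated windows as-is.
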