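"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the statistical structure the analysis assumes:

* a protein family of three superclades sharing a conserved core, each
  member carrying its superclade's HD nonapeptide plus clade motifs at
  the expected positions relative to the homeodomain;
* fragmentary transcript-derived sequences (contiguous subsequences);
* pairs of gene orders with planted shared-homolog blocks (including
  anchor-lost "proxy" blocks) on a background of unshared genes;
* promoters with planted cis-element instances, including deliberately
  overlapping pairs, on background scrubbed free of spurious matches.

Every generated entity is recorded in a :class:`SimTruth`, and a fixed
seed reproduces outputs exactly.  Substitution noise is a uniform
per-site replacement applied along the branches of a fixed species tree;
planted motif spans are written after mutation and therefore never
mutated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .motifs import MotifDefinition, default_library, parse_pattern
from .promoters import DnaMotif, PromoterRegion, default_dna_library
from .seqio import SequenceRecord
from .synteny import GeneOrder, HomologyMap

__all__ = [
    "SimClade",
    "SimConfig",
    "SimTruth",
    "simulate_family",
    "fragment_transcripts",
    "simulate_neighborhoods",
    "simulate_promoters",
]

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_NT = np.array(list("ACGT"))


def _concrete(pattern: str, rng: np.random.Generator) -> str:
    """A concrete peptide instance of a consensus pattern (random class picks)."""
    return "".join(sorted(cls)[rng.integers(len(cls))] for cls in parse_pattern(pattern))


@dataclass(frozen=True)
class SimClade:
    """One planted clade: superclade signature plus clade-motif plants.

    ``plants`` maps a region slot (``upstream`` | ``downstream`` |
    ``c-terminal``) to a peptide to write there.
    """

    superclade: str
    clade: str
    signature: str
    plants: dict[str, str] = field(default_factory=dict)
    n_members: int = 20


def _default_clades(rng: np.random.Generator) -> list[SimClade]:
    lib = {m.name: m for m in default_library()}
    return [
        SimClade(
            "T1", "WOX10/13/14", "NVYNWFQNR",
            {"upstream": _concrete(lib["t1wox_motif"].pattern, rng)},
        ),
        SimClade(
            "T2", "WOX8/9-11/12", "NVFYWFQNR",
            {"downstream": _concrete(lib["t2wox_motif"].pattern, rng)},
        ),
        SimClade(
            "T3", "WUS", "NVFYWFQNH",
            {
                "downstream": _concrete(lib["wus_box"].pattern, rng),
                "c-terminal": _concrete(lib["ear_wus"].pattern, rng),
            },
        ),
    ]


@dataclass
class SimConfig:
    """Knobs for all four generators; a fixed seed reproduces outputs exactly."""

    seed: int = 0
    # family
    clades: list[SimClade] | None = None
    core_length: int = 200
    substitution_rate: float = 0.05  # per site per unit branch length
    anchor_position: int = 80  # where the HD nonapeptide is written
    # fragmentation
    fragment_fraction: float = 0.3
    fragment_length_range: tuple[int, int] = (40, 80)
    # synteny neighbourhoods
    n_positive: int = 20
    n_negative: int = 20
    proxy_fraction: float = 0.25
    shared_genes_positive: int = 6
    shared_genes_negative: int = 3
    contig_size: int = 61
    window: int = 20
    # promoters
    n_promoters: int = 50
    promoter_length: int = 1500
    max_instances_per_motif: int = 3
    overlap_probability: float = 0.3

    def __post_init__(self) -> None:
        if not 0 <= self.fragment_fraction <= 1:
            raise ValueError("fragment_fraction must lie in [0, 1]")
        if self.substitution_rate < 0:
            raise ValueError("substitution_rate must be non-negative")


@dataclass
class SimTruth:
    """Planted ground truth, one record per generated entity."""

    clade_labels: dict[str, tuple[str, str]] = field(default_factory=dict)
    motif_spans: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    fragments: dict[str, bool] = field(default_factory=dict)
    synteny: dict[str, dict] = field(default_factory=dict)
    promoter_clusters: dict[tuple[str, str], int] = field(default_factory=dict)
    promoter_instances: dict[tuple[str, str], int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# protein family

# fixed balanced 8-leaf species "tree": leaves at depth 3, unit branch lengths
_TREE_DEPTH = 3


def _evolve(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """One unit branch of uniform per-site substitution."""
    out = seq.copy()
    hit = rng.random(len(seq)) < rate
    n = int(hit.sum())
    if n:
        out[hit] = _AA[rng.integers(len(_AA), size=n)]
    return out


def _leaf_sequences(
    ancestor: np.ndarray, rate: float, rng: np.random.Generator
) -> list[np.ndarray]:
    """Evolve the ancestor down a balanced binary tree of fixed depth."""
    level = [ancestor]
    for _ in range(_TREE_DEPTH):
        level = [_evolve(s, rate, rng) for s in level for _ in range(2)]
    return level


def simulate_family(cfg: SimConfig) -> tuple[list[SequenceRecord], SimTruth]:
    """A clade-structured protein family with planted diagnostic motifs.

    The ancestral core evolves along the fixed species tree; every member
    then receives its clade's HD signature at ``cfg.anchor_position`` and
    its clade motifs at region-appropriate offsets, overwriting whatever
    the substitution process produced there (planted spans are therefore
    invariant to noise).
    """
    rng = np.random.default_rng(cfg.seed)
    clades = cfg.clades if cfg.clades is not None else _default_clades(rng)
    if all(c.n_members == 0 for c in clades):
        raise ValueError("at least one clade must have members")
    records: list[SequenceRecord] = []
    truth = SimTruth()
    L = cfg.core_length
    anchor = cfg.anchor_position
    if anchor + 9 + 30 > L or anchor < 60:
        raise ValueError("core_length/anchor_position leave no room for motif regions")
    for clade in clades:
        ancestor = _AA[rng.integers(len(_AA), size=L)]
        leaves = _leaf_sequences(ancestor, cfg.substitution_rate, rng)
        for i in range(clade.n_members):
            seq = leaves[i % len(leaves)].copy()
            sid = f"{clade.superclade}_{clade.clade.replace('/', '-')}_{i:03d}"
            spans: list[tuple[str, int, int]] = []

            def plant(peptide: str, start: int, name: str) -> None:
                seq[start : start + len(peptide)] = list(peptide)
                spans.append((name, start, start + len(peptide)))

            plant(clade.signature, anchor, "hd_signature")
            for region, peptide in clade.plants.items():
                if region == "upstream":
                    # strictly before the HD span (anchor - 50)
                    plant(peptide, max(0, anchor - 50 - len(peptide) - 5), region)
                elif region == "downstream":
                    # after the HD span (anchor + 9 + 7), clear of the C-terminal window
                    plant(peptide, anchor + 9 + 12, region)
                elif region == "c-terminal":
                    plant(peptide, L - len(peptide) - 2, region)
                else:
                    raise ValueError(f"unknown plant region {region!r}")
            records.append(SequenceRecord(sid, "".join(seq), source="synthetic"))
            truth.clade_labels[sid] = (clade.superclade, clade.clade)
            truth.motif_spans[sid] = spans
    return records, truth


def fragment_transcripts(
    seqs: Sequence[SequenceRecord], cfg: SimConfig
) -> tuple[list[SequenceRecord], SimTruth]:
    """Replace a fraction of sequences by contiguous fragments.

    Fragment lengths are drawn uniformly from ``cfg.fragment_length_range``;
    fragmented records keep their id, are retagged ``transcriptome``, and
    are flagged in the truth record.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    lo, hi = cfg.fragment_length_range
    n_frag = int(round(cfg.fragment_fraction * len(seqs)))
    frag_idx = set(rng.choice(len(seqs), size=n_frag, replace=False)) if n_frag else set()
    out: list[SequenceRecord] = []
    truth = SimTruth()
    for i, rec in enumerate(seqs):
        if i in frag_idx:
            flen = int(rng.integers(lo, hi + 1))
            flen = min(flen, len(rec.residues))
            start = int(rng.integers(0, len(rec.residues) - flen + 1))
            out.append(
                SequenceRecord(
                    rec.id, rec.residues[start : start + flen],
                    rec.taxon, "transcriptome",
                )
            )
            truth.fragments[rec.id] = True
        else:
            out.append(rec)
            truth.fragments[rec.id] = False
    return out, truth


# ---------------------------------------------------------------------------
# gene neighbourhoods


def simulate_neighborhoods(
    cfg: SimConfig,
) -> tuple[GeneOrder, GeneOrder, HomologyMap, SimTruth]:
    """Query/target gene orders with planted shared-homolog blocks.

    Each anchor gets its own contig pair.  Positive anchors share
    ``cfg.shared_genes_positive`` window genes with the target block
    (anchor homolog deleted with probability ``cfg.proxy_fraction``,
    planting a syntenic proxy); negative anchors share only
    ``cfg.shared_genes_negative``.  All other genes are unshared
    background.
    """
    if cfg.shared_genes_positive + 1 > cfg.contig_size:
        raise ValueError("block size exceeds contig size")
    rng = np.random.default_rng(cfg.seed + 2)
    q_contigs: dict[str, list[str]] = {}
    t_contigs: dict[str, list[str]] = {}
    hm = HomologyMap()
    truth = SimTruth()
    center = cfg.contig_size // 2
    cases = [("pos", i) for i in range(cfg.n_positive)] + [
        ("neg", i) for i in range(cfg.n_negative)
    ]
    for kind, i in cases:
        tag = f"{kind}{i}"
        anchor = f"{tag}_anchor"
        q_genes = [f"{tag}_q{j}" for j in range(cfg.contig_size)]
        q_genes[center] = anchor
        t_genes = [f"{tag}_t{j}" for j in range(cfg.contig_size)]

        n_shared = cfg.shared_genes_positive if kind == "pos" else cfg.shared_genes_negative
        proxy = kind == "pos" and rng.random() < cfg.proxy_fraction
        # pick query-window ranks to mirror in the target block
        window_lo = max(0, center - cfg.window)
        window_hi = min(cfg.contig_size, center + cfg.window + 1)
        candidates = [r for r in range(window_lo, window_hi) if r != center]
        shared_ranks = sorted(
            rng.choice(candidates, size=n_shared - (0 if proxy else 1), replace=False)
        )
        if not proxy:
            shared_ranks.append(center)
            shared_ranks.sort()
        # place the block compactly around the target centre
        t_lo = center - len(shared_ranks) // 2
        for off, qrank in enumerate(shared_ranks):
            hm.add(q_genes[qrank], t_genes[t_lo + off])
        q_contigs[f"{tag}_qc"] = q_genes
        t_contigs[f"{tag}_tc"] = t_genes
        truth.synteny[anchor] = {
            "kind": kind,
            "shared": n_shared,
            "proxy": proxy,
            "target_contig": f"{tag}_tc",
        }
    return GeneOrder(q_contigs), GeneOrder(t_contigs), hm, truth


# ---------------------------------------------------------------------------
# promoters


def _feasible_overlap(motif: DnaMotif) -> int | None:
    """Smallest forward-forward overlap offset consistent with the consensus."""
    pos = motif.positions
    k = len(pos)
    for d in range(1, k):
        if all(pos[i + d] & pos[i] for i in range(k - d)):
            return d
    return None


def _instance(motif: DnaMotif, rng: np.random.Generator) -> str:
    return "".join(sorted(cls)[rng.integers(len(cls))] for cls in motif.positions)


def _overlapping_pair(motif: DnaMotif, d: int, rng: np.random.Generator) -> str:
    """A string carrying two overlapping matches of the motif at offset d."""
    pos = motif.positions
    k = len(pos)
    merged: list[frozenset[str]] = []
    for i in range(k + d):
        allowed = frozenset("ACGT")
        if i < k:
            allowed &= pos[i]
        if i >= d:
            allowed &= pos[i - d]
        merged.append(allowed)
    return "".join(sorted(cls)[rng.integers(len(cls))] for cls in merged)


def _footprint_hits(seq: str, motifs: Sequence[DnaMotif]) -> dict[str, set[tuple[int, int]]]:
    from .promoters import _scan_positions

    found: dict[str, set[tuple[int, int]]] = {m.name: set() for m in motifs}
    for m in motifs:
        k = len(m)
        for i in _scan_positions(seq, m.positions):
            found[m.name].add((i, i + k))
        for i in _scan_positions(seq, m.reverse_positions):
            found[m.name].add((i, i + k))
    return found


def simulate_promoters(
    cfg: SimConfig, motifs: Sequence[DnaMotif] | None = None
) -> tuple[list[PromoterRegion], SimTruth]:
    """Random promoters with planted cis-element clusters and exact truth.

    Clusters (single instances, or overlapping pairs for motifs whose
    consensus admits a self-overlap) are placed disjointly; the random
    background is then scrubbed by point mutation until scanning the
    finished promoter finds exactly the planted footprints, making the
    planted cluster counts exact rather than probabilistic.  Plants of
    different motifs never share positions (a cross-motif merge would
    leave the truth undefined).
    """
    if motifs is None:
        motifs = default_dna_library()
    rng = np.random.default_rng(cfg.seed + 3)
    regions: list[PromoterRegion] = []
    truth = SimTruth()
    L = cfg.promoter_length
    for p in range(cfg.n_promoters):
        gene = f"gene{p:04d}"
        for _attempt in range(50):
            # plan clusters
            plan: list[tuple[DnaMotif, str, list[int]]] = []  # motif, text, hit offsets
            for m in motifs:
                n_clusters = int(rng.integers(0, cfg.max_instances_per_motif + 1))
                d = _feasible_overlap(m)
                for _ in range(n_clusters):
                    if d is not None and rng.random() < cfg.overlap_probability:
                        text = _overlapping_pair(m, d, rng)
                        plan.append((m, text, [0, d]))
                    else:
                        plan.append((m, _instance(m, rng), [0]))
            # place clusters disjointly with >= 2 bp spacing
            order = rng.permutation(len(plan))
            placements: list[tuple[int, int]] = []
            placed: list[tuple[DnaMotif, str, list[int], int]] = []
            ok = True
            for j in order:
                m, text, offs = plan[j]
                for _try in range(100):
                    start = int(rng.integers(0, L - len(text) + 1))
                    if all(
                        start >= e + 2 or start + len(text) + 2 <= s
                        for s, e in placements
                    ):
                        placements.append((start, start + len(text)))
                        placed.append((m, text, offs, start))
                        break
                else:
                    ok = False
                    break
            if not ok:
                continue
            seq = _NT[rng.integers(4, size=L)]
            planted_positions: set[int] = set()
            expected: dict[str, set[tuple[int, int]]] = {m.name: set() for m in motifs}
            clusters: dict[str, int] = {m.name: 0 for m in motifs}
            instances: dict[str, int] = {m.name: 0 for m in motifs}
            for m, text, offs, start in placed:
                seq[start : start + len(text)] = list(text)
                planted_positions.update(range(start, start + len(text)))
                for off in offs:
                    expected[m.name].add((start + off, start + off + len(m)))
                clusters[m.name] += 1
                instances[m.name] += len(offs)
            # scrub spurious matches out of the background
            clean = False
            for _scrub in range(300):
                found = _footprint_hits("".join(seq), motifs)
                spurious = [
                    (name, span)
                    for name, spans in found.items()
                    for span in spans - expected[name]
                ]
                if not spurious:
                    clean = True
                    break
                progressed = False
                for name, (s, e) in spurious:
                    background = [i for i in range(s, e) if i not in planted_positions]
                    if not background:
                        continue  # unscrubbable; will retry placement
                    i = background[int(rng.integers(len(background)))]
                    choices = [c for c in "ACGT" if c != seq[i]]
                    seq[i] = choices[int(rng.integers(3))]
                    progressed = True
                if not progressed:
                    break
            if not clean:
                continue
            regions.append(
                PromoterRegion(gene, f"chr_{gene}", (1, L), "+", "".join(seq))
            )
            for m in motifs:
                truth.promoter_clusters[(gene, m.name)] = clusters[m.name]
                truth.promoter_instances[(gene, m.name)] = instances[m.name]
            break
        else:
            raise RuntimeError(f"could not realise promoter {gene} without artefacts")
    return regions, truth
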