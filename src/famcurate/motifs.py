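"""Peptide-signature scanning and superclade/clade classification.

WOX-family proteins fall into three superclades distinguished by a
diagnostic nonapeptide inside the homeodomain (HD):

* ``NVYNWFQNR`` — Type 1 (T1, the WOX10/13/14 lineage),
* ``NVFYWFQNR`` — Type 2 (T2, the WOX8/9 and WOX11/12 lineages),
* ``NVFYWFQNH`` — Type 3 (T3, the WUS/WOX1-6/WOX2/WOX3/WOX4/WOX5-7 lineages).

Finer clades carry additional motifs at characteristic positions relative
to the HD (for example a C-terminal EAR repression motif encoded
``L[DE]LRLS`` in WOX5/7 members and ``L[DE]L[ST]LN`` in WUS members).
Classification here scans a configurable signature library against each
protein and reports the induced superclade/clade labels together with the
motif evidence.  The HD nonapeptides imperfectly separate the
superclades — the T2 nonapeptide also occurs in some T3 proteins — so
conflicting evidence is surfaced as ``ambiguous`` rather than silently
resolved.

Patterns are exact-match consensus strings with per-position character
classes: a capital letter matches itself, ``[DE]`` matches D or E, and
``x`` (or ``.``) matches any residue.  An optional mismatch budget can be
enabled per scan; it is off (0) by default because the nonapeptides are
treated as exact diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import yaml

__all__ = [
    "MotifDefinition",
    "MotifHit",
    "CladeAssignment",
    "EarCall",
    "parse_pattern",
    "scan_pattern",
    "classify_superclade",
    "classify_ear",
    "locate_hd",
    "assign_clade",
    "load_library",
    "default_library",
    "T1_SIGNATURE",
    "T2_SIGNATURE",
    "T3_SIGNATURE",
    "HD_ANCHOR",
    "EAR_WOX57",
    "EAR_WUS",
]

# Superclade-diagnostic HD nonapeptides.
T1_SIGNATURE = "NVYNWFQNR"
T2_SIGNATURE = "NVFYWFQNR"
T3_SIGNATURE = "NVFYWFQNH"
# Shared HD core used to anchor homeodomain localisation.
HD_ANCHOR = "NV[YF][YN]WFQN[RH]"
# C-terminal EAR repression-motif variants.
EAR_WOX57 = "L[DE]LRLS"
EAR_WUS = "L[DE]L[ST]LN"

_AA = "ACDEFGHIKLMNPQRSTVWY"
_REGIONS = {None, "hd-internal", "upstream-of-hd", "downstream-of-hd", "c-terminal"}

# clade label -> superclade it belongs to
CLADE_SUPERCLADE = {
    "WOX10/13/14": "T1",
    "WOX8/9-11/12": "T2",
    "WOX8/9": "T2",
    "WOX11/12": "T2",
    "WUS": "T3",
    "WOX5/7": "T3",
    "WOX1/6": "T3",
    "WOX2": "T3",
    "WOX3": "T3",
    "WOX4": "T3",
}


def parse_pattern(pattern: str) -> list[frozenset[str]]:
    """Parse a consensus pattern into one character set per position."""
    positions: list[frozenset[str]] = []
    i = 0
    while i < len(pattern):
        c = pattern[i]
        if c == "[":
            j = pattern.index("]", i)
            chars = pattern[i + 1 : j]
            if not chars:
                raise ValueError(f"empty character class in pattern {pattern!r}")
            positions.append(frozenset(chars))
            i = j + 1
        elif c in ("x", "."):
            positions.append(frozenset(_AA))
            i += 1
        elif c.isalpha():
            positions.append(frozenset(c.upper()))
            i += 1
        else:
            raise ValueError(f"bad character {c!r} in pattern {pattern!r}")
    return positions


@dataclass(frozen=True)
class MotifDefinition:
    """A named consensus pattern tied to a superclade or clade label.

    ``kind`` distinguishes HD signatures (the superclade nonapeptides),
    superclade-wide motifs (like the WUS-box, shared by most T3 proteins)
    and clade-specific motifs.  ``region`` optionally restricts where the
    motif is expected relative to the homeodomain.
    """

    name: str
    pattern: str
    label: str
    kind: str = "clade-motif"  # hd-signature | superclade-motif | clade-motif
    region: str | None = None

    def __post_init__(self) -> None:
        positions = parse_pattern(self.pattern)
        if len(positions) < 5:
            raise ValueError(
                f"motif {self.name!r}: patterns must span at least 5 positions"
            )
        if self.region not in _REGIONS:
            raise ValueError(f"motif {self.name!r}: unknown region {self.region!r}")
        if self.kind not in ("hd-signature", "superclade-motif", "clade-motif"):
            raise ValueError(f"motif {self.name!r}: unknown kind {self.kind!r}")

    @property
    def positions(self) -> list[frozenset[str]]:
        return parse_pattern(self.pattern)

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class MotifHit:
    motif: str
    seq_id: str
    span: tuple[int, int]  # 0-based half-open
    matched: str
    strand: str = "+"

    def overlaps(self, other: "MotifHit") -> bool:
        return self.span[0] < other.span[1] and other.span[0] < self.span[1]


@dataclass
class CladeAssignment:
    seq_id: str
    superclade: str  # T1 | T2 | T3 | unclassified
    clade: str | None
    evidence: list[MotifHit]
    ambiguous: bool

    def __post_init__(self) -> None:
        if self.superclade == "unclassified" and self.clade is not None:
            raise ValueError("unclassified assignments cannot carry a clade")


@dataclass(frozen=True)
class EarCall:
    kind: str  # 'WOX5/7' | 'WUS' | 'both' | 'none'
    hits: tuple[MotifHit, ...]
    ambiguous: bool


def scan_pattern(
    seq: str,
    motif: MotifDefinition,
    seq_id: str = "",
    max_mismatches: int = 0,
) -> list[MotifHit]:
    """All (possibly overlapping) match positions of a motif, left to right."""
    positions = motif.positions
    k = len(positions)
    hits: list[MotifHit] = []
    for start in range(len(seq) - k + 1):
        window = seq[start : start + k]
        mismatches = sum(
            1 for c, allowed in zip(window, positions) if c not in allowed
        )
        if mismatches <= max_mismatches:
            hits.append(MotifHit(motif.name, seq_id, (start, start + k), window))
    return hits


def _signature_motifs(library: Sequence[MotifDefinition]) -> list[MotifDefinition]:
    return [m for m in library if m.kind == "hd-signature"]


def classify_superclade(
    seq: str,
    signatures: Sequence[MotifDefinition],
    seq_id: str = "",
) -> CladeAssignment:
    """Superclade call from the HD nonapeptide signatures.

    Exactly one signature present gives that superclade.  No signature
    gives ``unclassified``.  Multiple distinct signatures — or the T2
    signature co-occurring with a T3-diagnostic superclade motif such as
    the WUS-box — are reported with ``ambiguous=True`` (the superclade of
    the leftmost signature hit is kept as the nominal call).
    """
    sigs = _signature_motifs(signatures)
    if not sigs:
        raise ValueError("signature library holds no HD signatures")
    hits: list[tuple[MotifHit, str]] = []
    for m in sigs:
        for h in scan_pattern(seq, m, seq_id):
            hits.append((h, m.label))
    if not hits:
        return CladeAssignment(seq_id, "unclassified", None, [], False)
    hits.sort(key=lambda t: t[0].span)
    labels = {label for _, label in hits}
    evidence = [h for h, _ in hits]
    superclade = hits[0][1]
    ambiguous = len(labels) > 1
    if "T2" in labels and not ambiguous:
        # the T2 nonapeptide also occurs in several T3 proteins; a
        # co-occurring T3-wide motif (e.g. WUS-box) makes the call ambiguous
        for m in signatures:
            if m.kind == "superclade-motif" and m.label == "T3":
                box_hits = scan_pattern(seq, m, seq_id)
                if box_hits:
                    evidence.extend(box_hits)
                    ambiguous = True
    return CladeAssignment(seq_id, superclade, None, evidence, ambiguous)


def classify_ear(seq: str, seq_id: str = "", window: int = 30) -> EarCall:
    """Classify the C-terminal EAR motif variant, if any.

    Scanning is restricted to the last ``window`` residues (default 30).
    ``L[DE]LRLS`` marks WOX5/7-type, ``L[DE]L[ST]LN`` WUS-type; when both
    occur the call is 'both' with ``ambiguous=True``.
    """
    tail_start = max(0, len(seq) - window)
    tail = seq[tail_start:]
    wox57 = MotifDefinition("ear_wox5_7", EAR_WOX57, "WOX5/7", region="c-terminal")
    wus = MotifDefinition("ear_wus", EAR_WUS, "WUS", region="c-terminal")

    def shifted(motif: MotifDefinition) -> list[MotifHit]:
        return [
            MotifHit(h.motif, seq_id, (h.span[0] + tail_start, h.span[1] + tail_start), h.matched)
            for h in scan_pattern(tail, motif, seq_id)
        ]

    h57, hwus = shifted(wox57), shifted(wus)
    if h57 and hwus:
        return EarCall("both", tuple(h57 + hwus), True)
    if h57:
        return EarCall("WOX5/7", tuple(h57), False)
    if hwus:
        return EarCall("WUS", tuple(hwus), False)
    return EarCall("none", (), False)


@dataclass(frozen=True)
class HdSpan:
    span: tuple[int, int]
    anchor: tuple[int, int]
    clipped: bool


def locate_hd(seq: str, upstream: int = 50, downstream: int = 7) -> HdSpan | None:
    """Approximate homeodomain span from the shared HD core anchor.

    The leftmost ``NV[YF][YN]WFQN[RH]`` match anchors the HD near its
    C-terminal helix; the span extends ``upstream`` residues before the
    anchor start and ``downstream`` after its end (defaults give a 66-aa
    domain, within the canonical 60–66), clipped to the sequence with
    ``clipped=True``.  Returns ``None`` when the anchor is absent.
    """
    anchor_def = MotifDefinition("hd_anchor", HD_ANCHOR, "HD", kind="superclade-motif")
    hits = scan_pattern(seq, anchor_def)
    if not hits:
        return None
    a0, a1 = hits[0].span
    start, end = a0 - upstream, a1 + downstream
    clipped = start < 0 or end > len(seq)
    return HdSpan((max(0, start), min(len(seq), end)), (a0, a1), clipped)


def _region_ok(hit: MotifHit, region: str | None, hd: HdSpan | None, seq_len: int) -> bool:
    if region is None:
        return True
    if region == "c-terminal":
        return hit.span[1] > seq_len - 30
    if hd is None:
        return False
    if region == "hd-internal":
        return hit.span[0] >= hd.span[0] and hit.span[1] <= hd.span[1]
    if region == "upstream-of-hd":
        return hit.span[1] <= hd.span[0]
    if region == "downstream-of-hd":
        return hit.span[0] >= hd.span[1]
    raise AssertionError(region)


def assign_clade(
    seq: str,
    library: Sequence[MotifDefinition],
    seq_id: str = "",
) -> CladeAssignment:
    """Full superclade + clade assignment from a signature library.

    The superclade comes from :func:`classify_superclade`; the clade from
    clade-specific motif evidence, with region hints checked against the
    located homeodomain.  Evidence pointing at clades of a different
    superclade than the HD signature, or at several clades at once, is
    flagged ambiguous, never silently resolved.
    """
    if not library:
        raise ValueError("empty motif library")
    base = classify_superclade(seq, library, seq_id)
    if base.superclade == "unclassified":
        return base
    hd = locate_hd(seq)
    clade_votes: dict[str, list[MotifHit]] = {}
    for m in library:
        if m.kind != "clade-motif":
            continue
        for h in scan_pattern(seq, m, seq_id):
            if _region_ok(h, m.region, hd, len(seq)):
                clade_votes.setdefault(m.label, []).append(h)
    evidence = list(base.evidence)
    for hits in clade_votes.values():
        evidence.extend(hits)
    ambiguous = base.ambiguous
    clade: str | None = None
    consistent = {
        c for c in clade_votes if CLADE_SUPERCLADE.get(c) == base.superclade
    }
    foreign = set(clade_votes) - consistent
    if foreign:
        ambiguous = True
    if len(consistent) == 1:
        clade = next(iter(consistent))
    elif len(consistent) > 1:
        ambiguous = True
    return CladeAssignment(seq_id, base.superclade, clade, evidence, ambiguous)


def _parse_entry(entry: dict) -> MotifDefinition:
    return MotifDefinition(
        name=entry["name"],
        pattern=entry["pattern"],
        label=entry["label"],
        kind=entry.get("kind", "clade-motif"),
        region=entry.get("region"),
    )


def load_library(path: str | Path) -> list[MotifDefinition]:
    """Load a motif library from a YAML file (list of name/pattern/label/kind/region)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, list) or not data:
        raise ValueError(f"{path}: motif library must be a non-empty list")
    return [_parse_entry(e) for e in data]


def default_library() -> list[MotifDefinition]:
    """The shipped WOX signature library (see ``data/wox_motifs.yaml``)."""
    ref = resources.files("famcurate.data").joinpath("wox_motifs.yaml")
    with resources.as_file(ref) as path:
        return load_library(path)
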