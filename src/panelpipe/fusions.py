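"""Split-anchor rearrangement detection on the unaligned read pool.

Each unaligned read of length >= 60 is split into two 30 bp anchors (one
from each end).  Anchors are placed by exact 30-mer lookup with a
1-mismatch fallback; multi-mapping anchors stay unplaced.  A pair is
discordant when its anchors land on different chromosomes, on the same
chromosome with an implied span beyond ``max_span``, or with
orientations inconsistent with a contiguous read.  Discordant pairs are
grouped by position with single-linkage clustering; groups with at least
``min_support`` distinct reads are flagged as rearrangement candidates.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from ._seq import encode, revcomp_codes
from .align import Alignment
from .sim.panel import PanelDesign
from .sim.reads import SimRead
from .sim.reference import ReferenceModel

DEFAULT_ANCHOR_LENGTH = 30
DEFAULT_MIN_SUPPORT = 8
DEFAULT_WINDOW = 500
DEFAULT_MAX_SPAN = 10_000


@dataclass(frozen=True)
class Placement:
    chrom: str
    pos: int        # 0-based leftmost of the anchor
    strand: str     # "+" | "-"


@dataclass
class AnchorPair:
    read_id: str
    anchor_a: str   # first `anchor_length` bases of the read
    anchor_b: str   # last `anchor_length` bases
    placement_a: Optional[Placement] = None
    placement_b: Optional[Placement] = None

    @property
    def both_placed(self) -> bool:
        return self.placement_a is not None and self.placement_b is not None


@dataclass
class RearrangementCandidate:
    chrom_a: str
    pos_a: int
    strand_a: str
    chrom_b: str
    pos_b: int
    strand_b: str
    support: int
    read_ids: List[str]
    flagged: bool
    gene_a: Optional[str] = None
    gene_b: Optional[str] = None


def collect_unaligned(alignments: Sequence[Alignment]) -> List[str]:
    """Read ids with status unaligned, in stable input order."""
    return [a.read_id for a in alignments if not a.aligned]


def split_anchors(seq: str, anchor_length: int = DEFAULT_ANCHOR_LENGTH
                  ) -> Optional[Tuple[str, str]]:
    """First/last ``anchor_length`` bases, or None for too-short reads."""
    if len(seq) < 2 * anchor_length:
        return None
    return seq[:anchor_length], seq[-anchor_length:]


def make_anchor_pairs(reads: Dict[str, str], read_ids: Sequence[str],
                      anchor_length: int = DEFAULT_ANCHOR_LENGTH
                      ) -> Tuple[List[AnchorPair], int]:
    """Split the selected reads into anchor pairs; returns (pairs, n_skipped)."""
    pairs: List[AnchorPair] = []
    skipped = 0
    for rid in read_ids:
        anchors = split_anchors(reads[rid], anchor_length)
        if anchors is None:
            skipped += 1
            continue
        pairs.append(AnchorPair(rid, anchors[0], anchors[1]))
    return pairs, skipped


class AnchorIndex:
    """Exact k-mer positions for anchor placement (k = anchor length)."""

    def __init__(self, reference: ReferenceModel, k: int = DEFAULT_ANCHOR_LENGTH):
        self.k = k
        self.reference = reference
        self._index: Dict[bytes, List[Tuple[str, int]]] = {}
        for name in reference.names:
            buf = reference.codes(name).tobytes()
            for i in range(0, len(buf) - k + 1):
                self._index.setdefault(buf[i:i + k], []).append((name, i))

    def _exact(self, key: bytes) -> List[Tuple[str, int]]:
        return self._index.get(key, [])

    def _one_mismatch(self, codes: np.ndarray) -> List[Tuple[str, int]]:
        hits: Set[Tuple[str, int]] = set()
        work = codes.copy()
        for i in range(self.k):
            orig = work[i]
            for sub in range(4):
                if sub == orig:
                    continue
                work[i] = sub
                hits.update(self._exact(work.tobytes()))
            work[i] = orig
        return list(hits)

    def place(self, anchor: str) -> Optional[Placement]:
        """Unique best placement of an anchor (exact first, then 1-mismatch,
        forward and reverse strand); ambiguity -> None."""
        codes = encode(anchor)
        if (codes == 255).any():
            return None
        fwd = self._exact(codes.tobytes())
        rev = self._exact(revcomp_codes(codes).tobytes())
        exact = [(c, p, "+") for c, p in fwd] + [(c, p, "-") for c, p in rev]
        if len(exact) == 1:
            return Placement(*exact[0])
        if len(exact) > 1:
            return None
        near = ([(c, p, "+") for c, p in self._one_mismatch(codes)]
                + [(c, p, "-") for c, p in self._one_mismatch(revcomp_codes(codes))])
        if len(near) == 1:
            return Placement(*near[0])
        return None


def align_anchors(pairs: Sequence[AnchorPair], reference: ReferenceModel,
                  anchor_length: int = DEFAULT_ANCHOR_LENGTH,
                  index: Optional[AnchorIndex] = None) -> List[AnchorPair]:
    """Place both anchors of every pair (in place; also returned)."""
    if index is None:
        index = AnchorIndex(reference, k=anchor_length)
    cache: Dict[str, Optional[Placement]] = {}
    for pair in pairs:
        for attr, anchor in (("placement_a", pair.anchor_a), ("placement_b", pair.anchor_b)):
            if anchor not in cache:
                cache[anchor] = index.place(anchor)
            setattr(pair, attr, cache[anchor])
    return list(pairs)


def classify_discordant(pair: AnchorPair,
                        max_span: int = DEFAULT_MAX_SPAN) -> Optional[bool]:
    """True/False for a placed pair; None when either anchor is unplaced."""
    if not pair.both_placed:
        return None
    a, b = pair.placement_a, pair.placement_b
    if a.chrom != b.chrom:
        return True
    if a.strand != b.strand:
        return True
    # implied genomic span of the read from A anchor start to B anchor end
    span = (b.pos + len(pair.anchor_b)) - a.pos if a.strand == "+" \
        else (a.pos + len(pair.anchor_a)) - b.pos
    return not (0 < span <= max_span)


def _junction_coords(pair: AnchorPair) -> Tuple[Tuple[str, int, str], Tuple[str, int, str]]:
    """Junction-adjacent (innermost) coordinate of each anchor."""
    a, b = pair.placement_a, pair.placement_b
    la, lb = len(pair.anchor_a), len(pair.anchor_b)
    ca = a.pos + la if a.strand == "+" else a.pos
    cb = b.pos if b.strand == "+" else b.pos + lb
    return (a.chrom, ca, a.strand), (b.chrom, cb, b.strand)


def group_candidates(pairs: Sequence[AnchorPair],
                     window: int = DEFAULT_WINDOW,
                     min_support: int = DEFAULT_MIN_SUPPORT,
                     max_span: int = DEFAULT_MAX_SPAN,
                     panel: Optional[PanelDesign] = None) -> List[RearrangementCandidate]:
    """Cluster discordant pairs and flag clusters with enough support.

    Pairs are canonically oriented (lower (chrom, coord) side first) so
    the result is invariant to read input order; clustering is
    single-linkage with both breakpoint coordinates within ``window``.
    Breakpoints are the median junction-adjacent anchor coordinates.
    """
    events = []
    for pair in pairs:
        if classify_discordant(pair, max_span=max_span) is not True:
            continue
        side_a, side_b = _junction_coords(pair)
        if (side_b[0], side_b[1]) < (side_a[0], side_a[1]):
            side_a, side_b = side_b, side_a
        events.append((side_a, side_b, pair.read_id))
    events.sort(key=lambda e: (e[0][0], e[1][0], e[0][2], e[1][2], e[0][1], e[1][1], e[2]))

    # union-find single linkage within (chromA, chromB, strandA, strandB)
    parent = list(range(len(events)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(events)):
        for j in range(i + 1, len(events)):
            ea, eb = events[i], events[j]
            if (ea[0][0], ea[1][0], ea[0][2], ea[1][2]) != (eb[0][0], eb[1][0], eb[0][2], eb[1][2]):
                continue
            if abs(ea[0][1] - eb[0][1]) <= window and abs(ea[1][1] - eb[1][1]) <= window:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri

    clusters: Dict[int, List[int]] = {}
    for i in range(len(events)):
        clusters.setdefault(find(i), []).append(i)

    out: List[RearrangementCandidate] = []
    for members in clusters.values():
        side_as = [events[i][0] for i in members]
        side_bs = [events[i][1] for i in members]
        read_ids = sorted({events[i][2] for i in members})
        pos_a = int(np.median([c[1] for c in side_as]))
        pos_b = int(np.median([c[1] for c in side_bs]))
        chrom_a, strand_a = side_as[0][0], side_as[0][2]
        chrom_b, strand_b = side_bs[0][0], side_bs[0][2]
        cand = RearrangementCandidate(
            chrom_a=chrom_a, pos_a=pos_a, strand_a=strand_a,
            chrom_b=chrom_b, pos_b=pos_b, strand_b=strand_b,
            support=len(read_ids), read_ids=read_ids,
            flagged=len(read_ids) >= min_support)
        if panel is not None:
            cand.gene_a = panel.gene_at(chrom_a, pos_a) or chrom_a
            cand.gene_b = panel.gene_at(chrom_b, pos_b) or chrom_b
        out.append(cand)
    out.sort(key=lambda c: (c.chrom_a, c.pos_a, c.chrom_b, c.pos_b))
    return out


def detect_rearrangements(reads: Sequence[SimRead] | Dict[str, str],
                          alignments: Sequence[Alignment],
                          reference: ReferenceModel,
                          panel: Optional[PanelDesign] = None,
                          anchor_length: int = DEFAULT_ANCHOR_LENGTH,
                          window: int = DEFAULT_WINDOW,
                          min_support: int = DEFAULT_MIN_SUPPORT,
                          max_span: int = DEFAULT_MAX_SPAN) -> List[RearrangementCandidate]:
    """Full pipeline: unaligned pool -> anchors -> placements -> candidates."""
    if not isinstance(reads, dict):
        reads = {r.read_id: r.seq for r in reads}
    pool = collect_unaligned(alignments)
    pairs, _ = make_anchor_pairs(reads, pool, anchor_length)
    align_anchors(pairs, reference, anchor_length)
    return group_candidates(pairs, window=window, min_support=min_support,
                            max_span=max_span, panel=panel)
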