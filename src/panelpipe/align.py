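"""Simple ungapped read aligner and SAM import/export.

The aligner seeds candidate placements with exact k-mer hits (k=20 by
default, seeds taken at every k-th offset along the read), extends each
candidate by full ungapped comparison, and keeps the unique best
placement within the mismatch budget.  Ties on mismatch count are
treated as ambiguous and reported unaligned, as are reads spanning
non-reference sequence (e.g. fusion junctions).  Reverse-complement
placements are attempted when no forward placement verifies.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from ._seq import encode, revcomp_codes
from .errors import ConfigError, SamImportError
from .sim.panel import PanelDesign
from .sim.reads import SimRead
from .sim.reference import ReferenceModel

DEFAULT_SEED_K = 20
DEFAULT_MAX_MISMATCHES = 5


@dataclass
class Alignment:
    read_id: str
    status: str                      # "aligned" | "unaligned"
    chrom: Optional[str] = None
    pos: Optional[int] = None        # 0-based leftmost
    strand: Optional[str] = None     # "+" | "-"
    n_mismatches: Optional[int] = None
    is_duplicate: bool = False

    @property
    def aligned(self) -> bool:
        return self.status == "aligned"


class KmerIndex:
    """Exact k-mer index over all reference segments."""

    def __init__(self, reference: ReferenceModel, k: int = DEFAULT_SEED_K):
        if not reference.names:
            raise ConfigError("empty reference")
        self.k = k
        self.reference = reference
        self._index: Dict[bytes, List[Tuple[str, int]]] = {}
        for name in reference.names:
            codes = reference.codes(name)
            buf = codes.tobytes()
            for i in range(0, len(buf) - k + 1):
                self._index.setdefault(buf[i:i + k], []).append((name, i))

    def hits(self, kmer: bytes) -> List[Tuple[str, int]]:
        return self._index.get(kmer, [])


def _candidate_placements(codes: np.ndarray, index: KmerIndex) -> set:
    k = index.k
    n = len(codes)
    buf = codes.tobytes()
    cands = set()
    offsets = list(range(0, n - k + 1, k))
    if offsets and offsets[-1] != n - k:
        offsets.append(n - k)
    for off in offsets:
        for chrom, hit in index.hits(buf[off:off + k]):
            start = hit - off
            if start >= 0 and start + n <= index.reference.length(chrom):
                cands.add((chrom, start))
    return cands


def _mismatches(codes: np.ndarray, reference: ReferenceModel, chrom: str, pos: int) -> int:
    ref = reference.codes(chrom)[pos:pos + len(codes)]
    return int(np.count_nonzero(ref != codes))


def _best_placement(codes: np.ndarray, index: KmerIndex, strand: str,
                    max_mismatches: int) -> List[Tuple[int, str, int, str]]:
    out = []
    for chrom, start in _candidate_placements(codes, index):
        nm = _mismatches(codes, index.reference, chrom, start)
        if nm <= max_mismatches:
            out.append((nm, chrom, start, strand))
    return out


def align_read(seq: str, index: KmerIndex,
               max_mismatches: int = DEFAULT_MAX_MISMATCHES) -> Optional[Tuple[str, int, str, int]]:
    """Align one read; returns (chrom, pos, strand, n_mismatches) or None.

    The unique best ungapped placement wins; a tie on mismatch count or
    no placement within the budget yields None.
    """
    codes = encode(seq)
    if (codes == 255).any():
        return None
    hits = _best_placement(codes, index, "+", max_mismatches)
    if not hits:
        hits = _best_placement(revcomp_codes(codes), index, "-", max_mismatches)
    if not hits:
        return None
    hits.sort(key=lambda h: (h[0], h[1], h[2]))
    if len(hits) > 1 and hits[0][0] == hits[1][0]:
        return None  # ambiguous best
    nm, chrom, pos, strand = hits[0]
    return chrom, pos, strand, nm


def align_reads(reads: Sequence[SimRead],
                reference: ReferenceModel,
                panel: Optional[PanelDesign] = None,
                max_mismatches: int = DEFAULT_MAX_MISMATCHES,
                k: int = DEFAULT_SEED_K,
                index: Optional[KmerIndex] = None) -> List[Alignment]:
    """Align a batch of reads against the reference.

    ``panel`` is accepted for interface uniformity (alignment itself is
    panel-agnostic).  Results for identical sequences are cached, which
    speeds up amplicon data substantially.
    """
    del panel
    if index is None:
        index = KmerIndex(reference, k=k)
    cache: Dict[str, Optional[Tuple[str, int, str, int]]] = {}
    out: List[Alignment] = []
    for read in reads:
        res = cache.get(read.seq, "__miss__")
        if res == "__miss__":
            res = align_read(read.seq, index, max_mismatches=max_mismatches)
            cache[read.seq] = res
        if res is None:
            out.append(Alignment(read.read_id, "unaligned"))
        else:
            chrom, pos, strand, nm = res
            out.append(Alignment(read.read_id, "aligned", chrom, pos, strand, nm))
    return out


# ---------------------------------------------------------------------------
# SAM import/export (minimal mandatory columns)
# ---------------------------------------------------------------------------

def export_sam(alignments: Sequence[Alignment], reads: Dict[str, str],
               reference: ReferenceModel, path: str) -> None:
    """Write alignments as a plain-text SAM file (FLAG/POS/CIGAR only)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name in reference.names:
            fh.write(f"@SQ\tSN:{name}\tLN:{reference.length(name)}\n")
        for aln in alignments:
            seq = reads.get(aln.read_id, "*")
            if aln.aligned:
                flag = 16 if aln.strand == "-" else 0
                if aln.is_duplicate:
                    flag |= 1024
                cigar = f"{len(seq)}M" if seq != "*" else "*"
                fh.write(f"{aln.read_id}\t{flag}\t{aln.chrom}\t{aln.pos + 1}\t60\t"
                         f"{cigar}\t*\t0\t0\t{seq}\t*\tNM:i:{aln.n_mismatches or 0}\n")
            else:
                fh.write(f"{aln.read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t*\n")


def import_sam(path: str, reference: Optional[ReferenceModel] = None,
               panel: Optional[PanelDesign] = None) -> List[Alignment]:
    """Import a SAM file as a list of :class:`Alignment`.

    SAM POS is 1-based; internal positions are 0-based.  FLAG 4 records
    become unaligned; the duplicate flag (1024) is honored.  When a
    reference is given, @SQ names and lengths must match it.
    """
    del panel
    out: List[Alignment] = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        if reference is not None:
            names = list(sam.references)
            if set(names) - set(reference.names):
                raise SamImportError("SAM header names unknown chromosomes")
            for name in names:
                if sam.get_reference_length(name) != reference.length(name):
                    raise SamImportError(f"length mismatch for {name} in SAM header")
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped:
                out.append(Alignment(rec.query_name, "unaligned",
                                     is_duplicate=rec.is_duplicate))
            else:
                nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
                out.append(Alignment(rec.query_name, "aligned",
                                     chrom=rec.reference_name,
                                     pos=rec.reference_start,
                                     strand="-" if rec.is_reverse else "+",
                                     n_mismatches=int(nm),
                                     is_duplicate=rec.is_duplicate))
    return out


def read_sam_sequences(path: str) -> Dict[str, str]:
    """Read-id -> sequence map from a SAM file (for pileup construction)."""
    seqs: Dict[str, str] = {}
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.query_sequence:
                seqs[rec.query_name] = rec.query_sequence
    return seqs
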