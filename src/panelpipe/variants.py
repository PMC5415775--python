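"""Per-site pileups, background error model, and the mutation filter.

A candidate mutation passes when all three rules hold:

* alternate allele fraction f = a/d >= min_af (default 0.10),
* alternate read count a >= min_alt_reads (default 5),
* f >= background_factor x b (default 20x), where b is the mean
  alternate allele fraction at that site across control blood samples,
  floored at a small epsilon so error-free control sites do not make the
  ratio rule vacuous.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np

from ._seq import BASES, encode, revcomp_codes
from .errors import ConfigError
from .align import Alignment
from .sim.panel import PanelDesign
from .sim.reads import SimRead
from .sim.reference import ReferenceModel

BACKGROUND_FLOOR = 1e-4

DEFAULT_THRESHOLDS = {"min_af": 0.10, "min_alt_reads": 5, "background_factor": 20.0}


@dataclass
class PileupSite:
    chrom: str
    pos: int
    ref: str
    depth: int
    counts: Dict[str, int]  # base -> count, summing to depth


class Pileup:
    """Array-backed per-site base counts restricted to panel positions."""

    def __init__(self, reference: ReferenceModel, panel: PanelDesign):
        self.reference = reference
        self.panel = panel
        self.counts: Dict[str, np.ndarray] = {}
        self.mask: Dict[str, np.ndarray] = {}
        chroms = {a.chrom for a in panel}
        for chrom in chroms:
            length = reference.length(chrom)
            self.counts[chrom] = np.zeros((4, length), dtype=np.int32)
            self.mask[chrom] = panel.covered_mask(chrom, length)

    def add_read(self, chrom: str, pos: int, codes: np.ndarray) -> None:
        arr = self.counts[chrom]
        idx = np.arange(pos, pos + len(codes))
        valid = codes < 4
        np.add.at(arr, (codes[valid], idx[valid]), 1)

    def depth_at(self, chrom: str, pos: int) -> int:
        return int(self.counts[chrom][:, pos].sum())

    def site(self, chrom: str, pos: int) -> PileupSite:
        col = self.counts[chrom][:, pos]
        return PileupSite(chrom, pos, self.reference.sequence(chrom)[pos],
                          int(col.sum()), {b: int(col[i]) for i, b in enumerate(BASES)})

    def sites(self, min_depth: int = 0) -> Iterable[PileupSite]:
        """Iterate panel sites (optionally only those with depth >= min_depth)."""
        for chrom in sorted(self.counts):
            covered = np.flatnonzero(self.mask[chrom])
            depths = self.counts[chrom][:, covered].sum(axis=0)
            for pos, d in zip(covered, depths):
                if d >= min_depth:
                    yield self.site(chrom, int(pos))


def build_pileup(alignments: Sequence[Alignment],
                 reads: Mapping[str, str] | Sequence[SimRead],
                 reference: ReferenceModel,
                 panel: PanelDesign,
                 dedupe: bool = True) -> Pileup:
    """Accumulate per-site base counts over aligned reads.

    ``reads`` maps read-id to sequence (a sequence of SimRead works too).
    Duplicate-flagged alignments are excluded when ``dedupe`` is on.
    Reverse-strand alignments contribute the reverse complement of the
    stored read sequence.
    """
    if not isinstance(reads, Mapping):
        reads = {r.read_id: r.seq for r in reads}
    pile = Pileup(reference, panel)
    for aln in alignments:
        if not aln.aligned or (dedupe and aln.is_duplicate):
            continue
        if aln.read_id not in reads:
            raise ConfigError(f"alignment refers to unknown read {aln.read_id!r}")
        codes = encode(reads[aln.read_id])
        if aln.strand == "-":
            codes = revcomp_codes(codes)
        if aln.chrom in pile.counts:
            end = min(aln.pos + len(codes), reference.length(aln.chrom))
            pile.add_read(aln.chrom, aln.pos, codes[:end - aln.pos])
    return pile


class BackgroundErrorModel:
    """Mean alternate-allele fraction per (chrom, pos, alt) across controls."""

    def __init__(self, rates: Dict[str, np.ndarray], n_controls: int,
                 floor: float = BACKGROUND_FLOOR):
        self.rates = rates          # chrom -> (4, L) array, floored
        self.n_controls = n_controls
        self.floor = floor

    def rate(self, chrom: str, pos: int, alt: str) -> float:
        return float(self.rates[chrom][BASES.index(alt), pos])


def estimate_background(control_pileups: Sequence[Pileup],
                        floor: float = BACKGROUND_FLOOR) -> BackgroundErrorModel:
    """Estimate b(chrom, pos, alt) as the arithmetic mean over control
    samples of each sample's alternate allele fraction, then floor it.

    Sites with zero depth in a control are excluded from that sample's
    contribution (mean over the remaining samples).
    """
    if not control_pileups:
        raise ConfigError("at least one control sample is required")
    first = control_pileups[0]
    rates: Dict[str, np.ndarray] = {}
    for chrom, counts in first.counts.items():
        length = counts.shape[1]
        total = np.zeros((4, length))
        n_obs = np.zeros(length)
        for pile in control_pileups:
            c = pile.counts[chrom].astype(float)
            depth = c.sum(axis=0)
            has = depth > 0
            frac = np.zeros_like(c)
            frac[:, has] = c[:, has] / depth[has]
            total[:, has] += frac[:, has]
            n_obs += has
        mean = np.zeros((4, length))
        covered = n_obs > 0
        mean[:, covered] = total[:, covered] / n_obs[covered]
        # the model describes alternate bases only; blank the ref-base slot
        ref_codes = first.reference.codes(chrom)
        mean[ref_codes, np.arange(length)] = 0.0
        rates[chrom] = np.maximum(mean, floor)
    return BackgroundErrorModel(rates, n_controls=len(control_pileups), floor=floor)


@dataclass
class VariantCall:
    chrom: str
    pos: int            # 0-based
    ref: str
    alt: str
    alt_count: int
    depth: int
    af: float
    background: float
    pass_af: bool
    pass_depth: bool
    pass_background: bool

    @property
    def is_pass(self) -> bool:
        return self.pass_af and self.pass_depth and self.pass_background

    def filter_tags(self) -> List[str]:
        tags = []
        if not self.pass_af:
            tags.append("lowAF")
        if not self.pass_depth:
            tags.append("lowDepth")
        if not self.pass_background:
            tags.append("bgRatio")
        return tags or ["PASS"]


def call_variants(pileup: Pileup,
                  background: BackgroundErrorModel,
                  thresholds: Optional[Mapping[str, float]] = None) -> List[VariantCall]:
    """Emit one VariantCall per (panel site, non-reference base with a > 0)."""
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    min_af = float(th["min_af"])
    min_alt = int(th["min_alt_reads"])
    factor = float(th["background_factor"])

    calls: List[VariantCall] = []
    for chrom in sorted(pileup.counts):
        counts = pileup.counts[chrom]
        covered = np.flatnonzero(pileup.mask[chrom])
        if covered.size == 0:
            continue
        sub = counts[:, covered]
        depth = sub.sum(axis=0)
        ref_codes = pileup.reference.codes(chrom)[covered]
        bg = background.rates[chrom][:, covered]
        with np.errstate(invalid="ignore", divide="ignore"):
            af = np.where(depth > 0, sub / np.maximum(depth, 1), 0.0)
        for alt_code in range(4):
            is_alt = ref_codes != alt_code
            has_reads = (sub[alt_code] > 0) & is_alt
            for j in np.flatnonzero(has_reads):
                a = int(sub[alt_code, j])
                d = int(depth[j])
                f = float(af[alt_code, j])
                b = float(bg[alt_code, j])
                calls.append(VariantCall(
                    chrom=chrom, pos=int(covered[j]),
                    ref=BASES[ref_codes[j]], alt=BASES[alt_code],
                    alt_count=a, depth=d, af=f, background=b,
                    pass_af=f >= min_af,
                    pass_depth=a >= min_alt,
                    pass_background=f >= factor * b))
    calls.sort(key=lambda c: (c.chrom, c.pos, c.alt))
    return calls
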