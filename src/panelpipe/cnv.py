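"""Amplicon read-count copy-number calling.

Per-sample coverage is normalised by the median read count over control
amplicons; per-amplicon log2 ratios of the corrected tumor vs baseline
counts are summarised per gene by their median, and genes are called
loss/neutral/gain against configurable thresholds (default +/-0.5 in
log2 units).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np

from .align import Alignment
from .errors import ConfigError
from .sim.panel import Amplicon, PanelDesign

DEFAULT_LOSS_THRESHOLD = -0.5
DEFAULT_GAIN_THRESHOLD = 0.5
DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class AmpliconCounts:
    sample_id: str
    counts: Dict[str, int]          # amplicon_id -> read count
    n_unassigned: int = 0

    def vector(self, panel: PanelDesign) -> np.ndarray:
        try:
            return np.array([self.counts[a.amplicon_id] for a in panel], dtype=float)
        except KeyError as exc:
            raise ConfigError(f"counts missing amplicon {exc.args[0]!r}") from exc


@dataclass
class GeneCall:
    gene: str
    median_log2_ratio: float
    call: str                       # "loss" | "neutral" | "gain"
    n_amplicons: int


@dataclass
class CopyNumberProfile:
    sample_id: str
    log2_ratios: Dict[str, float]   # amplicon_id -> log2 ratio
    gene_calls: Dict[str, GeneCall]
    tumor_factor: float
    baseline_factor: float


def count_amplicons(alignments: Sequence[Alignment], panel: PanelDesign,
                    sample_id: str = "sample", dedupe: bool = True) -> AmpliconCounts:
    """Count aligned primary reads per amplicon.

    A read increments the amplicon whose interval contains its leftmost
    position; where overlapping amplicons both contain it, the one with
    the larger start wins (deterministic).  Reads matching no amplicon
    are counted separately as unassigned.
    """
    lookup: Dict[str, List[Amplicon]] = {}
    for amp in sorted(panel, key=lambda a: a.start):
        lookup.setdefault(amp.chrom, []).append(amp)
    counts = {a.amplicon_id: 0 for a in panel}
    unassigned = 0
    for aln in alignments:
        if not aln.aligned or (dedupe and aln.is_duplicate):
            continue
        hit = None
        for amp in lookup.get(aln.chrom, ()):  # sorted by start: last match wins
            if amp.start <= aln.pos < amp.end:
                hit = amp
        if hit is None:
            unassigned += 1
        else:
            counts[hit.amplicon_id] += 1
    return AmpliconCounts(sample_id, counts, n_unassigned=unassigned)


def coverage_correction(sample_counts: AmpliconCounts, panel: PanelDesign) -> float:
    """Scaling factor = median raw count over control amplicons."""
    try:
        ctrl = [sample_counts.counts[a.amplicon_id] for a in panel.control_amplicons]
    except KeyError as exc:
        raise ConfigError(f"counts missing amplicon {exc.args[0]!r}") from exc
    if not ctrl or max(ctrl) == 0:
        raise ConfigError("all control amplicons have zero counts")
    return float(np.median(ctrl))


def log_ratios(tumor: AmpliconCounts, baseline: AmpliconCounts, panel: PanelDesign,
               pseudocount: float = DEFAULT_PSEUDOCOUNT,
               loss_threshold: float = DEFAULT_LOSS_THRESHOLD,
               gain_threshold: float = DEFAULT_GAIN_THRESHOLD) -> CopyNumberProfile:
    """Per-amplicon log2 ratios and per-gene calls.

    Both samples are corrected by their own control-amplicon median
    factor.  The pseudocount is added to both raw counts only where one
    of them is zero, which keeps ratios exactly invariant to a global
    rescaling of either sample's counts whenever all counts are nonzero
    (and still defined at zero-count amplicons).  Control amplicons get
    log ratios but never gene calls.
    """
    ft = coverage_correction(tumor, panel)
    fb = coverage_correction(baseline, panel)
    t = tumor.vector(panel)
    b = baseline.vector(panel)
    add = np.where((t == 0) | (b == 0), pseudocount, 0.0)
    r = np.log2(((t + add) / ft) / ((b + add) / fb))
    ratios = {a.amplicon_id: float(r[i]) for i, a in enumerate(panel)}

    gene_calls: Dict[str, GeneCall] = {}
    for gene, amps in panel.by_gene().items():
        med = float(np.median([ratios[a.amplicon_id] for a in amps]))
        if med <= loss_threshold:
            call = "loss"
        elif med >= gain_threshold:
            call = "gain"
        else:
            call = "neutral"
        gene_calls[gene] = GeneCall(gene, med, call, len(amps))

    return CopyNumberProfile(sample_id=tumor.sample_id, log2_ratios=ratios,
                             gene_calls=gene_calls, tumor_factor=ft,
                             baseline_factor=fb)
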