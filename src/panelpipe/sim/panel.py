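"""Amplicon panel design.

Target genes are tiled with overlapping fixed-length amplicons; each of
the four control chromosomes carries 14-21 evenly spaced control
amplicons used for coverage normalisation in copy-number calling.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Tuple, Union

import numpy as np

from ..errors import ConfigError, PanelError
from .reference import ReferenceModel

MIN_CONTROL_AMPLICONS = 14
MAX_CONTROL_AMPLICONS = 21


@dataclass(frozen=True)
class Amplicon:
    amplicon_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    gene: str
    is_control: bool = False

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise PanelError(f"bad interval for {self.amplicon_id}: [{self.start},{self.end})")


class PanelDesign:
    """An ordered list of amplicons plus the target-gene map."""

    def __init__(self, amplicons: List[Amplicon],
                 target_genes: Mapping[str, Tuple[str, int, int]],
                 reference: Optional[ReferenceModel] = None):
        ids = [a.amplicon_id for a in amplicons]
        if len(set(ids)) != len(ids):
            raise PanelError("amplicon ids are not unique")
        self.amplicons: List[Amplicon] = list(amplicons)
        self.target_genes: Dict[str, Tuple[str, int, int]] = dict(target_genes)
        if reference is not None:
            self.validate_against(reference)

    def validate_against(self, reference: ReferenceModel) -> None:
        counts = {c: 0 for c in reference.control_chromosomes}
        for a in self.amplicons:
            if a.chrom not in reference:
                raise PanelError(f"{a.amplicon_id}: unknown chromosome {a.chrom!r}")
            if a.end > reference.length(a.chrom):
                raise PanelError(f"{a.amplicon_id} exceeds chromosome bounds")
            if a.is_control:
                if a.chrom not in counts:
                    raise PanelError(
                        f"control amplicon {a.amplicon_id} on non-control chromosome {a.chrom}")
                counts[a.chrom] += 1
        for chrom, n in counts.items():
            if not MIN_CONTROL_AMPLICONS <= n <= MAX_CONTROL_AMPLICONS:
                raise PanelError(
                    f"{chrom} carries {n} control amplicons (need "
                    f"{MIN_CONTROL_AMPLICONS}-{MAX_CONTROL_AMPLICONS})")

    def __len__(self):
        return len(self.amplicons)

    def __iter__(self):
        return iter(self.amplicons)

    @property
    def control_amplicons(self) -> List[Amplicon]:
        return [a for a in self.amplicons if a.is_control]

    @property
    def target_amplicons(self) -> List[Amplicon]:
        return [a for a in self.amplicons if not a.is_control]

    def by_gene(self) -> Dict[str, List[Amplicon]]:
        out: Dict[str, List[Amplicon]] = {}
        for a in self.target_amplicons:
            out.setdefault(a.gene, []).append(a)
        return out

    def gene_at(self, chrom: str, pos: int) -> Optional[str]:
        """Gene label whose target interval contains ``pos`` (None if outside)."""
        for gene, (gchrom, gstart, gend) in self.target_genes.items():
            if gchrom == chrom and gstart <= pos < gend:
                return gene
        return None

    def covered_mask(self, chrom: str, length: int) -> np.ndarray:
        """Boolean mask of positions on ``chrom`` covered by any amplicon."""
        mask = np.zeros(length, dtype=bool)
        for a in self.amplicons:
            if a.chrom == chrom:
                mask[a.start:a.end] = True
        return mask


def _tile_starts(start: int, end: int, length: int, step: int) -> List[int]:
    """Amplicon start positions tiling [start, end) contiguously."""
    starts = list(range(start, max(start + 1, end - length + 1), step))
    if starts[-1] + length < end:
        starts.append(end - length)
    return starts


def design_panel(reference: ReferenceModel,
                 target_genes: Mapping[str, Union[str, Tuple[str, int, int]]],
                 control_spec: Union[int, Mapping[str, int]] = MIN_CONTROL_AMPLICONS,
                 seed: int = 0,
                 amplicon_length: int = 150,
                 step: int = 100) -> PanelDesign:
    """Design an amplicon panel on ``reference``.

    Parameters
    ----------
    target_genes:
        Mapping gene name -> either a chromosome name (whole segment is
        the gene) or an explicit ``(chrom, start, end)`` interval.
    control_spec:
        Control amplicons per control chromosome: a single count applied
        to all four, or a per-chromosome mapping.  Each count must lie in
        [14, 21].
    seed:
        Accepted for interface uniformity; the design is deterministic.

    Notes
    -----
    Each gene is tiled with overlapping amplicons of ``amplicon_length``
    advancing by ``step`` so that the union of amplicon intervals covers
    the gene exactly.
    """
    del seed  # deterministic placement
    if step <= 0 or amplicon_length <= 0:
        raise ConfigError("amplicon_length and step must be positive")
    genes: Dict[str, Tuple[str, int, int]] = {}
    for gene, where in target_genes.items():
        if isinstance(where, str):
            if where not in reference:
                raise PanelError(f"gene {gene!r} maps to unknown chromosome {where!r}")
            genes[gene] = (where, 0, reference.length(where))
        else:
            chrom, gstart, gend = where
            if chrom not in reference:
                raise PanelError(f"gene {gene!r} maps to unknown chromosome {chrom!r}")
            genes[gene] = (chrom, int(gstart), int(gend))

    amplicons: List[Amplicon] = []
    for gene, (chrom, gstart, gend) in genes.items():
        chrom_len = reference.length(chrom)
        if gend - gstart > chrom_len or gend > chrom_len or gstart < 0:
            raise PanelError(f"gene {gene!r} does not fit on chromosome {chrom!r}")
        if gend - gstart < amplicon_length and gstart + amplicon_length > chrom_len:
            raise PanelError(f"gene {gene!r} too short to carry one amplicon")
        for i, s in enumerate(_tile_starts(gstart, gend, amplicon_length, step)):
            e = s + amplicon_length
            if e > chrom_len:
                s, e = chrom_len - amplicon_length, chrom_len
            amplicons.append(Amplicon(f"{gene}_a{i:03d}", chrom, s, e, gene))

    if isinstance(control_spec, int):
        control_counts = {c: control_spec for c in reference.control_chromosomes}
    else:
        control_counts = {c: int(control_spec[c]) for c in reference.control_chromosomes}
    for chrom, n in control_counts.items():
        if not MIN_CONTROL_AMPLICONS <= n <= MAX_CONTROL_AMPLICONS:
            raise ConfigError(
                f"control amplicon count {n} for {chrom} outside "
                f"[{MIN_CONTROL_AMPLICONS},{MAX_CONTROL_AMPLICONS}]")
        avail = reference.length(chrom) - amplicon_length
        if avail < 0:
            raise PanelError(f"control chromosome {chrom} shorter than one amplicon")
        starts = sorted({int(round(i * avail / max(1, n - 1))) for i in range(n)})
        if len(starts) != n:
            raise PanelError(f"cannot place {n} distinct control amplicons on {chrom}")
        for i, s in enumerate(starts):
            amplicons.append(Amplicon(f"CTRL_{chrom}_a{i:02d}", chrom, s,
                                      s + amplicon_length, chrom, is_control=True))

    return PanelDesign(amplicons, genes, reference=reference)
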