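"""Read-level sample simulation with spike-in lesions.

Reads are single-end with constant configured length.  Per-amplicon read
counts are Poisson(depth x copy-ratio of the covering gene); reads start
at the amplicon start, so a read covers its amplicon when amplicon
length equals read length.  Point mutations are carried by overlapping
reads with probability equal to the allele fraction, fusion junction
reads are emitted at an exact count with at least 30 bases on each side
of the junction, and sequencing/fixation noise is modelled as i.i.d.
base errors at a uniform rate.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .._seq import decode, encode
from ..errors import ConfigError
from .panel import PanelDesign
from .reference import ReferenceModel

MIN_FUSION_READ_LENGTH = 60  # two 30 bp anchors must fit in one read


@dataclass(frozen=True)
class SnvSpec:
    chrom: str
    pos: int          # 0-based
    ref: str
    alt: str
    vaf: float        # allele fraction in [0,1]

    def __post_init__(self):
        if not 0.0 <= self.vaf <= 1.0:
            raise ConfigError(f"allele fraction {self.vaf} outside [0,1]")
        if self.ref == self.alt or len(self.ref) != 1 or len(self.alt) != 1:
            raise ConfigError(f"bad SNV alleles {self.ref}>{self.alt}")


@dataclass(frozen=True)
class FusionSpec:
    """A junction joining ``chrom_a`` upstream of ``pos_a`` to ``chrom_b``
    downstream of ``pos_b`` (both segments read in forward orientation)."""
    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    n_reads: int
    orientation: str = "AB"

    def __post_init__(self):
        if self.n_reads < 0:
            raise ConfigError("junction-read count must be >= 0")
        if self.orientation != "AB":
            raise ConfigError(f"unsupported fusion orientation {self.orientation!r}")


@dataclass(frozen=True)
class CnvSpec:
    gene: str
    copy_ratio: float

    def __post_init__(self):
        if self.copy_ratio <= 0:
            raise ConfigError(f"copy ratio must be > 0, got {self.copy_ratio}")


@dataclass
class LesionSpec:
    snvs: List[SnvSpec] = field(default_factory=list)
    fusions: List[FusionSpec] = field(default_factory=list)
    cnvs: List[CnvSpec] = field(default_factory=list)

    def is_empty(self) -> bool:
        return not (self.snvs or self.fusions or self.cnvs)


@dataclass
class SimRead:
    read_id: str
    seq: str
    # true origin interval; junction reads record the A-side interval and
    # carry is_junction=True
    chrom: Optional[str]
    start: Optional[int]
    end: Optional[int]
    is_junction: bool = False


@dataclass
class SimulatedSample:
    sample_id: str
    sample_class: str                 # "tumor" | "control-blood"
    reads: List[SimRead]
    truth: LesionSpec
    base_error_rate: float
    seed: int
    read_length: int
    amplicon_counts: Dict[str, int]   # true per-amplicon read counts
    n_junction_reads: int


def _apply_errors(matrix: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    if rate <= 0 or matrix.size == 0:
        return
    mask = rng.random(matrix.shape) < rate
    k = int(mask.sum())
    if k:
        shift = rng.integers(1, 4, size=k, dtype=np.uint8)
        matrix[mask] = (matrix[mask] + shift) % 4


def simulate_sample(reference: ReferenceModel,
                    panel: PanelDesign,
                    lesions: Optional[LesionSpec] = None,
                    depth: float = 200.0,
                    read_length: int = 150,
                    base_error_rate: float = 0.0,
                    seed: int = 0,
                    sample_id: str = "S1",
                    sample_class: str = "tumor") -> SimulatedSample:
    """Simulate one sample's panel reads.

    Raises
    ------
    ConfigError
        On non-positive depth, a read length below 60 when fusions are
        spiked, or an SNV whose stated reference base does not match the
        reference sequence.

    Warns
    -----
    UserWarning
        For an SNV outside every panel amplicon (unobservable; it is
        excluded from the truth record).
    """
    if depth <= 0:
        raise ConfigError(f"depth must be > 0, got {depth}")
    lesions = lesions or LesionSpec()
    if lesions.fusions and read_length < MIN_FUSION_READ_LENGTH:
        raise ConfigError(
            f"read_length must be >= {MIN_FUSION_READ_LENGTH} when fusions are spiked")
    rng = np.random.default_rng(seed)
    ratio_by_gene = {c.gene: c.copy_ratio for c in lesions.cnvs}

    # SNV bookkeeping: validate and decide observability
    observable_snvs: List[SnvSpec] = []
    for snv in lesions.snvs:
        if snv.chrom not in reference or not 0 <= snv.pos < reference.length(snv.chrom):
            raise ConfigError(f"SNV position {snv.chrom}:{snv.pos} outside reference")
        if reference.sequence(snv.chrom)[snv.pos] != snv.ref:
            raise ConfigError(
                f"SNV ref base mismatch at {snv.chrom}:{snv.pos} "
                f"(reference has {reference.sequence(snv.chrom)[snv.pos]!r})")
        if any(a.chrom == snv.chrom and a.start <= snv.pos < a.end for a in panel):
            observable_snvs.append(snv)
        else:
            warnings.warn(
                f"SNV at {snv.chrom}:{snv.pos} overlaps no amplicon; unobservable",
                stacklevel=2)

    reads: List[SimRead] = []
    amplicon_counts: Dict[str, int] = {}
    for amp in panel:
        lam = depth * ratio_by_gene.get(amp.gene, 1.0)
        n = int(rng.poisson(lam))
        amplicon_counts[amp.amplicon_id] = n
        if n == 0:
            continue
        chrom_len = reference.length(amp.chrom)
        s = min(amp.start, max(0, chrom_len - read_length))
        e = min(s + read_length, chrom_len)
        template = reference.codes(amp.chrom)[s:e]
        matrix = np.tile(template, (n, 1))
        for snv in observable_snvs:
            if snv.chrom == amp.chrom and s <= snv.pos < e:
                carriers = rng.random(n) < snv.vaf
                matrix[carriers, snv.pos - s] = encode(snv.alt)[0]
        _apply_errors(matrix, base_error_rate, rng)
        for i in range(n):
            reads.append(SimRead(f"{sample_id}:{amp.amplicon_id}:{i}",
                                 decode(matrix[i]), amp.chrom, s, e))

    n_junction = 0
    for fi, fus in enumerate(lesions.fusions):
        for name, pos in ((fus.chrom_a, fus.pos_a), (fus.chrom_b, fus.pos_b)):
            if name not in reference:
                raise ConfigError(f"fusion breakpoint on unknown chromosome {name!r}")
        left_len = max(30, read_length // 2)
        right_len = read_length - left_len
        if fus.pos_a - left_len < 0 or fus.pos_b + right_len > reference.length(fus.chrom_b):
            raise ConfigError("fusion breakpoints too close to segment ends")
        junction = np.concatenate([
            reference.codes(fus.chrom_a)[fus.pos_a - left_len:fus.pos_a],
            reference.codes(fus.chrom_b)[fus.pos_b:fus.pos_b + right_len],
        ])
        matrix = np.tile(junction, (fus.n_reads, 1))
        _apply_errors(matrix, base_error_rate, rng)
        for i in range(fus.n_reads):
            reads.append(SimRead(f"{sample_id}:fusion{fi}:{i}", decode(matrix[i]),
                                 fus.chrom_a, fus.pos_a - left_len, fus.pos_a,
                                 is_junction=True))
        n_junction += fus.n_reads

    truth = LesionSpec(snvs=observable_snvs, fusions=list(lesions.fusions),
                       cnvs=list(lesions.cnvs))
    return SimulatedSample(sample_id=sample_id, sample_class=sample_class,
                           reads=reads, truth=truth,
                           base_error_rate=base_error_rate, seed=seed,
                           read_length=read_length,
                           amplicon_counts=amplicon_counts,
                           n_junction_reads=n_junction)
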