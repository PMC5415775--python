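"""Synthetic reference genome segments.

The reference is a small set of named chromosome segments with random
uniform base composition.  Four designated control chromosomes must be
present because the copy-number baseline correction relies on control
amplicons placed on them.  All coordinates are 0-based, half-open.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Tuple

import numpy as np

from .._seq import BASES, decode, encode
from ..errors import ConfigError

#: Chromosomes that must exist in every reference so control amplicons
#: can be placed on them.
CONTROL_CHROMOSOMES: Tuple[str, ...] = ("chr5", "chr8", "chr11", "chr18")


@dataclass(frozen=True)
class ReferenceConfig:
    """Configuration for :func:`build_reference`.

    Parameters
    ----------
    chromosomes:
        Mapping of chromosome name to length in bases.
    control_chromosomes:
        Names reserved for copy-number control amplicons; all must be
        present in ``chromosomes``.
    """

    chromosomes: Mapping[str, int]
    control_chromosomes: Tuple[str, ...] = CONTROL_CHROMOSOMES

    def validate(self) -> None:
        if not self.chromosomes:
            raise ConfigError("reference config names no chromosomes")
        for name, length in self.chromosomes.items():
            if int(length) <= 0:
                raise ConfigError(f"chromosome {name!r} has non-positive length {length}")
        missing = [c for c in self.control_chromosomes if c not in self.chromosomes]
        if missing:
            raise ConfigError(f"control chromosomes missing from config: {missing}")


class ReferenceModel:
    """A set of named sequence segments over {A,C,G,T}.

    Sequences are stored both as strings and as uint8 code arrays
    (A=0, C=1, G=2, T=3) for fast alignment arithmetic.
    """

    def __init__(self, segments: Mapping[str, str],
                 control_chromosomes: Tuple[str, ...] = CONTROL_CHROMOSOMES):
        if not segments:
            raise ConfigError("reference has no segments")
        names = list(segments)
        if len(set(names)) != len(names):
            raise ConfigError("duplicate chromosome names")
        self._seqs: Dict[str, str] = {}
        self._codes: Dict[str, np.ndarray] = {}
        for name, seq in segments.items():
            if not seq:
                raise ConfigError(f"chromosome {name!r} is empty")
            codes = encode(seq)
            if (codes == 255).any():
                raise ConfigError(f"chromosome {name!r} contains non-ACGT characters")
            self._seqs[name] = seq
            self._codes[name] = codes
        self.control_chromosomes = tuple(control_chromosomes)

    @property
    def names(self):
        return list(self._seqs)

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def length(self, name: str) -> int:
        return len(self._seqs[name])

    def sequence(self, name: str) -> str:
        return self._seqs[name]

    def codes(self, name: str) -> np.ndarray:
        return self._codes[name]

    def items(self):
        return self._seqs.items()


def build_reference(config: ReferenceConfig, seed: int) -> ReferenceModel:
    """Generate a random reference under a uniform base model.

    Deterministic for a fixed ``(config, seed)``.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    segments = {}
    for name, length in config.chromosomes.items():
        codes = rng.integers(0, len(BASES), size=int(length), dtype=np.uint8)
        segments[name] = decode(codes)
    return ReferenceModel(segments, control_chromosomes=tuple(config.control_chromosomes))
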