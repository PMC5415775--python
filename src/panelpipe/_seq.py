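"""Nucleotide sequence <-> integer code helpers.

Codes: A=0, C=1, G=2, T=3. Anything else maps to 255 (invalid).
Coordinates throughout the package are 0-based, half-open.
"""
from __future__ import annotations

import numpy as np

BASES = "ACGT"
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)
# complement of code i is 3-i


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 code array."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back into a DNA string."""
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes[::-1]).astype(np.uint8)


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))
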