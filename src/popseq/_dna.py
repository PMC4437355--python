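"""Byte-level DNA encoding shared by the simulator and the k-mer layer.

Bases are held as uint8 codes (A=0, C=1, G=2, T=3); anything else maps to
``INVALID`` and is skipped by windowed operations.
"""

from __future__ import annotations

import numpy as np

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

INVALID = np.uint8(255)

ENCODE = np.full(256, INVALID, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    ENCODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    ENCODE[_b] = _i


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode a DNA string into uint8 base codes (invalid characters -> 255)."""
    return ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def codes_to_seq(codes: np.ndarray) -> str:
    """Decode uint8 base codes (all < 4) back into an A/C/G/T string."""
    return BASES[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")
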