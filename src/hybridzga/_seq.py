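"""Low-level nucleotide encoding helpers shared across modules.

Bases are encoded A=0, C=1, G=2, T=3 so that the complement of a code ``x``
is ``3 - x``. Unknown characters (N etc.) map to 255 and are never packed
into k-mers.
"""

from __future__ import annotations

import numpy as np

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_ENC = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _ENC[b] = i
    _ENC[b + 32] = i  # lowercase


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a nucleotide string into uint8 codes (non-ACGT -> 255)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _ENC[np.frombuffer(seq, dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode uint8 codes back into a string (255 -> N)."""
    out = np.full(codes.shape, ord("N"), dtype=np.uint8)
    ok = codes < 4
    out[ok] = BASES[codes[ok]]
    return out.tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement along the last axis of a code array."""
    rc = np.where(codes < 4, 3 - codes, codes)
    return rc[..., ::-1]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))
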