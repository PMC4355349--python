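"""Low-level nucleotide helpers shared across modules.

Bases are encoded as uint8: A=0, C=1, G=2, T=3, N=4.  The complement of a
code c < 4 is 3 - c, which the reverse-complement routines rely on.
"""

from __future__ import annotations

import numpy as np

CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
BASES = "ACGTN"

_ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _c in CODE.items():
    _ENCODE_LUT[ord(_b)] = _c

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def encode(seq: str) -> np.ndarray:
    """Encode an uppercase A/C/G/T/N string as a uint8 code array."""
    codes = _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if codes.size and codes.max() == 255:
        bad = seq[int(np.argmax(codes == 255))]
        raise ValueError(f"disallowed character {bad!r} in sequence")
    return codes


def decode(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = codes[::-1].copy()
    acgt = out < 4
    out[acgt] = 3 - out[acgt]
    return out
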