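"""Nucleotide encoding shared by the scanner and simulator.

Bases are encoded A=0, C=1, G=2, T=3; anything else (N and IUPAC
ambiguity codes) maps to 4 so that scoring matrices can carry a
sentinel column that poisons N-containing windows.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
N_CODE = 4

_ENC = np.full(256, N_CODE, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

# reverse-complement in code space; N stays N
RC_CODE = np.array([3, 2, 1, 0, 4], dtype=np.int8)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to int8 codes (A=0 .. T=3, other=4)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)


def decode(codes: np.ndarray) -> str:
    return _DEC[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return RC_CODE[codes[::-1]]
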