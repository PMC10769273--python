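"""Low-level DNA sequence utilities shared across modules.

All sequences are handled as uppercase DNA strings (T, not U); numpy
integer encodings are used on hot paths (ORF enumeration, hexamer
counting).  Base encoding: A=0, C=1, G=2, T=3, anything else 4.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans(
    "ACGTNRYSWKMBDHVacgtnryswkmbdhv",
    "TGCANYRSWMKVHDBtgcanyrswmkvhdb",
)

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i

BASES = "ACGT"


def normalize(seq: str) -> str:
    """Uppercase and convert RNA (U) to DNA (T)."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    """Reverse complement; IUPAC ambiguity codes are complemented too."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode to uint8 array; non-ACGT bases become 4."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def codon_to_code(codon: str) -> int:
    """Base-4 integer code of an ACGT codon (0..63)."""
    a, b, c = (BASES.index(x) for x in codon)
    return 16 * a + 4 * b + c


def code_to_codon(code: int) -> str:
    return BASES[code >> 4] + BASES[(code >> 2) & 3] + BASES[code & 3]


def codon_codes(enc: np.ndarray, frame: int) -> np.ndarray:
    """Integer codes of consecutive codons in a frame; -1 where a codon
    contains a non-ACGT base."""
    n = (len(enc) - frame) // 3
    if n <= 0:
        return np.empty(0, dtype=np.int32)
    a = enc[frame : frame + 3 * n].reshape(n, 3).astype(np.int32)
    codes = a[:, 0] * 16 + a[:, 1] * 4 + a[:, 2]
    codes[(a >= 4).any(axis=1)] = -1
    return codes


def hexamer_codes(enc: np.ndarray) -> np.ndarray:
    """Integer codes (0..4095) of all overlapping 6-mers; -1 where the
    window contains a non-ACGT base.  Length is len(enc) - 5."""
    if len(enc) < 6:
        return np.empty(0, dtype=np.int64)
    a = np.lib.stride_tricks.sliding_window_view(enc, 6).astype(np.int64)
    codes = a[:, 0]
    for k in range(1, 6):
        codes = codes * 4 + a[:, k]
    codes = codes.copy()
    codes[(a >= 4).any(axis=1)] = -1
    return codes


def hexamer_to_code(hexamer: str) -> int:
    code = 0
    for ch in hexamer:
        code = code * 4 + BASES.index(ch)
    return code
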