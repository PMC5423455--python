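"""Amino-acid alphabet used throughout the package.

The internal alphabet is the 20 canonical residues plus ``X`` (unknown),
encoded as small integers with 0 reserved for the per-entry sentinel of the
packed reference text.  The translated-read stop marker ``*`` receives its
own code; it never occurs in a reference, so any exact match containing it
has zero occurrences by construction.
"""

from __future__ import annotations

import numpy as np

#: canonical residues + X, in sorted order; code = position + 1
AA_LETTERS = "ACDEFGHIKLMNPQRSTVWXY"
SENTINEL_CODE = 0
STOP = "*"
STOP_CODE = len(AA_LETTERS) + 1  # 22; absent from every index
N_CODES = len(AA_LETTERS) + 2  # sentinel + residues + stop

#: IUPAC ambiguity / rare residues folded onto the canonical set
AMBIGUITY_FOLD = {"B": "D", "Z": "E", "J": "L", "U": "C", "O": "K"}

_ENCODE = np.zeros(128, dtype=np.int8)
for _i, _c in enumerate(AA_LETTERS):
    _ENCODE[ord(_c)] = _i + 1
    _ENCODE[ord(_c.lower())] = _i + 1
_ENCODE[ord(STOP)] = STOP_CODE

_DECODE = np.array(["$"] + list(AA_LETTERS) + [STOP])


def normalize_protein(seq: str) -> str:
    """Uppercase, fold ambiguity codes, map anything non-canonical to X.

    A single trailing ``*`` (translation stop) is stripped; internal stops
    become ``X`` so the scoring alphabet stays closed.
    """
    seq = seq.upper()
    if seq.endswith(STOP):
        seq = seq[:-1]
    out = []
    for c in seq:
        c = AMBIGUITY_FOLD.get(c, c)
        out.append(c if c in AA_LETTERS else "X")
    return "".join(out)


def encode_aa(seq: str) -> np.ndarray:
    """Encode an amino-acid string (may contain ``*``) to int8 codes."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = _ENCODE[arr & 0x7F]
    # any unmapped character encodes as 0 == sentinel; remap to X
    codes = np.where((codes == 0), _ENCODE[ord("X")], codes).astype(np.int8)
    return codes


def decode_aa(codes: np.ndarray) -> str:
    return "".join(_DECODE[codes])
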