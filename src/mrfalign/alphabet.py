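"""Amino-acid alphabet shared across the package.

The working alphabet has 21 symbols: the 20 standard amino acids plus the
gap character ``-``.  Nonstandard/unknown residues (``X``, ``B``, ``Z``,
``U``, ``O``, ``J``, ``*``, ``.``) carry no single-letter identity and are
spread uniformly over the 20 amino acids when counting.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
ALPHABET = AMINO_ACIDS + GAP
NSYM = len(ALPHABET)  # 21
GAP_INDEX = NSYM - 1
UNKNOWN_CODE = NSYM  # internal code for X-like residues

_CODE = {c: i for i, c in enumerate(ALPHABET)}


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a sequence string as integer codes (0..20, 21 for unknown)."""
    out = np.empty(len(seq), dtype=np.int8)
    for i, c in enumerate(seq.upper()):
        if c == ".":
            c = "-"
        out[i] = _CODE.get(c, UNKNOWN_CODE)
    return out


def onehot_rows(codes: np.ndarray) -> np.ndarray:
    """Map integer codes to rows of a soft one-hot matrix over 21 symbols.

    Unknown residues become a uniform 1/20 row over the amino acids (gap
    component zero), so every row sums to 1.
    """
    table = np.zeros((NSYM + 1, NSYM))
    table[:NSYM] = np.eye(NSYM)
    table[UNKNOWN_CODE, :GAP_INDEX] = 1.0 / (NSYM - 1)
    return table[codes]
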