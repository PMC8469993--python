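"""Amino-acid alphabet conventions shared across the package.

The 20 standard residues are kept in alphabetical one-letter order; every
profile matrix column, BLOSUM row and feature definition uses this order.
Gaps and ambiguity codes are recognised so that profile construction can
exclude them from column counts.
"""

from __future__ import annotations

import numpy as np

#: The 20 standard amino acids, alphabetical by one-letter code.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

N_AMINO_ACIDS: int = 20

#: Index of each standard residue in :data:`AMINO_ACIDS`.
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

GAP_CHAR: str = "-"

#: Ambiguity / non-standard codes tolerated in alignments but excluded from
#: profile counts (B=Asx, Z=Glx, X=any, U=Sec, O=Pyl).
AMBIGUITY_CODES: frozenset[str] = frozenset("BZXUO")

#: Every character an aligned row may contain.
ALLOWED_CHARS: frozenset[str] = frozenset(AMINO_ACIDS) | {GAP_CHAR} | AMBIGUITY_CODES

# Fast uppercase-byte -> column-index lookup; -1 marks gap/ambiguity.
_CODE_TABLE = np.full(128, -1, dtype=np.int8)
for _aa, _i in AA_INDEX.items():
    _CODE_TABLE[ord(_aa)] = _i


def encode_row(row: str) -> np.ndarray:
    """Encode an aligned row as int8 column indices (-1 for gap/ambiguity)."""
    raw = np.frombuffer(row.encode("ascii"), dtype=np.uint8)
    return _CODE_TABLE[raw]


def is_standard_residue(char: str) -> bool:
    return char in AA_INDEX
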