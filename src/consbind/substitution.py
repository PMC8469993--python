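"""BLOSUM62 substitution scores.

The matrix ships with the package as a plain-text table in the standard NCBI
layout and is re-indexed to the package's alphabetical residue order
(:data:`consbind.alphabet.AMINO_ACIDS`). Scores are integers in half-bit
log-odds units.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .alphabet import AA_INDEX, AMINO_ACIDS, N_AMINO_ACIDS


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A 20x20 integer substitution matrix over the standard residues.

    ``scores[i, j]`` is the score for substituting residue ``AMINO_ACIDS[i]``
    with ``AMINO_ACIDS[j]``; the matrix is symmetric.
    """

    scores: np.ndarray
    name: str = "BLOSUM62"

    def __post_init__(self) -> None:
        s = self.scores
        if s.shape != (N_AMINO_ACIDS, N_AMINO_ACIDS):
            raise ValueError(f"substitution matrix must be 20x20, got {s.shape}")
        if not np.array_equal(s, s.T):
            raise ValueError("substitution matrix must be symmetric")

    def score(self, a: str, b: str) -> int:
        """Score for the residue pair (a, b)."""
        return int(self.scores[AA_INDEX[a], AA_INDEX[b]])

    def row(self, residue: str) -> np.ndarray:
        """The score row for ``residue`` against all 20 residues, in alphabet order."""
        return self.scores[AA_INDEX[residue]]


def _parse_ncbi_matrix(text: str) -> dict[tuple[str, str], int]:
    entries: dict[tuple[str, str], int] = {}
    header: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if not header:
            header = fields
            continue
        row_res, values = fields[0], fields[1:]
        if len(values) != len(header):
            raise ValueError(f"malformed matrix row for residue {row_res!r}")
        for col_res, val in zip(header, values):
            entries[(row_res, col_res)] = int(val)
    if not header:
        raise ValueError("no header row found in matrix file")
    return entries


def load_blosum62() -> SubstitutionMatrix:
    """Load the packaged BLOSUM62 table, restricted to the 20 standard residues."""
    text = resources.files("consbind.data").joinpath("BLOSUM62.txt").read_text()
    entries = _parse_ncbi_matrix(text)
    scores = np.empty((N_AMINO_ACIDS, N_AMINO_ACIDS), dtype=np.int64)
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            scores[i, j] = entries[(a, b)]
    return SubstitutionMatrix(scores=scores)


_BLOSUM62: SubstitutionMatrix | None = None


def blosum62() -> SubstitutionMatrix:
    """Cached accessor for the packaged BLOSUM62 matrix."""
    global _BLOSUM62
    if _BLOSUM62 is None:
        _BLOSUM62 = load_blosum62()
    return _BLOSUM62
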