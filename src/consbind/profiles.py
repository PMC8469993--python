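"""Multiple-sequence-alignment profiles and conservation measures.

This module reads MSAs in two dialects (aligned multi-FASTA as produced by
PSI-BLAST post-processing, and A3M as produced by HHblits), turns them into
position-specific probability matrices (PSPMs), and computes the three
conservation measures used throughout the predictor:

* per-column Shannon entropy (nats), with its mean and standard deviation
  over the sequence,
* the inner product between a PSPM row and a BLOSUM62 row,
* the Kullback-Leibler divergence between wild-type and mutant PSPM rows.

All sequence positions at the public interfaces are 1-based along the
ungapped query sequence.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Union

import numpy as np
from Bio import SeqIO

from .alphabet import ALLOWED_CHARS, N_AMINO_ACIDS, encode_row
from .substitution import SubstitutionMatrix

DEFAULT_PSEUDOCOUNT: float = 1e-4

LN20: float = math.log(20.0)


class MsaFormatError(ValueError):
    """Raised when an alignment file violates the dialect's format contract."""


class Dialect(str, Enum):
    """Alignment dialects the reader understands."""

    psiblast = "psiblast"  # aligned multi-FASTA, all records equal length
    hhblits = "hhblits"    # A3M, lowercase = insertion relative to the query


@dataclass
class MSA:
    """A query-anchored multiple sequence alignment.

    ``rows[0]`` is the query; every row has exactly ``L`` columns after
    dialect normalization (A3M insertion columns removed).
    """

    source: Dialect
    query_id: str
    rows: list[str]
    row_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.rows:
            raise MsaFormatError("alignment has no rows")
        L = len(self.rows[0])
        if L < 1:
            raise MsaFormatError("alignment has zero columns")
        for idx, row in enumerate(self.rows):
            if len(row) != L:
                name = self.row_ids[idx] if idx < len(self.row_ids) else f"row {idx}"
                raise MsaFormatError(
                    f"record {name!r} has length {len(row)}, expected {L}"
                )
            bad = set(row) - ALLOWED_CHARS
            if bad:
                name = self.row_ids[idx] if idx < len(self.row_ids) else f"row {idx}"
                raise MsaFormatError(
                    f"record {name!r} contains unexpected characters {sorted(bad)}"
                )
        if not self.row_ids:
            self.row_ids = [f"row{idx}" for idx in range(len(self.rows))]

    @property
    def L(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def query(self) -> str:
        return self.rows[0]


def _normalize_a3m_row(row: str) -> str:
    # Lowercase letters and '.' mark insertions relative to the query; dropping
    # them restores the query-length column frame.
    return "".join(c for c in row if not c.islower() and c != ".")


def read_msa(path: Union[str, Path, io.TextIOBase], dialect: Union[Dialect, str]) -> MSA:
    """Read an MSA file in the given dialect.

    psiblast dialect: aligned multi-FASTA, all records of equal length.
    hhblits dialect: A3M; lowercase (insertion) characters are removed so
    every row has exactly the query's column count. Row order is preserved
    and the first record is taken as the query.
    """
    dialect = Dialect(dialect)
    if isinstance(path, io.TextIOBase):
        records = list(SeqIO.parse(path, "fasta"))
        name = "<stream>"
    else:
        records = list(SeqIO.parse(str(path), "fasta"))
        name = str(path)
    if not records:
        raise MsaFormatError(f"{name}: no FASTA records found")
    rows: list[str] = []
    ids: list[str] = []
    for rec in records:
        seq = str(rec.seq)
        if dialect is Dialect.hhblits:
            seq = _normalize_a3m_row(seq)
        rows.append(seq.upper())
        ids.append(rec.id)
    L = len(rows[0])
    for rid, row in zip(ids, rows):
        if len(row) != L:
            raise MsaFormatError(
                f"{name}: record {rid!r} has {len(row)} aligned columns, "
                f"query has {L}"
            )
    return MSA(source=dialect, query_id=ids[0], rows=rows, row_ids=ids)


@dataclass
class PSPM:
    """Position-specific probability matrix: L rows over the 20 residue types.

    Rows are probability distributions (sum to 1); with the default
    pseudocount every entry is strictly positive, which keeps the KL
    divergence finite.
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != N_AMINO_ACIDS:
            raise ValueError(f"PSPM must be Lx20, got {p.shape}")
        sums = p.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("PSPM rows must sum to 1")
        self.probs = p

    @property
    def L(self) -> int:
        return self.probs.shape[0]

    def row(self, k: int) -> np.ndarray:
        """Row at 1-based position ``k``."""
        if not 1 <= k <= self.L:
            raise IndexError(f"position {k} out of range 1..{self.L}")
        return self.probs[k - 1]


def build_pspm(msa: MSA, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> PSPM:
    """Column-wise residue frequencies of an MSA, additively smoothed.

    Gaps and ambiguity codes are excluded from both the counts and the
    denominator; an all-gap column falls back to the uniform distribution.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    codes = np.stack([encode_row(r) for r in msa.rows])  # (n_rows, L)
    L = msa.L
    counts = np.zeros((L, N_AMINO_ACIDS), dtype=float)
    valid = codes >= 0
    for j in range(N_AMINO_ACIDS):
        counts[:, j] = (codes == j).sum(axis=0)
    denom = valid.sum(axis=0).astype(float)
    probs = np.empty_like(counts)
    nonempty = denom > 0
    probs[nonempty] = (counts[nonempty] + pseudocount) / (
        denom[nonempty, None] + N_AMINO_ACIDS * pseudocount
    )
    probs[~nonempty] = 1.0 / N_AMINO_ACIDS
    return PSPM(probs=probs)


@dataclass(frozen=True)
class ConservationProfile:
    """Per-column entropies (nats) with their mean and sample SD."""

    entropies: np.ndarray
    mean: float
    sd: float


def column_entropies(pspm: PSPM) -> np.ndarray:
    p = pspm.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0.0, p * np.log(p), 0.0)
    return -terms.sum(axis=1)


def entropy(pspm: PSPM) -> ConservationProfile:
    """Shannon entropy per column, plus mean and sample (n-1) SD over columns.

    ``0 * log 0`` is treated as 0; the SD is 0 for a single-column profile.
    """
    e = column_entropies(pspm)
    mu = float(e.mean())
    sd = float(e.std(ddof=1)) if e.size > 1 else 0.0
    return ConservationProfile(entropies=e, mean=mu, sd=sd)


def blosum_inner_product(
    pspm: PSPM, k: int, residue: str, matrix: SubstitutionMatrix
) -> float:
    """Dot product of PSPM row ``k`` (1-based) with the BLOSUM62 row of ``residue``.

    Measures how compatible the column's residue distribution is with the
    given residue, in half-bit units.
    """
    return float(pspm.row(k) @ matrix.row(residue))


def blosum_profile(seq: str, pspm: PSPM, matrix: SubstitutionMatrix) -> np.ndarray:
    """Inner-product score at every position, scored with that sequence's own residue.

    Positions where the sequence has a gap or ambiguity code get NaN.
    """
    if len(seq) != pspm.L:
        raise ValueError("sequence length must equal profile length")
    codes = encode_row(seq.upper())
    out = np.full(pspm.L, np.nan)
    ok = codes >= 0
    out[ok] = np.einsum("ij,ij->i", pspm.probs[ok], matrix.scores[codes[ok]])
    return out


def kl_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Kullback-Leibler divergence sum(p * ln(p/q)) between two PSPM rows (nats)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("rows must have equal shape")
    support = p > 0.0
    if np.any(q[support] == 0.0):
        raise ValueError(
            "q has a zero where p is positive; use a positive pseudocount "
            "when building the PSPMs"
        )
    return float(np.sum(p[support] * np.log(p[support] / q[support])))


def kl_profile(p: PSPM, q: PSPM) -> np.ndarray:
    """KL divergence per position between two equal-length PSPMs."""
    if p.L != q.L:
        raise ValueError("profiles must have equal length")
    pp, qq = p.probs, q.probs
    if np.any((qq == 0.0) & (pp > 0.0)):
        raise ValueError("q has a zero where p is positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(pp > 0.0, pp * np.log(pp / qq), 0.0)
    return terms.sum(axis=1)


def write_msa_fasta(msa: MSA, path: Union[str, Path]) -> None:
    """Write an MSA as aligned multi-FASTA (the psiblast dialect)."""
    with open(path, "w") as fh:
        for rid, row in zip(msa.row_ids, msa.rows):
            fh.write(f">{rid}\n{row}\n")
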