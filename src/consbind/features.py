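"""Fixed 60-dimensional feature extraction for one missense mutation.

Each mutation is described by four MSAs (two alignment sources, wild-type and
mutant sequence) and three per-residue binding-prediction channels
(DNA-binding, RNA-binding, generic ligand). These are converted into:

* an MSA block of 30 features — per alignment source, the mutated-column
  entropy, its z-score, the sequence-wide entropy mean and SD for wild-type
  and mutant (8), their signed wild-type-minus-mutant differences (4), and
  the BLOSUM62 profile inner product for wild-type, mutant and their signed
  difference (3): 2 x (8 + 4 + 3) = 30;
* a binding block of 30 features — per channel and per conservation measure
  (entropy, BLOSUM inner product, KL divergence), the largest absolute
  wild-type/mutant conservation shift among that channel's predicted binding
  positions, the linear distance from that position to the mutation, and the
  channel's binding propensity there (3 x 3 x 3 = 27), plus the distance to
  the closest predicted binding residue per channel (3): 27 + 3 = 30.

The feature schema (names and order) is fixed and identical across records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np

from .alphabet import AA_INDEX
from .profiles import (
    DEFAULT_PSEUDOCOUNT,
    MSA,
    PSPM,
    blosum_profile,
    build_pspm,
    entropy,
    kl_profile,
)
from .substitution import SubstitutionMatrix, blosum62

#: z-scores collapse to 0 when the entropy SD is below this.
SIGMA_FLOOR: float = 1e-12

MSA_SOURCES: tuple[str, str] = ("psiblast", "hhblits")

CONSERVATION_MEASURES: tuple[str, str, str] = ("entropy", "blosum", "kl")


class Channel(str, Enum):
    """Binding-prediction channels: NucBind-style DNA and RNA, S-SITE-style generic."""

    dna = "dna"
    rna = "rna"
    generic = "generic"


CHANNELS: tuple[Channel, Channel, Channel] = (Channel.dna, Channel.rna, Channel.generic)


class ContractError(ValueError):
    """Raised when inputs violate an operation's contract."""


@dataclass(frozen=True)
class MutationRecord:
    """One amino-acid substitution event, with an optional deleterious label."""

    protein_id: str
    wt_sequence: str
    position: int  # 1-based
    wt_residue: str
    mut_residue: str
    label: Optional[int] = None

    def __post_init__(self) -> None:
        k, L = self.position, len(self.wt_sequence)
        if not 1 <= k <= L:
            raise ContractError(
                f"{self.protein_id}: position {k} outside sequence of length {L}"
            )
        if self.wt_sequence[k - 1] != self.wt_residue:
            raise ContractError(
                f"{self.protein_id}: sequence has {self.wt_sequence[k - 1]!r} at "
                f"position {k}, record claims wild-type {self.wt_residue!r}"
            )
        if self.wt_residue == self.mut_residue:
            raise ContractError(f"{self.protein_id}: wild-type equals mutant residue")
        for res in (self.wt_residue, self.mut_residue):
            if res not in AA_INDEX:
                raise ContractError(f"{self.protein_id}: non-standard residue {res!r}")
        if self.label is not None and self.label not in (0, 1):
            raise ContractError(f"{self.protein_id}: label must be 0/1")

    @property
    def mutant_sequence(self) -> str:
        k = self.position
        return self.wt_sequence[: k - 1] + self.mut_residue + self.wt_sequence[k:]


@dataclass
class BindingPrediction:
    """Per-residue binary binding calls and propensities for one channel."""

    channel: Channel
    calls: np.ndarray
    propensities: np.ndarray

    def __post_init__(self) -> None:
        self.channel = Channel(self.channel)
        self.calls = np.asarray(self.calls, dtype=int)
        self.propensities = np.asarray(self.propensities, dtype=float)
        if self.calls.shape != self.propensities.shape or self.calls.ndim != 1:
            raise ContractError("calls and propensities must be equal-length vectors")
        if not np.isin(self.calls, (0, 1)).all():
            raise ContractError("calls must be binary")
        if ((self.propensities < 0) | (self.propensities > 1)).any():
            raise ContractError("propensities must lie in [0, 1]")

    @property
    def L(self) -> int:
        return self.calls.size

    @property
    def m(self) -> int:
        """Number of predicted binding residues."""
        return int(self.calls.sum())

    @property
    def positions(self) -> np.ndarray:
        """1-based positions of the predicted binding residues."""
        return np.flatnonzero(self.calls) + 1


# --------------------------------------------------------------------------
# Feature schema
# --------------------------------------------------------------------------

_MSA_SUBFEATURES = ("entropy", "zscore", "entropy_mean", "entropy_sd")


def msa_block_names(source: str) -> list[str]:
    """The 15 MSA-block feature names for one alignment source (8 + 4 + 3)."""
    names = [f"{source}_wt_{s}" for s in _MSA_SUBFEATURES]
    names += [f"{source}_mut_{s}" for s in _MSA_SUBFEATURES]
    names += [f"{source}_delta_{s}" for s in _MSA_SUBFEATURES]
    names += [f"{source}_wt_blosum", f"{source}_mut_blosum", f"{source}_delta_blosum"]
    return names


def binding_block_names() -> list[str]:
    """The 30 binding-block feature names (27 screening features + 3 distances)."""
    names = []
    for ch in CHANNELS:
        for meas in CONSERVATION_MEASURES:
            names += [
                f"{ch.value}_{meas}_max_shift",
                f"{ch.value}_{meas}_max_shift_dist",
                f"{ch.value}_{meas}_max_shift_propensity",
            ]
    names += [f"{ch.value}_min_binding_dist" for ch in CHANNELS]
    return names


MSA_BLOCK_NAMES: list[str] = [n for src in MSA_SOURCES for n in msa_block_names(src)]
BINDING_BLOCK_NAMES: list[str] = binding_block_names()
FEATURE_NAMES: list[str] = MSA_BLOCK_NAMES + BINDING_BLOCK_NAMES

FEATURE_GROUPS: dict[str, list[str]] = {
    "msa_block": MSA_BLOCK_NAMES,
    "binding_block": BINDING_BLOCK_NAMES,
}


@dataclass
class FeatureVector:
    """The 60 named features for one mutation."""

    values: np.ndarray
    names: Sequence[str] = field(default_factory=lambda: list(FEATURE_NAMES))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names),):
            raise ContractError("values/names length mismatch")
        if not np.isfinite(self.values).all():
            bad = [n for n, v in zip(self.names, self.values) if not np.isfinite(v)]
            raise ContractError(f"non-finite features: {bad}")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))


# --------------------------------------------------------------------------
# Blocks
# --------------------------------------------------------------------------

def msa_feature_block(
    wt_pspm: PSPM,
    mut_pspm: PSPM,
    k: int,
    wt_residue: str,
    mut_residue: str,
    matrix: Optional[SubstitutionMatrix] = None,
) -> np.ndarray:
    """The 15 conservation features from one alignment source.

    Order: (e_k, z_k, mu, sigma) wild-type; same for mutant; the four signed
    wild-type-minus-mutant differences; BLOSUM inner product b_k for the
    wild-type residue on the wild-type profile, for the mutant residue on
    the mutant profile, and their signed difference. z_k is defined as
    (e_k - mu) / sigma and set to 0 when sigma vanishes.
    """
    if wt_pspm.L != mut_pspm.L:
        raise ContractError(
            f"profile lengths differ: {wt_pspm.L} (wild-type) vs {mut_pspm.L} (mutant)"
        )
    if matrix is None:
        matrix = blosum62()

    def summarize(pspm: PSPM) -> tuple[float, float, float, float]:
        prof = entropy(pspm)
        e_k = float(prof.entropies[k - 1])
        z_k = 0.0 if prof.sd < SIGMA_FLOOR else (e_k - prof.mean) / prof.sd
        return e_k, z_k, prof.mean, prof.sd

    wt = summarize(wt_pspm)
    mut = summarize(mut_pspm)
    deltas = tuple(w - m for w, m in zip(wt, mut))
    b_wt = float(wt_pspm.row(k) @ matrix.row(wt_residue))
    b_mut = float(mut_pspm.row(k) @ matrix.row(mut_residue))
    return np.array([*wt, *mut, *deltas, b_wt, b_mut, b_wt - b_mut])


def _conservation_shifts(
    wt_pspm: PSPM,
    mut_pspm: PSPM,
    wt_sequence: str,
    mut_sequence: str,
    matrix: SubstitutionMatrix,
) -> dict[str, np.ndarray]:
    """Per-position absolute wild-type/mutant conservation shifts, one vector per measure."""
    e_wt = entropy(wt_pspm).entropies
    e_mut = entropy(mut_pspm).entropies
    b_wt = np.nan_to_num(blosum_profile(wt_sequence, wt_pspm, matrix))
    b_mut = np.nan_to_num(blosum_profile(mut_sequence, mut_pspm, matrix))
    return {
        "entropy": np.abs(e_wt - e_mut),
        "blosum": np.abs(b_wt - b_mut),
        "kl": kl_profile(wt_pspm, mut_pspm),
    }


def binding_feature_block(
    wt_pspm: PSPM,
    mut_pspm: PSPM,
    k: int,
    wt_sequence: str,
    mut_sequence: str,
    predictions: Mapping[Channel, BindingPrediction],
    matrix: Optional[SubstitutionMatrix] = None,
    screen_all_positions: bool = False,
) -> np.ndarray:
    """The 30 binding-block features.

    For each channel and each conservation measure the predicted binding
    positions are screened for the largest absolute wild-type/mutant shift
    (ties broken toward the smallest sequence index); the shift value, the
    linear distance from the winning position to the mutation, and the
    channel's propensity there are emitted. A channel with no predicted
    binding residues emits the sentinel triple (0, L, 0) and distance L.
    With ``screen_all_positions`` the argmax ranges over every sequence
    position instead of only the predicted ones.
    """
    if matrix is None:
        matrix = blosum62()
    L = wt_pspm.L
    if mut_pspm.L != L:
        raise ContractError("wild-type and mutant profiles must have equal length")
    if len(wt_sequence) != L or len(mut_sequence) != L:
        raise ContractError("sequence length must equal profile length")
    for ch in CHANNELS:
        if ch not in predictions:
            raise ContractError(f"missing binding-prediction channel {ch.value!r}")
        if predictions[ch].L != L:
            raise ContractError(
                f"channel {ch.value!r} has {predictions[ch].L} positions, expected {L}"
            )

    shifts = _conservation_shifts(wt_pspm, mut_pspm, wt_sequence, mut_sequence, matrix)

    screening: list[float] = []
    min_dists: list[float] = []
    for ch in CHANNELS:
        pred = predictions[ch]
        pos = np.arange(1, L + 1) if screen_all_positions else pred.positions
        if pos.size == 0:
            screening += [0.0, float(L), 0.0] * len(CONSERVATION_MEASURES)
        else:
            for meas in CONSERVATION_MEASURES:
                s = shifts[meas][pos - 1]
                # smallest index wins ties; values within 1e-9 of the max count
                # as tied so float summation noise cannot scramble the choice
                best = int(np.flatnonzero(s >= s.max() - 1e-9)[0])
                i_star = int(pos[best])
                screening += [
                    float(s[best]),
                    float(abs(i_star - k)),
                    float(pred.propensities[i_star - 1]),
                ]
        if pred.m == 0:
            min_dists.append(float(L))
        else:
            min_dists.append(float(np.min(np.abs(pred.positions - k))))
    return np.array(screening + min_dists)


# --------------------------------------------------------------------------
# Assembly
# --------------------------------------------------------------------------

@dataclass
class MsaSet:
    """The four alignments for one mutation: two sources x {wild-type, mutant}."""

    psiblast_wt: MSA
    psiblast_mut: MSA
    hhblits_wt: MSA
    hhblits_mut: MSA

    def pair(self, source: str) -> tuple[MSA, MSA]:
        if source == "psiblast":
            return self.psiblast_wt, self.psiblast_mut
        if source == "hhblits":
            return self.hhblits_wt, self.hhblits_mut
        raise ContractError(f"unknown alignment source {source!r}")


def assemble_features(
    record: MutationRecord,
    msas: MsaSet,
    predictions: Mapping[Channel, BindingPrediction],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    screen_all_positions: bool = False,
    matrix: Optional[SubstitutionMatrix] = None,
    _pspm_cache: Optional[dict] = None,
) -> FeatureVector:
    """Assemble the full 60-feature vector for one mutation record.

    Concatenates the two 15-feature MSA blocks (psiblast, then hhblits) and
    the 30-feature binding block, which screens with the psiblast-source
    profiles. ``_pspm_cache`` lets batch extraction reuse wild-type PSPMs
    across mutations of the same protein.
    """
    if matrix is None:
        matrix = blosum62()
    L = len(record.wt_sequence)

    def pspm_of(msa: MSA, role: str) -> PSPM:
        if msa.L != L:
            raise ContractError(
                f"{record.protein_id}: {role} alignment has {msa.L} columns, "
                f"sequence has {L}"
            )
        if _pspm_cache is not None:
            key = (id(msa), pseudocount)
            if key not in _pspm_cache:
                _pspm_cache[key] = build_pspm(msa, pseudocount)
            return _pspm_cache[key]
        return build_pspm(msa, pseudocount)

    values: list[float] = []
    psiblast_pair: tuple[PSPM, PSPM] | None = None
    for source in MSA_SOURCES:
        wt_msa, mut_msa = msas.pair(source)
        wt_pspm = pspm_of(wt_msa, f"{source} wild-type")
        mut_pspm = pspm_of(mut_msa, f"{source} mutant")
        if source == "psiblast":
            psiblast_pair = (wt_pspm, mut_pspm)
        values.extend(
            msa_feature_block(
                wt_pspm, mut_pspm, record.position,
                record.wt_residue, record.mut_residue, matrix,
            )
        )
    assert psiblast_pair is not None
    values.extend(
        binding_feature_block(
            psiblast_pair[0], psiblast_pair[1], record.position,
            record.wt_sequence, record.mutant_sequence, predictions,
            matrix, screen_all_positions,
        )
    )
    return FeatureVector(values=np.array(values))


# --------------------------------------------------------------------------
# Binding-site enrichment around mutated positions
# --------------------------------------------------------------------------

def nearest_binding_distance(
    record: MutationRecord, predictions: Mapping[Channel, BindingPrediction]
) -> float:
    """Linear distance from the mutation to the closest predicted binding residue
    over all channels; infinity when nothing is predicted."""
    best = np.inf
    for pred in predictions.values():
        if pred.m:
            best = min(best, float(np.min(np.abs(pred.positions - record.position))))
    return best


def enrichment_curve(
    records: Sequence[MutationRecord],
    predictions: Sequence[Mapping[Channel, BindingPrediction]],
    max_distance: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative fraction of mutations within distance d of a predicted binding
    residue, separately for the deleterious and the neutral class, d = 0..max_distance.

    Both curves are non-decreasing in d; deleterious mutations clustering at
    or near predicted binding residues show up as the deleterious curve
    dominating the neutral one.
    """
    if len(records) != len(predictions):
        raise ContractError("records and predictions must align")
    dists: dict[int, list[float]] = {0: [], 1: []}
    for rec, preds in zip(records, predictions):
        if rec.label is None:
            raise ContractError(f"{rec.protein_id}: unlabeled record")
        dists[rec.label].append(nearest_binding_distance(rec, preds))
    if not dists[1] or not dists[0]:
        raise ContractError("both a deleterious and a neutral class are required")
    d_grid = np.arange(max_distance + 1)

    def curve(values: list[float]) -> np.ndarray:
        arr = np.asarray(values)
        return np.array([(arr <= d).mean() for d in d_grid])

    return curve(dists[1]), curve(dists[0])
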