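"""Synthetic fixtures with a plantable deleterious signal.

The generator emulates the statistical structure the predictor exploits, not
real molecular evolution: alignment columns are either conserved (one
dominant residue) or variable (near-uniform), binding calls are enriched at
conserved columns, and deleterious mutations are preferentially planted at
conserved-or-binding positions with a perturbed mutant alignment column.
Everything is reproducible from a single integer seed.

Column compositions are shared between the two alignment sources (their rows
are sampled independently), so the psiblast-style and hhblits-style MSAs of
one protein agree on the query sequence but differ in sampling noise, like
two alignment tools run against different databases would.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .alphabet import AMINO_ACIDS, GAP_CHAR, N_AMINO_ACIDS
from .features import (
    CHANNELS,
    BindingPrediction,
    Channel,
    MsaSet,
    MutationRecord,
)
from .profiles import MSA, Dialect, build_pspm, column_entropies

#: Columns whose entropy is below this many nats count as conserved when the
#: generator needs to recover conservation from an alignment alone.
CONSERVED_ENTROPY_CUTOFF: float = 1.5

DEFAULT_GAP_RATE: float = 0.02
DEFAULT_BASE_RATE: float = 0.10
#: Dirichlet concentration for variable (non-conserved) columns.
VARIABLE_CONCENTRATION: float = 5.0


@dataclass
class SimulationConfig:
    """Knobs of the synthetic-dataset generator.

    ``conservation_strength`` is a concentration parameter: a conserved
    column's dominant residue carries mass strength / (strength + 2), i.e.
    about 0.91 at the default of 20 and 1 in the limit. ``deleterious_signal``
    is the probability that a deleterious mutation is actually planted at a
    conserved-or-binding position with a perturbed mutant column; the
    remainder are indistinguishable from neutral ones.
    """

    n_proteins: int = 50
    length_range: tuple[int, int] = (60, 120)
    n_msa_rows: int = 30
    mutations_per_protein: int = 40
    conserved_fraction: float = 0.3
    conservation_strength: float = 20.0
    gap_rate: float = DEFAULT_GAP_RATE
    binding_enrichment: float = 5.0
    base_rate: float = DEFAULT_BASE_RATE
    deleterious_signal: float = 0.9
    perturbation: float = 0.3
    label_noise: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("conserved_fraction", "gap_rate", "base_rate",
                     "deleterious_signal", "perturbation", "label_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.length_range[0] < 20:
            raise ValueError("minimum protein length is 20")
        if self.length_range[0] > self.length_range[1]:
            raise ValueError("length_range must be (min, max) with min <= max")

    @property
    def n_records(self) -> int:
        return self.n_proteins * self.mutations_per_protein


def _column_compositions(
    length: int,
    conserved_fraction: float,
    conservation_strength: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-column residue distributions and the conserved-column mask."""
    conserved = rng.random(length) < conserved_fraction
    comps = np.empty((length, N_AMINO_ACIDS))
    dominant_mass = conservation_strength / (conservation_strength + 2.0)
    for i in range(length):
        if conserved[i]:
            dom = rng.integers(N_AMINO_ACIDS)
            rest = rng.dirichlet(np.ones(N_AMINO_ACIDS - 1)) * (1.0 - dominant_mass)
            comp = np.insert(rest, dom, dominant_mass)
        else:
            comp = rng.dirichlet(np.full(N_AMINO_ACIDS, VARIABLE_CONCENTRATION))
        comps[i] = comp
    return comps, conserved


def _sample_rows(
    comps: np.ndarray,
    n_rows: int,
    gap_rate: float,
    rng: np.random.Generator,
    query: str,
) -> list[str]:
    L = comps.shape[0]
    rows = [query]
    for r in range(n_rows - 1):
        idx = np.array([rng.choice(N_AMINO_ACIDS, p=comps[i]) for i in range(L)])
        chars = np.array(list(AMINO_ACIDS))[idx]
        gaps = rng.random(L) < gap_rate
        chars[gaps] = GAP_CHAR
        rows.append("".join(chars))
    return rows


def _modal_query(comps: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[j] for j in comps.argmax(axis=1))


def simulate_msa(
    length: int,
    n_rows: int,
    conserved_fraction: float,
    conservation_strength: float,
    seed: int,
    gap_rate: float = DEFAULT_GAP_RATE,
    source: Dialect = Dialect.psiblast,
) -> MSA:
    """One synthetic alignment: row 0 is the per-column modal (query) sequence,
    the remaining rows are sampled independently per column, with a small gap rate."""
    rng = np.random.default_rng(seed)
    comps, _ = _column_compositions(length, conserved_fraction,
                                    conservation_strength, rng)
    query = _modal_query(comps)
    rows = _sample_rows(comps, n_rows, gap_rate, rng, query)
    return MSA(source=source, query_id="query", rows=rows,
               row_ids=["query"] + [f"hom{i}" for i in range(1, n_rows)])


def simulate_mutant_msa(
    wt_msa: MSA, k: int, mut_residue: str, perturbation: float, seed: int
) -> MSA:
    """The wild-type alignment with the query mutated at position ``k`` and a
    ``perturbation`` fraction of the other rows resampled to the mutant residue
    at that column; every other column is untouched."""
    if not 1 <= k <= wt_msa.L:
        raise IndexError(f"position {k} out of range 1..{wt_msa.L}")
    rng = np.random.default_rng(seed)
    rows = list(wt_msa.rows)
    col = k - 1
    rows[0] = rows[0][:col] + mut_residue + rows[0][col + 1:]
    for r in range(1, len(rows)):
        if rng.random() < perturbation:
            rows[r] = rows[r][:col] + mut_residue + rows[r][col + 1:]
    return MSA(source=wt_msa.source, query_id=wt_msa.query_id, rows=rows,
               row_ids=list(wt_msa.row_ids))


def simulate_binding(
    msa: MSA,
    binding_enrichment: float,
    base_rate: float = DEFAULT_BASE_RATE,
    seed: int = 0,
) -> dict[Channel, BindingPrediction]:
    """Three binding-prediction channels whose call rate is multiplied by
    ``binding_enrichment`` at conserved columns (capped at 1).

    Conservation is read off the alignment itself (column entropy below
    ``CONSERVED_ENTROPY_CUTOFF`` nats). Propensities are a noisy monotone
    function of the call: calls land in [0.7, 1], non-calls in [0, 0.3].
    """
    if not 0.0 < base_rate < 1.0:
        raise ValueError("base_rate must be in (0, 1)")
    rng = np.random.default_rng(seed)
    e = column_entropies(build_pspm(msa))
    conserved = e < CONSERVED_ENTROPY_CUTOFF
    p_call = np.clip(
        base_rate * np.where(conserved, binding_enrichment, 1.0), 0.0, 1.0
    )
    out: dict[Channel, BindingPrediction] = {}
    for ch in CHANNELS:
        calls = (rng.random(msa.L) < p_call).astype(int)
        props = np.clip(0.7 * calls + 0.3 * rng.random(msa.L), 0.0, 1.0)
        out[ch] = BindingPrediction(channel=ch, calls=calls, propensities=props)
    return out


@dataclass
class SimulatedProtein:
    """One synthetic protein: shared column compositions, two source MSAs,
    binding predictions, and the masks used for planting mutations."""

    protein_id: str
    sequence: str
    msa_psiblast: MSA
    msa_hhblits: MSA
    predictions: dict[Channel, BindingPrediction]
    conserved_mask: np.ndarray
    binding_mask: np.ndarray


@dataclass
class SimulatedDataset:
    """A full in-memory fixture: labeled records with their alignments and
    binding predictions, ready for feature extraction."""

    config: SimulationConfig
    proteins: list[SimulatedProtein]
    records: list[MutationRecord]
    msa_sets: list[MsaSet]
    predictions: list[dict[Channel, BindingPrediction]] = field(default_factory=list)

    def record_id(self, idx: int) -> str:
        rec = self.records[idx]
        return f"{rec.protein_id}_{rec.wt_residue}{rec.position}{rec.mut_residue}"


def _simulate_protein(
    protein_id: str, config: SimulationConfig, rng: np.random.Generator
) -> SimulatedProtein:
    L = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
    comps, conserved = _column_compositions(
        L, config.conserved_fraction, config.conservation_strength, rng
    )
    query = _modal_query(comps)
    msa_psi = MSA(
        source=Dialect.psiblast, query_id=protein_id,
        rows=_sample_rows(comps, config.n_msa_rows, config.gap_rate, rng, query),
        row_ids=[protein_id] + [f"hom{i}" for i in range(1, config.n_msa_rows)],
    )
    msa_hh = MSA(
        source=Dialect.hhblits, query_id=protein_id,
        rows=_sample_rows(comps, config.n_msa_rows, config.gap_rate, rng, query),
        row_ids=[protein_id] + [f"hom{i}" for i in range(1, config.n_msa_rows)],
    )
    preds = simulate_binding(
        msa_psi, config.binding_enrichment, config.base_rate,
        seed=int(rng.integers(2**31)),
    )
    binding_mask = np.zeros(L, dtype=bool)
    for pred in preds.values():
        binding_mask |= pred.calls.astype(bool)
    return SimulatedProtein(
        protein_id=protein_id, sequence=query, msa_psiblast=msa_psi,
        msa_hhblits=msa_hh, predictions=preds,
        conserved_mask=conserved, binding_mask=binding_mask,
    )


def _pick_position(mask: np.ndarray, rng: np.random.Generator) -> int:
    """1-based position sampled uniformly from a boolean mask (anywhere if empty)."""
    candidates = np.flatnonzero(mask)
    if candidates.size == 0:
        candidates = np.arange(mask.size)
    return int(rng.choice(candidates)) + 1


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a labeled mutation dataset with a planted deleterious signal.

    Per protein, half the mutations are deleterious and half neutral (before
    label noise). A deleterious mutation is, with probability
    ``deleterious_signal``, placed at a conserved-or-binding position and its
    mutant alignments have the mutated column perturbed toward the mutant
    residue; otherwise — and for all neutral mutations — the position is
    drawn from the unconserved non-binding columns and the mutant alignments
    differ from the wild type only through the query row. Label noise flips
    labels last.
    """
    rng = np.random.default_rng(config.seed)
    proteins = [
        _simulate_protein(f"P{p:04d}", config, rng) for p in range(config.n_proteins)
    ]
    records: list[MutationRecord] = []
    msa_sets: list[MsaSet] = []
    predictions: list[dict[Channel, BindingPrediction]] = []
    n_del = config.mutations_per_protein // 2
    for prot in proteins:
        signal_mask = prot.conserved_mask | prot.binding_mask
        background_mask = ~signal_mask
        for m_idx in range(config.mutations_per_protein):
            deleterious = m_idx < n_del
            planted = deleterious and rng.random() < config.deleterious_signal
            mask = signal_mask if planted else background_mask
            k = _pick_position(mask, rng)
            wt_res = prot.sequence[k - 1]
            mut_res = rng.choice([aa for aa in AMINO_ACIDS if aa != wt_res])
            perturbation = config.perturbation if planted else 0.0
            label = int(deleterious)
            if rng.random() < config.label_noise:
                label = 1 - label
            record = MutationRecord(
                protein_id=prot.protein_id, wt_sequence=prot.sequence,
                position=k, wt_residue=wt_res, mut_residue=mut_res, label=label,
            )
            mut_seed_a = int(rng.integers(2**31))
            mut_seed_b = int(rng.integers(2**31))
            msa_sets.append(MsaSet(
                psiblast_wt=prot.msa_psiblast,
                psiblast_mut=simulate_mutant_msa(
                    prot.msa_psiblast, k, mut_res, perturbation, mut_seed_a),
                hhblits_wt=prot.msa_hhblits,
                hhblits_mut=simulate_mutant_msa(
                    prot.msa_hhblits, k, mut_res, perturbation, mut_seed_b),
            ))
            records.append(record)
            predictions.append(prot.predictions)
    return SimulatedDataset(
        config=config, proteins=proteins, records=records,
        msa_sets=msa_sets, predictions=predictions,
    )


# --------------------------------------------------------------------------
# On-disk fixture
# --------------------------------------------------------------------------

def _write_a3m(msa: MSA, path: Path, rng: np.random.Generator,
               insertion_rate: float = 0.1) -> None:
    """Write an MSA as A3M, sprinkling lowercase insertion runs into non-query
    rows so the fixture exercises the A3M normalization path."""
    with open(path, "w") as fh:
        for idx, (rid, row) in enumerate(zip(msa.row_ids, msa.rows)):
            out = row
            if idx > 0 and rng.random() < insertion_rate:
                pos = int(rng.integers(len(row) + 1))
                run = "".join(rng.choice(list(AMINO_ACIDS.lower()),
                                         size=int(rng.integers(1, 4))))
                out = row[:pos] + run + row[pos:]
            fh.write(f">{rid}\n{out}\n")


def write_dataset(dataset: SimulatedDataset, out_dir) -> dict:
    """Write a complete on-disk fixture (mutation TSV, FASTA, MSAs, binding TSVs)
    in exactly the dialects the pipeline reads, plus a JSON manifest."""
    out = Path(out_dir)
    (out / "msa").mkdir(parents=True, exist_ok=True)
    (out / "binding").mkdir(exist_ok=True)
    rng = np.random.default_rng(dataset.config.seed + 1)

    manifest: dict = {
        "seed": dataset.config.seed,
        "n_records": len(dataset.records),
        "mutations": "mutations.tsv",
        "fasta": "sequences.fasta",
        "msa_dir": "msa",
        "binding_dir": "binding",
        "records": [],
    }

    with open(out / "sequences.fasta", "w") as fh:
        for prot in dataset.proteins:
            fh.write(f">{prot.protein_id}\n{prot.sequence}\n")

    for prot in dataset.proteins:
        with open(out / "msa" / f"{prot.protein_id}_psiblast_wt.fasta", "w") as fh:
            for rid, row in zip(prot.msa_psiblast.row_ids, prot.msa_psiblast.rows):
                fh.write(f">{rid}\n{row}\n")
        _write_a3m(prot.msa_hhblits, out / "msa" / f"{prot.protein_id}_hhblits_wt.a3m", rng)
        for ch, pred in prot.predictions.items():
            with open(out / "binding" / f"{prot.protein_id}_{ch.value}.tsv", "w") as fh:
                fh.write("position\tresidue\tcall\tpropensity\n")
                for i in range(pred.L):
                    fh.write(f"{i + 1}\t{prot.sequence[i]}\t{pred.calls[i]}\t"
                             f"{pred.propensities[i]:.6f}\n")

    with open(out / "mutations.tsv", "w") as fh:
        fh.write("record_id\tprotein_id\tposition\twt\tmut\tlabel\n")
        for idx, (rec, mset) in enumerate(zip(dataset.records, dataset.msa_sets)):
            rid = dataset.record_id(idx)
            fh.write(f"{rid}\t{rec.protein_id}\t{rec.position}\t{rec.wt_residue}\t"
                     f"{rec.mut_residue}\t{rec.label}\n")
            with open(out / "msa" / f"{rid}_psiblast_mut.fasta", "w") as mf:
                for row_id, row in zip(mset.psiblast_mut.row_ids, mset.psiblast_mut.rows):
                    mf.write(f">{row_id}\n{row}\n")
            _write_a3m(mset.hhblits_mut, out / "msa" / f"{rid}_hhblits_mut.a3m", rng)
            manifest["records"].append({
                "record_id": rid,
                "protein_id": rec.protein_id,
                "psiblast_wt": f"msa/{rec.protein_id}_psiblast_wt.fasta",
                "psiblast_mut": f"msa/{rid}_psiblast_mut.fasta",
                "hhblits_wt": f"msa/{rec.protein_id}_hhblits_wt.a3m",
                "hhblits_mut": f"msa/{rid}_hhblits_mut.a3m",
                "binding": {
                    ch.value: f"binding/{rec.protein_id}_{ch.value}.tsv"
                    for ch in dataset.predictions[idx]
                },
            })

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
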