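"""Tabular input/output: mutation datasets, binding predictions, feature tables.

Formats:

* mutation TSV — columns record_id (optional), protein_id, position, wt, mut,
  label (optional), plus a FASTA of wild-type sequences;
* binding TSV — one channel per file with columns position, residue, call,
  propensity;
* feature table — TSV with record_id, protein_id, label and the 60 schema
  columns, byte-identical across runs for identical inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio import SeqIO

from .features import (
    CHANNELS,
    FEATURE_NAMES,
    BindingPrediction,
    Channel,
    ContractError,
    MsaSet,
    MutationRecord,
    assemble_features,
)
from .profiles import DEFAULT_PSEUDOCOUNT, read_msa

logger = logging.getLogger(__name__)

ID_COLUMNS = ["record_id", "protein_id", "label"]


def read_fasta_sequences(path) -> dict[str, str]:
    """Wild-type sequences keyed by record id."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_mutations(path, sequences: dict[str, str]) -> list[MutationRecord]:
    """Parse a mutation TSV against the FASTA of wild-type sequences."""
    df = pd.read_csv(path, sep="\t", dtype={"wt": str, "mut": str})
    required = {"protein_id", "position", "wt", "mut"}
    missing = required - set(df.columns)
    if missing:
        raise ContractError(f"mutation table is missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        pid = str(row.protein_id)
        if pid not in sequences:
            raise ContractError(f"no sequence for protein {pid!r}")
        label = int(row.label) if "label" in df.columns and pd.notna(row.label) else None
        records.append(MutationRecord(
            protein_id=pid, wt_sequence=sequences[pid], position=int(row.position),
            wt_residue=str(row.wt), mut_residue=str(row.mut), label=label,
        ))
    return records


def read_binding_tsv(path, channel: Channel) -> BindingPrediction:
    """Parse one binding-prediction channel (position, residue, call, propensity)."""
    df = pd.read_csv(path, sep="\t")
    required = {"position", "call", "propensity"}
    missing = required - set(df.columns)
    if missing:
        raise ContractError(f"{path}: missing columns {sorted(missing)}")
    df = df.sort_values("position")
    positions = df["position"].to_numpy()
    if not np.array_equal(positions, np.arange(1, len(df) + 1)):
        raise ContractError(f"{path}: positions must be contiguous 1..L")
    return BindingPrediction(
        channel=channel,
        calls=df["call"].to_numpy(),
        propensities=df["propensity"].to_numpy(),
    )


@dataclass
class ExtractionSummary:
    """How many records were extracted and why any were skipped."""

    n_extracted: int
    skipped: list[tuple[str, str]]


def record_identifier(rec: MutationRecord) -> str:
    return f"{rec.protein_id}_{rec.wt_residue}{rec.position}{rec.mut_residue}"


def extract_feature_table(
    records: list[MutationRecord],
    msa_sets: list[MsaSet],
    predictions: list[dict[Channel, BindingPrediction]],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    screen_all_positions: bool = False,
    skip_errors: bool = False,
) -> tuple[pd.DataFrame, ExtractionSummary]:
    """Assemble the 60-feature vector for every record into one table.

    Wild-type profile matrices are cached across mutations of the same
    protein. With ``skip_errors`` a record whose inputs are unusable is
    logged and skipped instead of aborting the batch.
    """
    if not (len(records) == len(msa_sets) == len(predictions)):
        raise ContractError("records, MSAs and predictions must align")
    cache: dict = {}
    rows, ids, skipped = [], [], []
    for rec, mset, preds in zip(records, msa_sets, predictions):
        rid = record_identifier(rec)
        try:
            fv = assemble_features(
                rec, mset, preds, pseudocount=pseudocount,
                screen_all_positions=screen_all_positions, _pspm_cache=cache,
            )
        except (ContractError, ValueError) as exc:
            if not skip_errors:
                raise
            logger.warning("skipping %s: %s", rid, exc)
            skipped.append((rid, str(exc)))
            continue
        rows.append(fv.values)
        ids.append((rid, rec.protein_id, rec.label))
    if not rows:
        raise ContractError("zero extractable records")
    table = pd.DataFrame(np.vstack(rows), columns=FEATURE_NAMES)
    meta = pd.DataFrame(ids, columns=ID_COLUMNS)
    out = pd.concat([meta, table], axis=1)
    return out, ExtractionSummary(n_extracted=len(rows), skipped=skipped)


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(FEATURE_NAMES) - set(df.columns)
    if missing:
        raise ContractError(f"feature table is missing columns {sorted(missing)}")
    return df


def split_feature_table(table: pd.DataFrame) -> tuple[pd.DataFrame, Optional[np.ndarray]]:
    """Separate the 60 feature columns from the identifier columns; returns
    (features, labels-or-None)."""
    X = table[FEATURE_NAMES]
    y = None
    if "label" in table.columns and table["label"].notna().all():
        y = table["label"].to_numpy().astype(int)
    return X, y


def load_disk_dataset(root, skip_errors: bool = False) -> tuple[
    list[MutationRecord], list[MsaSet], list[dict[Channel, BindingPrediction]]
]:
    """Load an on-disk fixture written by :func:`consbind.simulate.write_dataset`
    (or assembled by hand in the same layout) back into memory.

    With ``skip_errors`` a record whose alignment or binding files are missing
    or malformed is logged and dropped instead of aborting the load.
    """
    root = Path(root)
    sequences = read_fasta_sequences(root / "sequences.fasta")
    df = pd.read_csv(root / "mutations.tsv", sep="\t", dtype={"wt": str, "mut": str})
    records, msa_sets, predictions = [], [], []
    msa_cache: dict[str, object] = {}
    binding_cache: dict[str, dict[Channel, BindingPrediction]] = {}

    def cached_msa(path: Path, dialect: str):
        key = str(path)
        if key not in msa_cache:
            msa_cache[key] = read_msa(path, dialect)
        return msa_cache[key]

    for row in df.itertuples(index=False):
        pid = str(row.protein_id)
        rid = str(row.record_id)
        label = int(row.label) if pd.notna(row.label) else None
        try:
            record = MutationRecord(
                protein_id=pid, wt_sequence=sequences[pid], position=int(row.position),
                wt_residue=str(row.wt), mut_residue=str(row.mut), label=label,
            )
            mset = MsaSet(
                psiblast_wt=cached_msa(root / "msa" / f"{pid}_psiblast_wt.fasta", "psiblast"),
                psiblast_mut=read_msa(root / "msa" / f"{rid}_psiblast_mut.fasta", "psiblast"),
                hhblits_wt=cached_msa(root / "msa" / f"{pid}_hhblits_wt.a3m", "hhblits"),
                hhblits_mut=read_msa(root / "msa" / f"{rid}_hhblits_mut.a3m", "hhblits"),
            )
            if pid not in binding_cache:
                binding_cache[pid] = {
                    ch: read_binding_tsv(root / "binding" / f"{pid}_{ch.value}.tsv", ch)
                    for ch in CHANNELS
                }
        except (OSError, ContractError, ValueError) as exc:
            if not skip_errors:
                raise
            logger.warning("skipping record %s: %s", rid, exc)
            continue
        records.append(record)
        msa_sets.append(mset)
        predictions.append(binding_cache[pid])
    return records, msa_sets, predictions
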