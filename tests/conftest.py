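from __future__ import annotations

import numpy as np
import pytest

from consbind.features import BindingPrediction, Channel, MsaSet, MutationRecord
from consbind.profiles import MSA, Dialect
from consbind.simulate import SimulationConfig, simulate_dataset


def random_mutation_fixture(rng: np.random.Generator, length_range=(25, 45),
                            n_rows=12, allow_empty_channel=True):
    """One random mutation with its four alignments and three binding channels.

    Deliberately unstructured (uniform residues, random calls) — used for
    oracle-equivalence and property checks, not for planted-signal tests.
    Returns (record, MsaSet, predictions, raw_rows, raw_predictions) where
    the raw entries are plain lists for the naive reference implementation.
    """
    from consbind.alphabet import AMINO_ACIDS

    L = int(rng.integers(*length_range))
    aa = np.array(list(AMINO_ACIDS))

    def random_rows(query: str) -> list[str]:
        rows = [query]
        for _ in range(n_rows - 1):
            chars = aa[rng.integers(20, size=L)]
            gaps = rng.random(L) < 0.05
            chars = np.where(gaps, "-", chars)
            rows.append("".join(chars))
        return rows

    query = "".join(aa[rng.integers(20, size=L)])
    k = int(rng.integers(1, L + 1))
    wt_res = query[k - 1]
    mut_res = str(rng.choice([a for a in AMINO_ACIDS if a != wt_res]))
    mut_query = query[: k - 1] + mut_res + query[k:]

    raw_rows = {}
    msas = {}
    for source in ("psiblast", "hhblits"):
        for which, q in (("wt", query), ("mut", mut_query)):
            rows = random_rows(q)
            raw_rows[(source, which)] = rows
            msas[(source, which)] = MSA(
                source=Dialect(source), query_id="q", rows=rows,
            )

    predictions, raw_preds = {}, {}
    for ch in (Channel.dna, Channel.rna, Channel.generic):
        calls = (rng.random(L) < 0.2).astype(int)
        if not allow_empty_channel and calls.sum() == 0:
            calls[int(rng.integers(L))] = 1
        props = np.clip(0.7 * calls + 0.3 * rng.random(L), 0, 1)
        predictions[ch] = BindingPrediction(channel=ch, calls=calls,
                                            propensities=props)
        raw_preds[ch.value] = (calls.tolist(), props.tolist())

    record = MutationRecord(protein_id="prot", wt_sequence=query, position=k,
                            wt_residue=wt_res, mut_residue=mut_res,
                            label=int(rng.integers(2)))
    mset = MsaSet(
        psiblast_wt=msas[("psiblast", "wt")], psiblast_mut=msas[("psiblast", "mut")],
        hhblits_wt=msas[("hhblits", "wt")], hhblits_mut=msas[("hhblits", "mut")],
    )
    return record, mset, predictions, raw_rows, raw_preds


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted-signal dataset shared across tests (120 records)."""
    config = SimulationConfig(n_proteins=6, mutations_per_protein=20,
                              length_range=(50, 80), seed=11)
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def small_feature_table(small_dataset):
    from consbind.io import extract_feature_table

    table, summary = extract_feature_table(
        small_dataset.records, small_dataset.msa_sets, small_dataset.predictions
    )
    assert not summary.skipped
    return table
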