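import numpy as np
import pytest

from consbind.features import (
    BINDING_BLOCK_NAMES,
    CHANNELS,
    FEATURE_GROUPS,
    FEATURE_NAMES,
    MSA_BLOCK_NAMES,
    BindingPrediction,
    Channel,
    ContractError,
    MutationRecord,
    assemble_features,
    binding_feature_block,
    enrichment_curve,
    msa_block_names,
    msa_feature_block,
)
from consbind.profiles import PSPM, build_pspm
from consbind.simulate import SimulationConfig, simulate_dataset

from conftest import random_mutation_fixture
from naive_reference import naive_feature_vector


def uniform_pspm(L):
    return PSPM(probs=np.full((L, 20), 1 / 20))


def random_pspm(L, rng):
    return PSPM(probs=rng.dirichlet(np.ones(20), size=L))


def preds_with_calls(L, call_positions, propensities=None):
    out = {}
    for ch in CHANNELS:
        calls = np.zeros(L, dtype=int)
        calls[[p - 1 for p in call_positions]] = 1
        props = propensities if propensities is not None else 0.8 * calls
        out[ch] = BindingPrediction(channel=ch, calls=calls, propensities=props)
    return out


class TestSchema:
    def test_cardinalities(self):
        assert len(FEATURE_NAMES) == 60
        assert len(MSA_BLOCK_NAMES) == 30
        assert len(BINDING_BLOCK_NAMES) == 30
        assert FEATURE_NAMES == MSA_BLOCK_NAMES + BINDING_BLOCK_NAMES
        assert len(set(FEATURE_NAMES)) == 60

    def test_msa_block_is_two_sources_of_fifteen(self):
        # per source: 8 single-sequence stats + 4 differences + 3 inner products
        for source in ("psiblast", "hhblits"):
            names = msa_block_names(source)
            assert len(names) == 8 + 4 + 3
            assert sum(n.startswith(f"{source}_wt") for n in names) == 5
            assert sum(n.startswith(f"{source}_mut") for n in names) == 5
            assert sum(n.startswith(f"{source}_delta") for n in names) == 5

    def test_binding_block_is_27_plus_3(self):
        screening = [n for n in BINDING_BLOCK_NAMES if "min_binding" not in n]
        distances = [n for n in BINDING_BLOCK_NAMES if "min_binding" in n]
        assert len(screening) == 27 and len(distances) == 3
        # 3 features x 3 conservation measures per channel
        for ch in CHANNELS:
            per_channel = [n for n in screening if n.startswith(ch.value + "_")]
            assert len(per_channel) == 9

    def test_groups_partition(self):
        assert FEATURE_GROUPS["msa_block"] + FEATURE_GROUPS["binding_block"] == \
            FEATURE_NAMES


class TestMsaFeatureBlock:
    def test_identical_profiles_zero_differences(self, ):
        rng = np.random.default_rng(0)
        pspm = random_pspm(12, rng)
        vals = msa_feature_block(pspm, pspm, k=3, wt_residue="A", mut_residue="A"
                                 if False else "G")
        # indices 8..11 are the four signed differences
        assert np.allclose(vals[8:12], 0.0)

    def test_flat_entropy_gives_zero_zscore(self):
        pspm = uniform_pspm(10)  # identical columns -> sigma = 0
        vals = msa_feature_block(pspm, pspm, k=5, wt_residue="A", mut_residue="C")
        z_wt, z_mut = vals[1], vals[5]
        assert z_wt == 0.0 and z_mut == 0.0

    def test_blosum_features_use_each_sequences_residue(self):
        from consbind.substitution import blosum62

        rng = np.random.default_rng(1)
        wt, mut = random_pspm(8, rng), random_pspm(8, rng)
        vals = msa_feature_block(wt, mut, k=2, wt_residue="A", mut_residue="W")
        b_wt = float(wt.row(2) @ blosum62().row("A"))
        b_mut = float(mut.row(2) @ blosum62().row("W"))
        assert vals[12] == pytest.approx(b_wt)
        assert vals[13] == pytest.approx(b_mut)
        assert vals[14] == pytest.approx(b_wt - b_mut)

    def test_length_mismatch_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ContractError):
            msa_feature_block(random_pspm(5, rng), random_pspm(6, rng),
                              k=1, wt_residue="A", mut_residue="C")


class TestBindingFeatureBlock:
    def test_closest_distance(self):
        L = 50
        rng = np.random.default_rng(0)
        wt = random_pspm(L, rng)
        seq = "A" * L
        preds = preds_with_calls(L, [13, 40])
        vals = binding_feature_block(wt, wt, k=10, wt_sequence=seq,
                                     mut_sequence=seq, predictions=preds)
        min_dists = vals[-3:]
        assert np.allclose(min_dists, 3.0)  # |13 - 10|

    def test_identical_profiles_zero_shifts_and_tiebreak(self):
        L = 30
        rng = np.random.default_rng(1)
        wt = random_pspm(L, rng)
        seq = "".join("ACDEFG"[i % 6] for i in range(L))
        props = np.linspace(0, 1, L)
        preds = preds_with_calls(L, [7, 19], propensities=props)
        vals = binding_feature_block(wt, wt, k=5, wt_sequence=seq,
                                     mut_sequence=seq, predictions=preds)
        named = dict(zip(BINDING_BLOCK_NAMES, vals))
        for ch in CHANNELS:
            for meas in ("entropy", "blosum", "kl"):
                assert named[f"{ch.value}_{meas}_max_shift"] == pytest.approx(0.0)
                # all shifts tie at 0 -> smallest predicted index (7) wins
                assert named[f"{ch.value}_{meas}_max_shift_dist"] == abs(7 - 5)
                assert named[f"{ch.value}_{meas}_max_shift_propensity"] == \
                    pytest.approx(props[6])

    def test_empty_channel_sentinels(self):
        L = 25
        rng = np.random.default_rng(2)
        wt, mut = random_pspm(L, rng), random_pspm(L, rng)
        seq = "A" * L
        preds = preds_with_calls(L, [])
        vals = binding_feature_block(wt, mut, k=3, wt_sequence=seq,
                                     mut_sequence=seq, predictions=preds)
        named = dict(zip(BINDING_BLOCK_NAMES, vals))
        for ch in CHANNELS:
            assert named[f"{ch.value}_entropy_max_shift"] == 0.0
            assert named[f"{ch.value}_kl_max_shift_dist"] == L
            assert named[f"{ch.value}_blosum_max_shift_propensity"] == 0.0
            assert named[f"{ch.value}_min_binding_dist"] == L

    def test_matches_exhaustive_argmax_loop(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            record, mset, preds, raw_rows, raw_preds = random_mutation_fixture(
                rng, allow_empty_channel=False)
            wt = build_pspm(mset.psiblast_wt)
            mut = build_pspm(mset.psiblast_mut)
            vals = binding_feature_block(
                wt, mut, record.position, record.wt_sequence,
                record.mutant_sequence, preds)
            from naive_reference import naive_binding_block
            expected = naive_binding_block(
                raw_rows[("psiblast", "wt")], raw_rows[("psiblast", "mut")],
                record.position, record.wt_sequence, record.mutant_sequence,
                raw_preds, 1e-4)
            assert np.allclose(vals, expected, atol=1e-9)

    def test_missing_channel_rejected(self):
        L = 10
        rng = np.random.default_rng(3)
        wt = random_pspm(L, rng)
        preds = preds_with_calls(L, [2])
        del preds[Channel.rna]
        with pytest.raises(ContractError, match="rna"):
            binding_feature_block(wt, wt, 1, "A" * L, "A" * L, preds)


class TestAssembleFeatures:
    def test_full_vector_matches_naive_reference(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            record, mset, preds, raw_rows, raw_preds = random_mutation_fixture(rng)
            fv = assemble_features(record, mset, preds)
            expected = naive_feature_vector(record, raw_rows, raw_preds, 1e-4)
            assert fv.values.shape == (60,)
            assert np.allclose(fv.values, expected, atol=1e-9)

    def test_swap_symmetry(self):
        """Swapping wild-type and mutant inputs negates the signed differences
        and preserves the absolute entropy/BLOSUM shifts."""
        from consbind.features import MsaSet

        rng = np.random.default_rng(5)
        record, mset, preds, _, _ = random_mutation_fixture(rng)
        swapped_record = MutationRecord(
            protein_id=record.protein_id, wt_sequence=record.mutant_sequence,
            position=record.position, wt_residue=record.mut_residue,
            mut_residue=record.wt_residue, label=record.label)
        swapped = MsaSet(
            psiblast_wt=mset.psiblast_mut, psiblast_mut=mset.psiblast_wt,
            hhblits_wt=mset.hhblits_mut, hhblits_mut=mset.hhblits_wt)
        a = assemble_features(record, mset, preds).as_dict()
        b = assemble_features(swapped_record, swapped, preds).as_dict()
        for name in FEATURE_NAMES:
            if "_delta_" in name:
                assert a[name] == pytest.approx(-b[name], abs=1e-9)
            elif "entropy_max_shift" in name and name.endswith("max_shift"):
                assert a[name] == pytest.approx(b[name], abs=1e-9)
            elif "blosum_max_shift" in name and name.endswith("max_shift"):
                assert a[name] == pytest.approx(b[name], abs=1e-9)

    def test_schema_is_stable_across_records(self):
        rng = np.random.default_rng(6)
        names = None
        for _ in range(3):
            record, mset, preds, _, _ = random_mutation_fixture(rng)
            fv = assemble_features(record, mset, preds)
            if names is None:
                names = list(fv.names)
            assert list(fv.names) == names == FEATURE_NAMES

    def test_length_mismatch_names_record(self):
        rng = np.random.default_rng(8)
        record, mset, preds, _, _ = random_mutation_fixture(rng)
        bad = MutationRecord(protein_id="other", wt_sequence="A" * 10, position=2,
                             wt_residue="A", mut_residue="C")
        with pytest.raises(ContractError, match="other"):
            assemble_features(bad, mset, preds)


class TestMutationRecord:
    def test_sequence_residue_consistency_enforced(self):
        with pytest.raises(ContractError):
            MutationRecord(protein_id="p", wt_sequence="ACD", position=2,
                           wt_residue="A", mut_residue="G")

    def test_wt_must_differ_from_mut(self):
        with pytest.raises(ContractError):
            MutationRecord(protein_id="p", wt_sequence="ACD", position=1,
                           wt_residue="A", mut_residue="A")

    def test_mutant_sequence(self):
        rec = MutationRecord(protein_id="p", wt_sequence="ACD", position=2,
                             wt_residue="C", mut_residue="W")
        assert rec.mutant_sequence == "AWD"


class TestEnrichmentCurve:
    def _records_at(self, positions_labels, L=50):
        recs, preds = [], []
        for k, label in positions_labels:
            seq = "A" * L
            recs.append(MutationRecord(protein_id="p", wt_sequence=seq,
                                       position=k, wt_residue="A",
                                       mut_residue="C", label=label))
        return recs

    def test_mutations_at_binding_sites_hit_one_at_distance_zero(self):
        L = 50
        recs = self._records_at([(10, 1), (20, 1), (30, 0)], L)
        preds = [preds_with_calls(L, [r.position]) if r.label == 1
                 else preds_with_calls(L, [1]) for r in recs]
        dele, neut = enrichment_curve(recs, preds, max_distance=10)
        assert dele[0] == 1.0

    def test_curves_non_decreasing(self, small_dataset):
        dele, neut = enrichment_curve(small_dataset.records,
                                      small_dataset.predictions)
        assert np.all(np.diff(dele) >= 0)
        assert np.all(np.diff(neut) >= 0)

    def test_planted_enrichment_gives_dominance(self, small_dataset):
        # at small n both curves saturate near 1 at the tail, so the direction
        # is checked where the planted signal lives: at and near distance 0
        dele, neut = enrichment_curve(small_dataset.records,
                                      small_dataset.predictions)
        assert dele[0] > neut[0] + 0.3
        assert np.mean(dele - neut) > 0

    def test_single_class_rejected(self):
        L = 30
        recs = self._records_at([(5, 1), (9, 1)], L)
        preds = [preds_with_calls(L, [3])] * 2
        with pytest.raises(ContractError):
            enrichment_curve(recs, preds)

    def test_unlabeled_record_rejected(self):
        L = 30
        rec = MutationRecord(protein_id="p", wt_sequence="A" * L, position=4,
                             wt_residue="A", mut_residue="C", label=None)
        with pytest.raises(ContractError):
            enrichment_curve([rec], [preds_with_calls(L, [3])])
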