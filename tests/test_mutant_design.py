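import math

import numpy as np
import pytest

from protexp import mutant_design as md
from protexp.lm_core import VOCAB, MaskedBatch, TrainConfig, apply_pretrain_masking, \
    desk_config, encode_sequence
from protexp.nn import TransformerEncoder


class FixedLogitModel:
    """Duck-typed stand-in encoder whose MLM logits are a fixed table.

    ``logit_fn(flat_position) -> length-25 logit vector`` fully determines
    predictions, making M-Values and mutation rates hand-computable.
    """

    def __init__(self, config, logit_fn):
        self.config = config
        self._logit_fn = logit_fn

    def encode(self, ids, pad_mask, collect_attention=False):
        self._ids = ids
        return None, []

    def mlm_logits(self, hidden, flat_positions):
        class _Out:
            pass

        out = _Out()
        out.data = np.stack([self._logit_fn(int(f), self._ids) for f in flat_positions])
        return out


def wildtype_reproducing_model(config):
    """Always predicts the original wild-type token at every position."""

    def logit_fn(flat, ids):
        L = ids.shape[1]
        logits = np.zeros(25)
        logits[_WT_IDS[flat % L]] = 10.0
        return logits

    return FixedLogitModel(config, logit_fn)


WT = "MKVLAAGGAAKDEV"
_CFG = desk_config(32)
_WT_IDS = encode_sequence(WT, _CFG, pad=False)


class TestTrainingSet:
    def test_exact_count_and_mask_token_only(self, tiny_config):
        homolog = "".join("ACDEFGHIKL"[i % 10] for i in range(30))
        batch = md.build_mutgen_training_set([homolog], tiny_config, rate=0.10, seed=0)
        assert len(batch.mask_positions) == 3
        flat = batch.input_ids.reshape(-1)
        assert np.all(flat[batch.mask_positions] == VOCAB.index("[MASK]"))

    def test_fifty_residues_five_masked(self, tiny_config):
        homolog = "".join("ACDEFGHIKL"[i % 10] for i in range(50))
        cfg = desk_config(64)
        batch = md.build_mutgen_training_set([homolog], cfg, rate=0.10, seed=1)
        assert len(batch.mask_positions) == 5

    def test_rate_one_masks_everything(self, tiny_config):
        batch = md.build_mutgen_training_set(["MKVLMKVL"], tiny_config, rate=1.0, seed=0)
        assert len(batch.mask_positions) == 8

    def test_deterministic(self, tiny_config):
        b1 = md.build_mutgen_training_set(["MKVLMKVLAC"], tiny_config, seed=7)
        b2 = md.build_mutgen_training_set(["MKVLMKVLAC"], tiny_config, seed=7)
        np.testing.assert_array_equal(b1.input_ids, b2.input_ids)

    def test_a2m_inserts_stripped(self):
        assert md.strip_alignment("MK-v.LA") == "MKLA"

    def test_empty_rejected(self, tiny_config):
        with pytest.raises(ValueError):
            md.build_mutgen_training_set([], tiny_config)


class TestMValue:
    def test_minimum(self):
        assert md.m_value([0.9, 0.5, 0.7]) == 0.5

    def test_single_certain_position(self):
        assert md.m_value([1.0]) == 1.0

    def test_permutation_invariant(self):
        assert md.m_value([0.3, 0.9]) == md.m_value([0.9, 0.3])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            md.m_value([])


class TestGeneration:
    def test_wildtype_reproducer_yields_no_mutations(self):
        model = wildtype_reproducing_model(_CFG)
        cands = md.generate_mutants(model, WT, n_samples=20, seed=0)
        assert len(cands) == 1          # all collapse to the wild type
        assert cands[0].sequence == WT
        assert cands[0].mutated_sites == ()

    def test_fixed_logit_oracle_m_value(self):
        # position-dependent peaked distribution with known probabilities
        rng = np.random.default_rng(0)
        tables = {}

        def logit_fn(flat, ids):
            if flat not in tables:
                r = np.random.default_rng(flat)
                logits = np.full(25, -1e9)
                logits[5:25] = r.normal(0, 2, 20)
                tables[flat] = logits
            return tables[flat]

        model = FixedLogitModel(_CFG, logit_fn)
        cands = md.generate_mutants(model, WT, n_samples=5, seed=1, batch_size=1)
        L = len(encode_sequence(WT, _CFG, pad=False))
        for cand in cands:
            assert cand.m_value == pytest.approx(min(cand.probabilities))
            # oracle: recompute softmax-over-residues max probability per position
            for pos0, p in zip(cand.masked_positions, cand.probabilities):
                logits = logit_fn(pos0 + 1, None)[5:25]
                e = np.exp(logits - logits.max())
                assert p == pytest.approx(float(e.max() / e.sum()))

    def test_mutated_sites_subset_of_masked(self):
        rng_tables = {}

        def logit_fn(flat, ids):
            logits = np.full(25, -1e9)
            logits[VOCAB.index("A")] = 1.0   # always predict alanine
            return logits

        model = FixedLogitModel(_CFG, logit_fn)
        cands = md.generate_mutants(model, WT, n_samples=10, seed=2)
        for cand in cands:
            mutated_pos = {int(s[1:-1]) - 1 for s in cand.mutated_sites}
            assert mutated_pos <= set(cand.masked_positions)
            for site in cand.mutated_sites:
                assert site[-1] == "A"
                assert WT[int(site[1:-1]) - 1] == site[0]

    def test_deterministic_under_seed(self):
        model = wildtype_reproducing_model(_CFG)
        c1 = md.generate_mutants(model, WT, n_samples=50, seed=5)
        c2 = md.generate_mutants(model, WT, n_samples=50, seed=5)
        assert [c.sequence for c in c1] == [c.sequence for c in c2]

    def test_zero_samples_rejected(self):
        model = wildtype_reproducing_model(_CFG)
        with pytest.raises(ValueError):
            md.generate_mutants(model, WT, n_samples=0)


class TestMutationRate:
    def _batch(self, model):
        rows = [encode_sequence(WT, _CFG, pad=False)]
        return apply_pretrain_masking(rows, rate=0.5, seed=0, mask_only=True)

    def test_always_original_gives_zero(self):
        model = wildtype_reproducing_model(_CFG)
        batch = self._batch(model)
        assert md.mutation_rate(model, [batch]) == 0.0

    def test_never_original_gives_one(self):
        def logit_fn(flat, ids):
            L = ids.shape[1]
            logits = np.zeros(25)
            wt = _WT_IDS[flat % L]
            # peak on some other residue
            other = 5 if wt != 5 else 6
            logits[other] = 10.0
            return logits

        model = FixedLogitModel(_CFG, logit_fn)
        batch = self._batch(model)
        assert md.mutation_rate(model, [batch]) == 1.0

    def test_seven_of_ten_recovered_is_point_three(self):
        # batch with exactly 10 masked positions; recover first 7
        rows = [encode_sequence("ACDEFGHIKL" * 2, _CFG, pad=False)]
        batch = apply_pretrain_masking(rows, rate=0.5, seed=3, mask_only=True)
        assert len(batch.mask_positions) == 10
        recovered = set(batch.mask_positions[:7].tolist())

        def logit_fn(flat, ids):
            logits = np.zeros(25)
            if flat in recovered:
                logits[batch.targets[list(batch.mask_positions).index(flat)]] = 10.0
            else:
                wt = batch.targets[list(batch.mask_positions).index(flat)]
                logits[5 if wt != 5 else 6] = 10.0
            return logits

        model = FixedLogitModel(_CFG, logit_fn)
        assert md.mutation_rate(model, [batch]) == pytest.approx(0.3)

    def test_no_masked_positions_rejected(self):
        model = wildtype_reproducing_model(_CFG)
        with pytest.raises(ValueError):
            md.mutation_rate(model, [])


def _candidate(seq, m=0.5, he=None):
    return md.MutantCandidate(
        sequence=seq, masked_positions=(0,), predicted_residues=(seq[0],),
        probabilities=(m,), m_value=m, mutated_sites=(), he_value=he,
    )


class TestEntropy:
    def test_conserved_position_zero(self):
        cands = [_candidate("MKV"), _candidate("MKA"), _candidate("MKC")]
        prof = md.position_entropy(cands, 3)
        assert prof.entropy[0] == 0.0
        assert prof.entropy[1] == 0.0

    def test_fifty_fifty_is_ln2(self):
        cands = [_candidate("MKV"), _candidate("AKV")]
        prof = md.position_entropy(cands, 3)
        assert prof.entropy[0] == pytest.approx(math.log(2))

    def test_uniform_twenty_is_ln20(self):
        from protexp.io_formats import STANDARD_AA

        cands = [_candidate(aa + "KV") for aa in STANDARD_AA]
        prof = md.position_entropy(cands, 3)
        assert prof.entropy[0] == pytest.approx(math.log(20))
        assert np.all(prof.entropy <= math.log(20) + 1e-12)

    def test_distributions_sum_to_one(self):
        cands = [_candidate("MKV"), _candidate("AKV")]
        prof = md.position_entropy(cands, 3)
        np.testing.assert_allclose(prof.distributions.sum(axis=1), 1.0)


class TestSelection:
    def test_top_k_by_m_value(self):
        cands = [_candidate(f"SEQ{i}", m=0.1 * (i + 1)) for i in range(5)]
        top = md.select_candidates(cands, k=2)
        assert [c.m_value for c in top] == pytest.approx([0.5, 0.4])

    def test_k_larger_than_pool_returns_all(self):
        cands = [_candidate("A"), _candidate("B")]
        assert len(md.select_candidates(cands, k=10)) == 2

    def test_ties_break_lexicographically(self):
        cands = [_candidate("ZZZ", m=0.5), _candidate("AAA", m=0.5)]
        top = md.select_candidates(cands, k=1)
        assert top[0].sequence == "AAA"

    def test_superset_maximum_property(self):
        rng = np.random.default_rng(4)
        cands = [_candidate(f"S{i:03d}", m=float(rng.uniform(0.01, 1)))
                 for i in range(50)]
        k = 10
        top = md.select_candidates(cands, k=k)
        kth = top[-1].m_value
        excluded = {c.sequence for c in cands} - {c.sequence for c in top}
        for c in cands:
            if c.sequence in excluded:
                assert not c.m_value > kth


class TestDesignPipeline:
    def test_end_to_end_report(self, tiny_pretrained, planted_dataset):
        from protexp.dataset_builder import SplitSpec, make_splits
        from protexp.lm_core import finetune_classifier
        from protexp.synthetic_fixtures import PlantedFamilySpec, gen_homolog_family

        ds, truth = planted_dataset
        splits = make_splits(ds, SplitSpec(n_folds=2, seed=0))
        ensemble = finetune_classifier(
            tiny_pretrained, ds, splits,
            TrainConfig(lr=1e-3, epochs=1, batch_size=32, seed=0),
        )
        wt = ds.entries[0].sequence
        fam = gen_homolog_family(PlantedFamilySpec(
            seed_sequence=wt, n_members=20,
            tolerance=tuple(0.2 for _ in wt), seed=1,
        ))
        mutgen = md.finetune_mutant_generator(
            tiny_pretrained, fam, TrainConfig(lr=1e-3, epochs=1, batch_size=16, seed=0)
        )
        rows = md.design_expression_mutants(
            wt, mutgen, ensemble, aei_table=truth, n_samples=30, k=5, seed=0
        )
        assert rows[-1]["sequence_id"] == "wild-type"
        mutant_rows = rows[:-1]
        assert 1 <= len(mutant_rows) <= 5
        he_values = [r["he_value"] for r in mutant_rows]
        assert he_values == sorted(he_values, reverse=True)
        for r in mutant_rows:
            assert 0 < r["m_value"] <= 1
            assert r["srab"] > 0
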