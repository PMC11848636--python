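import numpy as np
import pytest

from protexp.dataset_builder import ExpressionDataset, LabeledSequence, SplitSpec, make_splits
from protexp.lm_core import TrainConfig, desk_config, pretrain_mlm
from protexp.synthetic_fixtures import (
    PlantedExpressionSpec,
    gen_corpus,
    gen_expression_dataset,
)


@pytest.fixture(scope="session")
def tiny_config():
    """Smallest encoder that still has multi-head attention."""
    return desk_config(max_seq_len=34)


@pytest.fixture(scope="session")
def planted_dataset():
    """Small planted-composition dataset shared across tests."""
    spec = PlantedExpressionSpec(n_per_class=60, length_range=(20, 32), seed=11)
    dataset, truth = gen_expression_dataset(spec)
    return dataset, truth


@pytest.fixture(scope="session")
def tiny_pretrained(tiny_config):
    """A briefly MLM-pretrained tiny encoder shared across tests."""
    corpus = gen_corpus(120, length_range=(16, 32), seed=5)
    model, history = pretrain_mlm(
        corpus, tiny_config, TrainConfig(lr=1e-3, epochs=1, batch_size=16, seed=0)
    )
    return model


def make_labeled_dataset(sequences_high, sequences_low, species_id="test"):
    """Assemble an ExpressionDataset from explicit high/low sequence lists."""
    entries = []
    for i, s in enumerate(sequences_high):
        entries.append(LabeledSequence(f"h{i:03d}", s, 1000.0 - i, "high"))
    for i, s in enumerate(sequences_low):
        entries.append(LabeledSequence(f"l{i:03d}", s, 1.0 - i * 1e-4, "low"))
    return ExpressionDataset(species_id=species_id, entries=entries)
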