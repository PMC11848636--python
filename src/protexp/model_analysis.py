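"""Interpretability and cross-species generalization analyses.

* [CLS]-row attention extraction: average attention over the ensemble's
  folds, take the last layer, average over heads, read the [CLS]-query row,
  drop special-token columns and renormalize — a per-residue importance
  profile for the classification decision.
* Cross-species prediction: evaluate each species' classifier ensemble on
  every other species' independent test set, after removing test sequences
  with >= 90% identity to any training sequence of the predicting model
  (homology exclusion prevents trivially inflated transfer accuracy).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .dataset_builder import DatasetSplits, ExpressionDataset, cluster_identity_greedy
from .lm_core import ClassifierEnsemble, encode_sequence, evaluate_classifier

logger = logging.getLogger(__name__)


@dataclass
class AttentionSummary:
    """Per-residue attention weights from the [CLS] query row."""

    weights: np.ndarray          # (n_residues,) nonnegative, sums to 1
    residues: str                # the encoded residue prefix the weights cover
    n_folds: int
    layer_index: int
    n_heads_averaged: int


@dataclass(frozen=True)
class CrossPredictionCell:
    model_species: str
    target_species: str
    n_test_after_exclusion: int
    acc: float | None


def extract_cls_attention(
    ensemble: ClassifierEnsemble, sequence: str
) -> AttentionSummary:
    """Average fold/head attention at the last layer, read the [CLS] row.

    Entries for [CLS]/[EOS]/[PAD] are dropped and the remaining residue
    weights renormalized to sum to 1, making profiles comparable across
    sequence lengths.  Sequences longer than the encoder window are covered
    only over their encoded N-terminal prefix (a warning is logged).
    """
    config = ensemble.models[0].config
    if len(sequence) > config.max_seq_len - 2:
        logger.warning(
            "sequence length %d exceeds window; attention covers first %d residues",
            len(sequence), config.max_seq_len - 2,
        )
    ids = np.array([encode_sequence(sequence, config, pad=False)])
    pad_mask = ids == 0
    last_layers = []
    for model in ensemble.models:
        _, attentions = model.encode(ids, pad_mask, collect_attention=True)
        last_layers.append(attentions[-1][0])     # (heads, L, L)
    avg = np.mean(last_layers, axis=0)            # fold average
    head_avg = avg.mean(axis=0)                   # (L, L)
    cls_row = head_avg[0]
    n_res = ids.shape[1] - 2                      # drop [CLS] at 0 and [EOS] at -1
    weights = cls_row[1 : 1 + n_res]
    weights = weights / weights.sum()
    return AttentionSummary(
        weights=weights,
        residues=sequence[:n_res],
        n_folds=len(ensemble.models),
        layer_index=config.n_layers - 1,
        n_heads_averaged=config.n_heads,
    )


def write_attention_tsv(summary: AttentionSummary, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("position\tresidue\tweight\n")
        for i, (aa, w) in enumerate(zip(summary.residues, summary.weights), start=1):
            fh.write(f"{i}\t{aa}\t{w!r}\n")


def homology_excluded_test_set(
    train_sequences: Mapping[str, str],
    foreign_test: Mapping[str, str],
    threshold: float = 0.90,
) -> dict[str, str]:
    """Drop test sequences sharing an identity cluster with any training sequence.

    Train and test are clustered jointly (greedy, CD-HIT style); a test
    sequence at or above the identity threshold to a cluster containing a
    training sequence is removed.
    """
    if not train_sequences or not foreign_test:
        raise ValueError("both sequence sets must be nonempty")
    union = {f"train::{k}": v for k, v in train_sequences.items()}
    union.update({f"test::{k}": v for k, v in foreign_test.items()})
    clusters = cluster_identity_greedy(union, threshold=threshold)
    kept: dict[str, str] = {}
    for cl in clusters:
        has_train = any(m.startswith("train::") for m in cl.members)
        for m in cl.members:
            if m.startswith("test::") and not has_train:
                key = m[len("test::"):]
                kept[key] = foreign_test[key]
    n_removed = len(foreign_test) - len(kept)
    if n_removed:
        logger.info("homology exclusion removed %d/%d test sequences",
                    n_removed, len(foreign_test))
    return kept


def cross_prediction_matrix(
    ensembles: Mapping[str, ClassifierEnsemble],
    datasets: Mapping[str, ExpressionDataset],
    splits: Mapping[str, DatasetSplits],
    threshold: float = 0.90,
) -> list[CrossPredictionCell]:
    """Accuracy of every species model on every species' independent test set.

    Diagonal cells use the model's own test set unfiltered; off-diagonal
    cells use the foreign test set after homology exclusion against the
    model's training sequences.  Cells with an empty post-exclusion test
    set are marked missing (``acc=None``).
    """
    if len(ensembles) < 2:
        raise ValueError("cross-prediction requires at least 2 species")
    cells: list[CrossPredictionCell] = []
    for model_sp, ensemble in ensembles.items():
        model_ds = datasets[model_sp]
        model_split = splits[model_sp]
        train_idx = sorted(set(range(len(model_ds.entries))) - set(model_split.test_idx))
        train_seqs = {
            model_ds.entries[i].protein_id: model_ds.entries[i].sequence for i in train_idx
        }
        for target_sp, target_ds in datasets.items():
            test_entries = [target_ds.entries[i] for i in splits[target_sp].test_idx]
            if model_sp == target_sp:
                surviving = test_entries
            else:
                test_map = {e.protein_id: e.sequence for e in test_entries}
                kept = homology_excluded_test_set(train_seqs, test_map, threshold)
                surviving = [e for e in test_entries if e.protein_id in kept]
            if not surviving:
                cells.append(CrossPredictionCell(model_sp, target_sp, 0, None))
                continue
            probs = ensemble.predict_proba([e.sequence for e in surviving]).mean(axis=1)
            labels = np.array([1 if e.expr_class == "high" else 0 for e in surviving])
            acc = evaluate_classifier(probs, labels)["acc"]
            cells.append(
                CrossPredictionCell(model_sp, target_sp, len(surviving), acc)
            )
    return cells


def write_cross_prediction_tsv(cells: Sequence[CrossPredictionCell], path) -> None:
    species = sorted({c.model_species for c in cells})
    grid = {(c.model_species, c.target_species): c for c in cells}
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("model_species\t" + "\t".join(species) + "\n")
        for sp in species:
            row = [sp]
            for tgt in species:
                cell = grid.get((sp, tgt))
                row.append("NA" if cell is None or cell.acc is None else f"{cell.acc:.4f}")
            fh.write("\t".join(row) + "\n")
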