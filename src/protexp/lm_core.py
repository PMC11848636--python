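"""Masked-language-model encoder and expression fine-tuning.

Covers the full model stack: tokenization over a 25-token vocabulary (20
standard amino acids + [PAD]/[CLS]/[EOS]/[MASK]/[UNK]), 15% MLM masking
with the 80/10/10 rewrite rule, cross-entropy pretraining with AdamW, and
two fine-tuned heads — a 2-way expression classifier trained per
cross-validation fold (the per-fold high-class probabilities average into
the HE-Value) and a scalar regressor on log abundance.

Two architecture presets ship with the module: ``full_scale_config()``
mirrors the production encoder (8 layers, 16 heads, hidden 1024, sequence
length 1024, ~87M parameters) and ``desk_config()`` is a CPU-trainable
reduction (2 layers, 4 heads, hidden 64) used throughout the test suite.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn import metrics as skmetrics

from .dataset_builder import DatasetSplits, ExpressionDataset
from .io_formats import STANDARD_AA
from .nn import AdamW, TransformerEncoder, parameter_count, softmax_cross_entropy
from .nn.autodiff import Tensor

logger = logging.getLogger(__name__)

PAD, CLS, EOS, MASK, UNK = "[PAD]", "[CLS]", "[EOS]", "[MASK]", "[UNK]"


@dataclass(frozen=True)
class Vocabulary:
    """Stable 25-token vocabulary: 5 special tokens then the 20 residues."""

    tokens: tuple[str, ...] = (PAD, CLS, EOS, MASK, UNK) + STANDARD_AA

    def __post_init__(self) -> None:
        assert len(self.tokens) == 25 and len(set(self.tokens)) == 25

    def __len__(self) -> int:
        return len(self.tokens)

    def index(self, token: str) -> int:
        return self.tokens.index(token)

    @property
    def residue_ids(self) -> np.ndarray:
        """Ids of the 20 standard residues (contiguous block after specials)."""
        return np.arange(5, 25)


VOCAB = Vocabulary()
_PAD_ID, _CLS_ID, _EOS_ID, _MASK_ID, _UNK_ID = range(5)
_AA_TO_ID = {aa: 5 + i for i, aa in enumerate(STANDARD_AA)}
_ID_TO_AA = {v: k for k, v in _AA_TO_ID.items()}


@dataclass(frozen=True)
class EncoderConfig:
    n_layers: int
    n_heads: int
    hidden_size: int
    ffn_inner_size: int
    max_seq_len: int
    vocab_size: int = 25

    def __post_init__(self) -> None:
        if self.hidden_size % self.n_heads != 0:
            raise ValueError("hidden_size must be divisible by n_heads")
        if self.max_seq_len < 3:
            raise ValueError("max_seq_len must be >= 3 ([CLS] + residue + [EOS])")


def full_scale_config() -> EncoderConfig:
    """Production-scale preset: 8 layers, 16 heads, hidden 1024, length 1024."""
    return EncoderConfig(n_layers=8, n_heads=16, hidden_size=1024,
                         ffn_inner_size=3200, max_seq_len=1024)


def desk_config(max_seq_len: int = 128) -> EncoderConfig:
    """CPU-trainable preset used for tests and examples."""
    return EncoderConfig(n_layers=2, n_heads=4, hidden_size=64,
                         ffn_inner_size=128, max_seq_len=max_seq_len)


def encode_sequence(sequence: str, config: EncoderConfig, pad: bool = True) -> list[int]:
    """Token ids: [CLS] + residues (nonstandard -> [UNK]) + [EOS], padded.

    Sequences longer than ``max_seq_len - 2`` keep their first
    ``max_seq_len - 2`` N-terminal residues.
    """
    if not sequence:
        raise ValueError("cannot encode an empty sequence")
    body = [_AA_TO_ID.get(ch, _UNK_ID) for ch in sequence[: config.max_seq_len - 2]]
    ids = [_CLS_ID] + body + [_EOS_ID]
    if pad:
        ids += [_PAD_ID] * (config.max_seq_len - len(ids))
    return ids


def count_parameters(config: EncoderConfig) -> int:
    """Closed-form trainable-parameter total (see nn.transformer)."""
    return parameter_count(config)


@dataclass
class MaskedBatch:
    """Masked token rows with targets defined only at masked positions."""

    input_ids: np.ndarray      # (B, L) int
    pad_mask: np.ndarray       # (B, L) bool, True at [PAD]
    mask_positions: np.ndarray  # (n_masked,) flat indices into B*L
    targets: np.ndarray        # (n_masked,) original token ids


def n_masked(rate: float, n_residues: int) -> int:
    """Exact masked-position count: round(rate * n), at least 1."""
    return max(1, round(rate * n_residues))


def apply_pretrain_masking(
    token_rows: Sequence[Sequence[int]],
    rate: float = 0.15,
    seed: int = 0,
    mask_only: bool = False,
) -> MaskedBatch:
    """Mask residue positions for MLM training.

    Exactly ``round(rate * n_residues)`` positions per row (min 1), chosen
    uniformly without replacement; special tokens are never selected.  Each
    chosen position is rewritten with probability 0.8 to [MASK], 0.1 to a
    random residue, 0.1 left unchanged — unless ``mask_only``, which always
    writes [MASK] (the mutant-generation fine-tuning regime).  Targets are
    the original tokens.  Deterministic under ``seed``.
    """
    if not 0 < rate <= 1:
        raise ValueError("masking rate must be in (0, 1]")
    if not token_rows:
        raise ValueError("empty batch")
    rng = np.random.default_rng(seed)
    L = max(len(r) for r in token_rows)
    B = len(token_rows)
    ids = np.full((B, L), _PAD_ID, dtype=np.int64)
    for i, row in enumerate(token_rows):
        ids[i, : len(row)] = row
    targets_full = ids.copy()
    flat_positions: list[int] = []
    for i in range(B):
        residue_pos = np.flatnonzero(ids[i] >= _UNK_ID)  # residues and [UNK]
        if residue_pos.size == 0:
            raise ValueError(f"row {i} has no residue positions")
        k = n_masked(rate, residue_pos.size)
        chosen = rng.choice(residue_pos, size=k, replace=False)
        for pos in sorted(chosen):
            if mask_only:
                ids[i, pos] = _MASK_ID
            else:
                u = rng.random()
                if u < 0.8:
                    ids[i, pos] = _MASK_ID
                elif u < 0.9:
                    ids[i, pos] = rng.choice(VOCAB.residue_ids)
                # else: leave unchanged
            flat_positions.append(i * L + pos)
    flat = np.array(sorted(flat_positions), dtype=np.int64)
    return MaskedBatch(
        input_ids=ids,
        pad_mask=ids == _PAD_ID,
        mask_positions=flat,
        targets=targets_full.reshape(-1)[flat],
    )


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters shared by pretraining and fine-tuning."""

    lr: float = 1e-3
    weight_decay: float = 0.01
    epochs: int = 3
    batch_size: int = 16
    warmup_frac: float = 0.05
    seed: int = 0


def _batched(items: Sequence, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(len(items))
    for start in range(0, len(items), batch_size):
        yield [items[i] for i in order[start : start + batch_size]]


def pretrain_mlm(
    corpus: Sequence[str],
    config: EncoderConfig,
    train: TrainConfig = TrainConfig(),
    mask_rate: float = 0.15,
    mask_only: bool = False,
    model: TransformerEncoder | None = None,
) -> tuple[TransformerEncoder, list[float]]:
    """MLM-pretrain an encoder on a sequence corpus.

    Loss is cross-entropy over masked positions only.  Returns the trained
    encoder and the per-step loss history.  Pass ``model`` to continue
    training an existing encoder (used by mutant-generation fine-tuning).
    """
    if not corpus:
        raise ValueError("empty pretraining corpus")
    if model is None:
        model = TransformerEncoder(config, seed=train.seed)
    rows = [encode_sequence(s, config, pad=False) for s in corpus]
    n_steps = train.epochs * math.ceil(len(rows) / train.batch_size)
    opt = AdamW(model.trainable(), lr=train.lr, weight_decay=train.weight_decay,
                warmup_steps=max(1, int(train.warmup_frac * n_steps)))
    rng = np.random.default_rng(train.seed)
    history: list[float] = []
    for epoch in range(train.epochs):
        for chunk in _batched(rows, train.batch_size, rng):
            batch = apply_pretrain_masking(
                chunk, rate=mask_rate, seed=int(rng.integers(2**31)), mask_only=mask_only
            )
            hidden, _ = model.encode(batch.input_ids, batch.pad_mask)
            logits = model.mlm_logits(hidden, batch.mask_positions)
            loss = softmax_cross_entropy(logits, batch.targets)
            opt.zero_grad()
            loss.backward()
            opt.step()
            history.append(float(loss.data))
    logger.info("pretraining done: %d steps, final loss %.4f", len(history), history[-1])
    return model, history


def masked_token_accuracy(
    model: TransformerEncoder,
    sequences: Sequence[str],
    rate: float = 0.15,
    seed: int = 0,
    mask_only: bool = False,
) -> float:
    """Fraction of masked tokens recovered by argmax over the full vocabulary."""
    rows = [encode_sequence(s, model.config, pad=False) for s in sequences]
    batch = apply_pretrain_masking(rows, rate=rate, seed=seed, mask_only=mask_only)
    hidden, _ = model.encode(batch.input_ids, batch.pad_mask)
    logits = model.mlm_logits(hidden, batch.mask_positions)
    return float((logits.data.argmax(axis=1) == batch.targets).mean())


def _encode_batch(sequences: Sequence[str], config: EncoderConfig):
    rows = [encode_sequence(s, config, pad=False) for s in sequences]
    L = max(len(r) for r in rows)
    ids = np.full((len(rows), L), _PAD_ID, dtype=np.int64)
    for i, row in enumerate(rows):
        ids[i, : len(row)] = row
    return ids, ids == _PAD_ID


@dataclass
class ExpressionPrediction:
    """Ensembled high-expression probability (HE-Value)."""

    he_value: float
    fold_probabilities: tuple[float, ...]

    def __post_init__(self) -> None:
        assert all(0 <= p <= 1 for p in self.fold_probabilities)


@dataclass
class ClassifierEnsemble:
    """Per-fold fine-tuned classifiers; predictions average across folds."""

    models: list[TransformerEncoder]
    species_id: str = ""

    def predict_proba(self, sequences: Sequence[str], batch_size: int = 64) -> np.ndarray:
        """(n_sequences, n_folds) high-class probabilities."""
        cols = [[] for _ in self.models]
        for start in range(0, len(sequences), batch_size):
            chunk = sequences[start : start + batch_size]
            ids, pad = _encode_batch(chunk, self.models[0].config)
            for j, m in enumerate(self.models):
                hidden, _ = m.encode(ids, pad)
                logits = m.cls_logits(hidden).data
                z = logits - logits.max(axis=1, keepdims=True)
                e = np.exp(z)
                cols[j].append(e[:, 1] / e.sum(axis=1))
        return np.stack([np.concatenate(c) for c in cols], axis=1)


def _train_head(
    model: TransformerEncoder,
    sequences: Sequence[str],
    targets: np.ndarray,
    train: TrainConfig,
    task: str,
) -> TransformerEncoder:
    rows = list(range(len(sequences)))
    n_steps = train.epochs * math.ceil(len(rows) / train.batch_size)
    opt = AdamW(model.trainable(), lr=train.lr, weight_decay=train.weight_decay,
                warmup_steps=max(1, int(train.warmup_frac * n_steps)))
    rng = np.random.default_rng(train.seed)
    for epoch in range(train.epochs):
        for chunk in _batched(rows, train.batch_size, rng):
            ids, pad = _encode_batch([sequences[i] for i in chunk], model.config)
            hidden, _ = model.encode(ids, pad)
            if task == "cls":
                logits = model.cls_logits(hidden)
                loss = softmax_cross_entropy(logits, targets[chunk])
            else:
                pred = model.reg_output(hidden).reshape(len(chunk))
                diff = pred - Tensor(targets[chunk])
                loss = (diff * diff).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
    return model


def finetune_classifier(
    encoder: TransformerEncoder,
    dataset: ExpressionDataset,
    splits: DatasetSplits,
    train: TrainConfig = TrainConfig(),
) -> ClassifierEnsemble:
    """Fine-tune one classifier per cross-validation fold (high=1, low=0)."""
    sequences = [e.sequence for e in dataset.entries]
    labels = np.array([1 if e.expr_class == "high" else 0 for e in dataset.entries])
    models = []
    for fold_i, (train_idx, _val_idx) in enumerate(splits.folds):
        fold_labels = labels[list(train_idx)]
        if len(set(fold_labels.tolist())) < 2:
            raise ValueError(f"fold {fold_i}: training data contains a single class")
        model = encoder.copy()
        model.add_classifier_head(n_classes=2, seed=train.seed + fold_i)
        _train_head(
            model,
            [sequences[i] for i in train_idx],
            labels[list(train_idx)],
            replace(train, seed=train.seed + fold_i),
            task="cls",
        )
        models.append(model)
    return ClassifierEnsemble(models=models, species_id=dataset.species_id)


def predict_he_value(ensemble: ClassifierEnsemble, sequence: str) -> ExpressionPrediction:
    """HE-Value: arithmetic mean of per-fold high-class probabilities."""
    probs = ensemble.predict_proba([sequence])[0]
    return ExpressionPrediction(
        he_value=float(probs.mean()), fold_probabilities=tuple(float(p) for p in probs)
    )


@dataclass
class RegressorEnsemble:
    models: list[TransformerEncoder]

    def predict(self, sequences: Sequence[str]) -> np.ndarray:
        ids, pad = _encode_batch(sequences, self.models[0].config)
        preds = []
        for m in self.models:
            hidden, _ = m.encode(ids, pad)
            preds.append(m.reg_output(hidden).data[:, 0])
        return np.mean(preds, axis=0)


def finetune_regressor(
    encoder: TransformerEncoder,
    dataset: ExpressionDataset,
    splits: DatasetSplits,
    train: TrainConfig = TrainConfig(),
) -> RegressorEnsemble:
    """Fine-tune per-fold regressors on log-scale abundance (MSE loss)."""
    sequences = [e.sequence for e in dataset.entries]
    abundances = np.array([e.abundance for e in dataset.entries])
    if (abundances <= 0).any():
        raise ValueError("regression requires strictly positive abundances (log scale)")
    y = np.log(abundances)
    models = []
    for fold_i, (train_idx, _val) in enumerate(splits.folds):
        model = encoder.copy()
        model.add_regressor_head(seed=train.seed + fold_i)
        _train_head(
            model,
            [sequences[i] for i in train_idx],
            y[list(train_idx)],
            replace(train, seed=train.seed + fold_i),
            task="reg",
        )
        models.append(model)
    return RegressorEnsemble(models=models)


def evaluate_classifier(
    probabilities: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> dict[str, float | None]:
    """Standard binary-classification metrics at a 0.5 threshold.

    AUC and MCC are reported as None when the labels are single-class.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels, dtype=int)
    preds = (probabilities >= threshold).astype(int)
    out: dict[str, float | None] = {
        "acc": float(skmetrics.accuracy_score(labels, preds)),
        "recall": float(skmetrics.recall_score(labels, preds, zero_division=0)),
        "precision": float(skmetrics.precision_score(labels, preds, zero_division=0)),
        "f1": float(skmetrics.f1_score(labels, preds, zero_division=0)),
    }
    if len(set(labels.tolist())) < 2:
        out["auc"] = None
        out["mcc"] = None
    else:
        out["auc"] = float(skmetrics.roc_auc_score(labels, probabilities))
        out["mcc"] = float(skmetrics.matthews_corrcoef(labels, preds))
    return out


def evaluate_regressor(
    predictions: np.ndarray, targets: np.ndarray
) -> dict[str, float | None]:
    """RMSE, R^2 and Spearman correlation; R^2/Spearman None for constant targets."""
    predictions = np.asarray(predictions, dtype=float)
    targets = np.asarray(targets, dtype=float)
    rmse = float(np.sqrt(np.mean((predictions - targets) ** 2)))
    if np.ptp(targets) == 0:
        return {"rmse": rmse, "r2": None, "spearman": None}
    r2 = float(skmetrics.r2_score(targets, predictions))
    rho = float(stats.spearmanr(predictions, targets).statistic)
    return {"rmse": rmse, "r2": r2, "spearman": rho}
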