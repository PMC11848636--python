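"""Mask-based mutant design for raising heterologous expression.

Procedure: fine-tune the pretrained encoder on a homolog family of the
wild type with 10% all-[MASK] masking (no 80/10/10 rewrite), then repeatedly
mask 10% of the wild-type residues and let the model fill them in.  Each
generated sequence carries an **M-Value** — the minimum predicted-residue
probability over its masked positions, a confidence floor for the whole
mutant.  Candidates are shortlisted by M-Value (top 200 by default), scored
by an expression classifier ensemble (HE-Value), ranked, and annotated with
their SRAB under the host's AEI table.

Per-position **entropy** over the generated pool, S = -sum p_i ln p_i,
maps which regions of the protein the generator treats as mutable
(high S) versus conserved (S near 0).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .composition_stats import AEITable, compute_srab
from .io_formats import STANDARD_AA
from .lm_core import (
    ClassifierEnsemble,
    EncoderConfig,
    MaskedBatch,
    TrainConfig,
    apply_pretrain_masking,
    encode_sequence,
    n_masked,
    pretrain_mlm,
    predict_he_value,
)
from .nn import TransformerEncoder

logger = logging.getLogger(__name__)

_RESIDUE_IDS = np.arange(5, 25)
_ID_TO_AA = {5 + i: aa for i, aa in enumerate(STANDARD_AA)}


@dataclass
class MutantCandidate:
    """One generated sequence with its masked positions and confidence."""

    sequence: str
    masked_positions: tuple[int, ...]           # 0-based positions in the sequence
    predicted_residues: tuple[str, ...]
    probabilities: tuple[float, ...]
    m_value: float
    mutated_sites: tuple[str, ...]              # e.g. ("K45E",) 1-based
    he_value: float | None = None
    srab: float | None = None

    def __post_init__(self) -> None:
        assert len(self.masked_positions) == len(self.predicted_residues)
        assert not self.m_value > 1 and self.m_value > 0


@dataclass
class EntropyProfile:
    """Per-position Shannon entropy (natural log) over a mutant pool."""

    entropy: np.ndarray          # (L,)
    distributions: np.ndarray    # (L, 20) residue probabilities


def strip_alignment(sequence: str) -> str:
    """Drop A2M insert columns (lowercase) and gap characters."""
    return "".join(ch for ch in sequence if ch.isupper() and ch not in "-.")


def build_mutgen_training_set(
    homologs: Sequence[str],
    config: EncoderConfig,
    rate: float = 0.10,
    seed: int = 0,
) -> MaskedBatch:
    """Masked batch for mutant-generator fine-tuning: [MASK]-only rewrites.

    ``round(rate * n)`` positions per homolog (min 1) are replaced by
    [MASK]; targets are the original residues.
    """
    if not homologs:
        raise ValueError("empty homolog set")
    rows = [encode_sequence(strip_alignment(s), config, pad=False) for s in homologs]
    return apply_pretrain_masking(rows, rate=rate, seed=seed, mask_only=True)


def finetune_mutant_generator(
    encoder: TransformerEncoder,
    homologs: Sequence[str],
    train: TrainConfig = TrainConfig(),
    rate: float = 0.10,
) -> TransformerEncoder:
    """Continue MLM training on the homolog family with 10% [MASK]-only masking."""
    cleaned = [strip_alignment(s) for s in homologs]
    if not cleaned or any(not s for s in cleaned):
        raise ValueError("homolog set empty or contains empty sequences")
    model = encoder.copy()
    model, _ = pretrain_mlm(
        cleaned, model.config, train=train, mask_rate=rate, mask_only=True, model=model
    )
    return model


def _predict_masked(
    model: TransformerEncoder, ids: np.ndarray, flat_positions: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Argmax residue ids and probabilities at masked positions.

    Prediction is restricted to the 20 residue tokens; probabilities are the
    softmax renormalized over those tokens.
    """
    pad_mask = ids == 0
    hidden, _ = model.encode(ids, pad_mask)
    logits = model.mlm_logits(hidden, flat_positions).data[:, _RESIDUE_IDS]
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    best = p.argmax(axis=1)
    return _RESIDUE_IDS[best], p[np.arange(len(best)), best]


def generate_mutants(
    model: TransformerEncoder,
    wild_type: str,
    n_samples: int,
    rate: float = 0.10,
    seed: int = 0,
    batch_size: int = 32,
) -> list[MutantCandidate]:
    """Generate mutants by repeated 10% masking and filling of the wild type.

    Each sample draws a fresh random mask; the model's argmax residue (over
    the 20 residue tokens) replaces each masked position.  A mutation is
    recorded where the prediction differs from the wild type.  Duplicate
    sequences are collapsed keeping the highest M-Value.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    base = np.array(encode_sequence(wild_type, model.config, pad=False))
    residue_pos = np.flatnonzero(base >= 4)      # residues and [UNK]
    n_res = residue_pos.size
    k = n_masked(rate, n_res)
    by_sequence: dict[str, MutantCandidate] = {}
    effective = wild_type[: model.config.max_seq_len - 2]
    for start in range(0, n_samples, batch_size):
        nb = min(batch_size, n_samples - start)
        ids = np.tile(base, (nb, 1))
        masked_cols = np.stack(
            [np.sort(rng.choice(residue_pos, size=k, replace=False)) for _ in range(nb)]
        )
        rows = np.repeat(np.arange(nb), k)
        ids[rows, masked_cols.reshape(-1)] = 3   # [MASK]
        flat = rows * ids.shape[1] + masked_cols.reshape(-1)
        pred_ids, pred_p = _predict_masked(model, ids, flat)
        pred_ids = pred_ids.reshape(nb, k)
        pred_p = pred_p.reshape(nb, k)
        for b in range(nb):
            seq = list(effective)
            sites = []
            for pos_tok, rid in zip(masked_cols[b], pred_ids[b]):
                pos0 = pos_tok - 1              # token row has [CLS] at 0
                aa = _ID_TO_AA[int(rid)]
                if seq[pos0] != aa:
                    sites.append(f"{seq[pos0]}{pos0 + 1}{aa}")
                seq[pos0] = aa
            mutant = "".join(seq)
            cand = MutantCandidate(
                sequence=mutant,
                masked_positions=tuple(int(p - 1) for p in masked_cols[b]),
                predicted_residues=tuple(_ID_TO_AA[int(r)] for r in pred_ids[b]),
                probabilities=tuple(float(p) for p in pred_p[b]),
                m_value=float(pred_p[b].min()),
                mutated_sites=tuple(sites),
            )
            prev = by_sequence.get(mutant)
            if prev is None or cand.m_value > prev.m_value:
                by_sequence[mutant] = cand
    return list(by_sequence.values())


def m_value(probabilities: Sequence[float]) -> float:
    """Mutant confidence: the minimum predicted-residue probability."""
    if not probabilities:
        raise ValueError("m_value requires at least one masked position")
    return float(min(probabilities))


def mutation_rate(
    model: TransformerEncoder, eval_batches: Sequence[MaskedBatch]
) -> float:
    """1 - fraction of masked positions predicted back to the original residue."""
    recovered = 0
    total = 0
    for batch in eval_batches:
        pred_ids, _ = _predict_masked(model, batch.input_ids, batch.mask_positions)
        recovered += int((pred_ids == batch.targets).sum())
        total += len(batch.targets)
    if total == 0:
        raise ValueError("no masked positions in evaluation batches")
    return 1.0 - recovered / total


def position_entropy(
    candidates: Sequence[MutantCandidate], wild_type_length: int
) -> EntropyProfile:
    """Residue-distribution entropy at each position across all candidates."""
    if not candidates:
        raise ValueError("no candidates")
    aa_index = {aa: i for i, aa in enumerate(STANDARD_AA)}
    counts = np.zeros((wild_type_length, 20))
    for cand in candidates:
        for pos, ch in enumerate(cand.sequence[:wild_type_length]):
            i = aa_index.get(ch)
            if i is not None:
                counts[pos, i] += 1
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(totals > 0, counts / totals, 0.0)
        logs = np.where(p > 0, np.log(p), 0.0)
    return EntropyProfile(entropy=-(p * logs).sum(axis=1), distributions=p)


def select_candidates(
    candidates: Sequence[MutantCandidate], k: int = 200
) -> list[MutantCandidate]:
    """Top-k distinct sequences by M-Value.

    Ties break by HE-Value descending (when present) then sequence
    lexicographically, so the shortlist is stable across runs.
    """
    if not candidates:
        raise ValueError("no candidates to select from")
    best: dict[str, MutantCandidate] = {}
    for c in candidates:
        prev = best.get(c.sequence)
        if prev is None or c.m_value > prev.m_value:
            best[c.sequence] = c
    ranked = sorted(
        best.values(),
        key=lambda c: (-c.m_value, -(c.he_value if c.he_value is not None else -math.inf),
                       c.sequence),
    )
    return ranked[:k]


def design_expression_mutants(
    wild_type: str,
    mutgen_model: TransformerEncoder,
    expression_ensemble: ClassifierEnsemble,
    aei_table: AEITable | None = None,
    n_samples: int = 1000,
    rate: float = 0.10,
    k: int = 200,
    seed: int = 0,
) -> list[dict]:
    """Full design pipeline: generate, shortlist by M-Value, rank by HE-Value.

    Returns report rows (dicts) ranked by HE-Value descending, with the wild
    type appended as a reference row (its M-Value is undefined).  Columns:
    sequence_id, sequence, m_value, he_value, srab, n_mutations,
    mutated_sites.
    """
    pool = generate_mutants(mutgen_model, wild_type, n_samples, rate=rate, seed=seed)
    shortlist = select_candidates(pool, k=k)
    for cand in shortlist:
        cand.he_value = predict_he_value(expression_ensemble, cand.sequence).he_value
        if aei_table is not None:
            cand.srab = compute_srab(cand.sequence, aei_table).value
    shortlist.sort(key=lambda c: (-c.he_value, c.sequence))
    rows = []
    for i, cand in enumerate(shortlist, start=1):
        rows.append(
            {
                "sequence_id": f"mutant-{i:03d}",
                "sequence": cand.sequence,
                "m_value": cand.m_value,
                "he_value": cand.he_value,
                "srab": cand.srab,
                "n_mutations": len(cand.mutated_sites),
                "mutated_sites": ",".join(cand.mutated_sites),
            }
        )
    wt_he = predict_he_value(expression_ensemble, wild_type).he_value
    rows.append(
        {
            "sequence_id": "wild-type",
            "sequence": wild_type,
            "m_value": None,
            "he_value": wt_he,
            "srab": compute_srab(wild_type, aei_table).value if aei_table else None,
            "n_mutations": 0,
            "mutated_sites": "",
        }
    )
    return rows


def write_report(rows: Sequence[Mapping], path) -> None:
    """Write a design report as TSV."""
    cols = ["sequence_id", "m_value", "he_value", "srab", "n_mutations",
            "mutated_sites", "sequence"]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join("" if row[c] is None else str(row[c]) for c in cols) + "\n")
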