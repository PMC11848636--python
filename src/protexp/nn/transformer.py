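"""Transformer encoder for protein sequences, built on the autodiff core.

Architecture: token + learned position embeddings followed by a layer norm,
then a stack of post-layer-norm transformer blocks (multi-head self
attention and a GELU feed-forward, each wrapped in residual + layer norm).
Three interchangeable output heads: an untied masked-language-model head
over the full vocabulary, a 2-way classification head on the [CLS]
representation, and a scalar regression head on [CLS].

Attention probabilities can be collected during the forward pass for
interpretability analyses.
"""

from __future__ import annotations

import json
import math
from typing import Mapping

import numpy as np

from .autodiff import Parameter, Tensor, softmax

__all__ = ["TransformerEncoder", "parameter_count"]


def parameter_count(config) -> int:
    """Closed-form trainable-parameter total for a given encoder config.

    token embedding V*H + position table L*H + per layer [4(H^2+H) attention
    + (H*F + F + F*H + H) feed-forward + 2 layer norms of 2H] + embedding
    layer norm 2H + untied MLM output head (H*V + V).
    """
    V, H, L = config.vocab_size, config.hidden_size, config.max_seq_len
    F, n = config.ffn_inner_size, config.n_layers
    per_layer = 4 * (H * H + H) + (H * F + F + F * H + H) + 2 * (2 * H)
    return V * H + L * H + n * per_layer + 2 * H + (H * V + V)


class TransformerEncoder:
    """MLM-pretrained protein encoder with swappable output heads."""

    def __init__(self, config, seed: int = 0):
        self.config = config
        if config.hidden_size % config.n_heads != 0:
            raise ValueError("hidden_size must be divisible by n_heads")
        rng = np.random.default_rng(seed)
        H, V, L, F = (config.hidden_size, config.vocab_size,
                      config.max_seq_len, config.ffn_inner_size)
        s = 0.02
        p: dict[str, Parameter] = {}
        p["tok_emb"] = Parameter(rng.normal(0, s, (V, H)))
        p["pos_emb"] = Parameter(rng.normal(0, s, (L, H)))
        p["emb_ln_g"] = Parameter(np.ones(H))
        p["emb_ln_b"] = Parameter(np.zeros(H))
        for i in range(config.n_layers):
            for name in ("q", "k", "v", "o"):
                p[f"l{i}.{name}_w"] = Parameter(rng.normal(0, s, (H, H)))
                p[f"l{i}.{name}_b"] = Parameter(np.zeros(H))
            p[f"l{i}.ffn1_w"] = Parameter(rng.normal(0, s, (H, F)))
            p[f"l{i}.ffn1_b"] = Parameter(np.zeros(F))
            p[f"l{i}.ffn2_w"] = Parameter(rng.normal(0, s, (F, H)))
            p[f"l{i}.ffn2_b"] = Parameter(np.zeros(H))
            p[f"l{i}.ln1_g"] = Parameter(np.ones(H))
            p[f"l{i}.ln1_b"] = Parameter(np.zeros(H))
            p[f"l{i}.ln2_g"] = Parameter(np.ones(H))
            p[f"l{i}.ln2_b"] = Parameter(np.zeros(H))
        p["mlm_w"] = Parameter(rng.normal(0, s, (H, V)))
        p["mlm_b"] = Parameter(np.zeros(V))
        self.params = p
        self.heads: dict[str, dict[str, Parameter]] = {}

    # -- heads --------------------------------------------------------

    def add_classifier_head(self, n_classes: int = 2, seed: int = 0) -> None:
        rng = np.random.default_rng(seed)
        H = self.config.hidden_size
        self.heads["cls"] = {
            "w": Parameter(rng.normal(0, 0.02, (H, n_classes))),
            "b": Parameter(np.zeros(n_classes)),
        }

    def add_regressor_head(self, seed: int = 0) -> None:
        rng = np.random.default_rng(seed)
        H = self.config.hidden_size
        self.heads["reg"] = {
            "w": Parameter(rng.normal(0, 0.02, (H, 1))),
            "b": Parameter(np.zeros(1)),
        }

    # -- bookkeeping --------------------------------------------------

    def num_parameters(self, include_heads: bool = False) -> int:
        total = sum(t.data.size for t in self.params.values())
        if include_heads:
            total += sum(t.data.size for h in self.heads.values() for t in h.values())
        return total

    def trainable(self) -> dict[str, Parameter]:
        out = dict(self.params)
        for hname, head in self.heads.items():
            for k, v in head.items():
                out[f"head.{hname}.{k}"] = v
        return out

    def copy(self) -> "TransformerEncoder":
        clone = TransformerEncoder.__new__(TransformerEncoder)
        clone.config = self.config
        clone.params = {k: Parameter(v.data.copy()) for k, v in self.params.items()}
        clone.heads = {
            h: {k: Parameter(v.data.copy()) for k, v in head.items()}
            for h, head in self.heads.items()
        }
        return clone

    def save(self, path) -> None:
        arrays = {k: v.data for k, v in self.trainable().items()}
        cfg = json.dumps(self.config.__dict__)
        np.savez(path, __config__=np.frombuffer(cfg.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path, config_cls):
        with np.load(path) as npz:
            cfg = json.loads(bytes(npz["__config__"]).decode())
            model = cls(config_cls(**cfg))
            for k in npz.files:
                if k == "__config__":
                    continue
                if k.startswith("head."):
                    _, hname, pname = k.split(".", 2)
                    model.heads.setdefault(hname, {})[pname] = Parameter(npz[k].copy())
                else:
                    model.params[k].data = npz[k].copy()
        return model

    # -- forward ------------------------------------------------------

    def encode(
        self,
        ids: np.ndarray,
        pad_mask: np.ndarray,
        collect_attention: bool = False,
    ) -> tuple[Tensor, list[np.ndarray]]:
        """Hidden states (B, L, H) for integer token ids (B, L).

        ``pad_mask`` is True at [PAD] positions; those keys are excluded from
        attention.  When ``collect_attention`` the per-layer softmax
        probability arrays (B, heads, L, L) are returned as plain numpy.
        """
        cfg = self.config
        B, L = ids.shape
        if L > cfg.max_seq_len:
            raise ValueError(f"sequence length {L} exceeds max_seq_len {cfg.max_seq_len}")
        p = self.params
        x = p["tok_emb"][ids] + p["pos_emb"][np.arange(L)]
        x = x.layer_norm(p["emb_ln_g"], p["emb_ln_b"])
        h, dh = cfg.n_heads, cfg.hidden_size // cfg.n_heads
        key_mask = pad_mask[:, None, None, :]  # (B, 1, 1, L) exclude pad keys
        attentions: list[np.ndarray] = []
        for i in range(cfg.n_layers):
            q = (x @ p[f"l{i}.q_w"]) + p[f"l{i}.q_b"]
            k = (x @ p[f"l{i}.k_w"]) + p[f"l{i}.k_b"]
            v = (x @ p[f"l{i}.v_w"]) + p[f"l{i}.v_b"]
            q = q.reshape(B, L, h, dh).transpose(0, 2, 1, 3)
            k = k.reshape(B, L, h, dh).transpose(0, 2, 1, 3)
            v = v.reshape(B, L, h, dh).transpose(0, 2, 1, 3)
            scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dh))
            attn = softmax(scores, mask=np.broadcast_to(key_mask, scores.shape))
            if collect_attention:
                attentions.append(attn.data.copy())
            ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, L, cfg.hidden_size)
            ctx = (ctx @ p[f"l{i}.o_w"]) + p[f"l{i}.o_b"]
            x = (x + ctx).layer_norm(p[f"l{i}.ln1_g"], p[f"l{i}.ln1_b"])
            f = ((x @ p[f"l{i}.ffn1_w"]) + p[f"l{i}.ffn1_b"]).gelu()
            f = (f @ p[f"l{i}.ffn2_w"]) + p[f"l{i}.ffn2_b"]
            x = (x + f).layer_norm(p[f"l{i}.ln2_g"], p[f"l{i}.ln2_b"])
        return x, attentions

    def mlm_logits(self, hidden: Tensor, flat_positions: np.ndarray) -> Tensor:
        """Vocabulary logits at selected flattened (B*L) positions."""
        B, L, H = hidden.shape
        flat = hidden.reshape(B * L, H)[flat_positions]
        return (flat @ self.params["mlm_w"]) + self.params["mlm_b"]

    def cls_logits(self, hidden: Tensor) -> Tensor:
        head = self.heads["cls"]
        return (hidden[:, 0, :] @ head["w"]) + head["b"]

    def reg_output(self, hidden: Tensor) -> Tensor:
        head = self.heads["reg"]
        return (hidden[:, 0, :] @ head["w"]) + head["b"]
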