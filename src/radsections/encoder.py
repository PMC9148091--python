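"""Size-configurable transformer encoder with MLM pre-training.

The encoder follows the standard bidirectional-transformer recipe: token +
position embeddings, post-layer-norm attention blocks, and a dense+tanh
pooler over the first ([CLS]) token that yields the sentence embedding used
by every downstream classifier. Pre-training is masked language modelling
only (no next-sentence objective), on single sentences at a short sequence
length — breast radiology sentences are short and the relevant signal sits
at the head of each section.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from . import nn
from .corpus import Report
from .wordpiece import TokenSequence, Vocab, encode

MASK_RATE = 0.15  # fraction of content tokens selected for the MLM objective
IGNORE_INDEX = -100


@dataclass
class EncoderConfig:
    layers: int = 2
    hidden_dim: int = 64
    heads: int = 2
    intermediate_dim: int = 128
    max_seq_len: int = 32
    vocab_size: int = 2000
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_dim % self.heads:
            raise ValueError("hidden_dim must be divisible by heads")
        if self.max_seq_len < 2:
            raise ValueError("max_seq_len must be >= 2")


# BERT-base scale, available behind a flag for full-scale runs.
BASE_CONFIG = EncoderConfig(
    layers=12, hidden_dim=768, heads=12, intermediate_dim=3072,
    max_seq_len=32, vocab_size=30522,
)


@dataclass
class MLMBatch:
    """Masked input ids and per-position targets (IGNORE_INDEX = no loss)."""

    input_ids: np.ndarray
    attention_mask: np.ndarray
    targets: np.ndarray


def mask_tokens(
    seq: TokenSequence,
    vocab: Vocab,
    rng: np.random.Generator,
    mask_rate: float = MASK_RATE,
) -> MLMBatch:
    """Apply the 80/10/10 masking policy to one encoded sequence.

    Each non-special position is independently selected with probability
    mask_rate; of selected positions 80% become [MASK], 10% a random
    vocabulary token, 10% stay unchanged. Targets hold the original id at
    selected positions and IGNORE_INDEX elsewhere. A sequence with only
    special tokens yields zero masked positions.
    """
    ids = np.array(seq.ids, dtype=np.int64)
    attn = np.array(seq.attention_mask, dtype=np.int64)
    special = np.isin(ids, list(vocab.special_ids))
    candidates = (~special) & (attn == 1)
    selected = candidates & (rng.random(len(ids)) < mask_rate)

    targets = np.full(len(ids), IGNORE_INDEX, dtype=np.int64)
    targets[selected] = ids[selected]

    out = ids.copy()
    action = rng.random(len(ids))
    to_mask = selected & (action < 0.8)
    to_random = selected & (action >= 0.8) & (action < 0.9)
    out[to_mask] = vocab.mask_id
    n_rand = int(to_random.sum())
    if n_rand:
        out[to_random] = rng.integers(len(vocab.special_ids), len(vocab), n_rand)
    return MLMBatch(out, attn, targets)


class TransformerLayer(nn.Module):
    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        h = cfg.hidden_dim
        self.q = nn.Linear(h, h, rng)
        self.k = nn.Linear(h, h, rng)
        self.v = nn.Linear(h, h, rng)
        self.attn_out = nn.Linear(h, h, rng)
        self.ln1 = nn.LayerNorm(h)
        self.ff1 = nn.Linear(h, cfg.intermediate_dim, rng)
        self.ff2 = nn.Linear(cfg.intermediate_dim, h, rng)
        self.ln2 = nn.LayerNorm(h)
        self.heads = cfg.heads
        self.head_dim = h // cfg.heads

    def __call__(
        self,
        x: nn.Tensor,
        attn_bias: np.ndarray,
        dropout: float,
        rng: Optional[np.random.Generator],
    ) -> nn.Tensor:
        B, T, H = x.shape
        nh, hd = self.heads, self.head_dim

        def split_heads(t: nn.Tensor) -> nn.Tensor:
            return t.reshape(B, T, nh, hd).swapaxes(1, 2)  # (B, nh, T, hd)

        q, k, v = split_heads(self.q(x)), split_heads(self.k(x)), split_heads(self.v(x))
        scores = q @ k.swapaxes(-1, -2) * (1.0 / math.sqrt(hd))
        scores = scores + nn.Tensor(attn_bias)  # -inf-ish at padding keys
        probs = scores.softmax(axis=-1)
        if dropout > 0 and rng is not None:
            probs = probs.dropout(dropout, rng)
        ctx = (probs @ v).swapaxes(1, 2).reshape(B, T, H)
        attn = self.attn_out(ctx)
        if dropout > 0 and rng is not None:
            attn = attn.dropout(dropout, rng)
        x = self.ln1(x + attn)
        ff = self.ff2(self.ff1(x).gelu())
        if dropout > 0 and rng is not None:
            ff = ff.dropout(dropout, rng)
        return self.ln2(x + ff)


class TransformerEncoder(nn.Module):
    """Bidirectional transformer with a first-token dense+tanh pooler."""

    def __init__(self, config: EncoderConfig):
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.token_emb = nn.Tensor(
            rng.normal(0, 0.02, (config.vocab_size, config.hidden_dim)),
            requires_grad=True,
        )
        self.pos_emb = nn.Tensor(
            rng.normal(0, 0.02, (config.max_seq_len, config.hidden_dim)),
            requires_grad=True,
        )
        self.emb_ln = nn.LayerNorm(config.hidden_dim)
        self.blocks = [TransformerLayer(config, rng) for _ in range(config.layers)]
        # MLM-only pre-training never exercises the pooler, so it starts
        # from scratch at fine-tuning time: Glorot keeps its tanh output at
        # unit scale instead of crushing the pooled features
        self.pooler = nn.Linear(config.hidden_dim, config.hidden_dim, rng, init_std=None)
        # MLM head: dense + gelu + layernorm + vocab projection
        self.mlm_dense = nn.Linear(config.hidden_dim, config.hidden_dim, rng)
        self.mlm_ln = nn.LayerNorm(config.hidden_dim)
        self.mlm_out = nn.Linear(config.hidden_dim, config.vocab_size, rng)

    # -- forward passes -------------------------------------------------

    def hidden_states(
        self,
        input_ids: np.ndarray,
        attention_mask: np.ndarray,
        train: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> nn.Tensor:
        input_ids = np.atleast_2d(input_ids)
        attention_mask = np.atleast_2d(attention_mask)
        B, T = input_ids.shape
        if T > self.config.max_seq_len:
            raise ValueError(
                f"sequence length {T} exceeds max_seq_len {self.config.max_seq_len}"
            )
        x = nn.embedding_lookup(self.token_emb, input_ids)
        pos = nn.embedding_lookup(
            self.pos_emb, np.broadcast_to(np.arange(T), (B, T))
        )
        x = self.emb_ln(x + pos)
        dropout = self.config.dropout if train else 0.0
        if dropout > 0 and rng is not None:
            x = x.dropout(dropout, rng)
        # additive attention bias: 0 at real keys, large negative at padding
        bias = np.where(attention_mask[:, None, None, :] == 1, 0.0, -1e9).astype(
            np.float32
        )
        for block in self.blocks:
            x = block(x, bias, dropout, rng)
        return x

    def embed_batch(
        self,
        input_ids: np.ndarray,
        attention_mask: np.ndarray,
        train: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> nn.Tensor:
        """Pooled embeddings (B, hidden): tanh(dense(h[CLS]))."""
        h = self.hidden_states(input_ids, attention_mask, train, rng)
        return self.pooler(h.take_position(0)).tanh()

    def mlm_logits(
        self,
        input_ids: np.ndarray,
        attention_mask: np.ndarray,
        positions: Optional[np.ndarray] = None,
        train: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> nn.Tensor:
        """Vocabulary logits, at `positions` (flat indices into B*T) if given.

        Restricting the vocabulary projection to the masked positions is the
        usual MLM economy: the loss only looks at those rows.
        """
        h = self.hidden_states(input_ids, attention_mask, train, rng)
        B, T, H = h.shape
        flat = h.reshape(B * T, H)
        if positions is not None:
            flat = flat.take_rows(positions)
        h2 = self.mlm_ln(self.mlm_dense(flat).gelu())
        return self.mlm_out(h2)

    # -- persistence ----------------------------------------------------

    def save(self, directory: str | Path, vocab: Optional[Vocab] = None) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        (d / "config.json").write_text(json.dumps(asdict(self.config)))
        np.savez(d / "weights.npz", **self.state_dict())
        if vocab is not None:
            vocab.save(d / "vocab.txt")

    @classmethod
    def load(cls, directory: str | Path) -> "TransformerEncoder":
        d = Path(directory)
        cfg = EncoderConfig(**json.loads((d / "config.json").read_text()))
        enc = cls(cfg)
        with np.load(d / "weights.npz") as z:
            enc.load_state_dict({k: z[k] for k in z.files})
        return enc


class BagOfEmbeddings(nn.Module):
    """Debug backbone: mean of token embeddings through a tanh pooler.

    Satisfies the same embed contract as the transformer (fixed-width
    bounded vector, deterministic, padding-invariant) with no attention, so
    downstream classifiers can be exercised backbone-agnostically.
    """

    def __init__(self, config: EncoderConfig):
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.token_emb = nn.Tensor(
            rng.normal(0, 0.02, (config.vocab_size, config.hidden_dim)),
            requires_grad=True,
        )
        self.pooler = nn.Linear(config.hidden_dim, config.hidden_dim, rng)

    def embed_batch(
        self,
        input_ids: np.ndarray,
        attention_mask: np.ndarray,
        train: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> nn.Tensor:
        input_ids = np.atleast_2d(input_ids)
        attention_mask = np.atleast_2d(attention_mask).astype(np.float32)
        x = nn.embedding_lookup(self.token_emb, input_ids)
        w = attention_mask / attention_mask.sum(axis=1, keepdims=True)
        pooled = (x * nn.Tensor(w[:, :, None])).swapaxes(1, 2) @ nn.Tensor(
            np.ones((input_ids.shape[1], 1), np.float32)
        )
        pooled = pooled.reshape(input_ids.shape[0], self.config.hidden_dim)
        return self.pooler(pooled).tanh()


Backbone = Union[TransformerEncoder, BagOfEmbeddings]


def embed(seq: TokenSequence, encoder: Backbone) -> np.ndarray:
    """Pooled embedding of a single encoded sequence (hidden_dim vector)."""
    ids = np.array([seq.ids])
    mask = np.array([seq.attention_mask])
    with nn.no_grad():
        return encoder.embed_batch(ids, mask).data[0]


def _collect_sentences(corpus: Iterable[Union[Report, str]]) -> list[str]:
    out: list[str] = []
    for item in corpus:
        if isinstance(item, Report):
            out.extend(s.text for s in item.sentences)
        else:
            out.append(item)
    return out


def _mlm_batch_loss(
    encoder: TransformerEncoder,
    batches: list[MLMBatch],
    train: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> nn.Tensor:
    """Cross-entropy over the masked positions of a list of MLM batches."""
    ids = np.stack([b.input_ids for b in batches])
    attn = np.stack([b.attention_mask for b in batches])
    tgt = np.stack([b.targets for b in batches]).reshape(-1)
    positions = np.nonzero(tgt != IGNORE_INDEX)[0]
    if len(positions) == 0:
        return nn.Tensor(0.0)
    logits = encoder.mlm_logits(ids, attn, positions=positions, train=train, rng=rng)
    return nn.cross_entropy(logits, tgt[positions])


def mlm_pretrain(
    corpus: Sequence[Union[Report, str]],
    vocab: Vocab,
    config: EncoderConfig,
    steps: int,
    batch_size: int = 32,
    lr: float = 1e-4,
    seed: int = 0,
    holdout_frac: float = 0.1,
    train_seq_len: int = 32,
) -> tuple[TransformerEncoder, dict]:
    """Pre-train an encoder with masked language modelling only.

    Sentences are the training unit, encoded at train_seq_len (default 32 —
    the short-sequence regime these terse reports allow; config.max_seq_len
    only sizes the position table, which may be longer for downstream
    fine-tuning). A held-out slice (holdout_frac) is excluded from the
    batches and used to report initial/final MLM loss. Returns
    (encoder, history) with "initial_holdout_loss", "final_holdout_loss"
    and per-step "train_loss".
    """
    sentences = _collect_sentences(corpus)
    if not sentences:
        raise ValueError("pre-training corpus is empty")
    if train_seq_len > config.max_seq_len:
        raise ValueError("train_seq_len exceeds config.max_seq_len")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sentences))
    n_hold = max(1, int(holdout_frac * len(sentences))) if len(sentences) > 1 else 0
    hold_idx, train_idx = order[:n_hold], order[n_hold:]
    if len(train_idx) == 0:
        train_idx = order
    encoded = [encode(s, vocab, train_seq_len) for s in sentences]

    encoder = TransformerEncoder(config)
    opt = nn.AdamW(encoder.parameters(), lr=lr, total_steps=steps)

    def holdout_loss(chunk: int = 64) -> float:
        if not len(hold_idx):
            return float("nan")
        h_rng = np.random.default_rng(seed + 1)
        batches = [mask_tokens(encoded[i], vocab, h_rng) for i in hold_idx]
        losses, weights = [], []
        with nn.no_grad():
            for c0 in range(0, len(batches), chunk):
                part = batches[c0 : c0 + chunk]
                n_masked = sum(int((b.targets != IGNORE_INDEX).sum()) for b in part)
                if n_masked == 0:
                    continue
                losses.append(float(_mlm_batch_loss(encoder, part).data))
                weights.append(n_masked)
        return float(np.average(losses, weights=weights)) if losses else float("nan")

    history: dict = {"train_loss": [], "initial_holdout_loss": holdout_loss()}
    for _ in range(steps):
        pick = rng.choice(train_idx, size=min(batch_size, len(train_idx)), replace=False)
        batches = [mask_tokens(encoded[i], vocab, rng) for i in pick]
        encoder.zero_grad()
        loss = _mlm_batch_loss(encoder, batches, train=True, rng=rng)
        loss.backward()
        opt.step()
        history["train_loss"].append(float(loss.data))
    history["final_holdout_loss"] = holdout_loss()
    return encoder, history
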