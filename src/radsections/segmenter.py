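"""Sentence-level BI-RADS section classification.

Each sentence is embedded by the contextual backbone (pooled first-token
vector); optionally an auxiliary global-context vector — previous sentence's
section, sentence ordinal, and report length — is encoded by a small MLP and
concatenated before the softmax head. Inference walks the report in order,
feeding each sentence the *predicted* label of its predecessor; training
uses the gold predecessor (teacher forcing).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import nn
from .corpus import Report, SectionLabel
from .encoder import Backbone
from .wordpiece import Vocab, encode

N_SECTIONS = len(SectionLabel)
START_INDEX = N_SECTIONS  # one-hot slot for "no previous sentence"
AUX_RAW_DIM = N_SECTIONS + 1 + 2  # one-hot(8) + position ratio + length
AUX_ENC_DIM = 128
TOTAL_CAP = 64  # report lengths are squashed to total/64, capped at 1
SEGMENT_SEQ_LEN = 32  # sentence encoding length for segmentation


@dataclass
class AuxFeatures:
    """Global textual features for one sentence.

    prev_label is None for the first sentence of a report (START).
    """

    prev_label: Optional[SectionLabel]
    sentence_number: int
    total_sentences: int

    def __post_init__(self) -> None:
        if self.total_sentences < 1 or not (
            1 <= self.sentence_number <= self.total_sentences
        ):
            raise ValueError("need 1 <= sentence_number <= total_sentences")
        if (self.prev_label is None) != (self.sentence_number == 1):
            raise ValueError("prev_label must be START exactly at sentence 1")


def featurize_aux(aux: AuxFeatures) -> np.ndarray:
    """Raw length-10 feature vector: one-hot(8) ++ [i/N, min(N,64)/64]."""
    v = np.zeros(AUX_RAW_DIM, dtype=np.float32)
    slot = START_INDEX if aux.prev_label is None else int(aux.prev_label)
    v[slot] = 1.0
    v[N_SECTIONS + 1] = aux.sentence_number / aux.total_sentences
    v[N_SECTIONS + 2] = min(aux.total_sentences, TOTAL_CAP) / TOTAL_CAP
    return v


class AuxEncoder(nn.Module):
    """3-layer fully connected encoder, tanh throughout, 128-dim output."""

    def __init__(self, rng: np.random.Generator, widths: tuple[int, int] = (64, 64)):
        w1, w2 = widths
        # Glorot keeps the tanh activations at unit scale from the start —
        # this MLP has no pre-trained weights to inherit
        self.fc1 = nn.Linear(AUX_RAW_DIM, w1, rng, init_std=None)
        self.fc2 = nn.Linear(w1, w2, rng, init_std=None)
        self.fc3 = nn.Linear(w2, AUX_ENC_DIM, rng, init_std=None)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        return self.fc3(self.fc2(self.fc1(x).tanh()).tanh()).tanh()


def encode_aux(aux_raw: np.ndarray, aux_encoder: AuxEncoder) -> np.ndarray:
    """Encode raw aux features to the 128-dim bounded vector."""
    out = aux_encoder(nn.Tensor(np.atleast_2d(aux_raw)))
    return out.data[0] if aux_raw.ndim == 1 else out.data


@dataclass
class SectionPrediction:
    scores: np.ndarray  # softmax probabilities over the 7 sections
    label: SectionLabel


class SectionSegmenter(nn.Module):
    """Backbone + optional aux branch + 7-way softmax head."""

    def __init__(self, backbone: Backbone, use_aux: bool, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.backbone = backbone
        self.use_aux = use_aux
        hidden = backbone.config.hidden_dim
        if use_aux:
            self.aux_encoder = AuxEncoder(rng)
            head_in = hidden + AUX_ENC_DIM
        else:
            head_in = hidden
        # the head is initialized from scratch at fine-tuning time; Glorot
        # gives unit-scale logit gradients from the first step
        self.head = nn.Linear(head_in, N_SECTIONS, rng, init_std=None)

    def logits(
        self,
        input_ids: np.ndarray,
        attention_mask: np.ndarray,
        aux_raw: Optional[np.ndarray],
        train: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> nn.Tensor:
        emb = self.backbone.embed_batch(input_ids, attention_mask, train, rng)
        if self.use_aux:
            if aux_raw is None:
                raise ValueError("aux-enabled segmenter requires aux features")
            aux_vec = self.aux_encoder(nn.Tensor(np.atleast_2d(aux_raw)))
            emb = emb.concat(aux_vec, axis=-1)
        return self.head(emb)


def classify_sentence(
    model: SectionSegmenter,
    input_ids: np.ndarray,
    attention_mask: np.ndarray,
    aux: Optional[AuxFeatures] = None,
) -> SectionPrediction:
    """Score one sentence; softmax probabilities plus argmax label.

    Ties break toward the lowest section index (argmax picks the first).
    """
    aux_raw = (
        featurize_aux(aux)[None, :] if (model.use_aux and aux is not None) else None
    )
    with nn.no_grad():
        logits = model.logits(
            np.atleast_2d(input_ids), np.atleast_2d(attention_mask), aux_raw
        )
        probs = logits.softmax(axis=-1).data[0]
    return SectionPrediction(scores=probs, label=SectionLabel(int(np.argmax(probs))))


def segment_report(
    report: Report, model: SectionSegmenter, vocab: Vocab
) -> list[SectionLabel]:
    """Label every sentence of a report, in order.

    With the aux branch, sentence i > 1 consumes the *predicted* label of
    sentence i-1 (sequential, causal inference); sentence 1 consumes START.
    Without aux, all sentences are scored in one batch.
    """
    if not report.sentences:
        return []
    seqs = [encode(s.text, vocab, SEGMENT_SEQ_LEN) for s in report.sentences]
    ids = np.array([q.ids for q in seqs])
    masks = np.array([q.attention_mask for q in seqs])
    n = len(seqs)
    if not model.use_aux:
        with nn.no_grad():
            logits = model.logits(ids, masks, None).data
        return [SectionLabel(int(np.argmax(row))) for row in logits]
    labels: list[SectionLabel] = []
    prev: Optional[SectionLabel] = None
    for i in range(n):
        aux = AuxFeatures(prev, i + 1, n)
        pred = classify_sentence(model, ids[i], masks[i], aux)
        labels.append(pred.label)
        prev = pred.label
    return labels


@dataclass
class TrainingExample:
    input_ids: np.ndarray
    attention_mask: np.ndarray
    aux_raw: np.ndarray
    label: int


def _collect_examples(reports: Sequence[Report], vocab: Vocab) -> list[TrainingExample]:
    out: list[TrainingExample] = []
    for r in reports:
        n = len(r.sentences)
        prev: Optional[SectionLabel] = None
        for i, s in enumerate(r.sentences):
            if s.section is None:
                raise ValueError(
                    f"unlabeled sentence: report {r.report_id!r} index {s.index}"
                )
            seq = encode(s.text, vocab, SEGMENT_SEQ_LEN)
            aux = featurize_aux(AuxFeatures(prev, i + 1, n))
            out.append(
                TrainingExample(
                    np.array(seq.ids), np.array(seq.attention_mask), aux, int(s.section)
                )
            )
            prev = s.section  # teacher forcing: gold previous label
    return out


def train_segmenter(
    reports: Sequence[Report],
    model: SectionSegmenter,
    vocab: Vocab,
    epochs: int = 4,
    batch_size: int = 32,
    lr: float = 5e-5,
    seed: int = 0,
) -> dict:
    """Fine-tune backbone, aux encoder and head jointly.

    Defaults mirror the report fine-tuning recipe: 4 epochs, batch 32,
    Adam with weight decay at learning rate 5e-5. Deterministic given seed.
    Returns a history dict with per-epoch mean loss.
    """
    examples = _collect_examples(reports, vocab)
    if not examples:
        raise ValueError("no training sentences")
    rng = np.random.default_rng(seed)
    steps_per_epoch = max(1, (len(examples) + batch_size - 1) // batch_size)
    opt = nn.AdamW(model.parameters(), lr=lr, total_steps=epochs * steps_per_epoch)
    history: dict = {"epoch_loss": []}
    for _ in range(epochs):
        order = rng.permutation(len(examples))
        losses = []
        for b0 in range(0, len(order), batch_size):
            batch = [examples[i] for i in order[b0 : b0 + batch_size]]
            ids = np.stack([e.input_ids for e in batch])
            masks = np.stack([e.attention_mask for e in batch])
            aux = np.stack([e.aux_raw for e in batch]) if model.use_aux else None
            y = np.array([e.label for e in batch])
            model.zero_grad()
            logits = model.logits(ids, masks, aux, train=True, rng=rng)
            loss = nn.cross_entropy(logits, y)
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history["epoch_loss"].append(float(np.mean(losses)))
    return history
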