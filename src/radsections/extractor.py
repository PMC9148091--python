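"""Report-level field extraction, whole-document or section-routed.

Six independent classifiers extract modality/procedure, previous cancer,
menopausal status, exam purpose, breast density and BPE. In section-routed
mode the segmenter's output narrows the input to the section that carries
the field, with a per-task sequence-length policy; a report lacking the
routed section falls back to the task's "not stated" label without invoking
the classifier at all.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import nn
from .corpus import (
    FIELD_TASKS,
    Report,
    SectionLabel,
    Sentence,
    fallback_label,
    field_labels,
)
from .encoder import Backbone
from .segmenter import SectionSegmenter, segment_report
from .wordpiece import Vocab, encode

# task -> (section that carries the field, fine-tuning sequence length).
# Modality reads the whole title (long titles enumerate every modality);
# menopausal status sits at the *end* of the history so it needs the longer
# window; the remaining fields surface near the head of their section.
ROUTING_TABLE: dict[str, tuple[SectionLabel, int]] = {
    "MODALITY": (SectionLabel.TITLE, 128),
    "PREVIOUS_CANCER": (SectionLabel.HISTORY_CLIND, 32),
    "MENOPAUSAL_STATUS": (SectionLabel.HISTORY_CLIND, 128),
    "PURPOSE": (SectionLabel.HISTORY_CLIND, 32),
    "DENSITY": (SectionLabel.FINDINGS, 32),
    "BPE": (SectionLabel.FINDINGS, 32),
}

WHOLE_DOC_SEQ_LEN = 128  # default head-truncation for no-segmentation mode


def task_route(task: str) -> tuple[SectionLabel, int]:
    try:
        return ROUTING_TABLE[task]
    except KeyError:
        raise KeyError(f"unknown field task {task!r}; known: {FIELD_TASKS}")


@dataclass
class FieldPrediction:
    task: str
    label: str
    scores: Optional[np.ndarray] = None  # per-class softmax, schema order


def route_section(report: Report, task: str) -> Optional[str]:
    """Concatenated text of the task's section, or None if absent.

    Uses whatever section labels the sentences carry (gold during training,
    predicted at inference).
    """
    section, _ = task_route(task)
    texts = [s.text for s in report.sentences if s.section == section]
    return " ".join(texts) if texts else None


class FieldExtractor(nn.Module):
    """Backbone + softmax head over one task's closed label set."""

    def __init__(self, backbone: Backbone, task: str, seq_len: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.backbone = backbone
        self.task = task
        self.labels = field_labels(task)
        self.seq_len = seq_len
        self.head = nn.Linear(
            backbone.config.hidden_dim, len(self.labels), rng, init_std=None
        )

    def logits(
        self,
        input_ids: np.ndarray,
        attention_mask: np.ndarray,
        train: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> nn.Tensor:
        emb = self.backbone.embed_batch(input_ids, attention_mask, train, rng)
        return self.head(emb)


def extract_field(text: str, task: str, model: FieldExtractor, vocab: Vocab) -> FieldPrediction:
    """Classify a piece of text into the task's closed label set."""
    if model.task != task:
        raise ValueError(f"model is trained for {model.task!r}, not {task!r}")
    seq = encode(text, vocab, model.seq_len)
    with nn.no_grad():
        logits = model.logits(
            np.array([seq.ids]), np.array([seq.attention_mask])
        )
        probs = logits.softmax(axis=-1).data[0]
    return FieldPrediction(task, model.labels[int(np.argmax(probs))], probs)


def extract_with_segmentation(
    report: Report,
    task: str,
    segmenter: SectionSegmenter,
    extractor: FieldExtractor,
    vocab: Vocab,
    use_gold_sections: bool = False,
) -> FieldPrediction:
    """Segment (or reuse gold sections), route, then classify.

    A report lacking the routed section gets the task's fallback label
    ("NotStated", or "No" for previous cancer) independent of model state.
    Modality has no absence class — every report opens with a title — so if
    the segmenter labels no sentence TITLE the first sentence stands in.
    """
    if use_gold_sections:
        routed = route_section(report, task)
    else:
        labels = segment_report(report, segmenter, vocab)
        relabeled = Report(
            report_id=report.report_id,
            raw_text=report.raw_text,
            sentences=[
                Sentence(text=s.text, index=s.index, section=lab)
                for s, lab in zip(report.sentences, labels)
            ],
        )
        routed = route_section(relabeled, task)
    if routed is None:
        if task == "MODALITY" and report.sentences:
            routed = report.sentences[0].text
        else:
            return FieldPrediction(task, fallback_label(task), None)
    return extract_field(routed, task, extractor, vocab)


def extract_without_segmentation(
    report: Report, task: str, extractor: FieldExtractor, vocab: Vocab
) -> FieldPrediction:
    """Classify the whole document, head-truncated to the model's length."""
    return extract_field(_document_text(report), task, extractor, vocab)


def _document_text(report: Report) -> str:
    if report.sentences:
        return " ".join(s.text for s in report.sentences)
    return report.raw_text


@dataclass
class ExtractorHistory:
    epoch_loss: list[float]
    n_train: int
    n_dropped: int


def train_extractor(
    reports: Sequence[Report],
    task: str,
    mode: str,
    backbone: Backbone,
    vocab: Vocab,
    epochs: int = 4,
    batch_size: int = 32,
    lr: float = 5e-5,
    seed: int = 0,
) -> tuple[FieldExtractor, ExtractorHistory]:
    """Train one task's classifier.

    mode "with": inputs are the gold-routed section texts; reports lacking
    the routed section are dropped from training. mode "without": inputs
    are whole documents at WHOLE_DOC_SEQ_LEN. The class list is frozen from
    the schema, never from observed labels; a gold label outside the schema
    raises.
    """
    if mode not in ("with", "without"):
        raise ValueError("mode must be 'with' or 'without'")
    section, seq_len = task_route(task)
    if mode == "without":
        seq_len = WHOLE_DOC_SEQ_LEN
    labels = field_labels(task)
    label_index = {lab: i for i, lab in enumerate(labels)}

    texts: list[str] = []
    ys: list[int] = []
    dropped = 0
    for r in reports:
        if r.fields is None or task not in r.fields:
            raise ValueError(f"report {r.report_id!r} lacks a gold label for {task}")
        gold = r.fields[task]
        if gold not in label_index:
            raise ValueError(
                f"report {r.report_id!r}: label {gold!r} outside the {task} schema"
            )
        if mode == "with":
            routed = route_section(r, task)
            if routed is None:
                dropped += 1
                continue
            texts.append(routed)
        else:
            texts.append(_document_text(r))
        ys.append(label_index[gold])
    if not texts:
        raise ValueError(f"no usable training reports for {task} in mode {mode!r}")

    model = FieldExtractor(backbone, task, seq_len, seed=seed)
    encoded = [encode(t, vocab, seq_len) for t in texts]
    ids_all = np.array([q.ids for q in encoded])
    masks_all = np.array([q.attention_mask for q in encoded])
    y_all = np.array(ys)

    rng = np.random.default_rng(seed)
    steps_per_epoch = max(1, (len(texts) + batch_size - 1) // batch_size)
    opt = nn.AdamW(model.parameters(), lr=lr, total_steps=epochs * steps_per_epoch)
    history = ExtractorHistory(epoch_loss=[], n_train=len(texts), n_dropped=dropped)
    for _ in range(epochs):
        order = rng.permutation(len(texts))
        losses = []
        for b0 in range(0, len(order), batch_size):
            sel = order[b0 : b0 + batch_size]
            model.zero_grad()
            logits = model.logits(ids_all[sel], masks_all[sel], train=True, rng=rng)
            loss = nn.cross_entropy(logits, y_all[sel])
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.epoch_loss.append(float(np.mean(losses)))
    return model, history
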