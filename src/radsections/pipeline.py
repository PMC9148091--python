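"""End-to-end experiment orchestration at desk scale.

Glues the pipeline stages together: tokenizer training, MLM pre-training,
section segmentation with and without auxiliary features, section-routed
and whole-document field extraction, imbalance-weighted evaluation and the
model-comparison statistics. The experiment sizes here (a few hundred
synthetic reports, a 2-layer 64-dim encoder, 300 MLM steps) are chosen so a
full study runs on one CPU in minutes; the library accepts full-scale
configurations through the same entry points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .corpus import Report, SectionLabel, Sentence, field_labels
from .encoder import EncoderConfig, TransformerEncoder, mlm_pretrain
from .extractor import (
    FieldExtractor,
    extract_with_segmentation,
    extract_without_segmentation,
    train_extractor,
)
from .metrics import (
    ConfusionMatrix,
    ReportMetrics,
    accuracy,
    per_report_metrics,
    stratified_kfold,
)
from .segmenter import SectionSegmenter, segment_report, train_segmenter
from .synthetic import AmbiguousSuite, GoldRecord
from .wordpiece import Vocab, train_wordpiece

# Desk-scale extractor fine-tuning: the 64-dim encoder is pre-trained for a
# few hundred MLM steps only and each extractor sees just a few hundred
# routed texts, so the heads need a larger step budget than a fully
# pre-trained base model would; see docs/methods.md.
DESK_EXTRACTOR_HYPER = {"epochs": 16, "batch_size": 32, "lr": 1e-3}

# Segmenter fine-tuning keeps the reference recipe.
SEGMENTER_HYPER = {"epochs": 4, "batch_size": 32, "lr": 5e-5}

TINY_ENCODER = EncoderConfig(
    layers=2, hidden_dim=64, heads=2, intermediate_dim=128,
    max_seq_len=128, vocab_size=0,  # vocab_size filled after tokenizer training
)


def clone_backbone(encoder: TransformerEncoder) -> TransformerEncoder:
    """Independent copy so each fine-tuned model owns its weights."""
    fresh = TransformerEncoder(encoder.config)
    fresh.load_state_dict(encoder.state_dict())
    return fresh


@dataclass
class PretrainedStack:
    vocab: Vocab
    encoder: TransformerEncoder
    history: dict


def prepare_backbone(
    train_reports: Sequence[Report],
    vocab_size: int = 2000,
    config: Optional[EncoderConfig] = None,
    mlm_steps: int = 300,
    mlm_batch_size: int = 32,
    mlm_lr: float = 1e-4,
    seed: int = 0,
) -> PretrainedStack:
    """Train the WordPiece vocabulary and MLM-pre-train the encoder."""
    sentences = [s.text for r in train_reports for s in r.sentences]
    vocab = train_wordpiece(sentences, vocab_size, seed=seed)
    cfg = config or TINY_ENCODER
    cfg = EncoderConfig(
        layers=cfg.layers, hidden_dim=cfg.hidden_dim, heads=cfg.heads,
        intermediate_dim=cfg.intermediate_dim, max_seq_len=cfg.max_seq_len,
        vocab_size=len(vocab), dropout=cfg.dropout, seed=seed,
    )
    encoder, history = mlm_pretrain(
        list(train_reports), vocab, cfg, steps=mlm_steps,
        batch_size=mlm_batch_size, lr=mlm_lr, seed=seed,
    )
    return PretrainedStack(vocab, encoder, history)


def split_fold(
    records: Sequence[GoldRecord], k: int = 5, fold: int = 0, seed: int = 0
) -> tuple[list[GoldRecord], list[GoldRecord]]:
    """Hold out one fold of a modality-stratified k-fold plan."""
    ids = [rec.report.report_id for rec in records]
    strata = [rec.report.modality for rec in records]
    plan = stratified_kfold(ids, strata, k=k, seed=seed)
    train_ids, test_ids = plan.split(fold)
    by_id = {rec.report.report_id: rec for rec in records}
    return [by_id[i] for i in train_ids], [by_id[i] for i in test_ids]


# ---------------------------------------------------------------------------
# Section segmentation experiment
# ---------------------------------------------------------------------------


@dataclass
class SegmentationResult:
    metrics: ReportMetrics
    gold: list[list[SectionLabel]]
    predicted: list[list[SectionLabel]]
    report_ids: list[str]


def apply_predicted_sections(
    reports: Sequence[Report], model: SectionSegmenter, vocab: Vocab
) -> list[Report]:
    """Copies of the reports with section slots replaced by predictions.

    Lets a batch of downstream tasks share one segmentation pass instead of
    re-decoding the same report per task.
    """
    out = []
    for r in reports:
        labels = segment_report(r, model, vocab)
        out.append(
            Report(
                report_id=r.report_id,
                raw_text=r.raw_text,
                sentences=[
                    Sentence(text=s.text, index=s.index, section=lab)
                    for s, lab in zip(r.sentences, labels)
                ],
                fields=dict(r.fields) if r.fields else None,
                modality=r.modality,
            )
        )
    return out


def evaluate_segmenter(
    model: SectionSegmenter, vocab: Vocab, reports: Sequence[Report]
) -> SegmentationResult:
    gold, pred, ids = [], [], []
    for r in reports:
        gold.append([s.section for s in r.sentences])
        pred.append(segment_report(r, model, vocab))
        ids.append(r.report_id)
    metrics = per_report_metrics(gold, pred, list(SectionLabel), ids)
    return SegmentationResult(metrics, gold, pred, ids)


def run_segmentation_experiment(
    train_reports: Sequence[Report],
    test_reports: Sequence[Report],
    stack: PretrainedStack,
    use_aux: bool,
    seed: int = 0,
    hyper: Optional[dict] = None,
) -> tuple[SectionSegmenter, SegmentationResult]:
    hyper = dict(SEGMENTER_HYPER, **(hyper or {}))
    model = SectionSegmenter(clone_backbone(stack.encoder), use_aux=use_aux, seed=seed)
    train_segmenter(train_reports, model, stack.vocab, seed=seed, **hyper)
    return model, evaluate_segmenter(model, stack.vocab, test_reports)


# ---------------------------------------------------------------------------
# Field extraction experiments
# ---------------------------------------------------------------------------


@dataclass
class FieldResult:
    task: str
    mode: str  # "with_gold", "with_predicted", or "without"
    acc: float
    gold: list[str]
    predicted: list[str]
    n_train: int
    n_dropped: int


def run_field_experiment(
    train_reports: Sequence[Report],
    test_reports: Sequence[Report],
    stack: PretrainedStack,
    task: str,
    mode: str,
    segmenter: Optional[SectionSegmenter] = None,
    seed: int = 0,
    hyper: Optional[dict] = None,
) -> tuple[FieldExtractor, FieldResult]:
    """Train and evaluate one task in one mode.

    mode "without": whole-document training and inference.
    mode "with_gold": gold-section routing at train and test time.
    mode "with_predicted": gold routing at train time, the segmenter's
    predicted sections at test time (the deployed pipeline).
    """
    hyper = dict(DESK_EXTRACTOR_HYPER, **(hyper or {}))
    train_mode = "without" if mode == "without" else "with"
    extractor, history = train_extractor(
        train_reports, task, train_mode, clone_backbone(stack.encoder),
        stack.vocab, seed=seed, **hyper,
    )
    gold, pred = [], []
    for r in test_reports:
        gold.append(r.fields[task])
        if mode == "without":
            p = extract_without_segmentation(r, task, extractor, stack.vocab)
        elif mode == "with_gold":
            p = extract_with_segmentation(
                r, task, None, extractor, stack.vocab, use_gold_sections=True
            )
        elif mode == "with_predicted":
            if segmenter is None:
                raise ValueError("mode 'with_predicted' needs a trained segmenter")
            p = extract_with_segmentation(r, task, segmenter, extractor, stack.vocab)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        pred.append(p.label)
    cm = ConfusionMatrix.from_labels(gold, pred, field_labels(task))
    return extractor, FieldResult(
        task, mode, accuracy(cm), gold, pred, history.n_train, history.n_dropped
    )


# ---------------------------------------------------------------------------
# Ambiguous-suite evaluation
# ---------------------------------------------------------------------------


def ambiguous_sentence_accuracy(
    suite: AmbiguousSuite, result: SegmentationResult
) -> float:
    """Accuracy restricted to the suite's ambiguous sentences."""
    by_id = {rid: (g, p) for rid, g, p in zip(result.report_ids, result.gold, result.predicted)}
    correct = total = 0
    for rec in suite.records:
        rid = rec.report.report_id
        if rid not in by_id:
            continue
        gold, pred = by_id[rid]
        amb = {(text, sec) for text, sec in rec.ambiguous}
        for s, g, p in zip(rec.report.sentences, gold, pred):
            if (s.text, g) in amb:
                total += 1
                correct += int(g == p)
    return correct / total if total else float("nan")
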