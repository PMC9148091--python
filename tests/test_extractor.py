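"""Routing table, fallback rule, training drops, truncation invariance."""

import numpy as np
import pytest

from radsections.corpus import (
    FIELD_TASKS,
    NOT_STATED,
    Report,
    SectionLabel,
    Sentence,
    field_labels,
)
from radsections.encoder import BagOfEmbeddings, EncoderConfig
from radsections.extractor import (
    ROUTING_TABLE,
    FieldExtractor,
    extract_field,
    extract_with_segmentation,
    extract_without_segmentation,
    route_section,
    task_route,
    train_extractor,
)
from radsections.synthetic import GeneratorConfig, generate_corpus

S = SectionLabel


@pytest.fixture(scope="module")
def corpus():
    return generate_corpus(GeneratorConfig(n_reports=60, seed=31))


@pytest.fixture(scope="module")
def vocab(corpus):
    from radsections.wordpiece import train_wordpiece

    return train_wordpiece(
        [s.text for rec in corpus for s in rec.report.sentences], 1000, seed=31
    )


@pytest.fixture(scope="module")
def backbone(vocab):
    cfg = EncoderConfig(
        layers=1, hidden_dim=32, heads=1, intermediate_dim=64,
        max_seq_len=128, vocab_size=len(vocab), seed=17,
    )
    return BagOfEmbeddings(cfg)


class TestRouting:
    def test_table_is_total_over_tasks(self):
        assert set(ROUTING_TABLE) == set(FIELD_TASKS)
        for task, (section, seq_len) in ROUTING_TABLE.items():
            assert isinstance(section, S)
            assert seq_len in (32, 128)

    def test_sequence_length_policy(self):
        assert task_route("MODALITY") == (S.TITLE, 128)
        assert task_route("MENOPAUSAL_STATUS") == (S.HISTORY_CLIND, 128)
        for task in ("PREVIOUS_CANCER", "PURPOSE", "DENSITY", "BPE"):
            assert task_route(task)[1] == 32

    def test_unknown_task_rejected(self):
        with pytest.raises(KeyError):
            task_route("LATERALITY")

    def test_modality_always_routable(self, corpus):
        for rec in corpus:
            assert route_section(rec.report, "MODALITY") is not None

    def test_missing_history_routes_absent(self):
        r = Report(
            "r1",
            sentences=[
                Sentence("MAMMOGRAM.", 1, S.TITLE),
                Sentence("FINDINGS:", 2, S.FINDINGS),
            ],
        )
        assert route_section(r, "PREVIOUS_CANCER") is None

    def test_routed_text_matches_generator_spans(self, corpus):
        for rec in corpus:
            for task in FIELD_TASKS:
                section, _ = task_route(task)
                routed = route_section(rec.report, task)
                expected = rec.section_texts.get(section)
                assert routed == expected


class TestFallback:
    def test_missing_section_yields_not_stated_without_model(self, vocab):
        r = Report(
            "r2",
            sentences=[Sentence("MRI BREAST.", 1, S.TITLE)],
            fields={t: NOT_STATED for t in FIELD_TASKS},
        )
        # neither segmenter nor extractor is consulted: pass None for both
        pred = extract_with_segmentation(
            r, "BPE", None, None, vocab, use_gold_sections=True
        )
        assert pred.label == NOT_STATED
        assert pred.scores is None
        pred = extract_with_segmentation(
            r, "PREVIOUS_CANCER", None, None, vocab, use_gold_sections=True
        )
        assert pred.label == "No"

    def test_full_report_equals_direct_extraction(self, corpus, vocab, backbone):
        model = FieldExtractor(backbone, "DENSITY", seq_len=32, seed=0)
        rec = next(
            r for r in corpus
            if any(s.section is S.FINDINGS for s in r.report.sentences)
        )
        via_pipeline = extract_with_segmentation(
            rec.report, "DENSITY", None, model, vocab, use_gold_sections=True
        )
        direct = extract_field(
            route_section(rec.report, "DENSITY"), "DENSITY", model, vocab
        )
        assert via_pipeline.label == direct.label


class TestExtraction:
    def test_label_always_in_schema(self, corpus, vocab, backbone):
        model = FieldExtractor(backbone, "BPE", seq_len=32, seed=1)
        for rec in corpus[:10]:
            pred = extract_without_segmentation(rec.report, "BPE", model, vocab)
            assert pred.label in field_labels("BPE")

    def test_task_mismatch_rejected(self, vocab, backbone):
        model = FieldExtractor(backbone, "BPE", seq_len=32, seed=1)
        with pytest.raises(ValueError, match="BPE"):
            extract_field("text", "DENSITY", model, vocab)

    def test_one_sentence_report_matches_extract_field(self, vocab, backbone):
        model = FieldExtractor(backbone, "PURPOSE", seq_len=128, seed=2)
        r = Report("r3", sentences=[Sentence("Routine screening examination.", 1)])
        a = extract_without_segmentation(r, "PURPOSE", model, vocab)
        b = extract_field("Routine screening examination.", "PURPOSE", model, vocab)
        assert a.label == b.label
        assert np.allclose(a.scores, b.scores)

    def test_truncation_invariance_for_short_documents(self, corpus, vocab, backbone):
        short = min(corpus, key=lambda rec: len(rec.report.sentences)).report
        m128 = FieldExtractor(backbone, "DENSITY", seq_len=128, seed=3)
        m512cfg = EncoderConfig(
            layers=1, hidden_dim=32, heads=1, intermediate_dim=64,
            max_seq_len=512, vocab_size=len(vocab), seed=17,
        )
        m512 = FieldExtractor(BagOfEmbeddings(m512cfg), "DENSITY", seq_len=512, seed=3)
        a = extract_without_segmentation(short, "DENSITY", m128, vocab)
        b = extract_without_segmentation(short, "DENSITY", m512, vocab)
        assert a.label == b.label


class TestTraining:
    def test_no_drops_when_section_always_present(self, corpus, vocab, backbone):
        _, hist = train_extractor(
            [rec.report for rec in corpus], "MODALITY", "with",
            backbone, vocab, epochs=1,
        )
        assert hist.n_dropped == 0
        assert hist.n_train == len(corpus)

    def test_drop_count_matches_generator_bookkeeping(self, corpus, vocab, backbone):
        reports = [rec.report for rec in corpus]
        lacking = sum(
            1 for r in reports
            if all(s.section is not S.HISTORY_CLIND for s in r.sentences)
        )
        _, hist = train_extractor(
            reports, "PURPOSE", "with", backbone, vocab, epochs=1
        )
        assert hist.n_dropped == lacking
        assert hist.n_train == len(reports) - lacking

    def test_label_outside_schema_rejected(self, vocab, backbone):
        r = Report(
            "bad",
            sentences=[Sentence("MAMMOGRAM.", 1, S.TITLE)],
            fields={"MODALITY": "PETSCAN"},
        )
        with pytest.raises(ValueError, match="PETSCAN"):
            train_extractor([r], "MODALITY", "with", backbone, vocab, epochs=1)

    def test_seed_determinism(self, corpus, vocab):
        reports = [rec.report for rec in corpus[:20]]

        def run():
            cfg = EncoderConfig(
                layers=1, hidden_dim=32, heads=1, intermediate_dim=64,
                max_seq_len=128, vocab_size=len(vocab), seed=8,
            )
            model, hist = train_extractor(
                reports, "BPE", "with", BagOfEmbeddings(cfg), vocab,
                epochs=2, lr=1e-3, seed=8,
            )
            return [
                extract_with_segmentation(
                    r, "BPE", None, model, vocab, use_gold_sections=True
                ).label
                for r in reports
            ], hist.epoch_loss

        (p1, l1), (p2, l2) = run(), run()
        assert p1 == p2
        assert l1 == l2

    def test_edits_outside_routed_section_never_change_prediction(
        self, corpus, vocab, backbone
    ):
        model = FieldExtractor(backbone, "DENSITY", seq_len=32, seed=4)
        rec = next(
            r for r in corpus
            if any(s.section is S.FINDINGS for s in r.report.sentences)
        )
        base = extract_with_segmentation(
            rec.report, "DENSITY", None, model, vocab, use_gold_sections=True
        )
        edited_sentences = [
            Sentence(
                "COMPLETELY DIFFERENT TEXT." if s.section is not S.FINDINGS else s.text,
                s.index,
                s.section,
            )
            for s in rec.report.sentences
        ]
        edited = Report("edited", sentences=edited_sentences)
        assert (
            extract_with_segmentation(
                edited, "DENSITY", None, model, vocab, use_gold_sections=True
            ).label
            == base.label
        )
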