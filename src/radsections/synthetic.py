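"""Deterministic generator of BI-RADS-structured synthetic breast reports.

Every report carries gold per-sentence section labels and gold report-level
field labels, so the whole pipeline — tokenizer training, MLM pre-training,
section segmentation and field extraction — is trainable and testable with
no data download. The generator emulates the salient features of real
breast radiology reports:

* seven lexicon sections emitted in canonical order, with per-section
  omission probabilities (the title is never omitted);
* radiologist short-form style: terse header lines ("FINDINGS:"),
  unterminated title lines, acronyms;
* field mentions planted in their characteristic sections — modality in the
  title, purpose and previous cancer near the head of the history,
  menopausal status at the *end* of the history, density and BPE in the
  findings;
* strong label imbalance: each task's prior puts 0.7-0.9 of its mass on a
  dominant class;
* optional section-ambiguous sentences (same string legal in two sections)
  and distractor field phrases planted in non-host sections.

It does not attempt realistic clinical language modelling; see the methods
note for what that implies about test conclusions.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np

from .corpus import (
    FIELD_TASKS,
    NOT_STATED,
    Report,
    SectionLabel,
    fallback_label,
    normalize_text,
    segment_sentences,
)

S = SectionLabel

# ---------------------------------------------------------------------------
# Phrase banks
# ---------------------------------------------------------------------------

MODALITY_TITLES = {
    "MG": ["BILATERAL MAMMOGRAM", "SCREENING MAMMOGRAM", "DIGITAL MAMMOGRAPHY BOTH BREASTS"],
    "MRI": ["MRI BREAST WITH AND WITHOUT CONTRAST", "BILATERAL BREAST MRI"],
    "US": ["BREAST ULTRASOUND", "TARGETED ULTRASOUND LEFT BREAST"],
    "biopsy": ["ULTRASOUND GUIDED CORE BIOPSY", "STEREOTACTIC CORE BIOPSY"],
}

PURPOSE_PHRASES = {
    "Screening": [
        "Routine screening examination.",
        "Annual screening study requested.",
        "High risk screening exam.",
    ],
    "Diagnostic": [
        "Diagnostic workup of a palpable abnormality.",
        "Diagnostic evaluation of focal pain.",
        "Further diagnostic assessment of a recalled finding.",
    ],
}

PREVIOUS_CANCER_PHRASES = {
    "Yes": [
        "History of left breast invasive ductal carcinoma.",
        "Prior right breast cancer treated with lumpectomy and radiation.",
        "Known history of breast malignancy.",
    ],
    "No": [
        "No personal history of breast cancer.",
        "No prior breast malignancy.",
    ],
    "Suspicious": [
        "Prior lumpectomy, pathology not specified.",
        "Previous breast surgery of uncertain nature.",
        "History of treatment to the right breast, details not stated.",
    ],
}

MENOPAUSE_PHRASES = {
    "Pre": ["The patient is premenopausal.", "Premenopausal woman."],
    "Post": ["The patient is postmenopausal.", "Postmenopausal woman."],
}

DENSITY_PHRASES = {
    "fatty": ["The breasts are almost entirely fatty."],
    "scattered": [
        "There are scattered areas of fibroglandular density.",
        "Scattered fibroglandular densities are present.",
    ],
    "heterogeneously dense": [
        "The breast tissue is heterogeneously dense, which may obscure small masses.",
        "The breasts are heterogeneously dense.",
    ],
    "≤75% of breast volume": [
        "Fibroglandular tissue occupies ≤75% of the breast volume.",
    ],
    "dense": [
        "The breasts are extremely dense, lowering the sensitivity of mammography.",
        "The breast tissue is dense.",
    ],
}

BPE_PHRASES = {
    "minimal": ["There is minimal background parenchymal enhancement."],
    "mild": [
        "There is mild background parenchymal enhancement.",
        "Mild background parenchymal enhancement is noted.",
    ],
    "moderate": ["There is moderate background parenchymal enhancement."],
    "marked": ["There is marked background parenchymal enhancement."],
}

FIELD_PHRASES: dict[str, dict[str, list[str]]] = {
    "PURPOSE": PURPOSE_PHRASES,
    "PREVIOUS_CANCER": PREVIOUS_CANCER_PHRASES,
    "MENOPAUSAL_STATUS": MENOPAUSE_PHRASES,
    "DENSITY": DENSITY_PHRASES,
    "BPE": BPE_PHRASES,
}

SECTION_HEADERS = {
    S.HISTORY_CLIND: ["CLINICAL INDICATION:", "HISTORY:"],
    S.PREVIOUS_IMAGING: ["COMPARISON:"],
    S.TECHNIQUE_PROCEDURE: ["TECHNIQUE:", "PROCEDURE:"],
    S.FINDINGS: ["FINDINGS:"],
    S.IMPRESSION_OPINION: ["IMPRESSION:", "OPINION:"],
}

SECTION_FILLERS = {
    S.HISTORY_CLIND: [
        "Family history of breast cancer in a first degree relative.",
        "Patient reports no new breast symptoms.",
        "Referred by the high risk clinic.",
    ],
    S.PREVIOUS_IMAGING: [
        "Comparison is made with the prior examination.",
        "Prior imaging from an outside facility was reviewed.",
        "No previous examinations are available for comparison.",
    ],
    S.TECHNIQUE_PROCEDURE: [
        "Standard CC and MLO views of both breasts were obtained.",
        "Axial T1 and T2 weighted sequences were acquired before and after contrast.",
        "Targeted grayscale and Doppler images were obtained.",
        "The procedure was performed under sterile technique with local anesthesia.",
    ],
    S.FINDINGS: [
        "No suspicious mass, architectural distortion or suspicious calcifications.",
        "There is no abnormal enhancement.",
        "A benign appearing lymph node is noted in the left axilla.",
        "Stable benign calcifications are again demonstrated.",
        "No sonographic abnormality in the area of concern.",
    ],
    S.IMPRESSION_OPINION: [
        "No mammographic evidence of malignancy.",
        "Benign findings.",
        "No suspicious enhancement identified.",
        "Recommend continued routine screening.",
        "Short interval follow up is recommended.",
    ],
    S.ASSESSMENT_CATEGORY: [
        "BI-RADS 1, negative.",
        "BI-RADS 2, benign findings.",
        "BI-RADS 0, additional imaging required.",
        "BI-RADS 3, probably benign.",
        "BI-RADS 4, suspicious abnormality.",
    ],
}

# Strings legal in exactly two sections; the second element of each value is
# the probability of hosting the sentence in the FIRST listed section.
AMBIGUOUS_POOL: dict[str, tuple[tuple[SectionLabel, SectionLabel], float]] = {
    "No significant interval change.": ((S.FINDINGS, S.IMPRESSION_OPINION), 0.6),
    "Stable examination.": ((S.FINDINGS, S.IMPRESSION_OPINION), 0.4),
    "Correlation with clinical examination is advised.": (
        (S.IMPRESSION_OPINION, S.FINDINGS),
        0.7,
    ),
    "Previously noted asymmetry is again seen.": (
        (S.FINDINGS, S.PREVIOUS_IMAGING),
        0.6,
    ),
}

# Sections a distractor phrase for a task may be planted in (never the
# task's own host section, and somewhere every report is likely to have).
DISTRACTOR_HOSTS = {
    "PURPOSE": [S.IMPRESSION_OPINION],
    "PREVIOUS_CANCER": [S.IMPRESSION_OPINION, S.FINDINGS],
    "MENOPAUSAL_STATUS": [S.IMPRESSION_OPINION],
    "DENSITY": [S.IMPRESSION_OPINION],
    "BPE": [S.IMPRESSION_OPINION],
}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


def _default_modality_mix() -> dict[str, float]:
    return {
        "MG": 0.40,
        "MRI": 0.25,
        "US": 0.12,
        "biopsy": 0.06,
        "MG+US": 0.08,
        "US+biopsy": 0.04,
        "MG+MRI": 0.03,
        "MG+US+biopsy": 0.02,
    }


def _default_field_priors() -> dict[str, dict[str, float]]:
    # Dominant-class mass 0.7-0.9 per task: the imbalance regime in which
    # G.F1 and accuracy diverge on these reports.
    return {
        "PREVIOUS_CANCER": {"No": 0.75, "Yes": 0.18, "Suspicious": 0.07},
        "MENOPAUSAL_STATUS": {NOT_STATED: 0.70, "Post": 0.20, "Pre": 0.10},
        "PURPOSE": {"Screening": 0.70, "Diagnostic": 0.24, NOT_STATED: 0.06},
        "DENSITY": {
            "scattered": 0.70,
            "heterogeneously dense": 0.12,
            NOT_STATED: 0.08,
            "fatty": 0.05,
            "dense": 0.03,
            "≤75% of breast volume": 0.02,
        },
        "BPE": {
            NOT_STATED: 0.75,
            "minimal": 0.12,
            "mild": 0.07,
            "moderate": 0.04,
            "marked": 0.02,
        },
    }


def _default_omission_rates() -> dict[SectionLabel, float]:
    # History is the most frequently omitted section (roughly a third of
    # reports lack it); findings are almost always present.
    return {
        S.TITLE: 0.0,
        S.HISTORY_CLIND: 0.30,
        S.PREVIOUS_IMAGING: 0.25,
        S.TECHNIQUE_PROCEDURE: 0.15,
        S.FINDINGS: 0.005,
        S.IMPRESSION_OPINION: 0.05,
        S.ASSESSMENT_CATEGORY: 0.05,
    }


@dataclass
class GeneratorConfig:
    n_reports: int = 100
    seed: int = 0
    modality_mix: dict[str, float] = dc_field(default_factory=_default_modality_mix)
    field_priors: dict[str, dict[str, float]] = dc_field(
        default_factory=_default_field_priors
    )
    section_omission_rates: dict[SectionLabel, float] = dc_field(
        default_factory=_default_omission_rates
    )
    ambiguity_rate: float = 0.05
    distractor_rate: float = 0.10
    header_own_line_rate: float = 0.85
    fillers_per_section: tuple[int, int] = (1, 3)

    def __post_init__(self) -> None:
        for name, dist in [("modality_mix", self.modality_mix)] + [
            (f"field_priors[{t}]", d) for t, d in self.field_priors.items()
        ]:
            total = sum(dist.values())
            if any(p < 0 for p in dist.values()) or abs(total - 1.0) > 1e-6:
                raise ValueError(f"{name} must be a probability distribution")
        for sec, p in self.section_omission_rates.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"omission rate for {sec} outside [0, 1]")
        if self.section_omission_rates.get(S.TITLE, 0.0) != 0.0:
            raise ValueError("the title is never omitted: every report has a title")


@dataclass
class PlantedPhrase:
    task: str
    label: str
    section: SectionLabel
    text: str


@dataclass
class GoldRecord:
    """A generated report plus the generator's bookkeeping."""

    report: Report
    section_texts: dict[SectionLabel, str]
    planted: list[PlantedPhrase]
    distractors: list[PlantedPhrase]
    ambiguous: list[tuple[str, SectionLabel]]


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _pick(rng: np.random.Generator, options: list[str]) -> str:
    return options[int(rng.integers(len(options)))]


def _sample(rng: np.random.Generator, dist: dict[str, float]) -> str:
    keys = list(dist)
    probs = np.array([dist[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=probs / probs.sum()))]


def _title_text(rng: np.random.Generator, modality: str) -> str:
    parts = [_pick(rng, MODALITY_TITLES[atom]) for atom in modality.split("+")]
    return " AND ".join(parts)


def generate_report(config: GeneratorConfig, rng: np.random.Generator, report_id: str) -> GoldRecord:
    present = {
        sec: rng.random() >= config.section_omission_rates.get(sec, 0.0)
        for sec in SectionLabel
    }
    present[S.TITLE] = True

    modality = _sample(rng, config.modality_mix)
    fields: dict[str, str] = {"MODALITY": modality}
    for task, priors in config.field_priors.items():
        fields[task] = _sample(rng, priors)

    # a field whose host section is absent cannot be realized: its gold
    # label collapses to the task's fallback
    host = {
        "PURPOSE": S.HISTORY_CLIND,
        "PREVIOUS_CANCER": S.HISTORY_CLIND,
        "MENOPAUSAL_STATUS": S.HISTORY_CLIND,
        "DENSITY": S.FINDINGS,
        "BPE": S.FINDINGS,
    }
    for task, sec in host.items():
        if not present[sec]:
            fields[task] = fallback_label(task)

    planted: list[PlantedPhrase] = []
    distractors: list[PlantedPhrase] = []
    ambiguous: list[tuple[str, SectionLabel]] = []
    section_sentences: dict[SectionLabel, list[str]] = {}

    def plant(task: str, sec: SectionLabel) -> Optional[str]:
        label = fields[task]
        bank = FIELD_PHRASES[task]
        if label not in bank:  # NotStated (or fallback "No" with no history)
            return None
        text = _pick(rng, bank[label])
        planted.append(PlantedPhrase(task, label, sec, text))
        return text

    for sec in SectionLabel:
        if not present[sec]:
            continue
        sents: list[str] = []
        lo, hi = config.fillers_per_section
        n_fill = int(rng.integers(lo, hi + 1))
        fillers = [
            _pick(rng, SECTION_FILLERS[sec])
            for _ in range(n_fill)
            if sec in SECTION_FILLERS
        ]
        if sec == S.TITLE:
            sents.append(_title_text(rng, modality))
        elif sec == S.HISTORY_CLIND:
            for task in ("PURPOSE", "PREVIOUS_CANCER"):
                p = plant(task, sec)
                if p:
                    sents.append(p)
            sents.extend(fillers)
            p = plant("MENOPAUSAL_STATUS", sec)
            if p:
                sents.append(p)  # menopause goes at the end of the history
        elif sec == S.FINDINGS:
            planted_here = []
            for task in ("DENSITY", "BPE"):
                p = plant(task, sec)
                if p:
                    planted_here.append(p)
            # density/BPE near the head of the findings
            sents.extend(planted_here)
            sents.extend(fillers)
        else:
            sents.extend(fillers if fillers else [_pick(rng, SECTION_FILLERS[sec])])

        if sec in SECTION_HEADERS:
            header = _pick(rng, SECTION_HEADERS[sec])
            if rng.random() < config.header_own_line_rate or not sents:
                sents.insert(0, header)
            else:
                merged = f"{header} {sents[0]}"
                # keep phrase bookkeeping aligned with the final sentence text
                for p in planted:
                    if p.section == sec and p.text == sents[0]:
                        p.text = merged
                sents[0] = merged
        section_sentences[sec] = sents

    # ambiguous sentences: same string legal in two sections
    if config.ambiguity_rate > 0:
        for text, ((sec_a, sec_b), p_first) in AMBIGUOUS_POOL.items():
            if rng.random() < config.ambiguity_rate:
                sec = sec_a if rng.random() < p_first else sec_b
                if present[sec]:
                    section_sentences[sec].append(text)
                    ambiguous.append((text, sec))

    # distractor: a phrase for a *different* label of some task planted in a
    # non-host section, so whole-document classification sees conflicting cues
    if rng.random() < config.distractor_rate:
        task = _pick(rng, sorted(DISTRACTOR_HOSTS))
        bank = FIELD_PHRASES[task]
        wrong = [lab for lab in bank if lab != fields[task]]
        if wrong:
            lab = _pick(rng, wrong)
            sec_options = [s_ for s_ in DISTRACTOR_HOSTS[task] if present[s_]]
            if sec_options:
                sec = sec_options[int(rng.integers(len(sec_options)))]
                text = _pick(rng, bank[lab])
                section_sentences[sec].append(text)
                distractors.append(PlantedPhrase(task, lab, sec, text))

    # assemble: one line per sentence, normalize, re-segment
    lines: list[str] = []
    labels: list[SectionLabel] = []
    for sec in SectionLabel:
        if sec not in section_sentences:
            continue
        for s_text in section_sentences[sec]:
            lines.append(s_text)
            labels.append(sec)
    raw_text = normalize_text("\n".join(lines))
    sentences = segment_sentences(raw_text)
    if len(sentences) != len(labels):
        raise RuntimeError("generator produced text the sentencizer re-splits")
    for s, lab in zip(sentences, labels):
        s.section = lab

    report = Report(
        report_id=report_id,
        raw_text=raw_text,
        sentences=sentences,
        fields=fields,
        modality=modality,
    )
    section_texts = {
        sec: " ".join(
            s.text for s in sentences if s.section == sec
        )
        for sec in section_sentences
    }
    return GoldRecord(report, section_texts, planted, distractors, ambiguous)


def generate_corpus(config: GeneratorConfig) -> list[GoldRecord]:
    """Generate n_reports gold records, deterministically from config.seed."""
    rng = np.random.default_rng(config.seed)
    return [
        generate_report(config, rng, f"R{i:05d}") for i in range(config.n_reports)
    ]


def reports_of(corpus: list[GoldRecord]) -> list[Report]:
    return [rec.report for rec in corpus]


# ---------------------------------------------------------------------------
# Ambiguous-pair stress suite
# ---------------------------------------------------------------------------


@dataclass
class AmbiguousSuite:
    """Corpus whose ambiguous strings bound text-only accuracy below 1.

    ceiling: accuracy of the best constant-per-string classifier on the
    ambiguous sentences (max label frequency per string, averaged over
    occurrences). Any classifier that sees only the sentence text cannot
    beat it on those sentences.
    """

    records: list[GoldRecord]
    string_counts: dict[str, dict[SectionLabel, int]]
    ceiling: float

    @property
    def n_ambiguous(self) -> int:
        return sum(sum(d.values()) for d in self.string_counts.values())


def make_ambiguous_pair_suite(config: GeneratorConfig) -> AmbiguousSuite:
    """Generate a corpus and compute the text-only ceiling on its ambiguous
    sentences. With ambiguity_rate 0 the suite is empty (ceiling 1.0)."""
    records = generate_corpus(config)
    counts: dict[str, dict[SectionLabel, int]] = {}
    for rec in records:
        for text, sec in rec.ambiguous:
            counts.setdefault(text, {}).setdefault(sec, 0)
            counts[text][sec] += 1
    total = sum(sum(d.values()) for d in counts.values())
    best = sum(max(d.values()) for d in counts.values())
    ceiling = best / total if total else 1.0
    return AmbiguousSuite(records, counts, ceiling)


# ---------------------------------------------------------------------------
# Corpus statistics
# ---------------------------------------------------------------------------


def corpus_stats(corpus: list[GoldRecord]) -> dict:
    """Summary: reports per modality, sentences per section, label histograms."""
    if not corpus:
        raise ValueError("corpus is empty")
    per_modality: dict[str, int] = {}
    per_section: dict[str, int] = {s.name: 0 for s in SectionLabel}
    histograms: dict[str, dict[str, int]] = {t: {} for t in FIELD_TASKS}
    for rec in corpus:
        r = rec.report
        per_modality[r.modality] = per_modality.get(r.modality, 0) + 1
        for s in r.sentences:
            per_section[s.section.name] += 1
        for task in FIELD_TASKS:
            lab = r.fields[task]
            histograms[task][lab] = histograms[task].get(lab, 0) + 1
    return {
        "n_reports": len(corpus),
        "reports_per_modality": per_modality,
        "sentences_per_section": per_section,
        "field_label_histograms": histograms,
    }
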