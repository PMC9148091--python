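"""Report data model, text normalization, sentence segmentation and JSONL I/O.

A breast radiology report is modelled as an ordered list of sentences, each
optionally labelled with one of the seven BI-RADS lexicon sections, plus an
optional map of report-level field labels (modality, previous cancer,
menopausal status, purpose, density, BPE).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Optional


class SectionLabel(IntEnum):
    """The seven BI-RADS report sections, in lexicon order.

    The integer values encode the canonical ordering of sections within a
    well-formed report (title first, final assessment category last).
    """

    TITLE = 0
    HISTORY_CLIND = 1
    PREVIOUS_IMAGING = 2
    TECHNIQUE_PROCEDURE = 3
    FINDINGS = 4
    IMPRESSION_OPINION = 5
    ASSESSMENT_CATEGORY = 6


SECTION_NAMES = [s.name for s in SectionLabel]


@dataclass
class Sentence:
    text: str
    index: int  # 1-based ordinal within the report
    section: Optional[SectionLabel] = None

    def __post_init__(self) -> None:
        self.text = self.text.strip()
        if not self.text:
            raise ValueError("Sentence text must be non-empty")
        if self.index < 1:
            raise ValueError("Sentence index is 1-based and must be >= 1")


@dataclass
class Report:
    report_id: str
    raw_text: str = ""
    sentences: list[Sentence] = field(default_factory=list)
    fields: Optional[dict[str, str]] = None
    modality: Optional[str] = None

    def __post_init__(self) -> None:
        for i, s in enumerate(self.sentences, start=1):
            if s.index != i:
                raise ValueError(
                    f"report {self.report_id}: sentence indices must be "
                    f"contiguous 1..N (got {s.index} at position {i})"
                )

    @property
    def section_labels(self) -> list[Optional[SectionLabel]]:
        return [s.section for s in self.sentences]


# ---------------------------------------------------------------------------
# Field label schema
# ---------------------------------------------------------------------------

MODALITY_ATOMS = ["MG", "MRI", "US", "biopsy"]


def canonical_modality(atoms: Iterable[str]) -> str:
    """Canonicalize a combination of up to three modality atoms.

    Atoms are sorted into the fixed order MG, MRI, US, biopsy and joined
    with "+": e.g. {"US", "MG"} -> "MG+US".
    """
    uniq = sorted(set(atoms), key=MODALITY_ATOMS.index)
    if not 1 <= len(uniq) <= 3:
        raise ValueError("modality combinations use 1 to 3 atoms")
    return "+".join(uniq)


def _modality_labels() -> list[str]:
    from itertools import combinations

    labels = []
    for r in (1, 2, 3):
        for combo in combinations(MODALITY_ATOMS, r):
            labels.append("+".join(combo))
    return labels


NOT_STATED = "NotStated"

FIELD_TASKS = [
    "MODALITY",
    "PREVIOUS_CANCER",
    "MENOPAUSAL_STATUS",
    "PURPOSE",
    "DENSITY",
    "BPE",
]

FIELD_LABELS: dict[str, list[str]] = {
    "MODALITY": _modality_labels(),
    "PREVIOUS_CANCER": ["Yes", "No", "Suspicious"],
    "MENOPAUSAL_STATUS": ["Pre", "Post", NOT_STATED],
    "PURPOSE": ["Diagnostic", "Screening", NOT_STATED],
    "DENSITY": [
        "fatty",
        "scattered",
        "heterogeneously dense",
        "≤75% of breast volume",
        "dense",
        NOT_STATED,
    ],
    "BPE": ["minimal", "mild", "moderate", "marked", NOT_STATED],
}


def field_labels(task: str) -> list[str]:
    """Closed label set for a field-extraction task."""
    try:
        return list(FIELD_LABELS[task])
    except KeyError:
        raise KeyError(f"unknown field task {task!r}; known: {FIELD_TASKS}")


def fallback_label(task: str) -> str:
    """Label assigned when the task's host section is absent from a report.

    "NotStated" wherever the task's label set has it; PREVIOUS_CANCER has no
    explicit NotStated class, and absence of any mention maps to "No".
    """
    labels = field_labels(task)
    return NOT_STATED if NOT_STATED in labels else "No"


# ---------------------------------------------------------------------------
# Text normalization
# ---------------------------------------------------------------------------

_TERMINATORS = (".", "!", "?", ":")


def normalize_text(raw: str) -> str:
    """Terminate every non-blank line with punctuation.

    Radiologist short-form lines ("BILATERAL MAMMOGRAM", unterminated
    paragraph ends) get a trailing period; lines already ending in one of
    . ! ? : are left alone. Case, acronyms and in-line punctuation are
    preserved verbatim. Idempotent.
    """
    if not raw:
        return raw
    out_lines = []
    for line in raw.split("\n"):
        stripped = line.rstrip()
        if stripped and not stripped.endswith(_TERMINATORS):
            out_lines.append(stripped + ".")
        else:
            out_lines.append(stripped)
    return "\n".join(out_lines)


# ---------------------------------------------------------------------------
# Sentence segmentation
# ---------------------------------------------------------------------------

# Abbreviations that never terminate a sentence when followed by more text.
PROTECTED_ABBREVIATIONS = frozenset(
    {
        "dr.", "mr.", "mrs.", "ms.", "prof.", "st.",
        "vs.", "no.", "approx.", "e.g.", "i.e.", "etc.",
        "cm.", "mm.", "a.m.", "p.m.",
    }
)

_BOUNDARY = re.compile(r"[.!?]")


def _is_abbreviation(text: str, dot_pos: int) -> bool:
    """True if the period at dot_pos ends a protected abbreviation."""
    start = dot_pos
    while start > 0 and not text[start - 1].isspace():
        start -= 1
    word = text[start : dot_pos + 1].lower()
    return word in PROTECTED_ABBREVIATIONS


def _split_line(line: str) -> list[str]:
    """Split one line into sentences.

    Boundaries: '.', '!' or '?' followed by whitespace + uppercase/digit, or
    at end of line. A colon terminates a sentence only at end of line
    (section headers such as "FINDINGS:"). Decimal numbers ("1.5 cm") and a
    protected abbreviation list ("Dr.", "vs.", ...) are not boundaries.
    """
    sentences: list[str] = []
    start = 0
    for m in _BOUNDARY.finditer(line):
        pos = m.end()  # position just past the punctuation mark
        ch = m.group()
        if ch == ".":
            # decimal number: digit.digit
            i = m.start()
            if 0 < i < len(line) - 1 and line[i - 1].isdigit() and line[i + 1].isdigit():
                continue
            if _is_abbreviation(line, i):
                continue
        # boundary if end of line, or whitespace then uppercase/digit
        rest = line[pos:]
        if rest == "":
            chunk = line[start:pos].strip()
            if chunk:
                sentences.append(chunk)
            start = pos
        else:
            m2 = re.match(r"\s+([A-Z0-9])", rest)
            if m2:
                chunk = line[start:pos].strip()
                if chunk:
                    sentences.append(chunk)
                start = pos
    tail = line[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


def segment_sentences(text: str) -> list[Sentence]:
    """Segment normalized text into ordered, 1-indexed sentences.

    Lines (and hence blank-line paragraph breaks) are never merged across;
    within a line, rule-based boundary detection is applied.
    """
    out: list[Sentence] = []
    idx = 1
    for line in text.split("\n"):
        line = line.strip()
        if not line:
            continue
        for chunk in _split_line(line):
            out.append(Sentence(text=chunk, index=idx))
            idx += 1
    return out


# ---------------------------------------------------------------------------
# JSONL readers / writers
# ---------------------------------------------------------------------------


def _report_to_dict(report: Report) -> dict:
    d: dict = {"report_id": report.report_id, "raw_text": report.raw_text}
    d["sentences"] = [
        {
            "index": s.index,
            "text": s.text,
            "section": s.section.name if s.section is not None else None,
        }
        for s in report.sentences
    ]
    if report.fields is not None:
        d["fields"] = dict(report.fields)
    if report.modality is not None:
        d["modality"] = report.modality
    return d


def _report_from_dict(d: dict) -> Report:
    sentences = [
        Sentence(
            text=s["text"],
            index=s["index"],
            section=SectionLabel[s["section"]] if s.get("section") else None,
        )
        for s in d.get("sentences", [])
    ]
    return Report(
        report_id=d["report_id"],
        raw_text=d.get("raw_text", ""),
        sentences=sentences,
        fields=dict(d["fields"]) if d.get("fields") is not None else None,
        modality=d.get("modality"),
    )


def read_reports(path: str | Path) -> list[Report]:
    """Read a JSONL corpus, one report per line. Unknown keys are ignored."""
    reports = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                d = json.loads(line)
            except json.JSONDecodeError as e:
                raise ValueError(f"{path}: malformed JSON on line {lineno}: {e}") from e
            if "report_id" not in d:
                raise ValueError(f"{path}: line {lineno} is missing 'report_id'")
            reports.append(_report_from_dict(d))
    return reports


def write_reports(reports: Iterable[Report], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in reports:
            fh.write(json.dumps(_report_to_dict(r), ensure_ascii=False) + "\n")
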