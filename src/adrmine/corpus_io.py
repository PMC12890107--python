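"""Reading and writing the note corpus, structured-module ADR records and
annotation (gold / prediction) files.

All files are line-delimited JSON (one record per line, UTF-8). JSON lines
were chosen over column-delimited text because note text freely contains
tabs, quotes and newlines; embedding it in a JSON string keeps the corpus a
plain-text artifact that round-trips loss-free.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

import pandas as pd

__all__ = [
    "CorpusError",
    "Note",
    "StructuredAdrRecord",
    "AnnotationRecord",
    "NOTE_CATEGORIES",
    "read_corpus",
    "write_corpus",
    "read_annotations",
    "write_annotations",
    "read_structured",
    "write_structured",
    "corpus_summary",
]

NOTE_CATEGORIES = frozenset(
    {
        "consultation",
        "questionnaire",
        "microbiology",
        "pathology",
        "radiology",
        "medical_history",
    }
)


class CorpusError(ValueError):
    """Raised when a corpus/annotation file violates its schema."""


def _parse_date(value: str, where: str) -> dt.date:
    try:
        return dt.date.fromisoformat(value)
    except (TypeError, ValueError) as exc:
        raise CorpusError(f"{where}: bad date {value!r}") from exc


@dataclass(frozen=True)
class Note:
    """One free-text EHR document."""

    patient_id: str
    note_id: str
    category: str
    author_role: str
    specialty: str
    timestamp: dt.date
    text: str

    def __post_init__(self) -> None:
        if self.category not in NOTE_CATEGORIES:
            raise CorpusError(
                f"note {self.note_id!r}: unknown category {self.category!r}"
            )
        if self.text is None:
            raise CorpusError(f"note {self.note_id!r}: text must not be absent")

    def word_count(self) -> int:
        return len(self.text.split())

    def char_count(self) -> int:
        return len(self.text)


@dataclass(frozen=True)
class StructuredAdrRecord:
    """An ADR documented in the EHR's structured ADR/complications module."""

    patient_id: str
    term_code: str
    ingredient_id: str
    approved_by: str  # physician | pharmacist | none
    severity: str
    date: dt.date

    def __post_init__(self) -> None:
        if self.approved_by not in ("physician", "pharmacist", "none"):
            raise CorpusError(f"bad approved_by {self.approved_by!r}")


@dataclass(frozen=True)
class AnnotationRecord:
    """One row of an ADR annotation ledger (manual review or prediction).

    ``flags`` may contain ``duplicate`` and/or ``re_adr`` as planted or
    assessed; the reduction stage recomputes both from dates and does not
    trust the flags.
    """

    patient_id: str
    symptom_text: str
    ingredient_ids: tuple[str, ...]
    term_code: str
    trigger_word: str | None
    context: str
    date: dt.date
    professional: str
    assessor_id: str = ""
    naranjo_score: int | None = None
    serious: bool = False
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.ingredient_ids:
            raise CorpusError("annotation record needs at least one ingredient id")
        if self.naranjo_score is not None and not (-10 <= self.naranjo_score <= 13):
            raise CorpusError(f"naranjo score {self.naranjo_score} out of range")
        bad = self.flags - {"duplicate", "re_adr"}
        if bad:
            raise CorpusError(f"unknown annotation flags {sorted(bad)}")


# ---------------------------------------------------------------------------
# serialization


def _read_jsonl(path: str | Path) -> Iterable[tuple[int, dict]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                yield lineno, json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"{path}: line {lineno}: invalid JSON") from exc


def read_corpus(path: str | Path) -> list[Note]:
    """Read a note corpus; duplicate note ids and unknown categories are
    hard errors."""
    notes: list[Note] = []
    seen: set[str] = set()
    for lineno, rec in _read_jsonl(path):
        try:
            note = Note(
                patient_id=str(rec["patient_id"]),
                note_id=str(rec["note_id"]),
                category=rec["category"],
                author_role=rec.get("author_role", ""),
                specialty=rec.get("specialty", ""),
                timestamp=_parse_date(rec["timestamp"], f"{path}:{lineno}"),
                text=rec["text"],
            )
        except KeyError as exc:
            raise CorpusError(f"{path}: line {lineno}: missing field {exc}") from exc
        if note.note_id in seen:
            raise CorpusError(f"{path}: line {lineno}: duplicate note_id {note.note_id!r}")
        seen.add(note.note_id)
        notes.append(note)
    return notes


def write_corpus(notes: Iterable[Note], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for note in notes:
            rec = asdict(note)
            rec["timestamp"] = note.timestamp.isoformat()
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    records = []
    for lineno, rec in _read_jsonl(path):
        try:
            records.append(
                AnnotationRecord(
                    patient_id=str(rec["patient_id"]),
                    symptom_text=rec.get("symptom_text", ""),
                    ingredient_ids=tuple(rec["ingredient_ids"]),
                    term_code=rec["term_code"],
                    trigger_word=rec.get("trigger_word"),
                    context=rec.get("context", ""),
                    date=_parse_date(rec["date"], f"{path}:{lineno}"),
                    professional=rec.get("professional", ""),
                    assessor_id=rec.get("assessor_id", ""),
                    naranjo_score=rec.get("naranjo_score"),
                    serious=bool(rec.get("serious", False)),
                    flags=frozenset(rec.get("flags", ())),
                )
            )
        except KeyError as exc:
            raise CorpusError(f"{path}: line {lineno}: missing field {exc}") from exc
    return records


def write_annotations(records: Iterable[AnnotationRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            obj = asdict(rec)
            obj["date"] = rec.date.isoformat()
            obj["ingredient_ids"] = list(rec.ingredient_ids)
            obj["flags"] = sorted(rec.flags)
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


def read_structured(path: str | Path) -> list[StructuredAdrRecord]:
    records = []
    for lineno, rec in _read_jsonl(path):
        try:
            records.append(
                StructuredAdrRecord(
                    patient_id=str(rec["patient_id"]),
                    term_code=rec["term_code"],
                    ingredient_id=rec["ingredient_id"],
                    approved_by=rec.get("approved_by", "none"),
                    severity=rec.get("severity", ""),
                    date=_parse_date(rec["date"], f"{path}:{lineno}"),
                )
            )
        except KeyError as exc:
            raise CorpusError(f"{path}: line {lineno}: missing field {exc}") from exc
    return records


def write_structured(records: Iterable[StructuredAdrRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            obj = asdict(rec)
            obj["date"] = rec.date.isoformat()
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


# ---------------------------------------------------------------------------
# descriptive summary


def corpus_summary(
    notes: Iterable[Note],
    strata_of: Callable[[str], str] | Mapping[str, str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-patient and per-stratum note/word/character descriptors.

    Words are maximal whitespace-delimited tokens; the character count
    includes whitespace. Per-patient totals are computed first, stratum rows
    then report the median and range of those totals, mirroring how EHR
    data volume is usually described.

    Returns ``{"per_patient": ..., "per_stratum": ...}``; the stratum table
    covers the single stratum ``"all"`` when no stratification is given.
    """
    notes = list(notes)
    if not notes:
        raise CorpusError("empty corpus: nothing to summarize")
    rows = [
        {
            "patient_id": n.patient_id,
            "notes": 1,
            "words": n.word_count(),
            "chars": n.char_count(),
        }
        for n in notes
    ]
    per_patient = (
        pd.DataFrame(rows).groupby("patient_id", sort=True).sum().reset_index()
    )
    if strata_of is None:
        labels = pd.Series("all", index=per_patient.index)
    elif callable(strata_of):
        labels = per_patient["patient_id"].map(strata_of)
    else:
        labels = per_patient["patient_id"].map(dict(strata_of))
    if labels.isna().any():
        missing = per_patient.loc[labels.isna(), "patient_id"].tolist()
        raise CorpusError(f"patients without stratum label: {missing}")
    per_patient = per_patient.assign(stratum=labels)

    stratum_rows = []
    for label, grp in per_patient.groupby("stratum", sort=True):
        row: dict[str, object] = {"stratum": label, "n_patients": len(grp)}
        for col in ("notes", "words", "chars"):
            row[f"{col}_median"] = float(grp[col].median())
            row[f"{col}_min"] = int(grp[col].min())
            row[f"{col}_max"] = int(grp[col].max())
        stratum_rows.append(row)
    return {"per_patient": per_patient, "per_stratum": pd.DataFrame(stratum_rows)}
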