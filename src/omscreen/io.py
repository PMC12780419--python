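"""Reading and writing the plain-text interchange formats.

Visit records travel as JSONL (one object per line with keys ``child_id``,
``visit_id``, ``visit_date``, ``text``) or CSV with identical headers.
Screen results are JSONL with full match provenance; gold labels are CSV
with headers ``visit_id``, ``om_considered``.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .lexicon import ExclusionWord, SearchTerm
from .matcher import ExclusionHit, ScreenResult, TermMatch, VisitRecord

__all__ = [
    "RecordParseError",
    "read_records",
    "write_records",
    "read_gold_labels",
    "write_gold_labels",
    "write_screen_results",
    "read_screen_results",
]

PathLike = Union[str, Path]

_RECORD_FIELDS = ("child_id", "visit_id", "visit_date", "text")
_TRUTHY = {"true", "1", "yes", "t"}
_FALSY = {"false", "0", "no", "f"}


class RecordParseError(ValueError):
    """An input line/row could not be parsed; carries the line number."""

    def __init__(self, path: PathLike, lineno: int, message: str):
        super().__init__(f"{path}: line {lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def _record_from_mapping(obj: dict, path: PathLike, lineno: int) -> VisitRecord:
    missing = [k for k in ("child_id", "visit_id", "text") if k not in obj]
    if missing:
        raise RecordParseError(path, lineno, f"missing field(s) {missing}")
    text = obj["text"]
    if text is None:
        text = ""
    date = obj.get("visit_date") or None
    return VisitRecord(
        child_id=str(obj["child_id"]),
        visit_id=str(obj["visit_id"]),
        text=str(text),
        visit_date=str(date) if date is not None else None,
    )


def read_records(path: PathLike, format: Optional[str] = None) -> list[VisitRecord]:
    """Read visit records from JSONL or CSV (format inferred from suffix)."""
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "jsonl")
    records: list[VisitRecord] = []
    if fmt == "jsonl":
        with open(path, "r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise RecordParseError(path, lineno, f"invalid JSON: {exc}") from exc
                if not isinstance(obj, dict):
                    raise RecordParseError(path, lineno, "expected a JSON object")
                records.append(_record_from_mapping(obj, path, lineno))
    elif fmt == "csv":
        with open(path, "r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            for lineno, row in enumerate(reader, start=2):
                records.append(_record_from_mapping(row, path, lineno))
    else:
        raise ValueError(f"unknown record format {fmt!r}")
    return records


def write_records(records: Iterable[VisitRecord], path: PathLike, format: Optional[str] = None) -> None:
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "jsonl")
    if fmt == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for r in records:
                fh.write(
                    json.dumps(
                        {
                            "child_id": r.child_id,
                            "visit_id": r.visit_id,
                            "visit_date": r.visit_date,
                            "text": r.text,
                        },
                        ensure_ascii=False,
                    )
                    + "\n"
                )
    elif fmt == "csv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_RECORD_FIELDS)
            for r in records:
                writer.writerow([r.child_id, r.visit_id, r.visit_date or "", r.text])
    else:
        raise ValueError(f"unknown record format {fmt!r}")


def read_gold_labels(path: PathLike) -> dict[str, bool]:
    """Gold labels CSV (visit_id, om_considered) -> mapping."""
    path = Path(path)
    labels: dict[str, bool] = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "visit_id" not in reader.fieldnames or "om_considered" not in reader.fieldnames:
            raise RecordParseError(path, 1, "expected headers visit_id, om_considered")
        for lineno, row in enumerate(reader, start=2):
            raw = (row["om_considered"] or "").strip().lower()
            if raw in _TRUTHY:
                value = True
            elif raw in _FALSY:
                value = False
            else:
                raise RecordParseError(path, lineno, f"bad boolean {row['om_considered']!r}")
            vid = row["visit_id"]
            if vid in labels:
                raise RecordParseError(path, lineno, f"duplicate visit_id {vid!r}")
            labels[vid] = value
    return labels


def write_gold_labels(labels: dict[str, bool], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["visit_id", "om_considered"])
        for vid, value in labels.items():
            writer.writerow([vid, str(value).lower()])


def _match_to_dict(m: TermMatch) -> dict:
    d = {
        "term": m.term.surface,
        "case_sensitive": m.term.case_sensitive,
        "start": m.start,
        "end": m.end,
        "excluded": m.excluded,
    }
    if m.excluded_by is not None:
        d["excluded_by"] = {
            "word": m.excluded_by.word.surface,
            "case_sensitive": m.excluded_by.word.case_sensitive,
            "start": m.excluded_by.start,
            "end": m.excluded_by.end,
        }
    return d


def write_screen_results(
    results: Iterable[ScreenResult], path: PathLike, flagged_only: bool = False
) -> None:
    """Write results as JSONL with full match provenance."""
    with open(path, "w", encoding="utf-8") as fh:
        for r in results:
            if flagged_only and not r.flagged:
                continue
            fh.write(
                json.dumps(
                    {
                        "visit_id": r.visit_id,
                        "flagged": r.flagged,
                        "matches": [_match_to_dict(m) for m in r.matches],
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_screen_results(path: PathLike) -> list[ScreenResult]:
    path = Path(path)
    out: list[ScreenResult] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise RecordParseError(path, lineno, f"invalid JSON: {exc}") from exc
            matches = []
            for md in obj.get("matches", ()):
                hit = None
                if md.get("excluded_by") is not None:
                    eb = md["excluded_by"]
                    hit = ExclusionHit(
                        word=ExclusionWord(
                            surface=eb["word"], case_sensitive=eb.get("case_sensitive", True)
                        ),
                        start=eb["start"],
                        end=eb["end"],
                    )
                matches.append(
                    TermMatch(
                        term=SearchTerm(
                            surface=md["term"], case_sensitive=md.get("case_sensitive", True)
                        ),
                        start=md["start"],
                        end=md["end"],
                        excluded=md["excluded"],
                        excluded_by=hit,
                    )
                )
            out.append(
                ScreenResult(
                    visit_id=str(obj["visit_id"]),
                    flagged=bool(obj["flagged"]),
                    matches=tuple(matches),
                )
            )
    return out
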