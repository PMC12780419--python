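"""Clinician-review workflow: adjudication, discrepancy reports, refinement aids.

The workflow this models has four stages: independent labelling by several
reviewers, consensus adjudication of discordant visits, discrepancy review
against the algorithm (false positives especially), and a final clinician
pass over the flagged subset.  Discordance is never resolved by majority
vote — a discordant visit without an explicitly supplied resolution stays
``unresolved``.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .evaluation import GoldLabel, LabelAlignmentError
from .lexicon import Lexicon
from .matcher import ScreenResult, TermMatch, VisitRecord, occurrence_in_scope, token_spans

__all__ = [
    "ReviewerLabel",
    "AdjudicatedLabel",
    "Discrepancy",
    "AdjudicationError",
    "adjudicate",
    "discrepancy_report",
    "suggest_exclusion_candidates",
    "export_review_worksheet",
    "read_reviewer_labels",
    "read_resolutions",
]

PathLike = Union[str, Path]


class AdjudicationError(ValueError):
    pass


@dataclass(frozen=True)
class ReviewerLabel:
    visit_id: str
    reviewer_id: str
    om_considered: bool
    terms_noted: tuple[str, ...] = ()


@dataclass(frozen=True)
class AdjudicatedLabel:
    visit_id: str
    status: str  # unanimous | consensus_resolved | unresolved
    om_considered: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.status not in ("unanimous", "consensus_resolved", "unresolved"):
            raise ValueError(f"bad status {self.status!r}")
        if (self.om_considered is None) != (self.status == "unresolved"):
            raise ValueError("om_considered present iff status != unresolved")


@dataclass(frozen=True)
class Discrepancy:
    visit_id: str
    kind: str  # false_positive | false_negative
    matches: tuple[TermMatch, ...]
    snippets: tuple[str, ...] = field(default=())


def adjudicate(
    labels: Sequence[ReviewerLabel],
    resolutions: Optional[Sequence[AdjudicatedLabel]] = None,
) -> list[AdjudicatedLabel]:
    """Combine independent reviewer labels into adjudicated labels.

    Unanimous visits adopt the shared label; discordant visits adopt a
    supplied ``consensus_resolved`` resolution, else stay ``unresolved``.
    Each visit needs at least two reviewers; a resolution for a unanimous
    visit, or a duplicate resolution, is an error.
    """
    by_visit: dict[str, list[ReviewerLabel]] = defaultdict(list)
    seen_pairs: set[tuple[str, str]] = set()
    for lab in labels:
        pair = (lab.visit_id, lab.reviewer_id)
        if pair in seen_pairs:
            raise AdjudicationError(f"duplicate label for {pair}")
        seen_pairs.add(pair)
        by_visit[lab.visit_id].append(lab)

    res_map: dict[str, AdjudicatedLabel] = {}
    for res in resolutions or ():
        if res.visit_id in res_map:
            raise AdjudicationError(f"duplicate resolution for visit {res.visit_id!r}")
        if res.visit_id not in by_visit:
            raise AdjudicationError(f"resolution for unknown visit {res.visit_id!r}")
        res_map[res.visit_id] = res

    out: list[AdjudicatedLabel] = []
    for visit_id, visit_labels in by_visit.items():
        if len(visit_labels) < 2:
            raise AdjudicationError(
                f"visit {visit_id!r} has {len(visit_labels)} reviewer(s); need >= 2"
            )
        votes = {lab.om_considered for lab in visit_labels}
        if len(votes) == 1:
            if visit_id in res_map:
                raise AdjudicationError(
                    f"resolution supplied for unanimous visit {visit_id!r}"
                )
            out.append(
                AdjudicatedLabel(
                    visit_id=visit_id, status="unanimous", om_considered=votes.pop()
                )
            )
        elif visit_id in res_map:
            res = res_map[visit_id]
            out.append(
                AdjudicatedLabel(
                    visit_id=visit_id,
                    status="consensus_resolved",
                    om_considered=res.om_considered,
                )
            )
        else:
            out.append(AdjudicatedLabel(visit_id=visit_id, status="unresolved"))
    return out


def _align(
    results: Sequence[ScreenResult],
    gold: Iterable[GoldLabel],
    records: Sequence[VisitRecord],
) -> tuple[dict[str, ScreenResult], dict[str, bool], dict[str, VisitRecord]]:
    res_map = {r.visit_id: r for r in results}
    gold_map = {g.visit_id: g.om_considered for g in gold}
    rec_map = {r.visit_id: r for r in records}
    ids = set(res_map)
    orphans = (ids ^ set(gold_map)) | (ids ^ set(rec_map))
    if orphans:
        raise LabelAlignmentError(f"visit ids misaligned across inputs: {sorted(orphans)[:10]}")
    return res_map, gold_map, rec_map


def _snippet(text: str, start: int, end: int, radius: int) -> str:
    return text[max(0, start - radius) : min(len(text), end + radius)]


def discrepancy_report(
    results: Sequence[ScreenResult],
    gold: Iterable[GoldLabel],
    records: Sequence[VisitRecord],
    snippet_radius: int = 40,
) -> list[Discrepancy]:
    """One entry per disagreement between algorithm and gold standard.

    False positives come first, then false negatives, each sorted by
    visit_id; counts always reconcile with the confusion matrix on the same
    inputs.  Snippets show a text window around each match (for false
    negatives with no matches at all, the head of the note).
    """
    res_map, gold_map, rec_map = _align(results, gold, records)
    fps: list[Discrepancy] = []
    fns: list[Discrepancy] = []
    for visit_id in sorted(res_map):
        result = res_map[visit_id]
        positive = gold_map[visit_id]
        if result.flagged == positive:
            continue
        text = rec_map[visit_id].text
        if result.matches:
            snippets = tuple(
                _snippet(text, m.start, m.end, snippet_radius) for m in result.matches
            )
        else:
            snippets = (text[: 2 * snippet_radius],) if text else ()
        disc = Discrepancy(
            visit_id=visit_id,
            kind="false_positive" if result.flagged else "false_negative",
            matches=result.matches,
            snippets=snippets,
        )
        (fps if result.flagged else fns).append(disc)
    return fps + fns


def suggest_exclusion_candidates(
    fp_discrepancies: Sequence[Discrepancy],
    records: Sequence[VisitRecord],
    lexicon: Lexicon,
    top_k: int = 10,
    *,
    results: Optional[Sequence[ScreenResult]] = None,
    gold: Optional[Iterable[GoldLabel]] = None,
) -> list[tuple[str, int, int]]:
    """Rank words that co-occur with retained matches in false-positive visits.

    Returns ``(word, fp_support, flagged_tp_support)`` triples ordered by
    ``fp_support`` descending, with ``flagged_tp_support`` (how often the
    word also co-occurs with matches in true-positive visits — a penalty) as
    ascending tie-breaker, then alphabetically.  Words already in the lexicon
    are never suggested.  Candidates are counted case-insensitively within
    the active combination-policy scope of each retained match.

    This is refinement tooling beyond the validated pipeline: it automates
    the screen-and-discuss loop but its output still needs human review.
    """
    rec_map = {r.visit_id: r for r in records}
    known = {t.surface.lower() for t in lexicon.search_terms}
    known |= {w.surface.lower() for w in lexicon.exclusion_words}

    tp_ids: set[str] = set()
    if results is not None and gold is not None:
        gold_map = {g.visit_id: g.om_considered for g in gold}
        tp_ids = {
            r.visit_id for r in results if r.flagged and gold_map.get(r.visit_id, False)
        }

    def scope_words(result_matches: Sequence[TermMatch], text: str) -> set[str]:
        spans = token_spans(text)
        words: set[str] = set()
        for m in result_matches:
            if m.excluded:
                continue
            for s, e in spans:
                if not occurrence_in_scope(text, (m.start, m.end), (s, e), lexicon.policy, spans):
                    continue
                word = text[s:e].lower()
                if word not in known:
                    words.add(word)
        return words

    fp_support: dict[str, int] = defaultdict(int)
    for disc in fp_discrepancies:
        if disc.kind != "false_positive":
            continue
        record = rec_map.get(disc.visit_id)
        if record is None:
            raise LabelAlignmentError(f"discrepancy visit {disc.visit_id!r} not in corpus")
        for word in scope_words(disc.matches, record.text):
            fp_support[word] += 1

    tp_support: dict[str, int] = defaultdict(int)
    if tp_ids and results is not None:
        res_map = {r.visit_id: r for r in results}
        for visit_id in tp_ids:
            record = rec_map.get(visit_id)
            if record is None:
                continue
            for word in scope_words(res_map[visit_id].matches, record.text):
                tp_support[word] += 1

    ranked = sorted(
        ((w, n, tp_support.get(w, 0)) for w, n in fp_support.items()),
        key=lambda t: (-t[1], t[2], t[0]),
    )
    return ranked[:top_k]


def export_review_worksheet(
    results: Sequence[ScreenResult],
    records: Sequence[VisitRecord],
    path: PathLike,
    snippet_radius: int = 40,
) -> int:
    """Write the flagged-visit worksheet for the final clinician pass.

    One CSV row per flagged visit (visit_id, child_id, date, matched terms,
    snippets, blank reviewer_label/notes columns), ordered by child then
    date.  Returns the number of rows written.
    """
    rec_map = {r.visit_id: r for r in records}
    missing = [r.visit_id for r in results if r.flagged and r.visit_id not in rec_map]
    if missing:
        raise LabelAlignmentError(f"flagged results without records: {missing[:10]}")
    rows = []
    for result in results:
        if not result.flagged:
            continue
        record = rec_map[result.visit_id]
        retained = [m for m in result.matches if not m.excluded]
        rows.append(
            (
                record.child_id,
                record.visit_date or "",
                result.visit_id,
                "; ".join(m.term.surface for m in retained),
                " | ".join(
                    _snippet(record.text, m.start, m.end, snippet_radius) for m in retained
                ),
            )
        )
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["visit_id", "child_id", "visit_date", "matched_terms", "snippets", "reviewer_label", "notes"]
        )
        for child_id, date, visit_id, terms, snippets in rows:
            writer.writerow([visit_id, child_id, date, terms, snippets, "", ""])
    return len(rows)


def read_reviewer_labels(path: PathLike) -> list[ReviewerLabel]:
    """Reviewer labels CSV: visit_id, reviewer_id, om_considered[, terms_noted]."""
    out: list[ReviewerLabel] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            noted = tuple(t.strip() for t in (row.get("terms_noted") or "").split(";") if t.strip())
            out.append(
                ReviewerLabel(
                    visit_id=row["visit_id"],
                    reviewer_id=row["reviewer_id"],
                    om_considered=row["om_considered"].strip().lower() in ("true", "1", "yes"),
                    terms_noted=noted,
                )
            )
    return out


def read_resolutions(path: PathLike) -> list[AdjudicatedLabel]:
    """Consensus resolutions CSV: visit_id, om_considered."""
    out: list[AdjudicatedLabel] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                AdjudicatedLabel(
                    visit_id=row["visit_id"],
                    status="consensus_resolved",
                    om_considered=row["om_considered"].strip().lower() in ("true", "1", "yes"),
                )
            )
    return out
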