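"""Screening rule sets: search terms, exclusion words and the combination policy.

A :class:`Lexicon` bundles the surface strings whose presence in a visit note
suggests the target diagnosis was considered (search terms), the words that —
in combination with a search term — indicate the term does *not* signal the
diagnosis (exclusion words), and the :class:`CombinationPolicy` that defines
what "in combination" means (adjacent token, token window, same sentence, or
anywhere in the record).

Lexicon content is data, not code: rule sets are loaded from and saved to
YAML or CSV files, and the package ships a seed lexicon for otitis media
under ``omscreen/data/seed_lexicon.yaml``.
"""

from __future__ import annotations

import csv
import importlib.resources
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

__all__ = [
    "SearchTerm",
    "ExclusionWord",
    "CombinationPolicy",
    "Lexicon",
    "LexiconError",
    "LexiconFormatError",
    "LexiconValidationError",
    "MergeConflictError",
    "load_lexicon",
    "save_lexicon",
    "merge_lexicons",
    "seed_lexicon",
]

PolicyMode = Literal["phrase", "window", "sentence", "record"]


class LexiconError(Exception):
    """Base class for lexicon loading/validation problems."""


class LexiconFormatError(LexiconError):
    """The file could not be parsed under the declared schema."""


class LexiconValidationError(LexiconError):
    """The parsed content violates a lexicon invariant."""


class MergeConflictError(LexiconError):
    """Two lexicons disagree on the case rule for the same surface."""


def _check_surface(value: str) -> str:
    if not isinstance(value, str):
        raise ValueError(f"surface must be a string, got {type(value).__name__}")
    if value != value.strip():
        raise ValueError(f"surface has leading/trailing whitespace: {value!r}")
    if not value:
        raise ValueError("surface is empty")
    return value


class SearchTerm(BaseModel):
    """One literal surface string whose presence flags a visit.

    ``case_sensitive`` defaults to ``True``: tympanic-membrane variants such
    as ``'T/M'``, ``'t/m'``, ``'tm'`` and ``'TM'`` are listed as distinct
    terms, so exact-case matching is the conservative default.  Set the flag
    to ``False`` for full words like ``'otitis media'`` where capitalisation
    carries no meaning.
    """

    model_config = ConfigDict(frozen=True)

    surface: str
    case_sensitive: bool = True
    note: Optional[str] = None

    @field_validator("surface")
    @classmethod
    def _surface_ok(cls, v: str) -> str:
        return _check_surface(v)

    @property
    def key(self) -> tuple[str, bool]:
        """Canonical identity used for duplicate detection."""
        s = self.surface if self.case_sensitive else self.surface.lower()
        return (s, self.case_sensitive)


class ExclusionWord(BaseModel):
    """A word that, near a search term, marks the term as not signalling OM."""

    model_config = ConfigDict(frozen=True)

    surface: str
    case_sensitive: bool = True

    @field_validator("surface")
    @classmethod
    def _surface_ok(cls, v: str) -> str:
        return _check_surface(v)

    @property
    def key(self) -> tuple[str, bool]:
        s = self.surface if self.case_sensitive else self.surface.lower()
        return (s, self.case_sensitive)


class CombinationPolicy(BaseModel):
    """Proximity scope within which a search term + exclusion word combine.

    Modes:

    - ``phrase``   — exclusion word in the immediately adjacent token;
    - ``window``   — exclusion word within ``window_tokens`` tokens;
    - ``sentence`` — exclusion word anywhere in the same sentence;
    - ``record``   — exclusion word anywhere in the visit text.

    ``bidirectional`` controls whether an exclusion word *before* the search
    term also triggers exclusion; it applies to the ``phrase`` and ``window``
    modes (``sentence`` and ``record`` scopes are inherently symmetric).
    """

    model_config = ConfigDict(frozen=True)

    mode: PolicyMode = "window"
    window_tokens: int = Field(default=3, ge=1)
    bidirectional: bool = True


class Lexicon(BaseModel):
    """A validated, ordered screening rule set."""

    model_config = ConfigDict(frozen=True)

    search_terms: tuple[SearchTerm, ...]
    exclusion_words: tuple[ExclusionWord, ...] = ()
    policy: CombinationPolicy = CombinationPolicy()
    version: str = "unversioned"

    @model_validator(mode="after")
    def _invariants(self) -> "Lexicon":
        if not self.search_terms:
            raise ValueError("lexicon must contain at least one search term")
        dupes = _duplicate_surfaces(self.search_terms)
        if dupes:
            raise ValueError(f"duplicate search terms: {sorted(dupes)}")
        dupes = _duplicate_surfaces(self.exclusion_words)
        if dupes:
            raise ValueError(f"duplicate exclusion words: {sorted(dupes)}")
        clashes = []
        for term in self.search_terms:
            for excl in self.exclusion_words:
                if term.case_sensitive:
                    same = term.surface == excl.surface
                else:
                    same = term.surface.lower() == excl.surface.lower()
                if same:
                    clashes.append(term.surface)
        if clashes:
            raise ValueError(
                f"search terms also listed as exclusion words: {sorted(set(clashes))}"
            )
        return self

    def describe(self) -> str:
        return (
            f"Lexicon {self.version!r}: {len(self.search_terms)} search terms, "
            f"{len(self.exclusion_words)} exclusion words, "
            f"policy={self.policy.mode}"
        )


def _duplicate_surfaces(entries: Sequence) -> set[str]:
    seen: dict[tuple[str, bool], str] = {}
    dupes: set[str] = set()
    for e in entries:
        if e.key in seen:
            dupes.add(e.surface)
        seen[e.key] = e.surface
    return dupes


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def _infer_format(path: Path, format: Optional[str]) -> str:
    if format is not None:
        if format not in ("yaml", "csv"):
            raise ValueError(f"unknown lexicon format {format!r}")
        return format
    suffix = path.suffix.lower()
    if suffix in (".yaml", ".yml"):
        return "yaml"
    if suffix == ".csv":
        return "csv"
    raise ValueError(f"cannot infer lexicon format from suffix {suffix!r}")


def load_lexicon(
    path: Union[str, Path],
    format: Optional[str] = None,
    *,
    policy: Optional[CombinationPolicy] = None,
    version: Optional[str] = None,
) -> Lexicon:
    """Load and validate a lexicon from a YAML or CSV file.

    The YAML schema carries the policy and version inline; the CSV dialect
    holds only the term rows (columns ``kind, surface, case_sensitive,
    note``), so ``policy`` and ``version`` may be supplied by the caller and
    otherwise default.  A ``policy``/``version`` argument overrides the file
    content in either format.

    Raises
    ------
    LexiconFormatError
        If the file cannot be parsed, naming the offending line/field.
    LexiconValidationError
        If parsed content violates a lexicon invariant (duplicates, empty
        search-term list, term/exclusion clash).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "yaml":
        data = _read_yaml(path)
    else:
        data = _read_csv(path)
    if policy is not None:
        data["policy"] = policy.model_dump()
    if version is not None:
        data["version"] = version
    try:
        return Lexicon.model_validate(data)
    except Exception as exc:  # pydantic ValidationError wraps our messages
        raise LexiconValidationError(f"{path}: {exc}") from exc


def _read_yaml(path: Path) -> dict:
    try:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise LexiconFormatError(f"{path}: invalid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise LexiconFormatError(f"{path}: top level must be a mapping")
    unknown = set(raw) - {"version", "policy", "search_terms", "exclusion_words"}
    if unknown:
        raise LexiconFormatError(f"{path}: unknown top-level keys {sorted(unknown)}")
    data: dict = {}
    if "version" in raw:
        data["version"] = raw["version"]
    if "policy" in raw and raw["policy"] is not None:
        data["policy"] = raw["policy"]
    data["search_terms"] = raw.get("search_terms") or []
    data["exclusion_words"] = raw.get("exclusion_words") or []
    return data


_CSV_COLUMNS = ["kind", "surface", "case_sensitive", "note"]
_TRUTHY = {"true", "1", "yes"}
_FALSY = {"false", "0", "no"}


def _parse_bool(value: str, where: str) -> bool:
    v = value.strip().lower()
    if v in _TRUTHY:
        return True
    if v in _FALSY:
        return False
    raise LexiconFormatError(f"{where}: bad boolean {value!r}")


def _read_csv(path: Path) -> dict:
    search: list[dict] = []
    exclusion: list[dict] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != _CSV_COLUMNS:
            raise LexiconFormatError(
                f"{path}: expected header {_CSV_COLUMNS}, got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            where = f"{path}:line {lineno}"
            kind = (row.get("kind") or "").strip()
            surface = row.get("surface") or ""
            cs = _parse_bool(row.get("case_sensitive") or "true", where)
            if kind == "search":
                note = row.get("note") or None
                search.append(
                    {"surface": surface, "case_sensitive": cs, "note": note or None}
                )
            elif kind == "exclusion":
                exclusion.append({"surface": surface, "case_sensitive": cs})
            else:
                raise LexiconFormatError(f"{where}: kind must be 'search' or 'exclusion', got {kind!r}")
    return {"search_terms": search, "exclusion_words": exclusion}


def save_lexicon(lexicon: Lexicon, path: Union[str, Path], format: Optional[str] = None) -> None:
    """Write a lexicon to YAML or CSV.

    YAML round-trips the full structure (policy and version included).  CSV
    holds only the term rows; policy and version must travel separately (see
    :func:`load_lexicon`).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "yaml":
        doc = {
            "version": lexicon.version,
            "policy": lexicon.policy.model_dump(),
            "search_terms": [
                {k: v for k, v in t.model_dump().items() if not (k == "note" and v is None)}
                for t in lexicon.search_terms
            ],
            "exclusion_words": [w.model_dump() for w in lexicon.exclusion_words],
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)
    else:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_CSV_COLUMNS)
            for t in lexicon.search_terms:
                writer.writerow(["search", t.surface, str(t.case_sensitive).lower(), t.note or ""])
            for w in lexicon.exclusion_words:
                writer.writerow(["exclusion", w.surface, str(w.case_sensitive).lower(), ""])


def merge_lexicons(base: Lexicon, update: Lexicon) -> Lexicon:
    """Union of two rule sets, used in the iterative refinement loop.

    Search terms and exclusion words are unioned with duplicates collapsed
    (base order first, then new entries in update order).  The policy is
    taken from ``update``; the version label records both parents.  A surface
    appearing in both lexicons with *different* case-sensitivity flags is a
    conflict requiring explicit resolution, not a silent pick.
    """
    conflicts = _case_conflicts(base.search_terms, update.search_terms)
    conflicts |= _case_conflicts(base.exclusion_words, update.exclusion_words)
    if conflicts:
        raise MergeConflictError(
            "conflicting case_sensitive flags for surfaces "
            f"{sorted(conflicts)}; resolve explicitly before merging"
        )
    terms = list(base.search_terms)
    seen = {t.key for t in terms}
    for t in update.search_terms:
        if t.key not in seen:
            terms.append(t)
            seen.add(t.key)
    words = list(base.exclusion_words)
    seen_w = {w.key for w in words}
    for w in update.exclusion_words:
        if w.key not in seen_w:
            words.append(w)
            seen_w.add(w.key)
    if base.version == update.version:
        version = base.version
    else:
        version = f"{base.version}+{update.version}"
    return Lexicon(
        search_terms=tuple(terms),
        exclusion_words=tuple(words),
        policy=update.policy,
        version=version,
    )


def _case_conflicts(a: Iterable, b: Iterable) -> set[str]:
    flags_a = {e.surface: e.case_sensitive for e in a}
    out = set()
    for e in b:
        if e.surface in flags_a and flags_a[e.surface] != e.case_sensitive:
            out.add(e.surface)
    return out


def seed_lexicon() -> Lexicon:
    """The otitis-media seed lexicon shipped with the package."""
    ref = importlib.resources.files("omscreen").joinpath("data/seed_lexicon.yaml")
    with importlib.resources.as_file(ref) as path:
        return load_lexicon(path, "yaml")
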