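"""Seeded synthetic visit corpora with known gold labels.

Generates template-based pseudo-clinical notes emulating the structure of a
paediatric primary care validation corpus: ~200 children with ~50 visits
each and ~9% of visits where the target diagnosis was considered.  Positive
visits embed a sampled search term in affirmative text; negative visits are
filler, optionally decorated with one of the documented hard cases —

- *negation*: a term immediately followed by an exclusion word ("tm normal"),
  which a correct matcher excludes;
- *confounder*: an ambiguous abbreviation used non-otologically ("ROM" as
  range of movement), a designed false positive;
- *family mention*: the diagnosis attributed to a relative ("brother has
  otitis media"), likewise a designed false positive.

Gold labels depend only on the planting decisions, never on the matcher, so
regenerating with a different lexicon leaves gold unchanged.  Randomness is
split into two independent streams — one for label-determining draws, one
for text rendering — which is what makes that guarantee hold.  Character
misspellings are applied to filler text only (planted constructions stay
verbatim unless ``corrupt_planted_terms`` is set), and a generation-time
check reverts any typo that would accidentally create a lexicon term.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .evaluation import DiagnosticStats, GoldLabel, build_confusion, diagnostic_stats
from .io import write_gold_labels, write_records
from .lexicon import Lexicon
from .matcher import VisitRecord, find_term_occurrences, screen_corpus

__all__ = [
    "SyntheticCorpusSpec",
    "VisitProvenance",
    "LabelledCorpus",
    "ClosedLoopResult",
    "generate_corpus",
    "corpus_summary",
    "closed_loop_check",
    "write_corpus",
]

_ALPHABET = "abcdefghijklmnopqrstuvwxyz"

# Filler sentences: curated to contain no seed-lexicon term as a standalone
# token; a generation-time check enforces this against whatever lexicon is
# actually passed in.
_FILLER_SENTENCES = (
    "presented with runny nose and cough for two days",
    "afebrile today and chest is clear with good air entry",
    "immunisations given as per schedule with no concerns raised",
    "mild eczema on the flexures so emollient advised",
    "reviewed asthma plan and checked inhaler technique",
    "feeding well and weight tracking along the centile",
    "viral illness likely so supportive care discussed",
    "sore throat with no exudate and advised fluids and rest",
    "loose stools since yesterday but well hydrated",
    "rash on trunk settling and no fever reported",
    "sleep routine discussed with parents at length",
    "barking cough overnight consistent with mild croup",
    "teething and settled with paracetamol as needed",
    "follow up arranged in one week if not improving",
)

_POSITIVE_TEMPLATES = (
    "seen with fever and left ear pain. {term} diagnosed and amoxicillin started",
    "irritable overnight with right ear red and bulging. dx {term}. antibiotics prescribed",
    "ear ache since yesterday. {term} confirmed on examination and analgesia advised",
    "pulling at ears and febrile. impression {term} so treatment commenced today",
)

_NEGATION_TEMPLATES = (
    "checked ears today. {term} {excl} bilaterally and throat unremarkable",
    "examination fine. {term} {excl} both sides with no effusion seen",
    "ears examined. {term} {excl} and child otherwise well today",
)

_CONFOUNDER_TEMPLATES = (
    "fell at the playground. elbow ROM full and pain free on testing",
    "knee reviewed after sport. ROM intact with no swelling or laxity",
    "ankle sprain improving since physio and ROM returning steadily",
)

_FAMILY_TEMPLATES = (
    "mother mentions brother has otitis media. child is well today",
    "sister has otitis media currently. ears checked as a precaution",
    "father reports brother has otitis media at home. no issues for this child",
)


class SyntheticCorpusSpec(BaseModel):
    """Generative parameters for a corpus with known ground truth."""

    model_config = ConfigDict(frozen=True)

    n_children: int = Field(default=200, ge=1)
    mean_visits_per_child: float = Field(default=50.0, gt=0.0)
    dispersion: float = Field(default=20.0, gt=0.0)  # NB shape; larger = closer to Poisson
    prevalence: float = Field(default=0.09, ge=0.0, le=1.0)
    term_weights: Optional[dict[str, float]] = None
    negation_rate: float = Field(default=0.05, ge=0.0, le=1.0)
    confounder_rate: float = Field(default=0.02, ge=0.0, le=1.0)
    family_mention_rate: float = Field(default=0.01, ge=0.0, le=1.0)
    misspelling_rate: float = Field(default=0.0, ge=0.0, le=1.0)
    corrupt_planted_terms: bool = False
    seed: int

    @model_validator(mode="after")
    def _rates_ok(self) -> "SyntheticCorpusSpec":
        total = self.negation_rate + self.confounder_rate + self.family_mention_rate
        if total > 1.0:
            raise ValueError(
                "negation_rate + confounder_rate + family_mention_rate must be <= 1 "
                f"(got {total}); the constructions partition the negative visits"
            )
        if self.term_weights is not None:
            if not self.term_weights:
                raise ValueError("term_weights must be non-empty when given")
            if any(w < 0 for w in self.term_weights.values()):
                raise ValueError("term_weights must be non-negative")
            if sum(self.term_weights.values()) <= 0:
                raise ValueError("term_weights must not sum to zero")
        return self


@dataclass(frozen=True)
class VisitProvenance:
    """What was planted in one generated visit."""

    visit_id: str
    construction: str  # positive | negation | confounder | family | filler
    planted_term: Optional[str] = None
    planted_exclusion: Optional[str] = None


@dataclass(frozen=True)
class LabelledCorpus:
    records: tuple[VisitRecord, ...]
    gold: tuple[GoldLabel, ...]
    provenance: tuple[VisitProvenance, ...]

    def __post_init__(self) -> None:
        if not (
            len(self.records) == len(self.gold) == len(self.provenance)
            and all(
                r.visit_id == g.visit_id == p.visit_id
                for r, g, p in zip(self.records, self.gold, self.provenance)
            )
        ):
            raise ValueError("records, gold and provenance must be id-aligned")


def _contains_lexicon_surface(text: str, lexicon: Lexicon, include_exclusions: bool) -> bool:
    if find_term_occurrences(text, lexicon):
        return True
    if include_exclusions:
        from .matcher import _scan_surface  # boundary-respecting scan

        for word in lexicon.exclusion_words:
            if any(True for _ in _scan_surface(text, word.surface, word.case_sensitive)):
                return True
    return False


def _apply_typos(fragment: str, rate: float, rng: np.random.Generator, lexicon: Lexicon) -> str:
    """Per-character typos (substitute/transpose/delete); a typo that would
    create a lexicon term or exclusion word is reverted."""
    if rate <= 0.0:
        return fragment
    chars = list(fragment)
    i = 0
    while i < len(chars):
        if chars[i].isalpha() and rng.random() < rate:
            op = rng.integers(0, 3)
            candidate = chars.copy()
            if op == 0:
                candidate[i] = _ALPHABET[rng.integers(0, 26)]
            elif op == 1 and i + 1 < len(candidate):
                candidate[i], candidate[i + 1] = candidate[i + 1], candidate[i]
            else:
                del candidate[i]
            mutated = "".join(candidate)
            if not _contains_lexicon_surface(mutated, lexicon, include_exclusions=True):
                chars = candidate
        i += 1
    return "".join(chars)


def _pick_templates(
    templates: Sequence[str], lexicon: Lexicon, *, slots: dict[str, str], forbid_exclusions: bool
) -> list[str]:
    """Keep only templates whose fixed text plants nothing unintended."""
    ok = []
    for t in templates:
        rendered = t.format(**slots) if slots else t
        if not _contains_lexicon_surface(rendered, lexicon, include_exclusions=forbid_exclusions):
            ok.append(t)
    return ok


def generate_corpus(spec: SyntheticCorpusSpec, lexicon: Lexicon) -> LabelledCorpus:
    """Generate a labelled corpus; deterministic for a fixed seed.

    Label-determining draws (visit counts, per-visit construction category)
    come from one RNG stream; text rendering from another, so gold labels
    are identical across lexicons for the same spec.
    """
    label_ss, text_ss = np.random.SeedSequence(spec.seed).spawn(2)
    label_rng = np.random.default_rng(label_ss)
    text_rng = np.random.default_rng(text_ss)

    surfaces = [t.surface for t in lexicon.search_terms]
    if spec.term_weights is not None:
        unknown = sorted(set(spec.term_weights) - set(surfaces))
        if unknown:
            raise ValueError(f"term_weights reference unknown search terms: {unknown}")
        weighted = [s for s in surfaces if spec.term_weights.get(s, 0.0) > 0]
        weights = np.array([spec.term_weights[s] for s in weighted], dtype=float)
        weights /= weights.sum()
    else:
        weighted = surfaces
        weights = np.full(len(surfaces), 1.0 / len(surfaces))

    # Filler sentences must not accidentally plant a search term.
    fillers = [s for s in _FILLER_SENTENCES if not _contains_lexicon_surface(s, lexicon, False)]
    if not fillers:
        raise ValueError("no filler sentence is free of lexicon terms; extend the template pool")

    exclusion_words = list(lexicon.exclusion_words)

    # Visits per child: negative binomial with mean mu and shape k (variance
    # mu + mu^2/k), clipped to at least one visit.
    mu, k = spec.mean_visits_per_child, spec.dispersion
    counts = label_rng.negative_binomial(k, k / (k + mu), size=spec.n_children)
    counts = np.maximum(counts, 1)

    records: list[VisitRecord] = []
    gold: list[GoldLabel] = []
    provenance: list[VisitProvenance] = []

    for child_idx in range(spec.n_children):
        child_id = f"c{child_idx:04d}"
        visit_day = date(2010, 1, 1)
        for visit_idx in range(int(counts[child_idx])):
            visit_id = f"{child_id}-v{visit_idx:03d}"
            # --- label stream: category decides the gold label -------------
            if label_rng.random() < spec.prevalence:
                construction = "positive"
            else:
                u = label_rng.random()
                if u < spec.negation_rate and exclusion_words:
                    construction = "negation"
                elif u < spec.negation_rate + spec.confounder_rate:
                    construction = "confounder"
                elif u < spec.negation_rate + spec.confounder_rate + spec.family_mention_rate:
                    construction = "family"
                else:
                    construction = "filler"
            # --- text stream: render the note ------------------------------
            planted_term = planted_excl = None
            filler = fillers[text_rng.integers(0, len(fillers))]
            filler = _apply_typos(filler, spec.misspelling_rate, text_rng, lexicon)
            if construction == "positive":
                planted_term = weighted[text_rng.choice(len(weighted), p=weights)]
                pool = _pick_templates(
                    _POSITIVE_TEMPLATES, lexicon, slots={"term": ""}, forbid_exclusions=True
                )
                if not pool:
                    raise ValueError("no affirmative template is free of lexicon surfaces")
                template = pool[text_rng.integers(0, len(pool))]
                planted = template.format(term=planted_term)
                if spec.corrupt_planted_terms:
                    planted = _apply_typos_unchecked(planted, spec.misspelling_rate, text_rng)
                text = f"{planted}. {filler}"
                # positives must carry no exclusion word anywhere
                if not spec.corrupt_planted_terms:
                    filler_ok = not _contains_lexicon_surface(
                        filler, lexicon, include_exclusions=True
                    )
                    if not filler_ok:
                        text = planted
            elif construction == "negation":
                planted_term = weighted[text_rng.choice(len(weighted), p=weights)]
                word = exclusion_words[text_rng.integers(0, len(exclusion_words))]
                planted_excl = word.surface
                pool = _pick_templates(
                    _NEGATION_TEMPLATES, lexicon, slots={"term": "", "excl": ""}, forbid_exclusions=False
                )
                template = pool[text_rng.integers(0, len(pool))] if pool else _NEGATION_TEMPLATES[0]
                text = f"{template.format(term=planted_term, excl=planted_excl)}. {filler}"
            elif construction == "confounder":
                template = _CONFOUNDER_TEMPLATES[text_rng.integers(0, len(_CONFOUNDER_TEMPLATES))]
                text = f"{template}. {filler}"
                planted_term = "ROM"
            elif construction == "family":
                template = _FAMILY_TEMPLATES[text_rng.integers(0, len(_FAMILY_TEMPLATES))]
                text = f"{template}. {filler}"
                planted_term = "otitis media"
            else:
                second = fillers[text_rng.integers(0, len(fillers))]
                second = _apply_typos(second, spec.misspelling_rate, text_rng, lexicon)
                text = f"{filler}. {second}"

            visit_day = visit_day + timedelta(days=int(text_rng.integers(1, 30)))
            records.append(
                VisitRecord(
                    child_id=child_id,
                    visit_id=visit_id,
                    text=text,
                    visit_date=visit_day.isoformat(),
                )
            )
            gold.append(GoldLabel(visit_id=visit_id, om_considered=construction == "positive"))
            provenance.append(
                VisitProvenance(
                    visit_id=visit_id,
                    construction=construction,
                    planted_term=planted_term,
                    planted_exclusion=planted_excl,
                )
            )
    return LabelledCorpus(records=tuple(records), gold=tuple(gold), provenance=tuple(provenance))


def _apply_typos_unchecked(fragment: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return fragment
    chars = list(fragment)
    i = 0
    while i < len(chars):
        if chars[i].isalpha() and rng.random() < rate:
            op = rng.integers(0, 3)
            if op == 0:
                chars[i] = _ALPHABET[rng.integers(0, 26)]
            elif op == 1 and i + 1 < len(chars):
                chars[i], chars[i + 1] = chars[i + 1], chars[i]
            else:
                del chars[i]
        i += 1
    return "".join(chars)


def corpus_summary(corpus: LabelledCorpus) -> dict:
    """Shape summary: children, visits, per-child distribution, positives."""
    per_child: dict[str, int] = {}
    for r in corpus.records:
        per_child[r.child_id] = per_child.get(r.child_id, 0) + 1
    counts = np.array(list(per_child.values())) if per_child else np.array([0])
    n_positive = sum(1 for g in corpus.gold if g.om_considered)
    n_visits = len(corpus.records)
    return {
        "n_children": len(per_child),
        "n_visits": n_visits,
        "visits_per_child": {
            "min": int(counts.min()),
            "median": float(np.median(counts)),
            "mean": float(counts.mean()),
            "max": int(counts.max()),
        },
        "n_om_considered": n_positive,
        "pct_om_considered": 100.0 * n_positive / n_visits if n_visits else 0.0,
    }


@dataclass(frozen=True)
class ClosedLoopResult:
    stats: DiagnosticStats
    corpus: LabelledCorpus


def closed_loop_check(
    spec: SyntheticCorpusSpec, lexicon: Lexicon, level: float = 0.95
) -> ClosedLoopResult:
    """Generate, screen, evaluate: the end-to-end validation mirror."""
    corpus = generate_corpus(spec, lexicon)
    results = screen_corpus(list(corpus.records), lexicon)
    cm = build_confusion(results, corpus.gold)
    return ClosedLoopResult(stats=diagnostic_stats(cm, level=level), corpus=corpus)


def write_corpus(corpus: LabelledCorpus, out_dir: Union[str, Path]) -> dict[str, Path]:
    """Write records.jsonl, gold.csv, provenance.jsonl and summary.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "records": out_dir / "records.jsonl",
        "gold": out_dir / "gold.csv",
        "provenance": out_dir / "provenance.jsonl",
        "summary": out_dir / "summary.json",
    }
    write_records(corpus.records, paths["records"])
    write_gold_labels({g.visit_id: g.om_considered for g in corpus.gold}, paths["gold"])
    with open(paths["provenance"], "w", encoding="utf-8") as fh:
        for p in corpus.provenance:
            fh.write(
                json.dumps(
                    {
                        "visit_id": p.visit_id,
                        "construction": p.construction,
                        "planted_term": p.planted_term,
                        "planted_exclusion": p.planted_exclusion,
                    }
                )
                + "\n"
            )
    with open(paths["summary"], "w", encoding="utf-8") as fh:
        json.dump(corpus_summary(corpus), fh, indent=2)
    return paths
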