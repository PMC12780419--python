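"""Diagnostic-accuracy panel: confusion matrix, exact intervals, likelihood ratios.

Algorithm output is compared with the gold-standard clinician labels to form
a 2x2 confusion matrix, from which the full panel is derived:

- sensitivity, specificity, PPV, NPV with Clopper-Pearson exact binomial
  confidence intervals (beta-quantile formulation);
- positive/negative likelihood ratios with log-method intervals, where
  ``var(ln LR+) = 1/tp - 1/(tp+fn) + 1/fp - 1/(fp+tn)`` and
  ``var(ln LR-) = 1/fn - 1/(tp+fn) + 1/tn - 1/(fp+tn)``;
- the workload-reduction proportion ``1 - flagged/total``.

Zero cells make an estimate degenerate; degenerate estimates are reported as
such (no continuity correction by default; an optional Haldane +0.5
correction for the likelihood ratios is available but off by default).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Optional, Sequence

from scipy import stats as _stats

from .matcher import ScreenResult

__all__ = [
    "GoldLabel",
    "ConfusionMatrix",
    "IntervalEstimate",
    "DiagnosticStats",
    "LabelAlignmentError",
    "DegenerateEstimateError",
    "build_confusion",
    "proportion_ci",
    "lr_ci",
    "diagnostic_stats",
    "workload_reduction",
]


class LabelAlignmentError(ValueError):
    """Results and gold labels do not cover the same visit ids."""


class DegenerateEstimateError(ValueError):
    """A zero cell makes the requested estimate infinite, zero or undefined."""


@dataclass(frozen=True)
class GoldLabel:
    visit_id: str
    om_considered: bool


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 validation counts (algorithm vs gold standard)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def flagged(self) -> int:
        return self.tp + self.fp

    @property
    def gold_positive(self) -> int:
        return self.tp + self.fn

    @property
    def gold_negative(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class IntervalEstimate:
    """Point estimate with a two-sided confidence interval."""

    point: float
    lower: float
    upper: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if not (0.0 < self.level < 1.0):
            raise ValueError(f"confidence level must be in (0,1), got {self.level}")
        if math.isfinite(self.point) and not (self.lower <= self.point <= self.upper):
            raise ValueError(
                f"interval ({self.lower}, {self.upper}) does not contain point {self.point}"
            )


def build_confusion(
    results: Sequence[ScreenResult], gold: Iterable[GoldLabel]
) -> ConfusionMatrix:
    """Tabulate algorithm output against gold labels.

    Every result must have a gold label and vice versa; orphans on either
    side are an error (no silent dropping), as is an empty input.
    """
    gold_map: dict[str, bool] = {}
    for g in gold:
        if g.visit_id in gold_map:
            raise LabelAlignmentError(f"duplicate gold label for visit {g.visit_id!r}")
        gold_map[g.visit_id] = g.om_considered
    result_ids = [r.visit_id for r in results]
    if len(set(result_ids)) != len(result_ids):
        raise LabelAlignmentError("duplicate visit_id in results")
    missing_gold = sorted(set(result_ids) - set(gold_map))
    missing_results = sorted(set(gold_map) - set(result_ids))
    if missing_gold or missing_results:
        raise LabelAlignmentError(
            f"unmatched visit ids: {len(missing_gold)} without gold labels "
            f"{missing_gold[:10]}, {len(missing_results)} without results "
            f"{missing_results[:10]}"
        )
    if not results:
        raise LabelAlignmentError("no visits to evaluate")
    tp = fp = fn = tn = 0
    for r in results:
        positive = gold_map[r.visit_id]
        if r.flagged and positive:
            tp += 1
        elif r.flagged and not positive:
            fp += 1
        elif not r.flagged and positive:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def proportion_ci(successes: int, trials: int, level: float = 0.95) -> IntervalEstimate:
    """Clopper-Pearson exact binomial interval (beta-quantile formulation).

    ``lower = Beta(alpha/2; k, n-k+1)`` quantile (0 when k=0) and
    ``upper = Beta(1-alpha/2; k+1, n-k)`` quantile (1 when k=n).
    """
    if trials < 1:
        raise DegenerateEstimateError("proportion undefined: zero trials")
    if not (0 <= successes <= trials):
        raise ValueError(f"need 0 <= successes <= trials, got {successes}/{trials}")
    alpha = 1.0 - level
    k, n = successes, trials
    lower = 0.0 if k == 0 else float(_stats.beta.ppf(alpha / 2.0, k, n - k + 1))
    upper = 1.0 if k == n else float(_stats.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return IntervalEstimate(point=k / n, lower=lower, upper=upper, level=level)


def _lr_cells(cm: ConfusionMatrix, which: str) -> tuple[float, float, float, float]:
    tp, fp, fn, tn = float(cm.tp), float(cm.fp), float(cm.fn), float(cm.tn)
    if which == "positive":
        # numerator proportion tp/(tp+fn), denominator fp/(fp+tn)
        bad = [c for c, v in (("tp", tp), ("fp", fp)) if v == 0]
    else:
        bad = [c for c, v in (("fn", fn), ("tn", tn)) if v == 0]
    if tp + fn == 0 or fp + tn == 0:
        raise DegenerateEstimateError("likelihood ratio undefined: empty gold class")
    if bad:
        raise DegenerateEstimateError(
            f"LR{'+' if which == 'positive' else '-'} degenerate: zero cell(s) {bad}"
        )
    return tp, fp, fn, tn


def lr_ci(
    cm: ConfusionMatrix,
    which: Literal["positive", "negative"],
    level: float = 0.95,
) -> IntervalEstimate:
    """Likelihood-ratio interval by the log method (delta-method variance).

    Raises :class:`DegenerateEstimateError` when a zero cell makes the LR
    infinite or zero rather than returning a number.
    """
    if which not in ("positive", "negative"):
        raise ValueError(f"which must be 'positive' or 'negative', got {which!r}")
    tp, fp, fn, tn = _lr_cells(cm, which)
    return _lr_ci_from_cells(tp, fp, fn, tn, which, level)


def _lr_ci_from_cells(
    tp: float, fp: float, fn: float, tn: float, which: str, level: float
) -> IntervalEstimate:
    sens = tp / (tp + fn)
    spec = tn / (fp + tn)
    if which == "positive":
        point = sens / (1.0 - spec)
        variance = 1.0 / tp - 1.0 / (tp + fn) + 1.0 / fp - 1.0 / (fp + tn)
    else:
        point = (1.0 - sens) / spec
        variance = 1.0 / fn - 1.0 / (tp + fn) + 1.0 / tn - 1.0 / (fp + tn)
    z = float(_stats.norm.ppf(1.0 - (1.0 - level) / 2.0))
    half = z * math.sqrt(variance)
    return IntervalEstimate(
        point=point,
        lower=math.exp(math.log(point) - half),
        upper=math.exp(math.log(point) + half),
        level=level,
    )


def workload_reduction(cm: ConfusionMatrix) -> float:
    """Proportion of visits the screen removes from clinician review."""
    if cm.total < 1:
        raise DegenerateEstimateError("workload reduction undefined: empty corpus")
    return 1.0 - cm.flagged / cm.total


@dataclass(frozen=True)
class DiagnosticStats:
    """The full accuracy panel; degenerate estimates are None with a reason."""

    confusion: ConfusionMatrix
    sensitivity: Optional[IntervalEstimate]
    specificity: Optional[IntervalEstimate]
    ppv: Optional[IntervalEstimate]
    npv: Optional[IntervalEstimate]
    lr_positive: Optional[IntervalEstimate]
    lr_negative: Optional[IntervalEstimate]
    workload_reduction: float
    level: float = 0.95
    degenerate: Mapping[str, str] = field(default_factory=dict)

    _PROPORTIONS = ("sensitivity", "specificity", "ppv", "npv")
    _RATIOS = ("lr_positive", "lr_negative")

    def to_dict(self) -> dict:
        """Full-precision machine output."""
        out: dict = {
            "confusion": {
                "tp": self.confusion.tp,
                "fp": self.confusion.fp,
                "fn": self.confusion.fn,
                "tn": self.confusion.tn,
                "total": self.confusion.total,
                "flagged": self.confusion.flagged,
            },
            "level": self.level,
            "workload_reduction": self.workload_reduction,
            "degenerate": dict(self.degenerate),
        }
        for name in self._PROPORTIONS + self._RATIOS:
            est: Optional[IntervalEstimate] = getattr(self, name)
            out[name] = (
                None
                if est is None
                else {"point": est.point, "lower": est.lower, "upper": est.upper}
            )
        return out

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def rounded(self) -> dict[str, str]:
        """Presentation values: percentages and LRs to 2 decimal places."""
        out: dict[str, str] = {}
        for name in self._PROPORTIONS:
            est = getattr(self, name)
            out[name] = (
                "degenerate"
                if est is None
                else f"{100 * est.point:.2f}% ({100 * est.lower:.2f}% to {100 * est.upper:.2f}%)"
            )
        for name in self._RATIOS:
            est = getattr(self, name)
            out[name] = (
                "degenerate"
                if est is None
                else f"{est.point:.2f} ({est.lower:.2f} to {est.upper:.2f})"
            )
        out["workload_reduction"] = f"{100 * self.workload_reduction:.0f}%"
        return out

    def abstract_style(self) -> dict[str, str]:
        """Whole-percent presentation for proportions, 2 dp for LRs."""
        out: dict[str, str] = {}
        for name in self._PROPORTIONS:
            est = getattr(self, name)
            out[name] = (
                "degenerate"
                if est is None
                else f"{100 * est.point:.0f}% ({100 * est.lower:.0f}%-{100 * est.upper:.0f}%)"
            )
        for name in self._RATIOS:
            est = getattr(self, name)
            out[name] = (
                "degenerate"
                if est is None
                else f"{est.point:.2f} ({est.lower:.2f}-{est.upper:.2f})"
            )
        return out

    def to_markdown(self) -> str:
        cm = self.confusion
        rows = self.rounded()
        lines = [
            "| Parameter | Estimate (95% CI) |",
            "| --- | --- |",
            f"| Sensitivity | {rows['sensitivity']} |",
            f"| Specificity | {rows['specificity']} |",
            f"| Positive predictive value | {rows['ppv']} |",
            f"| Negative predictive value | {rows['npv']} |",
            f"| Positive likelihood ratio | {rows['lr_positive']} |",
            f"| Negative likelihood ratio | {rows['lr_negative']} |",
            f"| Visits flagged for review | {cm.flagged} of {cm.total} |",
            f"| Workload reduction | {rows['workload_reduction']} |",
        ]
        return "\n".join(lines)


def diagnostic_stats(
    cm: ConfusionMatrix, level: float = 0.95, haldane: bool = False
) -> DiagnosticStats:
    """Compute the six-estimate panel plus workload reduction.

    A degenerate estimate (zero denominator or zero LR cell) is reported as
    ``None`` with its reason under ``degenerate`` and does not abort the
    others.  ``haldane=True`` adds 0.5 to every cell for the *likelihood
    ratio* estimates only; the proportions always use the raw integer counts
    (Clopper-Pearson needs them).
    """
    if cm.total < 1:
        raise DegenerateEstimateError("empty confusion matrix")
    degenerate: dict[str, str] = {}

    def _prop(name: str, k: int, n: int) -> Optional[IntervalEstimate]:
        try:
            return proportion_ci(k, n, level)
        except DegenerateEstimateError as exc:
            degenerate[name] = str(exc)
            return None

    sens = _prop("sensitivity", cm.tp, cm.gold_positive)
    spec = _prop("specificity", cm.tn, cm.gold_negative)
    ppv = _prop("ppv", cm.tp, cm.flagged)
    npv = _prop("npv", cm.tn, cm.fn + cm.tn)

    def _ratio(name: str, which: str) -> Optional[IntervalEstimate]:
        if haldane:
            # +0.5 on every cell keeps the LRs finite with zero cells.
            return _lr_ci_from_cells(
                cm.tp + 0.5, cm.fp + 0.5, cm.fn + 0.5, cm.tn + 0.5, which, level
            )
        try:
            return lr_ci(cm, which, level)  # type: ignore[arg-type]
        except DegenerateEstimateError as exc:
            degenerate[name] = str(exc)
            return None

    lrp = _ratio("lr_positive", "positive")
    lrn = _ratio("lr_negative", "negative")
    return DiagnosticStats(
        confusion=cm,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        lr_positive=lrp,
        lr_negative=lrn,
        workload_reduction=workload_reduction(cm),
        level=level,
        degenerate=degenerate,
    )
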