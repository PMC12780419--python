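# omscreen

Lexicon-based screening of free-text primary care visit notes for otitis
media (OM), with a diagnostic-accuracy evaluation harness and a synthetic
corpus generator.

Uncoded primary care records make large-scale case identification
impractical by clinician review alone. `omscreen` implements a screening
algorithm that scans each visit's free text for OM-related search terms
(words, phrases, and abbreviations such as `OM`, `AOM`, `ROM`, `T/M`),
applies an exclusion-word combination rule (e.g. a tympanic-membrane term
next to `normal` means OM was ruled out), and flags the subset of visits
requiring clinician review. The package also models the surrounding
workflow: independent multi-reviewer labelling with consensus adjudication,
discrepancy reporting against the algorithm, the full diagnostic-accuracy
panel (sensitivity, specificity, predictive values, likelihood ratios, all
with 95% confidence intervals), and a seeded synthetic corpus generator so
the whole pipeline is testable with no real patient data.

## Library overview

| Module | Purpose |
| --- | --- |
| `omscreen.lexicon` | Load/save/merge rule sets (search terms, exclusion words, combination policy); ships a seed OM lexicon |
| `omscreen.matcher` | Boundary-respecting term matching, exclusion-combination rule, per-visit flagging |
| `omscreen.evaluation` | Confusion matrix, Clopper–Pearson exact intervals, log-method LR intervals, workload reduction |
| `omscreen.review` | Reviewer adjudication, FP/FN discrepancy reports, exclusion-candidate ranking, review worksheets |
| `omscreen.synthetic` | Seeded synthetic corpora with known gold labels (negations, ambiguous abbreviations, family mentions, misspellings) |
| `omscreen.cli` | `omscreen` command-line tool |

```python
import omscreen as om

lex = om.seed_lexicon()
result = om.screen_visit(om.VisitRecord("c1", "v1", "TM normal but L ear AOM"), lex)
# the negated TM finding is excluded; the AOM term keeps the visit flagged
assert result.flagged

cm = om.ConfusionMatrix(tp=801, fp=412, fn=116, tn=8705)
print(om.diagnostic_stats(cm).to_markdown())
```

The combination policy is configurable: `phrase` (adjacent token), `window`
(default, 3 tokens, bidirectional), `sentence`, or `record` scope.

## CLI

```sh
# generate a synthetic labelled corpus (seed required; fully deterministic)
omscreen simulate --out-dir corpus --seed 42

# screen it against the seed lexicon (or any YAML/CSV lexicon file)
omscreen lexicon-validate mylexicon.yaml
omscreen screen corpus/records.jsonl mylexicon.yaml --out results.jsonl

# evaluate against gold labels -> JSON + Markdown accuracy panel
omscreen evaluate results.jsonl corpus/gold.csv --out report.json

# inspect disagreements and candidate exclusion words
omscreen discrepancies results.jsonl corpus/gold.csv corpus/records.jsonl \
    --out discrepancies.csv --lexicon mylexicon.yaml

# combine independent reviewer labels (no automatic majority vote)
omscreen adjudicate reviewer_labels.csv --out adjudicated.csv
```

Policy overrides (`--mode`, `--window-tokens`, `--bidirectional`) on
`screen` take precedence over the lexicon file, supporting the
iterate-and-re-run refinement loop without editing data files.

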