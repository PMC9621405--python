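# Methods

## Labeling model

The labeler is a dictionary system with an explicit normality shortcut.
Let `d` be a report description after canonicalization (Unicode NFC,
lower case, single-spaced, all dash characters unified). Given a lexicon
with normality templates `T`, per-class keyword sets `K_c` for
`c ∈ {chest_wall, pleura, parenchyma, cardio}` and an other-abnormality
set `K_o`:

```
class_c(d)  = 1  iff some k ∈ K_c is a substring of d
other(d)    = 1  iff some k ∈ K_o is a substring of d
abnormal(d) = class_cw ∨ class_pl ∨ class_pa ∨ class_ca ∨ other
normal(d)   = 1  iff some t ∈ T is a substring of d
```

Decision order: any keyword hit ⇒ auto-label with the flags above; else a
template hit ⇒ the all-zero vector; else the description goes to a manual
queue for human annotation. The model assumes normality is expressed by
fixed template phrasings rather than negated findings, which holds for
report-template-driven HIS deployments; there is deliberately **no
negation handling** — a negated finding whose phrasing is not a template
falls through to the manual queue rather than being silently labeled.

Design choices where the procedure was genuinely open:

* **"Exactly appears" = substring containment** after normalization, not
  whole-string equality, because reports wrap templates in
  patient-specific boilerplate. The stricter reading remains available via
  `annotate(..., template_match="equals")`.
* **Keyword beats template** when a description matches both: abnormal
  evidence should not be erased by boilerplate, and the case is logged as
  a lexicon-conflict warning so the lexicon can be repaired.
* **Keyword search scans the whole description**, not per dash-separated
  section; the sections (`split_sections`) are kept for lexicon curation
  only. A dash opens a section when it is not glued to a word on its left,
  so intra-word hyphens ("x-quang") never split.
* **Shorthand expansion**: `trái/phải` (left/right) alternations expand to
  both variants; a parenthesized abbreviation such as `(đmc)` expands to
  the spelled-out phrase and, when the abbreviation's letters match the
  initials of the preceding words, to the abbreviated phrase
  (`quai đmc vồng`). At most one alternation per keyword.
* The shipped lexicon contains example keywords per class plus **eleven
  synthetic normality templates**: real deployed template inventories are
  site-specific and unpublished, so the lexicon is a required, editable
  input and the packaged file is a seed.

## Record matching

A study pairs with a report iff the patient ids agree, the report was
written within 24 hours of the study (read two-sided and inclusive —
`|Δt| ≤ 24 h` — since a reporting-protocol window does not fix the sign),
and the study time lies in the closed session interval
`[check_in, check_out]`. Duplicate candidates with identical normalized
descriptions are interchangeable; the earliest `report_time` (ties broken
by session id) is chosen for determinism. Differing candidates are a true
ambiguity and go to manual review. One report may serve several studies
(repeat acquisitions in one session); each study receives at most one
report. The PA-view probability threshold is strict (`p > 0.5`).
Timestamps are parsed as ISO-8601 on a single hospital clock; no timezone
arithmetic is attempted.

## Evaluation

Per-class precision `TP/(TP+FP)`, recall `TP/(TP+FN)`,
`F1 = 2PR/(P+R)`; macro averages are unweighted means over classes.
Zero-denominator convention: the metric is reported as 1.0 with a
`degenerate` flag ("no predictions, no mistakes"), keeping macro averages
defined for perfect classes; the pessimistic 0.0 convention is selectable.
Metrics are carried at full precision; table output rounds half-up to 4
decimals (2 for percentages).

Confidence intervals are nonparametric percentile bootstrap: instances
(rows) are resampled with replacement at the original n, the statistic is
recomputed per replicate (3,000 by default), and the 2.5/97.5 percentiles
are reported. With a single replicate the interval degenerates to that
replicate's statistic. If more than half the replicates have a degenerate
denominator the fixture is too small and an error advises enlarging it.

The 7/3 train/validation split uses greedy iterative stratification:
labels are processed rarest-first, each row is assigned to the fold with
the largest remaining desired count for that label (then largest remaining
capacity), and unlabeled rows fill the folds to exact size
`round(0.7·n)`. The procedure is deterministic for a fixed seed. On a
10,000-row corpus at the default prevalences the worst per-class
prevalence gap between a fold and the full set is well under one
percentage point.

## Synthetic data

`generate_corpus` emulates the structure of the target reports: a
four-category, dash-separated description (chest wall — pleura —
parenchyma — cardio), benign filler sentences for negative categories, a
lexicon keyword embedded per positive category, an optional extra segment
for other-abnormality findings, and whole-report normality templates for
negative studies. Per-class positivity is sampled independently at the
deployment-scale marginals (chest wall 2.37%, pleura 2.22%, parenchyma
21.72%, cardio 7.83%); marginals are all the deployment reports, so no
label-correlation model is attempted — under independence the abnormal
marginal (~31%) sits slightly above the deployed 28.23%, which is
acceptable for pipeline testing. The other-abnormality rate defaults to
0.5% (such findings are rare and the lexicon carries a single example
list). Misspelling noise corrupts, with probability `misspell_rate` per
keyword-bearing report, **every** embedded keyword by one character
substitution (corrupting only one of several would yield a wrong partial
auto-label; the intended failure mode is the manual queue, never a silent
mislabel). The default rate of 1% puts roughly 0.3% of reports in the
manual queue, consistent with a well-curated deployment (< 0.5%).
`generate_matching_fixture` likewise emits studies plus a conforming HIS
XML with known pairings, injecting duplicate-report cases (identical and
differing descriptions) and reports displaced 30 h from the study.

What passing on synthetic data does and does not show: the generators
exercise the pipeline's contracts (recovery of known labels, routing of
corrupted evidence, duplicate and window handling) but use clean
keyword placement and fixed fillers; real reports have richer phrasing,
abbreviation drift and genuinely ambiguous findings, so real-world labeler
accuracy depends on lexicon completeness, which only deployment-site
curation (the manual queue plus the 5% quality-control resampling loop)
can establish.

## Numerical and degenerate-input conventions

* Normalization is idempotent and total on strings; empty descriptions go
  to the manual queue with a warning.
* The quality-control sample draws `⌈fraction·n⌉` rows without
  replacement.
* CheXpert uncertainty labels (−1) are outside the binary mapping table;
  `batch_map` resolves them by flag (`to_negative` default). A positive
  No Finding alongside positive observations warns and the positives win.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); every generator and resampler is a pure
  function of (configuration, seed).

## Known limitations

* Substring matching cannot distinguish negated from affirmed findings if
  a lexicon keyword appears inside a negation ("không thấy gãy xương"
  would label chest wall positive). Deployed lexicons must encode
  normality as templates, as the scheme assumes.
* The matcher assumes one manifest row per study and comparable clocks; it
  does not reproduce PACS-level file/study grouping.
* Fine-to-coarse mapping loses the identity of the finding; it is meant
  for transfer-learning label alignment, not clinical reporting.
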