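# Methods

## Problem setting

The package automates extraction of staging and recurrence-risk fields
from thyroid cancer surgical pathology narratives by posing natural-language
questions against each report. Because answer backends have a bounded
context window, the pipeline's core is context construction: deciding what
part of a long report a backend gets to read for each question. Evaluation
follows the inter-rater paradigm: two answer sources are compared cell by
cell on a report × question grid, and agreement is summarized per question
and overall.

## Context construction

A report is used whole when its token count is within the backend budget
(default 2048). The token counter is pluggable with a whitespace-token
default: counters are a property of individual backends, and a whitespace
count is deterministic, backend-agnostic, and slightly conservative
relative to subword tokenizers on clinical prose.

Longer reports are split into consecutive 1200-character segments at raw
character offsets. Splits may cut words; segments do not overlap, because
adjacent segments are usually re-selected together and overlap would
complicate the offset arithmetic without measurably helping retrieval at
this segment size. Each segment and the bare question text (not the full
prompt — instruction boilerplate would only add noise to the similarity)
are embedded and scored by cosine similarity; the top k = 3 segments are
selected, ties broken toward the lower (earlier) segment index so results
are total-order deterministic.

Selected segments are assembled **in document order**, preserving narrative
coherence; the similarity ranking is retained in metadata. Runs of
consecutive segments are spliced back verbatim from the original text, so a
word cut at a segment boundary is restored; a single newline separates
non-contiguous runs. (Inserting separators between adjacent selected
segments would corrupt exactly the tokens — "5.5 c|m" — that retrieval is
meant to surface.)

The default embedder hashes lowercase word tokens (CRC32, stable across
processes and runs) into a 32768-dimension vector of sublinear term
frequencies (1 + ln count), unit-normalized. Dimension 32768 keeps the
collision probability negligible for report-sized vocabularies while the
vectors stay cheap. Empty text maps to a flagged zero vector whose
similarity against anything is defined as 0. Dense sentence-embedding
models plug in through the same contract (deterministic text → fixed-length
vector) but are deliberately outside the test surface: the shipped pipeline
must be runnable and reproducible with no model downloads.

`top_k`, `segment_length`, `token_limit`, and the embedding dimension are
exposed as pipeline configuration (YAML-loadable).

## Question schema and prompts

The default schema has 12 items: size, capsular extension and location
(T group); node presence and positive-node count (N); the pathologic TNM
token (TNM); and vascular invasion, lymphatic invasion, histology,
aggressive variant, second cancer and its histology (recurrence risk).
Conditional items resolve to `not_applicable` when their trigger is false
(no nodes examined; no second cancer), and `not_applicable` on both sides
counts as concordant — every grid cell is always answered, keeping the
84 × 12 = 1008 arithmetic exact.

Prompt construction is pure substitution of context and question into a
template with exactly one placeholder each; template wording is
configuration, not logic, and a default instruction-style template is
shipped.

## The reference backend

The rule-based reference backend makes the pipeline testable end to end
with zero stochastic components. Its per-question logic encodes documented
failure modes of generative extraction from pathology text:

* **Size**: a dimension counts only if its sentence mentions the tumor
  itself; three-dimensional specimen measurements (whole-lobe dimensions)
  are rejected, so a report whose only dimension is "right lobe measures
  4.2 x 3.0 x 2.1 cm" yields *not stated* rather than a wrong size.
* **Booleans**: topic keyword plus in-sentence negation detection
  (not/no/absent/without/negative for/free of).
* **Nodes**: "x of y … lymph nodes" patterns, digits or number words; an
  explicit "no lymph nodes identified" resolves the conditional count
  question to *not applicable*. The logic keys on "lymph node", never on
  the word "cervical", which most reports do not contain verbatim.
* **TNM**: pT token scan, case-normalized to the T token (pT3a → T3a).
* **Histology/variant/location**: controlled-vocabulary scan with
  second-cancer sentences excluded from primary-histology matching.

Normalization is total (unparseable → `not_stated`), unit-aware (mm → cm),
and idempotent on canonical phrasings. Backend failures degrade to
`not_stated` and the run continues.

`not_stated` is kept distinct from `false` at extraction time; equating
them is an evaluation-policy decision (below), not a property of the data.

## Synthetic corpus

The generator emulates an institutional corpus: per-report category
sampled from fixed proportions (default 84/102 malignant thyroid, 10
other-organ, 2 benign, 5 cytopathology, 1 outside review — the composition
of a realistic surgical query, realized exactly via largest-remainder
rounding), and for malignant reports a truth record with size ~ log-uniform
on [0.3, 6.5] cm, gross ETE 10%, right/left/isthmus 45/45/10, nodes
examined 0 with probability 0.35 else 1–12, vascular 20%, lymphatic 15%,
papillary/follicular/medullary 80/12/8, aggressive variants in 20% of
papillary cases, second cancers 15%. The rendered TNM token is derived from
the staging rules, never sampled, so text and truth cannot disagree.

Reports render in prose, synoptic or mixed style with specimen, gross
description and diagnosis sections. Realism features that matter for
retrieval and extraction: whole-lobe distractor dimensions in the gross
description; node sections labeled by level/compartment with "cervical"
appearing only with probability 0.2; tumor sizes in mm for 15% of reports;
and a `long_fraction` (default 0.3) of reports padded with
extraction-neutral boilerplate past the token budget, forcing the
segmentation path. The length distribution of real report corpora is not
publicly characterized, so `long_fraction` is an uncalibrated free
parameter. Every ground-truth fact is stated by a sentence literally
present in the text, recorded per question for hit-rate measurement.
Generation is deterministic per (n, seed, config): per-report RNG streams
are keyed on string-hashed (seed, index), immune to process hash
randomization.

What passing tests show — and do not. Exact full-text recovery and ≥95%
retrieval concordance on this corpus demonstrate that the pipeline
machinery (budget check, segmentation, ranking, assembly, conditional
handling, normalization, evaluation arithmetic) is correct, and that
fixed-length retrieval keeps answer-bearing text in context at realistic
report lengths. They do not estimate real-world extraction accuracy: the
generator's sentence inventory is a small grammar, whereas real reports
vary in dialect, abbreviation, OCR noise and layout far beyond it, and a
generative backend replaces the rule-based one in deployment.

## Staging rules

T category: gross ETE ⇒ T3b; else size ≤1 cm T1a, ≤2 cm T1b, ≤4 cm T2,
>4 cm T3a (inclusive upper bounds). N: any positive node ⇒ N1. Recurrence
tier: gross ETE ⇒ high; else vascular invasion, any aggressive variant or
nodal disease ⇒ intermediate; else low. This is a deliberately simplified,
versioned subset (no T4, no N1a/N1b, no M, no microscopic-ETE nuance, no
age-dependent stage groups) — sufficient for the 12-question schema, with
thresholds in an auditable YAML data file. Full-guideline fidelity is not
claimed.

## Concordance evaluation

Typed comparison: sizes equal after rounding to 0.1 cm; TNM compared
case-insensitively on the T token; enums exact; for boolean absence-type
questions the default policy equates `not_stated` with `false` (pathology
reports omit pertinent negatives routinely; silence read as absence is a
judgment about the same fact), switchable off for strict audits.

Overall agreement is reported under **both** framings — mean of the 12
per-question rates (with SD) and the pooled ratio of summed counts — since
they differ at the third digit whenever disagreements cluster by question.
The SD uses the sample (n−1) convention as the headline, with the
population convention in metadata. Pairings are compared with two-sided
t tests on per-question rates, paired by default (the 12 questions are
shared units), Welch's unpaired test by flag; identical vectors return
p = 1.0 rather than the indeterminate 0/0 statistic. Chance-corrected
agreement (kappa) and bootstrap intervals are out of scope. Per-answer
timing is logged but never compared — it is hardware-bound.

## Problem sizes and numerical choices

Tests and the acceptance script run the full pipeline on a 102-report
corpus (84 malignant × 12 questions = 1008 cells), a 200-report all-long
corpus for the hit-rate property, 1000-instance oracle-equivalence and
segmentation sweeps, and complete in well under a minute on one CPU —
chosen as the smallest sizes at which every code path (long and short
reports, all styles, all answer types, conditional triggers) is exercised
with comfortable margins. Cosine similarity is computed in float64;
unit-norm assertions use 1e−9, symmetry/scale-invariance properties 1e−12.

## Known limitations

* The hashed-TF embedder has no synonymy: a question phrased with
  vocabulary absent from the answer sentence ("histology" vs "histologic
  type") can miss its segment; this is the dominant residual error on the
  synthetic corpus and the motivation for pluggable dense embedders.
* The reference backend's rules are tuned to the generator's sentence
  grammar plus common real-world phrasings; it is a pipeline oracle, not a
  clinical extraction system.
* Retrieval carries no answerability guarantee: if the top-3 segments omit
  the evidence, the backend sees silence and the policy maps it to "no"
  for absence-type booleans — correct for true negatives, wrong for missed
  positives. This mirrors the deployed failure mode rather than hiding it.
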