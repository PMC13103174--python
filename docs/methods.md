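# Methods

## Problem setting

Pixel-level de-identification of medical images requires finding text that
was rendered ("burned") into the pixels and deciding whether it identifies
a person. `phimprint` models this as three stages — localize text regions,
extract (OCR) their content, analyze the text for PHI — and provides the
synthetic data, pluggable pipeline and two-level scoring needed to
benchmark implementations of those stages without access to real PHI.

## Imprint model

An imprint is `<accompanying><separator><main>`: an optional signal word
(`DOB`, `Patient ID`, `Weight`, …) naming the category, a separator drawn
from `{": ", " ", ", "}` (the union of separators seen in practice), and a
category-specific payload. Sixteen categories are registered, six of them
PHI. Content grammars are seeded samplers over shipped lexicons (~25–80
entries per list: names, streets, cities, hospitals, scanners, exam types,
diagnoses) and format pools:

- **date** — four formats (`DD-MM-YYYY`, `MM/DD/YYYY`, `YYYY-MM-DD`,
  `DD Mon YYYY`), years 1950–2024;
- **identifier** — digit/dot/dash shapes covering patient-id, SSN-like,
  MRN-like and insurance-like sequences, sampled uniformly (no published
  sub-grammar weights exist, so uniform is the least-informative choice);
- **age_lt90** — integers strictly below 90 (ages ≥ 90 are identifying and
  belong to the date category by definition);
- **marker** — 1–3 tokens from {L, R, POST, ANT, …}, never accompanied;
- the remaining categories sample their lexicons or unit-bearing numbers.

The accompanying text is omitted with probability 0.2 per imprint
(default; the omission rate is a free parameter — "sometimes omitted" is
the only constraint the setting imposes), which exercises an analyzer's
ability to infer categories from the payload shape alone.
`force_accompanying=True` disables omission; categories with an empty
signal lexicon (markers) always render bare.

## Dataset simulation

Each image is assigned one of three classes with an **exact** allocation:
`round(phi_ratio·n)` images get at least one PHI imprint,
`round(clean_ratio·n)` get none, the remainder get only non-PHI imprints
(rounding is half-up; order shuffled by the seed). Exact rather than
Bernoulli allocation makes printed dataset statistics deterministic. The
default evaluation split is n = 1000, `phi_ratio` 0.85, `clean_ratio` 0.05
(the clean/non-PHI division is not pinned by the setting; 0.05 keeps all
three branches populated), four modality tags partitioned equally.

Styles:

- `test` — at most 8 imprints per image, at most one per category
  (sampling without replacement), **disjoint** boxes; imprint count uniform
  on [1, 8] (the count distribution is otherwise unspecified);
- `train` — same limits, overlap permitted as deliberately hard localizer
  cases; default 6000 images with an 80–20 train/validation split;
- `midi` — 10–30 imprints with replacement across categories, emulating
  DICOM-tag viewer overlays where the same category repeats.

Backgrounds are synthetic grayscale canvases (base shade plus 0–4 filled
boxes in shades ≥ 20 levels away), tagged with a modality label. The
module also ships the generic preprocessing ops used to prepare real
modalities — percentile-clipped min-max 8-bit normalization (clip
percentile uniform in [0, 10]), uniform axial slice sampling
(`linspace` over the index range, round half-down), 3–5-tile horizontal
collages with probability-0.5 intensity inversion (bone-scan viewer
emulation; "flip" is interpreted as display-polarity inversion since a
geometric flip would not change a background), and center cropping (the
stand-in for model-based edge-marker removal, which is out of scope).

Text is rendered with PIL at font sizes 10–28 px from the DejaVu family
(resolved from the installed matplotlib; PIL's default font is the
fallback), with intensity chosen for ≥ 60/255 contrast against the local
mean background. Boxes are tight half-open pixel rectangles from the
rendering engine; render parameters (font, size, intensity, origin) are
stored in the sidecar so any crop can be reproduced from its label.
Placement retries are bounded (50 per imprint, then a full re-layout, up
to 20 layouts) before a placement error is raised.

All randomness flows from a single integer seed through
`numpy.random.SeedSequence.spawn`, one child stream per image, so datasets
are bit-identical across runs and machines for a fixed configuration.

## Pipeline

Backends implement small contracts (localizer, extractor, joint
localizer-extractor, text analyzer, vision analyzer) and are wired into
four setups; all extracted texts of an image are analyzed jointly as one
list (aggregated context), while crop-level vision analysis is one request
per crop — which is why that wiring carries a higher request count in the
built-in counters. Backend exceptions are caught per image and recorded as
failures; the pipeline error rate is `failed/total`. External engine
adapters keep their key knobs here: the OCR adapter's low-bound text
threshold defaults to 0.2 (more generous text regions so single-letter
markers survive), the chat adapter pins temperature to 0 and retries
transient errors twice.

The shipped backends are test doubles by design:

- **oracle localizer / extractor** replay the ground truth (score 1.0,
  stored text; a region matching no label at IoU ≥ 0.5 reads as empty);
- **noisy extractor** corrupts only the *main* text with visually
  confusable substitutions (O↔0, I↔1, S↔5, …) at a per-character rate,
  signal words intact — the error mode OCR actually exhibits;
- **reference analyzer** is a deterministic rule engine: longest-first
  signal-word matching decides the category when an accompanying prefix is
  present (so its decision is invariant to main-text noise); bare texts
  fall back to shape patterns (email `@`, phone groupings, date shapes,
  digit-group identifiers, street/state-zip address cues, marker and
  gender token sets); placeholder-only inputs (`Age:`, a bare number of
  ≤ 3 digits) are non-PHI. With `identifier_scope="patient_only"`,
  study/series/image identifier prefixes map to non-PHI. The analyzer
  emits the closed 8-type vocabulary {date, identifier, patient_name,
  address, phone_nr, email, other, non-phi} with `raw_text`, `reason` and
  `language` fields. It is co-designed with the taxonomy lexicons: a test
  oracle and offline fallback, not a claim of parity with an LLM analyzer.

Prompt templates for LLM-backed analyzers ship as editable text files and
embed the category definitions, the aggregated-context instruction,
few-shot ambiguity examples and the strict output schema;
`parse_structured_output` enforces the schema and closed vocabulary,
turning malformed responses into per-image failures.

## Evaluation

Case level is per-image binary classification of PHI presence (overall or
per category); failed images predict nothing, which inflates FN rather
than silently dropping them. Instance level matches PHI-typed predicted
boxes to PHI ground-truth boxes greedily by descending IoU (threshold
0.5), one-to-one; under a category scope both sides are filtered to that
category first, so a mislabeled instance costs one FN in its true category
and one FP in the predicted one. Undefined precision/recall (zero
denominator) is reported as absent, never as 0 or 1. Multi-run aggregation
reports the arithmetic mean and sample standard deviation (ddof = 1) per
metric; counts are averaged, so fractional means are expected.

Greedy matching is the standard choice; on disjoint ground truth a
prediction can reach IoU ≥ 0.5 with at most one box, so the matching graph
has prediction-degree ≤ 1 and greedy equals the optimal assignment — the
test suite verifies this against an exhaustive oracle on small instances.

## What the synthetic data does and does not show

The generator reproduces the *structure* of burned-in overlays (category
mix, signal-word grammar, per-image limits, disjoint line boxes,
deterministic ground truth) but not the appearance of real modalities:
backgrounds are flat canvases with boxes, fonts are a small family, all
content is English, and imprint text never wraps across lines. Passing the
perfect-recovery and robustness checks therefore validates the *plumbing*
— that the pipeline, contracts and metrics are lossless and correctly
wired — not that any real detector/OCR/analyzer stack will reach those
numbers on clinical images. Real-engine performance must be measured by
binding real adapters and expecting degradation at every stage.

## Sizes used in the shipped checks

The acceptance checks regenerate the full default splits (1000-image
evaluation split, 6000-image training split) because their statistics are
the point; property checks that do not depend on scale use 25–200 images,
which is enough for every category and both tail classes (clean,
non-PHI-only) to appear.

## Known limitations

- The reference analyzer cannot distinguish a bare patient name from a
  bare personnel name (both are two capitalized tokens); without a signal
  word it returns non-PHI. Real analyzers face the same ambiguity; the
  benchmark's robustness guarantees are scoped to imprints with
  accompanying text.
- Multi-line text blocks, non-Latin scripts, DICOM output and the actual
  redaction step are out of scope.
- Case-level FP for a category counts any image with a spurious prediction
  of that category, even if the image contains other PHI (pure
  per-category binarization).
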