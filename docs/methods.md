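# Methods

## Task and model

A record is a short text containing exactly one cannabis mention and one
depression mention; the target is one of four relation classes — Reason
(cannabis as self-medication), Effect (cannabis causing/worsening
depression), Addiction (depressive mood from lacking cannabis), Ambiguous.
The model assumes the pre-filtered single-pair setting: texts without both
categories are rejected by the locator (`EntityAbsentError`) rather than
silently classified, and only the first-best mention per category is used.

The architecture fuses two sentence representations. The *position-aware
branch* is order- and entity-aware: word embeddings concatenated with two
entity-relative position embeddings, a multi-window CNN (windows 2/3/4,
stride 1, tanh, zero-padded so every window size emits exactly n outputs),
and an attention whose scores see the hidden state, the mean hidden state
`q`, and both position embeddings. The *contextual branch* mean-pools one
hidden layer of a BERT-style transformer over hashed token ids. A sigmoid
gate mixes the two projected representations elementwise; a single softmax
layer classifies. Cross-entropy is minimized with Adam (Adadelta available
by flag).

## Entity location

Matching is character-level Levenshtein distance (via `edlib`) between each
lexicon surface and the space-joined n-gram, for n up to the longest
surface; a candidate is kept when distance / max(length) ≤ `max_dist`
(default **0.2** — admits one edit in strings of five or more characters,
e.g. "smokin"→"smoking" at 1/7, while rejecting short-word noise).
Distances are computed on the joined n-gram, so "marijuana candies" vs
"marijuana candy" scores 2/15 ≈ 0.13, not the 2/7 of a token-wise view.
Overlapping candidates are resolved greedily: lower distance first, then
longer span, then leftmost. Surfaces shorter than four characters ("cbd",
"pot") match exactly only, so one-edit neighbors ("cbt", "pet") cannot fire
them. Masking selects the single best span per category and collapses it to
one mask token; mask tokens have dedicated embedding rows so masking carries
learnable signal (verified by a gradient-flow test).

## Parameters that matter

| parameter | default | meaning / why |
|---|---|---|
| `max_dist` | 0.2 | normalized edit-distance threshold of the locator |
| position clip | 50 | offsets saturate at ±50 tokens; table has 2·50+1 rows |
| word dim `d` | 300 (full profile) / 16–24 (test profile) | word-embedding width |
| position dim `d_p` | 100 / 8 | position-embedding width |
| CNN windows, features | {2,3,4} × 128 (test: ×24) | hidden dim `d_h` = Σ features |
| attention dim `d_a` | 50 (test: 16) | scorer width |
| encoder profile | 12 layers × 12 heads × 768 | pretrained-scale shape; test profile 2×2×32, randomly initialized and trained with the rest |
| pooled layer | L−1 | second-last layer; last-layer states sit too close to pretraining objectives |
| fusion projection | `d_h` | lets the no-context ablation reuse the classifier shape |
| dropout | 0.3 | applied to the fused vector before the classifier (site chosen here; the rate is standard) |
| optimizer | Adam, lr 0.001 (test runs: 0.005) | lr 0.005 is used for the small test profile where 0.001 converges needlessly slowly at CI scale |

Word embeddings default to trainable; a text-format word2vec/FastText file
can be loaded (`EmbeddingTables.from_word2vec`), and out-of-vocabulary
tokens get deterministic vectors either by hash seeding (`random-fixed`) or
FastText-style character n-gram averaging (`subword`, n ∈ [3,6]) so
misspellings land near their source words. Tests run entirely on small
randomly initialized tables; no download is needed.

## Pooling convention

The contextual sentence vector zero-masks the `[CLS]`/`[SEP]` rows and
divides the row sum by the **content-token count n** (so a single-content
sequence returns that token's vector exactly). A flag
(`include_special_in_count`) divides by the padded length instead, and
`pooling="cls"` returns the `[CLS]` row for comparison; neither is the
default because content-mean pooling is the convention the rest of the
model is calibrated to.

## Synthetic corpus: what it emulates and what it does not

The generator plants one cannabis and one depression surface from the
lexicon into label-specific cue templates ("helps/treat/cure" → Reason,
"causes/making worse" → Effect, "lack of/withdrawal" → Addiction, neutral
co-occurrence → Ambiguous), inserts neutral distractor tokens
(rate 0.2 per gap), and misspells surfaces by one random character edit
(rate 0.1, only on surfaces of ≥5 characters so the edit stays inside the
locator threshold, and never on surfaces containing another lexicon surface
as a sub-span, where an exact sub-match would win the overlap tie-break).
Class proportions follow the 3243:707:158:1777 imbalance of the annotation
study via largest-remainder apportionment, which the generated counts match
exactly.

This emulates the *structure* of the task — slang, misspellings, rare
classes, cue-signaled relations — but not its difficulty: real tweets carry
implied relations without cue words, sarcasm, emoji, and annotator
disagreement. Passing tests therefore establish that the architecture,
gradients and pipeline are correct and that the model can exploit cue and
position information; they do not establish real-corpus accuracy, and no
such claim is made. The position-sensitive task is the sharpest probe: its
label depends only on which side of the cannabis mention a cue token sits,
with the cue count per record equal across labels, so bag-of-words models
stay at chance while sequence models solve it.

## Numerical and design choices

- Float64 throughout the autodiff engine; layer outputs match independent
  loop-based oracles to 1e-5 (the test tolerance; agreement is typically
  1e-12).
- Softmax and cross-entropy are max-shifted for stability; the sigmoid
  clips pre-activations at ±60 to avoid overflow (saturated values round to
  exactly 0/1 in float64 beyond |z| ≈ 37, which the gate-law tests respect).
- Attention position embeddings are the same (shared) table concatenated at
  the input, chosen for parameter economy; a separate table is a
  constructor choice away.
- Overlap ties and fold assignment are deterministic; every run is
  reproducible from one seed (stage seeds derive by fixed offsets), and
  identical configs produce byte-identical corpora and metrics.
- Training-scale choices in tests and the acceptance script (corpora of
  120–800 records, 2–20 epochs, small-profile dims) are the package's
  CI-scale study conditions; the full-scale profile is configured but not
  exercised by the suite.
- Cross-validation is stratified so the ~2.7% Addiction class appears in
  every fold; overall metrics are support-weighted, the convention under
  which per-class scores of an imbalanced corpus aggregate consistently to
  a headline number (the weighted mean of the reference per-class F1s,
  66.55, tracks the reported overall 66.75; the macro mean, 52.4, does
  not).
- Cohen's kappa is undefined for perfectly constant annotation pairs and is
  reported as NaN rather than coerced.

## Known limitations

- One mention per category: multi-mention texts use the first-best span;
  coreference and discontinuous mentions are out of scope.
- The lexicon is a flat surface table; no concept hierarchy or relation
  inventory is modeled.
- The transformer encoder is trained from random initialization at test
  scale; results with a pretrained 12-layer encoder would differ and are
  not claimed.
- The tokenizer is regex-based (lowercasing, punctuation splitting,
  URL/handle placeholders) and is the reference tokenization for span
  indices; corpora tokenized differently must be re-indexed.
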