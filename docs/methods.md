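# Methods

`radsections` implements a two-stage pipeline for understanding breast
radiology reports written against the BI-RADS lexicon: (1) sentence-level
**section segmentation** — assigning each sentence to one of the seven
lexicon sections (title; history/clinical indication; previous imaging;
technique/procedure; findings; impression/opinion; final assessment
category) — and (2) **section-routed field extraction** of six report-level
clinical variables (modality/procedure, previous cancer, menopausal status,
exam purpose, breast density, background parenchymal enhancement). This
note records the model, the choices that were genuinely open, and what the
synthetic-data experiments do and do not demonstrate.

## Text model

Reports are normalized by terminating every non-blank line with punctuation
(radiologists often leave short-form lines such as `BILATERAL MAMMOGRAM`
unterminated); acronyms and casing are preserved — the tokenizer is uncased
downstream. Sentence segmentation is rule-based: split on `.`, `!`, `?`
followed by whitespace plus an uppercase letter or digit, or at end of
line; a colon ends a sentence only at end of line, so section headers
(`FINDINGS:`) become their own sentences while inline headers
(`FINDINGS: No mass.`) stay attached. Decimal numbers (`1.5 cm`) and a
protected abbreviation list (`Dr.`, `vs.`, `a.m.`, …) are never boundaries.
Rules were preferred over a learned sentencizer because they are
deterministic, dependency-free, and reconstruct the input exactly
(concatenating sentences reproduces the text modulo whitespace — a tested
invariant).

## Tokenizer

An uncased WordPiece vocabulary is trained from scratch on the report
corpus: starting from the character alphabet (continuations prefixed
`##`), adjacent symbol pairs are merged greedily by the score
`count(ab) / (count(a)·count(b))` until the requested vocabulary size is
reached or no pairs remain. Encoding is greedy longest-match-first;
out-of-alphabet or over-long (>100 characters) words map to `[UNK]`.
Sequences are wrapped as `[CLS] … [SEP]`, padded with `[PAD]`, and
**head-truncated** when over-long: in these reports the informative phrase
sits near the beginning of the section of interest (density and BPE open
the findings, purpose opens the history), so the head carries the signal.
On a domain corpus the word *mammogram* becomes a single token — the
motivating property of a specialty vocabulary versus general-English
tokenizers that split it into three or four pieces.

## Contextual encoder

The backbone is a bidirectional transformer (token + learned position
embeddings, post-layer-norm blocks, GELU feed-forward) with a dense+tanh
pooler over the first-token hidden state providing the sentence embedding.
It is pre-trained with **masked language modelling only** (no next-sentence
objective): 15% of content tokens are selected per sequence; of those 80%
become `[MASK]`, 10% a random vocabulary token, 10% stay unchanged.
Pre-training units are single sentences at sequence length 32 — terse
radiology sentences fit comfortably — while the position table is sized to
128 so downstream tasks can fine-tune at longer lengths.

The implementation is pure numpy with a small reverse-mode autodiff core
(`radsections.nn`): broadcast-aware arithmetic, batched matmul, fused
layer-norm and softmax cross-entropy, AdamW with linear warmup/decay.
Everything is float32 and single-threaded deterministic; checkpoints
round-trip bit-exactly. A bag-of-token-embeddings debug backbone satisfies
the same embedding contract, keeping the classifiers backbone-agnostic.

### Desk-scale configuration

The default experiment configuration is deliberately small so a full study
runs on one CPU in minutes: 2 layers, 64 hidden units, 2 heads,
intermediate width 128, vocabulary ≈1000–2000, 300 MLM steps. Scaling down
changes the optimization regime, and three choices follow from it:

* **Pre-training**: batch 256 (the reference recipe's batch) at learning
  rate 3e-3. The usual 1e-4 is tuned for a 110M-parameter model trained
  for 10^5–10^6 steps; a 64-dim model given 300 steps needs proportionally
  larger steps to compress the corpus statistics into its embeddings at
  all.
* **Initialization**: transformer internals use the conventional
  N(0, 0.02). But with MLM-only pre-training the pooler is never exercised
  before fine-tuning, and the auxiliary MLP and classification heads are
  always trained from scratch — those layers use Glorot initialization so
  their tanh activations and logit gradients start at unit scale. At 0.02
  the pooler crushes the pooled features by ~6× and a low-learning-rate
  fine-tune cannot recover within its step budget.
* **Fine-tuning**: the segmenter keeps the reference recipe — 4 epochs,
  batch 32, AdamW at 5e-5. The six field extractors each see only a few
  hundred routed texts (tens of optimizer steps per epoch), which at 64
  hidden dimensions is far too little movement at 5e-5; the desk-scale
  extractor recipe is 16 epochs at 1e-3 (`pipeline.DESK_EXTRACTOR_HYPER`).
  Library defaults for both entry points remain 4 epochs / batch 32 / 5e-5.

## Section segmentation

Each sentence is embedded by the backbone; optionally an auxiliary vector
of **global textual features** is fused: the previous sentence's section
label, the sentence ordinal, and the report length. These are featurized
as one-hot(8) over {7 sections + START} ⊕ [ordinal/length,
min(length, 64)/64] — START is its own category so "first sentence" is
distinguishable from "previous was title"; whether position should be fed
raw, bucketed or normalized is not externally fixed, and this normalized
form was chosen for scale-freeness. The 10-dim vector passes through a
3-layer fully connected encoder with tanh activations (the final tanh is
architecturally required; using tanh throughout is our choice) to 128
features, concatenated with the pooled embedding before the 7-way softmax
head. Widths 64→64→128 keep the branch small.

Training uses **teacher forcing** (gold previous label); inference is
sequential and causal — sentence *i* consumes the *predicted* label of
sentence *i−1*, never anything later. Argmax ties break toward the lowest
section index. Without the aux branch the computation graph is exactly the
plain text classifier.

## Field extraction

One independent classifier per task (six heads, never multi-task), in two
configurations:

* **Without segmentation**: the whole document, head-truncated to 128
  tokens, into the classifier.
* **With segmentation**: the segmenter labels the report first; the
  sentences of the task's host section are concatenated and classified at
  a per-task sequence length — modality → (title, 128), previous cancer →
  (history, 32), menopausal status → (history, 128), purpose →
  (history, 32), density → (findings, 32), BPE → (findings, 32). Modality
  needs the whole title because long titles enumerate every modality
  performed; menopausal status sits at the *end* of the history; the rest
  surface near their section's head.

A report lacking the routed section receives **"Not Stated"** without
consulting the classifier; previous cancer has no explicit absence class,
so its fallback is "No" (no mention of prior malignancy is what "No"
records). Modality has no absence class either, and every report opens
with a title — if the segmenter labels no sentence as title, the first
sentence stands in. Training in routed mode uses gold sections and drops
reports lacking the section; inference uses predicted sections. Modality
combination labels are canonicalized as `+`-joined atoms in the fixed
order MG, MRI, US, biopsy (`MG+US`).

## Evaluation

Two metrics. Pooled (micro) multi-class **accuracy**; the printed binary
form generalizes to pooling correct predictions over all predictions.
**Generalized F1** derives from the generalized Dice coefficient:

    G.F1 = 2 Σ_i w_i·TP_i / Σ_i w_i·(2·TP_i + FP_i + FN_i),   w_i = 1/P_i²

with P_i the class's positive count in the test set. Squared inverse
support makes one error on a rare class cost more than one on the dominant
class — the regime these reports live in, where most fields take their
majority value. Classes with P_i = 0 are excluded (their weight is
undefined). Per-report aggregation computes both metrics per report and
reports mean ± population (ddof 0) standard deviation.

Cross-validation stratifies reports by modality/procedure (strata smaller
than k merge into "other"); within training folds, sentence-level
train/validation splits stratify by section label. The 10%-data ablation
subsamples each fold's training reports stratified by their
section-signature group, warning and re-adding a report if a section would
vanish entirely.

Model comparison: **McNemar** for paired classifiers — exact two-sided
binomial when the discordant count b+c < 25, else chi-square with
continuity correction (|b−c|−1)²/(b+c); b+c = 0 gives p = 1. **Mann–Whitney
U** for per-report metric distributions — exact permutation enumeration
(dynamic programming over doubled midranks, so ties are handled) when both
samples have ≤ 20 observations, tie-corrected normal approximation
otherwise. **Bonferroni** adjustment is min(1, m·p). The exact/approximate
thresholds are declared constants so results are deterministic.

## Synthetic reports

The generator emulates the structure of the private hospital corpus the
method targets, with gold labels at both levels:

* seven sections in lexicon order; per-section omission probabilities
  (defaults: history 0.30, previous imaging 0.25, technique 0.15,
  findings 0.005, impression and assessment 0.05; the title is never
  omitted — every report has one). A field whose host section is omitted
  collapses to its fallback label, so gold labels are always realizable
  from the text;
* field phrases planted in their characteristic positions: modality in
  the title, purpose and previous cancer at the head of the history,
  menopausal status at its end, density and BPE at the head of the
  findings, drawn from per-label phrase banks using the lexicon's own
  category vocabulary;
* label priors skewed 0.7–0.9 toward a dominant class per task, the
  imbalance regime in which G.F1 and accuracy diverge;
* optional **ambiguous sentences** — fixed strings legal in two sections
  (e.g. "No significant interval change." in findings or impression),
  disambiguated only by position/previous label. The suite stores the
  exact ceiling for any text-only classifier (per-string majority
  frequency): a deterministic function of sentence text cannot beat it,
  which is what makes the auxiliary-feature comparison falsifiable;
* optional **distractor phrases** — a wrong-label field phrase planted in
  a non-host section, which confuses whole-document extraction but not
  routed extraction.

Reports are 8–27 sentences in the default configuration, matching terse
radiology style. The same seed yields a byte-identical corpus.

When the ambiguous-pair suite is used to compare aux-enabled against
text-only segmentation, both arms are trained with the same converged
desk-scale recipe (4 epochs at 1e-3): sequential decoding feeds each
sentence its predecessor's *predicted* label, so an undertrained aux model
cascades its early errors and the comparison would measure exposure bias
rather than the information the auxiliary features carry.

**What this does not show.** The generator's language is templated; it has
none of the lexical variety, negation scope, typos, or cross-section
information leakage of real dictation. Passing the recovery experiments
demonstrates that the pipeline's machinery — tokenizer, pre-training,
fused classification, routing, fallback, metrics — is correctly wired and
that its comparative claims (auxiliary features help where text alone is
provably insufficient; routing beats whole-document reading in the
presence of distractors) hold in a controlled setting. It does not
estimate real-world accuracy, and the headline numbers from the private
hospital evaluation are not reproducible here.

## Experiment sizes

The bundled study (`scripts/acceptance.py`, and the heavier tests) uses
400 synthetic reports, an 80/20 modality-stratified split (fold 0 of 5),
vocabulary 2000, 300 MLM steps at batch 256, the pinned segmenter recipe,
and the desk-scale extractor recipe; it completes in roughly ten minutes
on one CPU. All entry points accept full-scale configurations (12×768
encoder, 30,522-token vocabulary, 5-fold loops) unchanged.

## Known limitations

* Exact WordPiece merge order can differ from other implementations when
  pair scores tie; ties break lexicographically here.
* The Mann–Whitney exact branch enumerates conditional on observed ties;
  for samples larger than 20 the normal approximation is used regardless.
* Sequential aux inference is greedy; no beam or CRF decoding over the
  label sequence (deliberately out of scope).
* The encoder is CPU-bound numpy; it is meant for desk-scale studies and
  method development, not 25M-word pre-training runs.
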