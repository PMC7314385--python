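# Methods

## Instance construction

A document-level annotated corpus gives gold relations per (chemical
concept, disease concept) pair per document.  For every such combination —
C chemicals × D diseases yield C·D candidates — we build one instance: the
contiguous sentence block from the first to the last sentence containing a
mention of *either* target concept (the min/max hull over all mentions of
both concepts), joined by single spaces, with every mention offset re-based
into the new string.  The label is the pair's gold relation type, or
`negative` when the document asserts none.  This avoids the noise of
heuristic intra/inter splitting while discarding sentences unrelated to the
pair.

Decisions taken where the procedure is underdetermined:

* **Offsets.** PubTator offsets are 0-based half-open over
  `title + " " + abstract`.  Documents violating offset integrity are
  rejected, never silently shifted.
* **Sentence splitting** is rule-based (terminal punctuation + whitespace +
  capital/digit, with an abbreviation and single-initial guard).  Any
  candidate boundary that would bisect a mention is dropped; mention
  integrity, not linguistic perfection, is the binding constraint, and a
  one-sentence fallback is always legal.  Statistics that depend on the
  splitter (sentences per instance) are therefore implementation-relative.
* **Composite concept annotations** (`D001|D002`) expand to one mention per
  identifier at shared offsets; they re-merge on writing, so PubTator
  round-trips are byte-stable.
* Mentions with concept identifier `-1` (unnormalized) are kept as type
  `other` and never form target pairs.
* **Relations whose concepts never appear as mentions** cannot label any
  instance; they are dropped with a logged warning rather than aborting,
  since real corpora contain such annotations.
* Self- and duplicate relations deduplicate on (type, id1, id2).

The heuristic baseline (`heuristic_split`) reproduces the prior-work rule
for comparison: a pair gets an intra-sentence instance from any single
sentence holding mentions of both concepts at whitespace-token distance
below a threshold (default 10); pairs with at least one intra instance are
excluded from the inter-sentence level.  Token distance is the index
difference between the mention-edge whitespace tokens, punctuation attached
to its word — the convention under which the example sentence about
amitriptyline and blurred vision measures 12.

## Pretreatment

Instances of different pairs over the same sentence block share text but
may carry different labels.  The *replacement* pretreatment rewrites every
target chemical mention to `chemical`, target disease to `disease`, and
every non-target entity mention to `entity`, which both disambiguates the
pair and removes rare surface forms; the *addition* pretreatment wraps
target mentions in `[[ … ]]` / `<< … >>` markers and leaves non-target
mentions untouched.  Overlapping mentions resolve to the longest span
(targets win ties), logged.  Replacement is idempotent; addition is
invertible by stripping markers.

Tokenization is uncased greedy longest-match WordPiece over
whitespace-split words with `##` continuation pieces.  Any one-token-per-
line vocabulary file is accepted.  Truncation beyond the configured width
keeps the head of the instance (target mentions typically open the span,
because the span is their hull); this choice is ours — the interaction of
truncation with very long instances is not otherwise specified.  Segment
ids are a single constant: the task is single-sequence, though the segment
embedding table exists for compatibility with pretrained checkpoints.

## Encoder

The classifier is the standard transformer encoder: summed
token/segment/position embeddings, k stacks of (multi-head scaled
dot-product self-attention → residual → layer norm → position-wise FFN with
m = 4d → residual → layer norm), and a linear map from the final [CLS] row
to class scores, trained with softmax cross-entropy (the standard choice
for a linear/FFN head; no class reweighting).  Numerical conventions:

* Attention logits scale by √l with l = d/h, the per-head dimension.
* Padded positions are masked out of every attention softmax (additive
  −1e9 before normalisation), so padding never alters the [CLS] scores —
  a tested invariant.
* FFN biases broadcast per position (each row identical).
* Layer-norm ε = 1e-12 and dropout 0.1 by default; dropout (inverted, on
  embeddings and on each sub-layer output before its residual) draws from
  the training generator, so runs are bit-reproducible given a seed.
* An alternative `literal` architecture flag drops the post-concatenation
  projection W^O and the FFN residual + layer norm, leaving exactly the
  bare equation form; `standard` (the reference encoder structure) is the
  default.  Both variants have hand-derived backward passes verified
  against central-difference numerical gradients.
* Weight archives are flat named-tensor `.npz` files
  (`tok_emb`, `stack{i}.wq`, …, `w_pred`); `load_pretrained` takes a
  name-mapping dict for externally converted public checkpoints and
  validates every shape.  Attention projections carry no biases, matching
  the equation form; converted checkpoints with projection biases need
  them folded or dropped by the converter.

Training uses Adam (β₁=0.9, β₂=0.999) with linear learning-rate decay.
Defaults mirror the published fine-tuning recipe — 3 epochs, results
averaged over 5 runs (seeds base+0…base+4), per-dataset (max_len, batch)
presets (512, 6) / (150, 32) / (200, 23) for CDR–PPIm / DDI / CPR, and
learning rate 2e-5 for fine-tuning pretrained weights.  From-scratch
training of tiny models uses 1e-3, the standard Adam regime when no
pretrained initialisation exists.

## Evaluation

Per-class precision/recall/F1 (percent) delegate to scikit-learn;
the micro average pools contingency counts over the evaluated classes
only, excluding the negative/"no relation" class, as the relation-
extraction shared tasks do.  Multi-run averaging is the arithmetic mean of
every field.  The length-binned report groups instances by whitespace-token
count of the untreated text into bins [1,50], [51,100], …, >400 (bin width
50), with per-bin metrics; whitespace counting (rather than WordPiece) is
used because the corpus-level token statistics are consistent with it, and
the `stats` command reports token counts on the same convention.

## Synthetic corpus generator

`generate_corpus` emulates the *structure* of a document-level annotated
corpus: title + multi-sentence abstract, typed mentions with exact
character offsets and concept identifiers, and document-level gold
relations.  Positive documents plant a lexical cue ("induced", "caused",
…) near or between the target mentions — in a separate sentence from the
chemical with probability `cross_sentence_fraction` — while negative
documents use distractor verbs; `cue_strength` is the probability a
positive pair emits its cue, and `nonce_entities` swaps the small realistic
surface-form lexicons for randomized nonce words so no lexical prior ties
surface form to label.

Relations are drawn **per document** (all pairs related or none).  This is
deliberate: an instance spans the hull of all target-concept mentions, so
a per-pair cue sentence mentioning chemical c would fall inside the hull of
every pair involving c and decouple cue presence from the label.  With
document-level positivity, cue presence and label correspond exactly at
cue strength 1.0 — verified by a bag-of-words check before any encoder
test.  Defaults (200 docs, 3–6 sentences, 1 chemical × 1–2 disease
concepts, 1–2 mentions per concept, positive rate 0.3, cross-sentence
fraction 0.5, cue strength 1.0) keep instances short and the signal
identifiable; wider concept ranges are available for structural tests.

What passing tests on this corpus do **not** show: performance on real
abstracts, whose relation signals are not single lexical triggers, whose
entities are compound and ambiguous, and whose negative pairs share far
more context with positives.  The synthetic experiments certify the
machinery (offsets, hulls, pretreatment, optimisation, metrics), not
corpus-level F1.

## Problem sizes

The learnability experiment trains a k=2, h=2, d=32 encoder with max_len
64 on 500 synthetic instances for 3 epochs (batch 16, Adam 1e-3, seed 0)
and evaluates on a disjointly seeded held-out split — small enough that
the whole suite runs in seconds on one CPU while still exercising every
code path of the full-scale configuration, which differs only in k, h, d
and vocabulary size.

## Known limitations

* Pretraining (masked-language-model) is out of scope; pretrained weights
  enter only through the archive loader, and full-scale corpus F1 is not
  reproduced here.
* The rule-based sentence splitter is English-centric; sentences-per-
  instance statistics are splitter-dependent.
* Whether the original implementation used the standard sub-layer
  structure or literally the bare equations is unverifiable from the
  equations alone; both are provided, standard by default.
* The generator's templated text carries no syntax or coreference;
  attention analyses on it are illustrative only.
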