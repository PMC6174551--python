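# Methods

## Problem and pipeline

The package extracts chemical–protein relations from abstracts with
pre-annotated entity mentions. Relations are only sought *within* a
sentence: the pipeline segments each document (the title is always the
first sentence), aligns mention character offsets to sentences, enumerates
every chemical × gene pair per sentence, and labels each pair from the gold
annotation. Gold relations of the non-evaluated groups (CPR 1, 2, 7, 8, 10)
and unannotated pairs are negatives (NA); gold relations whose arguments
never co-occur in a sentence are counted and reported as unreachable — they
are unpredictable by construction and are paid for as false negatives in
tuple evaluation, never silently dropped.

Character offsets are trusted verbatim and validated against the mention
surface string (`text == slice`); a mismatch is an error, because silently
repairing offsets hides corpus corruption. Whether a corpus joins title and
abstract with a tab or a space is auto-detected per document by the same
validation rule.

## Segmentation, tokenization, blinding

No trained sentence model is assumed. The default segmenter splits after
`[.?!]` (+ optional closing brackets/quotes) followed by whitespace and an
uppercase letter or digit; any callable mapping text to sentence spans can
be plugged in instead. A mention straddling a detected boundary merges the
two sentences — a segmentation error must not delete a gold pair.

The tokenizer splits on whitespace and detaches punctuation, but keeps
hyphen/period/slash compounds with alphanumeric ends intact, so identifiers
like `UCCB01-125` stay single tokens.

Entity blinding replaces *every* mention in the sentence (not only the
candidate pair) by its type token, and a multi-word mention collapses to
one token. Collapsing keeps exactly one position index per entity. All
other tokens are lowercased. Ties and conflicts have fixed rules: a pair
annotated with several evaluated groups keeps the lowest CPR number (with
a warning); argmax ties in prediction and attention break toward the lowest
index / earliest token.

## Input representation

Per token: a 300-dim word embedding plus two 50-dim position embeddings
(one track per candidate entity), i.e. 400 dims. Position indices are
`clamp(d, −offset, offset−1) + offset` of the signed token distance `d` to
the entity token; the offset equals the sequence cap (default 150), so the
table has 300 rows and distance 0 maps to index 150. The offset value is an
arbitrary convention (any shift making indices non-negative works) and is
not claimed to match any particular published index example. Sequences
longer than the cap are cropped to a window centered between the two entity
tokens; if even then both entities cannot co-fit, the instance is truncated
from the right and flagged.

Word embeddings may be initialized from any `word v1 … v300` text file;
tokens not found there (or all tokens, if no file is given) are drawn from
seeded uniform(−0.25, 0.25). Position tables are initialized uniform(−0.05,
0.05) and, like the word table, trained jointly. Padding row 0 is held at
zero.

## Models

All three encoders feed dropout (rate 0.5) and a softmax over 6 labels
(5 CPR groups + NA), trained with Adam (lr 0.001) on sparse categorical
cross-entropy, batch size 64.

* CNN: valid 1-D convolution, 100 filters of length 3, tanh, global
  max-pooling over positions (windows beyond the real length are masked).
* GRU (hidden size 128): the update gate scales the **previous** hidden
  state, `h_t = z_t ∗ h_{t−1} + (1 − z_t) ∗ h̃_t`. Several libraries use
  the complementary convention (z scaling the candidate); the form above is
  normative here and is pinned by an element-by-element oracle test, so a
  drop-in replacement backed by such a library would need its gates
  re-mapped. Padded timesteps are masked: they neither advance the state
  nor receive gradient. The non-attention GRU classifies from the hidden
  state at the last real token.
* ATT-GRU: word-level attention pooling over the GRU outputs;
  `u_t = tanh(W_w h_t + b_w)`, scores `u_tᵀ u_w`, masked softmax over real
  tokens, `s = Σ α_t h_t`. At inference the per-token α are returned
  aligned to the unpadded tokens.

The networks are implemented directly in NumPy with hand-derived
backpropagation (the recurrent and attention equations are the package's
core, so they are authored here rather than delegated); correctness is
guarded by numerical finite-difference gradient checks for all three models
and by the brute-force equation oracles. Supported model kinds are `cnn`,
`gru`, `att_gru`; an LSTM variant is deliberately not included — it adds a
second hand-written cell without adding a tested guarantee.

Weight init: Glorot-uniform input transforms, orthogonal recurrent
transforms, zero biases, all from one seeded generator per run. Training
shuffles with a generator derived from the same seed, uses dynamic
per-batch padding (batches are cropped to the longest real sequence in the
batch), selects the parameter snapshot with the best development micro-F1
across epochs (default cap 30), and logs the per-epoch loss/F1 curve.
Optional per-class loss weights exist but are off by default — they shift
the precision/recall balance without reliably improving F1. Inference is
deterministic (dropout off).

## Evaluation

Micro P/R/F1 pool TP/FP/FN over the five positive classes with NA excluded
from the positive set. A gold-positive instance predicted as a *different*
positive class counts as one FP and one FN — the convention that agrees
with tuple-set comparison, where the mismatched tuple appears in both
difference sets. All 0/0 cases report 0. The tuple path compares
deduplicated (pmid, CPR, Arg1, Arg2) sets restricted to evaluated classes
and is the headline score; a per-class one-vs-rest table and a 6×6
confusion matrix (rows gold, columns predicted, order NA, CPR:3, CPR:4,
CPR:5, CPR:6, CPR:9) are derived alongside, and the micro scores recomputed
from the confusion matrix must agree with the pooled counts (tested).

## Attention analysis

For each positive test instance the token with the largest attention weight
is collected; tallying them per class yields the trigger-word table
(word, count, percentage of the class's positive instances). The entity
placeholders `chemical`/`gene` are excluded from the argmax by default
(exposed as a flag): the quantity of interest is the context word carrying
the relation, and placeholders would otherwise occasionally win on
position alone. If every token is a placeholder the best one is returned
with an explicit flag. `render_heat` emits per-token intensities normalized
by the maximum weight for visualization.

## Synthetic corpus: what it emulates and what it does not

The generator emits the three TSV dialects with valid offsets, a truth
table, and planted signal: each positive sentence contains one trigger word
from its class lexicon (inhibition vocabulary for CPR:4, agonism for CPR:5,
etc.; lexicons are disjoint) in a relation slot between the candidate
entities. Positive and NA sentences share identical scaffold pools (verbs,
adjectives, prepositions); NA sentences put a random filler word in the
trigger slot, so the trigger is the only class-informative token. By
default 25% of sentences carry a second, unrelated entity pair (producing
multiple candidate instances per sentence, the known hard regime for
sentence-level classifiers), and 20% of NA sentences contain a distractor
trigger far from both entities, so trigger presence alone is insufficient.
Entity names come from an identifier grammar (letters/digits/hyphens) that
the tokenizer must keep intact.

Defaults: 1000 documents, 3–4 sentences each, class mix 15% for each of the
five positive classes and 25% NA, 120 filler words — with the default
0.6/0.2/0.2 document-level split this yields ≈600 training documents and
≳300 positive training instances per class, enough for stable recovery.

What it does **not** emulate: real syntactic variety, anaphora, nested or
overlapping mentions, cross-sentence relations, annotation noise, class
imbalance as extreme as real corpora, or lexical ambiguity of trigger words
(real "inhibitor" occurs in negative contexts too). Near-ceiling scores
here therefore demonstrate that the implementation can recover a planted
signal end-to-end — parameter recovery — not that it would reach comparable
scores on real ChemProt data, where published sentence-level systems of
this family sit around 0.5 micro-F1.

## Problem sizes and numerical choices

The recovery experiments used in tests and `scripts/acceptance.py` run the
ATT-GRU for 6 epochs on the 1000-document corpus (convergence occurs within
the first 2–3 epochs on planted signal) and 10 epochs for the 3-seed
ATT-GRU/GRU/CNN comparison on a 240-document corpus; these sizes are the
package's own choice of a compact but non-trivial recovery setting.
Training uses float32; the functional layer APIs accept float64, and the
oracle/gradient tests run in float64 with tolerances 1e-6 (equations) and
1e-5 (finite differences). Softmaxes are max-shifted; the sigmoid is the
numerically stable piecewise form; padded positions receive score −inf
before attention softmax and are excluded from max-pooling. Degenerate
inputs have defined behavior: empty training set, empty attention sequence
and sub-filter-length sequences raise errors (in batched CNN training such
sequences fall back to the first zero-padded window instead, keeping the
batch well defined).

## Known limitations

* Same-sentence scope: cross-sentence relations are invisible except as
  reported unreachable gold.
* The rule-based segmenter under-splits sentences that resume with a
  lowercase word; merged sentences only enlarge candidate sets (recall is
  preserved, precision may suffer on real data).
* One hand-written GRU cell runs on one CPU; no GPU path. Throughput is
  adequate for corpus-scale experiments (minutes), not for web-scale.
* Attention argmax is a one-token explanation; multi-word cues are reduced
  to their strongest token.
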