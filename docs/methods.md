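# Methods

## The interactive annotation model

`looptag` implements the automation layer of a human-in-the-loop annotation
workflow for biomedical text. An annotator labels entity mentions (typed,
contiguous token spans) and typed binary relations between them; after each
batch of annotation a model is retrained on everything annotated so far and
proposes labels for the remaining text, which the annotator accepts or
corrects. Two suggestion mechanisms are provided, matching the two kinds of
annotation:

* **span suggestions** come from a statistical sequence tagger (below);
* **relation suggestions** come from a non-statistical *copy annotator*:
  every annotated relation is remembered as the five-field signature
  (relation label, source covered text, source entity label, target covered
  text, target entity label), and a new instance is proposed wherever an
  ordered span pair with exactly matching texts and labels recurs in scope.
  This is deliberately high-precision and cannot generalize to unseen
  pairs; it models the "copy" interaction, not relation classification.

Both label vocabularies are open: new entity or relation types introduced
during annotation extend the model inventory on the fly rather than being
rejected.

## Sequence tagger

The tagger is an averaged structured perceptron over BIO tag sequences with
a first-order transition structure:

    score(y | x) = start[y_1] + Σ_t w_emit[y_t]·φ(x, t)
                 + Σ_t w_trans[y_{t-1}, y_t] + stop[y_n]

Decoding is exact Viterbi restricted to BIO-valid sequences: transitions
into `I-X` from anything but `B-X`/`I-X`, and `I` tags in initial position,
are structurally forbidden rather than merely penalized. The decoder also
returns the best sequence differing from the winner in at least one
position (a top-2 Viterbi); the margin between the two is mapped through a
logistic to a suggestion confidence in [0, 1], which is monotone in the
margin. Exact score ties are broken toward the sequence that is
lexicographically smallest in tag-inventory order, earliest position first,
so decoding is deterministic and matches exhaustive enumeration.

Training is the standard online update: decode each sentence with the
current weights; when the prediction differs from gold, add the gold
feature/transition counts and subtract the predicted ones (learning rate
1). Sentences are shuffled each epoch with a caller-supplied seed; 5 epochs
is the default. Weight averaging over all sentence presentations is
maintained with the lazy accumulator trick (`avg = w − u/steps`); averaged
weights are used for suggestion/prediction decoding, raw weights inside
training. On the synthetic benchmark the averaged decode is on average a
few F1 points better than the final-weight decode, with per-seed scatter of
a couple of points either way.

`learn` never mutates its input: it returns a new model with an incremented
version number. This is the model-swap contract of an interactive system —
suggestions keep flowing from the old model while the new one is built, and
the swap is atomic. Interactive rounds retrain from scratch on all
annotations so far (cumulative); a single-pass incremental mode
(`cumulative=False` in the simulator, or calling `learn` on the previous
model) is available but not the default, since retraining matches the
replace-the-model semantics.

### Features

Per token, evaluated at every offset in a ±2-token window (each feature
name prefixed with its offset; out-of-sentence positions contribute
explicit `BOS`/`EOS` markers):

* lowercased surface;
* first and last character 3-grams of the lowercased surface (whole surface
  when shorter than 3 — biomedical text is full of short symbols);
* word shape (uppercase→`A`, lowercase→`a`, digit→`0`, other characters
  verbatim) plus its run-collapsed form (`IL-2` → `AA-0` → `A-0`);
* a word-cluster id from a cluster lexicon, when one is supplied.

Case information is carried only by the shape features; surfaces and
affixes are lowercased to cut sparsity.

The cluster lexicon is induced distributionally: the most frequent word
types (default 5000) are represented by L2-normalised count vectors of the
most frequent neighbour types (default 200) in their immediate left/right
slots and clustered with k-means (fixed seed, deterministic). Unseen words
fall back to the majority cluster of their longest known word-final k-gram
(k = 4..1, suffixes supported by at least 5 clustered types), then to a
catch-all cluster, so lookup is total. This is a self-contained stand-in
with the same interface contract as externally trained part-of-speech
cluster models: one cluster id per token, robust on unseen vocabulary.

## Corpus formats and conventions

* **IOB**: token-per-line, ≥2 whitespace-separated columns (token … tag),
  blank line between sentences, `-DOCSTART-\t<doc_id>` between documents.
  Document text is reconstructed by single-space joins within sentences and
  newlines between them, so offsets stay well-defined.
* **Standoff**: raw `.txt` plus `T<id>\tlabel begin end\tcovered_text` and
  `R<id>\tlabel Arg1:T<i> Arg2:T<j>` lines, offsets 0-based half-open.
  Sentence segmentation splits on newlines; tokens are maximal runs of
  alphanumerics with internal hyphens, every other non-space character a
  single-character token. The rule is deterministic and reversible against
  offsets; it is a project convention, not a claim about any particular
  corpus's original tokenization.
* Orphan `I-X` tags are repaired to `B-X` with a logged warning in the
  default lenient mode and rejected in strict mode; published corpora
  contain such glitches.
* Overlapping or discontinuous entities are rejected outright — the BIO
  target representation cannot express them, and silent dropping would
  corrupt round trips.
* Spans always satisfy `covered_text == text[begin:end]` after any read.

## Evaluation arithmetic

Span scoring is exact-match (label, begin, end), micro-averaged, with a
per-label breakdown; precision/recall/F1 are percentages reported to two
decimals, and undefined ratios (zero denominators) are reported as 0.00
(the conlleval convention). Relation suggestion yield is summarised as
suggestions per annotated relation (one decimal), per document (two
decimals), and cross-document suggestions per annotated relation (two
decimals).

## Simulation protocols

* **Learning curve**: train a fresh tagger on growing cumulative prefixes
  of the corpus in corpus order (no re-sampling — this simulates sequential
  annotation) and evaluate each on one fixed development set. The classic
  full-corpus schedule (40…18,555 sentences) is kept as
  `DEFAULT_SCHEDULE`; the bundled benchmark uses the scaled schedule
  40/120/280/600 on synthetic data.
* **Accept/reject**: documents arrive in order; the current model's
  suggestions are compared with gold, exact matches count as accepted (a
  UI "accept" adopts the span verbatim; partial matches are corrections,
  counted as rejections), gold replaces everything else, and the model is
  retrained after every round.

## The synthetic corpus generator

The generator emulates the statistics that make this pipeline work on real
biomedical abstracts, with no linguistic realism beyond them:

* Zipfian background vocabulary (exponent 1.1, 1500 pseudo-words, filtered
  against entity suffixes), sentence lengths uniform on 8–25 tokens,
  documents of 5–12 sentences, 40 documents by default.
* Eight default entity types (cell, condition, disorder, gene, molecule,
  molecular_pathway, protein, substance), each with a characteristic
  suffix, capitalization pattern and digit rate — mention shape differing
  from background tokens is exactly why shape/affix features earn their
  keep. Multi-token mentions are a morphology head plus type-typical tail
  words ("… pathway", "… complex", "… cells"); geometric length, mostly 1–2
  tokens. Entity density 0.10 per token-draw.
* Each type has a context cue word preceding 60 % of its mentions
  (`trigger_prob`), which is what gives distributional cluster induction
  and window features a signal.
* 5 % of entity surfaces are *ambiguous* (also occur as plain background
  words, at a 1 % token rate), so the tagger's ceiling is below 100 % —
  genuinely ambiguous surface forms are a small minority in real text.
* Ten default relation labels over type pairs (Equivalent,
  Protein-component, Subunit-complex, Activator-reactor, Antibody-antigen,
  Cell-marker, Cell-variant, DNA-transcript, Ligand-receptor,
  Protein-variant), planted on co-occurring pairs with per-pair
  probabilities. Previously related pairs recur later (rate 0.3), biased
  0.75 toward the current document: documents dwell on the same pairs, the
  discourse property that makes same-document relation copying far more
  productive than copying across independently selected documents.
* Ground truth (hidden word classes, mention tables, annotated relation
  signatures) ships as separate bookkeeping, never inside the corpus
  formats, so tests can compute oracle answers (cluster purity,
  relation-copy opportunity counts, expected counts) independently of the
  code under test.

What passing on this generator shows — and what it does not: the synthetic
task isolates morphology, local context and exact surface recurrence. Real
abstracts add nested/discontinuous mentions, long-range context,
orthographic variation and annotation noise, none of which the generator
models; absolute scores here say nothing about absolute scores on real
corpora, which is why the published-corpus protocol is provided separately
(`scripts/run_nlpba_curve.py`, requiring a locally supplied corpus) and why
only curve *shape* properties are asserted.

## Benchmark sizes and recorded reference values

The committed benchmark (default generator, seed 1) trains on the first 200
sentences and evaluates on the following whole documents covering ≥100
sentences (103 at seed 1). The pre-registered run of this pipeline measured
span F1 88.71 (P 93.06, R 84.74), and the test suite pins that value as its
floor. Across generator seeds 1–7 the same pipeline spans roughly 82–92 F1.
The scaled learning curve (90 documents, schedule 40/120/280/600, ~100
dev sentences) rises monotonically with per-sentence gains shrinking by an
order of magnitude between the first and last interval, on every seed
tried. Problem sizes were chosen so the whole default suite and the
acceptance script each run in a couple of minutes on one CPU.

## Numerical and degenerate-input choices

* Ties in decoding: exact float equality → lexicographic tie-break (see
  above); with all-zero weights a sentence decodes to all-`O`, so an
  untrained model makes no suggestions.
* A one-tag inventory has no runner-up sequence; the margin is treated as
  infinite and confidence saturates at 1.
* Empty training sets, empty sentences, non-increasing schedules, schedules
  exceeding the corpus, k exceeding the clusterable vocabulary, and
  reflexive or dangling relations are all rejected with explicit errors.
* Model serialization is plain text with `repr`-round-tripped floats, so a
  saved and reloaded model is bit-identical and decodes identically.

## Known limitations

* The relation suggester is exact-match by design; no statistical relation
  model is included.
* BIO cannot represent overlapping or discontinuous mentions; such
  annotations are rejected at the format boundary.
* The perceptron is linear; no feature conjunctions beyond the explicit
  templates, no embeddings.
* Sentence-level confidence: all spans suggested from one sentence share
  the sentence's Viterbi margin rather than having per-span margins.
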