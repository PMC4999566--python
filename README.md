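# looptag

Human-in-the-loop sequence tagging and relation-copy suggestion for
biomedical text annotation.

Annotating biomedical literature — entity mentions such as proteins, cells
or disorders, and typed relations between them — is expensive because it
needs domain experts. An interactive workflow cuts the cost: a model
trained on whatever has been annotated so far proposes labels for the next
document, the annotator accepts or corrects them, and the model is rebuilt
after every round. `looptag` is a self-contained toolkit for that
workflow, aimed at annotation-tool builders and at anyone studying how
quickly suggestion quality grows with annotation effort.

It provides:

* readers/writers for two standard corpus dialects: token-per-line **IOB**
  files (BIO tags, blank-line sentence breaks) and **standoff** documents
  (raw text plus `T`/`R` annotation lines with character offsets), with
  validated, lossless conversion between them;
* an **averaged structured perceptron** BIO tagger with exact Viterbi
  decoding over BIO-valid sequences, margin-based suggestion confidences,
  an open label vocabulary, and non-mutating retrain-and-swap semantics:

  `score(y|x) = start[y₁] + Σₜ w_emit[yₜ]·φ(x,t) + Σₜ w_trans[yₜ₋₁,yₜ] + stop[yₙ]`

  with sparse features per token (character affix 3-grams, word shapes,
  induced word clusters, lowercased surfaces) in a ±2-token window;
* a **relation copy annotator** that remembers every annotated relation as
  a (label, source text, source type, target text, target type) signature
  and re-proposes it wherever a matching span pair recurs;
* a **simulation harness** for the incremental-annotation protocol:
  learning curves over growing training prefixes on a fixed dev set,
  exact-match span precision/recall/F1 with per-label breakdowns, and an
  accept/reject loop;
* a **deterministic synthetic corpus generator** (biomedical-like
  morphology, planted relations, hidden ground truth for oracle checks), so
  everything is testable without downloading any corpus.

## Worked example

```python
import looptag as lt
from looptag.simulate import split_corpus
from looptag.relations import build_memory, suggest_relations, relation_metrics

docs, book = lt.generate_corpus(lt.GeneratorConfig())      # seed 1 defaults
train, dev = split_corpus(docs, 200, 100)
model = lt.learn(lt.TaggerModel(), train, epochs=5, seed=1)
result = lt.evaluate_spans(dev, [lt.predict_document(model, d) for d in dev])

blank = lt.AnnotatedDocument(dev[0].doc_id, dev[0].text, dev[0].sentences, [], [])
suggestions = lt.suggest_spans(model, blank)

memory = build_memory(docs)
total = sum(len(suggest_relations(memory, d)) for d in docs)
metrics = relation_metrics(len(docs), total, sum(len(d.relations) for d in docs))
```

prints (via the obvious `print` lines, run on this repository):

```
generated 40 documents, 323 sentences, 645 entity mentions, 174 relations
model v1: 168 perceptron updates over 1000 sentence presentations
held-out span P/R/F1: 93.06 / 84.74 / 88.71
9 suggestions for syn0027; first: cell 'pzqwcyte' (confidence 1.00)
relation copy: 97 signatures, 34 suggestions, 0.2 per relation, 0.85 per document
```

Reading the numbers: after 200 simulated-annotated sentences the tagger
already labels unseen documents at ~89 span F1 (exact-match: label and both
boundaries), so most suggestions can simply be accepted. The relation-copy
figures are yield averages — how many new relation instances the copy
annotator proposes per annotated relation and per document.

The same pipeline is available from the shell:

```bash
looptag generate --seed 1 --out-dir corpus --format both
looptag train --in corpus/corpus.iob --model model.txt --epochs 5 --seed 1
looptag suggest --model model.txt --in corpus/standoff --out suggested
looptag relate --memory-from corpus/standoff --in corpus/standoff --out related
looptag curve --corpus corpus/corpus.iob --dev corpus/corpus.iob \
              --schedule 40,120,280 --seed 1 --out curve.tsv
looptag eval --gold corpus/standoff --pred suggested --per-label
```

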