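"""Incremental-annotation simulation and span evaluation arithmetic.

Two protocols are implemented:

* **learning curve** -- train a fresh tagger on growing prefixes of a
  corpus (cumulative, in corpus order, simulating sequential annotation)
  and evaluate each model on one fixed development set, producing one
  (training size, precision/recall/F1) point per schedule entry;

* **accept/reject simulation** -- process documents in order; for each,
  compare the current model's suggestions with gold: exact span matches
  count as accepted, everything else is discarded and replaced by the gold
  annotation (simulating the annotator's correction), then the model is
  retrained on everything annotated so far.

Span scoring is exact-match (label, begin and end must all agree),
micro-averaged, with a per-label breakdown.  Undefined precision/recall/F1
(zero denominators) are reported as 0.00, following the conlleval
convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .corpus_io import ACCEPTED, GOLD, AnnotatedDocument, Sentence
from .features import ClusterLexicon, FeatureConfig
from .tagger import TaggerModel, learn, predict_document, suggest_spans

log = logging.getLogger(__name__)


@dataclass
class EvalResult:
    """Exact-match span counts with percentages rounded to 2 decimals."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    per_label: dict[str, "EvalResult"] = field(default_factory=dict)

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int) -> "EvalResult":
        p = 100.0 * tp / (tp + fp) if tp + fp else 0.0
        r = 100.0 * tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        return cls(tp, fp, fn, round(p, 2), round(r, 2), round(f, 2))


@dataclass
class CurvePoint:
    train_sentences: int
    result: EvalResult


DEFAULT_SCHEDULE = [40, 120, 280, 600, 1240, 2520, 5080, 10200, 18555]


def split_corpus(docs: list[AnnotatedDocument], n_train_sentences: int,
                 n_dev_sentences: int) -> tuple[list[Sentence], list[AnnotatedDocument]]:
    """Split a corpus into training sentences and held-out dev documents.

    The first ``n_train_sentences`` sentences (in corpus order) form the
    training set; development documents start at the first document lying
    entirely beyond the training prefix and accumulate until they cover at
    least ``n_dev_sentences`` sentences.  Document boundaries are respected
    on the dev side so span evaluation stays document-based.
    """
    total = sum(len(d.sentences) for d in docs)
    if total < n_train_sentences:
        raise ValueError(
            f"corpus has {total} sentences, need {n_train_sentences} for training")
    train: list[Sentence] = []
    cum = 0
    split_at = len(docs)
    for i, d in enumerate(docs):
        cum += len(d.sentences)
        train.extend(d.sentences)
        if cum >= n_train_sentences:
            split_at = i + 1
            break
    train = train[:n_train_sentences]
    dev: list[AnnotatedDocument] = []
    n_dev = 0
    for d in docs[split_at:]:
        dev.append(d)
        n_dev += len(d.sentences)
        if n_dev >= n_dev_sentences:
            break
    if n_dev < n_dev_sentences:
        raise ValueError(
            f"only {n_dev} sentences remain after the training prefix, "
            f"need {n_dev_sentences}")
    return train, dev


def evaluate_spans(gold_docs, pred_docs) -> EvalResult:
    """Micro-averaged exact-match span P/R/F with per-label breakdown.

    A predicted span is a true positive iff a gold span with identical
    label, begin and end exists in the same document.  Gold side counts
    spans with provenance gold/accepted; the prediction side counts all
    spans of the predicted documents.
    """
    if isinstance(gold_docs, AnnotatedDocument):
        gold_docs, pred_docs = [gold_docs], [pred_docs]
    gold_docs, pred_docs = list(gold_docs), list(pred_docs)
    if len(gold_docs) != len(pred_docs):
        raise ValueError("gold and predicted document lists differ in length")
    gold_keys, pred_keys = set(), set()
    for g, p in zip(gold_docs, pred_docs):
        if g.doc_id != p.doc_id:
            raise ValueError(f"document id mismatch: {g.doc_id} vs {p.doc_id}")
        for s in g.spans:
            if s.provenance in (GOLD, ACCEPTED):
                gold_keys.add((g.doc_id, s.label, s.begin, s.end))
        for s in p.spans:
            pred_keys.add((p.doc_id, s.label, s.begin, s.end))
    result = EvalResult.from_counts(
        len(gold_keys & pred_keys),
        len(pred_keys - gold_keys),
        len(gold_keys - pred_keys),
    )
    labels = {k[1] for k in gold_keys | pred_keys}
    for lab in sorted(labels):
        g = {k for k in gold_keys if k[1] == lab}
        p = {k for k in pred_keys if k[1] == lab}
        result.per_label[lab] = EvalResult.from_counts(
            len(g & p), len(p - g), len(g - p))
    return result


def run_learning_curve(corpus: list[AnnotatedDocument],
                       dev_docs: list[AnnotatedDocument],
                       schedule: list[int],
                       feature_config: FeatureConfig | None = None,
                       lexicon: ClusterLexicon | None = None,
                       epochs: int = 5, seed: int = 0) -> list[CurvePoint]:
    """Train on growing sentence prefixes, evaluate each on the fixed dev set.

    Prefixes are cumulative and taken in corpus order (no re-sampling);
    shuffling happens only inside the learner.  Deterministic for a fixed
    seed.  Raises ``ValueError`` when the schedule is not strictly
    increasing or exceeds the corpus size.
    """
    if not schedule or any(s <= 0 for s in schedule):
        raise ValueError("schedule must contain positive sizes")
    if any(b <= a for a, b in zip(schedule, schedule[1:])):
        raise ValueError("schedule must be strictly increasing")
    sentences = [s for d in corpus for s in d.sentences]
    too_big = [s for s in schedule if s > len(sentences)]
    if too_big:
        raise ValueError(
            f"schedule sizes {too_big} exceed the corpus ({len(sentences)} sentences)")
    points: list[CurvePoint] = []
    for size in schedule:
        model = learn(TaggerModel(), sentences[:size], epochs=epochs, seed=seed,
                      feature_config=feature_config, lexicon=lexicon)
        preds = [predict_document(model, d, feature_config, lexicon)
                 for d in dev_docs]
        result = evaluate_spans(dev_docs, preds)
        log.info("curve point: %d sentences -> F1 %.2f", size, result.f1)
        points.append(CurvePoint(size, result))
    return points


@dataclass
class RoundStats:
    """Per-round outcome of the accept/reject simulation."""

    round: int
    suggestions: int
    accepted: int
    acceptance_rate: float          # 0.0 when there were no suggestions
    cumulative_accepted_fraction: float


def simulate_accept_reject(docs: list[AnnotatedDocument],
                           feature_config: FeatureConfig | None = None,
                           lexicon: ClusterLexicon | None = None,
                           epochs: int = 5, seed: int = 0,
                           cumulative: bool = True,
                           suggest_fn=None) -> list[RoundStats]:
    """Simulate the interactive accept/ignore annotation loop.

    Each document is presented to the current model; suggestions exactly
    matching a gold span count as accepted, the rest are ignored and the
    gold annotation is adopted (the simulated correction).  After every
    round the model is retrained -- from scratch on all annotations so far
    when ``cumulative`` (the model-swap semantics), or by a single
    additional online pass over the new document when not.

    ``suggest_fn(model, doc) -> list[Suggestion]`` may replace the standard
    suggester (e.g. an oracle upper bound in tests).
    """
    model = TaggerModel()
    stats: list[RoundStats] = []
    train: list[Sentence] = []
    cum_suggestions = 0
    cum_accepted = 0
    for rnd, doc in enumerate(docs, start=1):
        blank = AnnotatedDocument(doc.doc_id, doc.text, doc.sentences, [], [])
        if suggest_fn is not None:
            suggestions = suggest_fn(model, blank)
        else:
            suggestions = suggest_spans(model, blank, feature_config, lexicon)
        gold_keys = {(s.label, s.begin, s.end) for s in doc.spans
                     if s.provenance in (GOLD, ACCEPTED)}
        accepted = sum(1 for s in suggestions if s.span.signature() in gold_keys)
        cum_suggestions += len(suggestions)
        cum_accepted += accepted
        stats.append(RoundStats(
            round=rnd,
            suggestions=len(suggestions),
            accepted=accepted,
            acceptance_rate=accepted / len(suggestions) if suggestions else 0.0,
            cumulative_accepted_fraction=(
                cum_accepted / cum_suggestions if cum_suggestions else 0.0),
        ))
        if cumulative:
            train.extend(doc.sentences)
            model = learn(TaggerModel(), train, epochs=epochs, seed=seed,
                          feature_config=feature_config, lexicon=lexicon)
        else:
            model = learn(model, list(doc.sentences), epochs=1, seed=seed,
                          feature_config=feature_config, lexicon=lexicon)
    return stats


def curve_tsv(points: list[CurvePoint]) -> str:
    """TSV rendering of a learning curve (size, precision, recall, F1)."""
    lines = ["sentences\tprecision\trecall\tf1"]
    for pt in points:
        r = pt.result
        lines.append(f"{pt.train_sentences}\t{r.precision:.2f}\t{r.recall:.2f}\t{r.f1:.2f}")
    return "\n".join(lines) + "\n"
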