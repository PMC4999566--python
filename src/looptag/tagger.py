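"""Averaged structured perceptron for BIO sequence tagging.

The model is a linear chain scorer: a tag sequence ``y`` for a sentence with
per-token feature vectors ``x`` scores

    score(y) = start[y_1] + sum_t emit[y_t] . x_t
             + sum_t trans[y_{t-1}, y_t] + stop[y_n]

Decoding is exact Viterbi over the BIO-valid sequences only: a transition
into ``I-X`` is hard-forbidden unless it comes from ``B-X``/``I-X``, and a
sequence may not start with an ``I`` tag, regardless of weights.  Ties are
broken toward the sequence that is lexicographically smallest in
tag-inventory order (earliest position first).

Learning is the standard online structured perceptron: sentences are
shuffled per epoch with a fixed seed, each sentence is decoded with the
current weights, and when the decode differs from gold the gold
feature/transition counts are added and the predicted ones subtracted
(learning rate 1).  Weight averaging over all sentence presentations is
maintained with the usual lazy-accumulator trick; suggestions are decoded
with the averaged weights.

``learn`` never mutates its input model: it returns a fresh model with an
incremented version, so an application can keep serving suggestions from
the old model while the new one is being built, and swap atomically.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass, replace

import numpy as np

from .corpus_io import (ACCEPTED, GOLD, SUGGESTED, AnnotatedDocument,
                        EntitySpan, Sentence, tags_to_spans, validate_bio)
from .features import ClusterLexicon, FeatureConfig, token_context_features

log = logging.getLogger(__name__)

MODEL_MAGIC = "looptag-model\t1"


@dataclass
class Suggestion:
    """A proposed entity span with a decoder-derived confidence in [0, 1]."""

    span: EntitySpan
    confidence: float
    model_version: int


class TaggerModel:
    """Weights, averaging accumulators and version id of the tagger.

    ``labels`` is the ordered BIO tag inventory (``O`` always first; the
    inventory is open and extended as new gold labels appear).  Emission
    weights live in ``ew[feature] -> ndarray(T)`` with averaging
    accumulators in ``eu``; transitions in ``(T, T)`` matrices plus start
    and stop rows.  ``steps`` counts sentence presentations (the averaging
    denominator), ``update_count`` counts actual perceptron updates and
    ``version`` increases by one on every (non-mutating) call to ``learn``.
    """

    def __init__(self, labels: list[str] | None = None):
        labels = list(labels) if labels else ["O"]
        if "O" not in labels:
            labels = ["O"] + labels
        self.labels = labels
        self.label_index = {t: i for i, t in enumerate(labels)}
        T = len(labels)
        self.ew: dict[str, np.ndarray] = {}
        self.eu: dict[str, np.ndarray] = {}
        self.tw = np.zeros((T, T))
        self.tu = np.zeros((T, T))
        self.sw = np.zeros(T)
        self.su = np.zeros(T)
        self.pw = np.zeros(T)  # stop weights
        self.pu = np.zeros(T)
        self.steps = 0
        self.update_count = 0
        self.version = 0
        self._topology: tuple | None = None

    # ------------------------------------------------------------------
    @property
    def n_labels(self) -> int:
        return len(self.labels)

    def copy(self) -> "TaggerModel":
        new = TaggerModel(self.labels)
        new.ew = {f: v.copy() for f, v in self.ew.items()}
        new.eu = {f: v.copy() for f, v in self.eu.items()}
        new.tw, new.tu = self.tw.copy(), self.tu.copy()
        new.sw, new.su = self.sw.copy(), self.su.copy()
        new.pw, new.pu = self.pw.copy(), self.pu.copy()
        new.steps = self.steps
        new.update_count = self.update_count
        new.version = self.version
        return new

    def extend_labels(self, new_tags: list[str]) -> None:
        """Grow the tag inventory in place (open label vocabulary)."""
        fresh = [t for t in new_tags if t not in self.label_index]
        if not fresh:
            return
        m = len(fresh)
        self.labels.extend(fresh)
        self.label_index = {t: i for i, t in enumerate(self.labels)}
        self.ew = {f: np.pad(v, (0, m)) for f, v in self.ew.items()}
        self.eu = {f: np.pad(v, (0, m)) for f, v in self.eu.items()}
        self.tw = np.pad(self.tw, ((0, m), (0, m)))
        self.tu = np.pad(self.tu, ((0, m), (0, m)))
        self.sw = np.pad(self.sw, (0, m))
        self.su = np.pad(self.su, (0, m))
        self.pw = np.pad(self.pw, (0, m))
        self.pu = np.pad(self.pu, (0, m))
        self._topology = None

    # ------------------------------------------------------------------
    def topology(self):
        """Allowed predecessors per tag and start legality (BIO constraints)."""
        if self._topology is None or self._topology[0] != len(self.labels):
            T = len(self.labels)
            preds, start_ok = [], []
            for tag in self.labels:
                if tag.startswith("I-"):
                    lab = tag[2:]
                    preds.append([i for i, t in enumerate(self.labels)
                                  if t == "B-" + lab or t == "I-" + lab])
                    start_ok.append(False)
                else:
                    preds.append(list(range(T)))
                    start_ok.append(True)
            self._topology = (T, preds, start_ok)
        return self._topology[1], self._topology[2]

    def _ev(self, feat: str) -> np.ndarray:
        vec = self.ew.get(feat)
        if vec is None:
            vec = self.ew[feat] = np.zeros(self.n_labels)
            self.eu[feat] = np.zeros(self.n_labels)
        return vec

    def emissions(self, feats: list[dict[str, float]], averaged: bool) -> np.ndarray:
        """Per-token, per-tag emission scores for one sentence."""
        E = np.zeros((len(feats), self.n_labels))
        inv = 1.0 / self.steps if (averaged and self.steps) else 0.0
        for i, fv in enumerate(feats):
            row = E[i]
            for f, val in fv.items():
                w = self.ew.get(f)
                if w is None:
                    continue
                if inv:
                    row += val * (w - self.eu[f] * inv)
                else:
                    row += val * w
        return E

    def chain_weights(self, averaged: bool):
        if averaged and self.steps:
            inv = 1.0 / self.steps
            return (self.sw - self.su * inv, self.tw - self.tu * inv,
                    self.pw - self.pu * inv)
        return self.sw, self.tw, self.pw


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------


def _decode_indices(model: TaggerModel, feats, averaged: bool, k: int):
    """Top-k (k in {1,2}) BIO-valid tag index sequences with their scores.

    Entries per DP cell are (score, path) tuples; on exact score ties the
    lexicographically smaller path (tag-inventory order, earliest position
    first) wins, matching exhaustive enumeration order.
    """
    if not feats:
        raise ValueError("cannot decode an empty sentence")
    E = model.emissions(feats, averaged)
    S, A, P = model.chain_weights(averaged)
    preds, start_ok = model.topology()
    T = model.n_labels
    n = len(feats)

    cells = []
    for j in range(T):
        cells.append([(S[j] + E[0, j], (j,))] if start_ok[j] else [])
    for i in range(1, n):
        new_cells = []
        Ei = E[i]
        for j in range(T):
            base = Ei[j]
            b1 = b2 = None
            for p in preds[j]:
                for s, path in cells[p]:
                    cand = (s + A[p, j] + base, path)
                    if b1 is None or cand[0] > b1[0] or (cand[0] == b1[0] and cand[1] < b1[1]):
                        b1, b2 = cand, b1
                    elif k > 1 and (b2 is None or cand[0] > b2[0]
                                    or (cand[0] == b2[0] and cand[1] < b2[1])):
                        b2 = cand
            entries = []
            if b1 is not None:
                entries.append((b1[0], b1[1] + (j,)))
            if k > 1 and b2 is not None:
                entries.append((b2[0], b2[1] + (j,)))
            new_cells.append(entries)
        cells = new_cells

    best = second = None
    for j in range(T):
        for s, path in cells[j]:
            cand = (s + P[j], path)
            if best is None or cand[0] > best[0] or (cand[0] == best[0] and cand[1] < best[1]):
                best, second = cand, best
            elif k > 1 and (second is None or cand[0] > second[0]
                            or (cand[0] == second[0] and cand[1] < second[1])):
                second = cand
    return best, second


def viterbi_decode(model: TaggerModel, feats: list[dict[str, float]],
                   averaged: bool = False,
                   ) -> tuple[list[str], float, float | None]:
    """Best BIO-valid tag sequence, its score, and the runner-up score.

    The runner-up is the score of the best sequence differing from the
    winner in at least one position (``None`` when only one valid sequence
    exists, e.g. a one-label inventory).
    """
    best, second = _decode_indices(model, feats, averaged, k=2)
    tags = [model.labels[j] for j in best[1]]
    return tags, best[0], (second[0] if second is not None else None)


# ---------------------------------------------------------------------------
# learning
# ---------------------------------------------------------------------------


def _sentence_features(sentences, feature_config, lexicon):
    cfg = feature_config or FeatureConfig()
    return [
        [token_context_features(s, i, cfg, lexicon) for i in range(len(s.tokens))]
        for s in sentences
    ]


def _apply_update(model: TaggerModel, feats, gold: list[int], pred: list[int]) -> None:
    c = model.steps - 1  # averaging accumulator factor
    for fv, g, p in zip(feats, gold, pred):
        if g == p:
            continue
        for f, val in fv.items():
            w = model._ev(f)
            u = model.eu[f]
            w[g] += val
            u[g] += val * c
            w[p] -= val
            u[p] -= val * c
    for seq, sgn in ((gold, 1.0), (pred, -1.0)):
        model.sw[seq[0]] += sgn
        model.su[seq[0]] += sgn * c
        for a, b in zip(seq, seq[1:]):
            model.tw[a, b] += sgn
            model.tu[a, b] += sgn * c
        model.pw[seq[-1]] += sgn
        model.pu[seq[-1]] += sgn * c


def learn(model: TaggerModel, sentences: list[Sentence], epochs: int = 5,
          seed: int = 0, *, feature_config: FeatureConfig | None = None,
          lexicon: ClusterLexicon | None = None,
          features: list[list[dict[str, float]]] | None = None) -> TaggerModel:
    """Train on gold-tagged sentences; return a NEW model (version + 1).

    The input model is never mutated -- the caller can keep decoding with it
    while this call builds its successor.  Gold tags outside the current
    inventory extend it (logged).  Deterministic for a fixed seed:
    per-epoch shuffling is the only randomness.

    ``features`` may carry precomputed per-token feature vectors (parallel
    to ``sentences``) to avoid recomputation across calls.
    """
    if not sentences:
        raise ValueError("empty training set")
    for s in sentences:
        if s.gold_tags is None:
            raise ValueError("all training sentences need gold tags")
        validate_bio(s.gold_tags)
    new = model.copy()
    new.version += 1
    seen = {t for s in sentences for t in s.gold_tags}
    missing = sorted(t for t in seen if t not in new.label_index)
    if missing:
        log.info("extending tag inventory with %s", missing)
        new.extend_labels(missing)
    if features is None:
        features = _sentence_features(sentences, feature_config, lexicon)
    gold_idx = [[new.label_index[t] for t in s.gold_tags] for s in sentences]

    rng = random.Random(seed)
    order = list(range(len(sentences)))
    for _ in range(epochs):
        rng.shuffle(order)
        for si in order:
            new.steps += 1
            best, _ = _decode_indices(new, features[si], averaged=False, k=1)
            pred = list(best[1])
            if pred != gold_idx[si]:
                new.update_count += 1
                _apply_update(new, features[si], gold_idx[si], pred)
    return new


# ---------------------------------------------------------------------------
# suggestion / prediction
# ---------------------------------------------------------------------------


def _confidence(margin: float) -> float:
    """Logistic of the Viterbi margin; monotone in the margin."""
    if margin > 50:
        return 1.0
    return 1.0 / (1.0 + math.exp(-margin))


def suggest_spans(model: TaggerModel, doc: AnnotatedDocument,
                  feature_config: FeatureConfig | None = None,
                  lexicon: ClusterLexicon | None = None) -> list[Suggestion]:
    """Decode every sentence with the averaged weights and propose spans.

    Confidence is the logistic of the sentence-level Viterbi margin (best
    minus runner-up score).  Spans overlapping an existing gold or accepted
    annotation are suppressed: suggestions never overwrite the user's work.
    """
    cfg = feature_config or FeatureConfig()
    existing = [s for s in doc.spans if s.provenance in (GOLD, ACCEPTED)]
    out: list[Suggestion] = []
    nid = 0
    for sent in doc.sentences:
        feats = [token_context_features(sent, i, cfg, lexicon)
                 for i in range(len(sent.tokens))]
        tags, best, runner = viterbi_decode(model, feats, averaged=True)
        margin = best - runner if runner is not None else float("inf")
        conf = _confidence(margin)
        for sp in tags_to_spans(sent, tags, text=doc.text, provenance=SUGGESTED):
            if any(sp.overlaps(e) for e in existing):
                continue
            nid += 1
            out.append(Suggestion(replace(sp, id=f"S{nid}"), conf, model.version))
    return out


def predict_document(model: TaggerModel, doc: AnnotatedDocument,
                     feature_config: FeatureConfig | None = None,
                     lexicon: ClusterLexicon | None = None) -> AnnotatedDocument:
    """A copy of ``doc`` whose spans are the model's averaged-decode output."""
    cfg = feature_config or FeatureConfig()
    spans: list[EntitySpan] = []
    nid = 1
    for sent in doc.sentences:
        feats = [token_context_features(sent, i, cfg, lexicon)
                 for i in range(len(sent.tokens))]
        tags, _, _ = viterbi_decode(model, feats, averaged=True)
        new = tags_to_spans(sent, tags, text=doc.text, id_start=nid,
                            provenance=SUGGESTED)
        nid += len(new)
        spans.extend(new)
    return AnnotatedDocument(doc.doc_id, doc.text, doc.sentences, spans, [])


def accept(doc: AnnotatedDocument, suggestion: Suggestion) -> AnnotatedDocument:
    """Adopt a suggestion as an annotation; idempotent for the same span.

    Returns a new document with the span added with provenance ``accepted``.
    Accepting a suggestion that overlaps a different existing annotation is
    an error (the UI contract never overwrites annotations).
    """
    sp = suggestion.span
    for e in doc.spans:
        if e.provenance not in (GOLD, ACCEPTED):
            continue
        if (e.label, e.begin, e.end) == (sp.label, sp.begin, sp.end):
            return doc
        if e.overlaps(sp):
            raise ValueError(
                f"suggestion [{sp.begin},{sp.end}) overlaps existing "
                f"annotation {e.id} [{e.begin},{e.end})")
    taken = {s.id for s in doc.spans}
    nid = 1
    while f"T{nid}" in taken:
        nid += 1
    new_span = replace(sp, id=f"T{nid}", provenance=ACCEPTED)
    return AnnotatedDocument(doc.doc_id, doc.text, doc.sentences,
                             doc.spans + [new_span], list(doc.relations))


# ---------------------------------------------------------------------------
# serialization (versioned key-value text; bit-exact round trip)
# ---------------------------------------------------------------------------


def save_model(model: TaggerModel, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(MODEL_MAGIC + "\n")
        fh.write(f"version\t{model.version}\n")
        fh.write(f"update_count\t{model.update_count}\n")
        fh.write(f"steps\t{model.steps}\n")
        fh.write("labels\t" + "\t".join(model.labels) + "\n")
        for j in range(model.n_labels):
            if model.sw[j] or model.su[j]:
                fh.write(f"S\t{j}\t{float(model.sw[j])!r}\t{float(model.su[j])!r}\n")
            if model.pw[j] or model.pu[j]:
                fh.write(f"P\t{j}\t{float(model.pw[j])!r}\t{float(model.pu[j])!r}\n")
        for a in range(model.n_labels):
            for b in range(model.n_labels):
                if model.tw[a, b] or model.tu[a, b]:
                    fh.write(f"T\t{a}\t{b}\t{float(model.tw[a, b])!r}"
                             f"\t{float(model.tu[a, b])!r}\n")
        for feat in sorted(model.ew):
            w, u = model.ew[feat], model.eu[feat]
            if not (w.any() or u.any()):
                continue
            for j in range(model.n_labels):
                if w[j] or u[j]:
                    fh.write(f"F\t{feat}\t{j}\t{float(w[j])!r}\t{float(u[j])!r}\n")


def load_model(path) -> TaggerModel:
    with open(path, encoding="utf-8") as fh:
        magic = fh.readline().rstrip("\n")
        if magic != MODEL_MAGIC:
            raise ValueError(f"not a looptag model file: {path}")
        model = TaggerModel()
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            key = parts[0]
            if key == "version":
                model.version = int(parts[1])
            elif key == "update_count":
                model.update_count = int(parts[1])
            elif key == "steps":
                model.steps = int(parts[1])
            elif key == "labels":
                model = _with_labels(model, parts[1:])
            elif key == "S":
                model.sw[int(parts[1])] = float(parts[2])
                model.su[int(parts[1])] = float(parts[3])
            elif key == "P":
                model.pw[int(parts[1])] = float(parts[2])
                model.pu[int(parts[1])] = float(parts[3])
            elif key == "T":
                model.tw[int(parts[1]), int(parts[2])] = float(parts[3])
                model.tu[int(parts[1]), int(parts[2])] = float(parts[4])
            elif key == "F":
                feat, j = parts[1], int(parts[2])
                model._ev(feat)[j] = float(parts[3])
                model.eu[feat][j] = float(parts[4])
            else:
                raise ValueError(f"unknown model record {key!r}")
    return model


def _with_labels(model: TaggerModel, labels: list[str]) -> TaggerModel:
    new = TaggerModel(labels)
    new.version = model.version
    new.update_count = model.update_count
    new.steps = model.steps
    return new
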