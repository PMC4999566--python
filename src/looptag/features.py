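"""Sparse token features for biomedical mention tagging.

Each token in its sentence context is represented by binary features drawn
from four templates, evaluated in a window of +/- ``window_radius`` tokens
around the focus token:

* character affixes -- first and last ``n`` character grams (n=3 by default);
* word shape -- capitalization/character-class abstraction (``IL-2`` ->
  ``AA-0``), with a run-collapsed variant (``A-0``);
* induced word-cluster id -- from a word->cluster lexicon with a
  longest-suffix fallback for unseen words;
* the lowercased surface itself.

Case information is carried exclusively by the shape features; surfaces and
affixes are lowercased to reduce sparsity.  Window positions outside the
sentence contribute explicit ``BOS``/``EOS`` boundary features.

The cluster lexicon is normally produced by :func:`induce_clusters`, a
distributional stand-in for externally trained part-of-speech cluster
models: frequent word types are clustered by k-means on their left/right
neighbour count signatures, and a word-final k-gram table (k = 1..4) maps
unseen words to the majority cluster of their longest known suffix.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from .corpus_io import AnnotatedDocument, Sentence

log = logging.getLogger(__name__)

#: cluster id returned when neither the word nor any suffix is known
UNKNOWN_CLUSTER = "UNK"


@dataclass
class FeatureConfig:
    """Feature template switches and sizes.

    affix_n
        length of prefix/suffix character grams (default 3).
    window_radius
        context half-width in tokens (default 2, i.e. a 5-token window).
    """

    affix_n: int = 3
    window_radius: int = 2
    use_shape: bool = True
    use_cluster: bool = True
    collapse_shape: bool = True

    def __post_init__(self):
        if self.affix_n < 1:
            raise ValueError("affix_n must be >= 1")
        if self.window_radius < 0:
            raise ValueError("window_radius must be >= 0")


@dataclass
class ClusterLexicon:
    """Total word -> cluster-id mapping with longest-suffix fallback.

    Lookup order: exact word; longest word-final k-gram (k = 4..1) present
    in the fallback table; the default cluster.  Lookup therefore never
    fails, for any input string.
    """

    word2cluster: dict[str, str] = field(default_factory=dict)
    suffix2cluster: dict[str, str] = field(default_factory=dict)
    default: str = UNKNOWN_CLUSTER

    def lookup(self, word: str) -> str:
        hit = self.word2cluster.get(word)
        if hit is not None:
            return hit
        for k in (4, 3, 2, 1):
            if len(word) >= k:
                hit = self.suffix2cluster.get(word[-k:])
                if hit is not None:
                    return hit
        return self.default

    # -- two-column text serialization; suffix entries use a reserved
    #    "~suffix:<gram>" pseudo-word, the default uses "~default".
    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"~default\t{self.default}\n")
            for sfx in sorted(self.suffix2cluster):
                fh.write(f"~suffix:{sfx}\t{self.suffix2cluster[sfx]}\n")
            for word in sorted(self.word2cluster):
                fh.write(f"{word}\t{self.word2cluster[word]}\n")

    @classmethod
    def load(cls, path) -> "ClusterLexicon":
        lex = cls()
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                word, _, cid = line.partition("\t")
                if word == "~default":
                    lex.default = cid
                elif word.startswith("~suffix:"):
                    lex.suffix2cluster[word[len("~suffix:"):]] = cid
                else:
                    lex.word2cluster[word] = cid
        return lex


# ---------------------------------------------------------------------------
# single-template features
# ---------------------------------------------------------------------------


def affix_features(surface: str, n: int = 3) -> set[str]:
    """Prefix/suffix n-gram features; whole surface for tokens shorter than n."""
    if not surface:
        raise ValueError("empty token surface")
    prefix = surface[:n]
    suffix = surface[-n:]
    return {f"prefix{n}={prefix}", f"suffix{n}={suffix}"}


def word_shape(surface: str) -> str:
    """Map uppercase->A, lowercase->a, digit->0; other characters verbatim."""
    out = []
    for ch in surface:
        if ch.isupper():
            out.append("A")
        elif ch.islower():
            out.append("a")
        elif ch.isdigit():
            out.append("0")
        else:
            out.append(ch)
    return "".join(out)


def collapse_shape(shape: str) -> str:
    """Squeeze runs of identical shape symbols (``AA-0`` -> ``A-0``)."""
    out = []
    for ch in shape:
        if not out or out[-1] != ch:
            out.append(ch)
    return "".join(out)


def shape_features(surface: str, collapse: bool = True) -> set[str]:
    if not surface:
        raise ValueError("empty token surface")
    raw = word_shape(surface)
    feats = {f"shape={raw}"}
    if collapse:
        feats.add(f"cshape={collapse_shape(raw)}")
    return feats


def cluster_feature(surface: str, lexicon: ClusterLexicon) -> str:
    """Exactly one cluster feature for any surface (lookup is total)."""
    return f"cluster={lexicon.lookup(surface)}"


# ---------------------------------------------------------------------------
# windowed context features
# ---------------------------------------------------------------------------


def token_context_features(sentence: Sentence, i: int,
                           config: FeatureConfig | None = None,
                           lexicon: ClusterLexicon | None = None) -> dict[str, float]:
    """Sparse feature vector for token ``i`` of ``sentence``.

    Emits, for each window offset ``d``, the affix/shape/cluster/surface
    features of the token at ``i+d`` prefixed with ``[d]``; out-of-sentence
    positions contribute ``[d]BOS``/``[d]EOS`` markers.  Pure: identical
    inputs give identical vectors.
    """
    config = config or FeatureConfig()
    n = len(sentence.tokens)
    if not 0 <= i < n:
        raise IndexError(f"token index {i} out of range for sentence of length {n}")
    feats: dict[str, float] = {}
    r = config.window_radius
    for d in range(-r, r + 1):
        tag = f"[{d:+d}]" if d else "[0]"
        j = i + d
        if j < 0:
            feats[f"{tag}BOS"] = 1.0
            continue
        if j >= n:
            feats[f"{tag}EOS"] = 1.0
            continue
        surface = sentence.tokens[j].surface
        lower = surface.lower()
        feats[f"{tag}w={lower}"] = 1.0
        for a in affix_features(lower, config.affix_n):
            feats[f"{tag}{a}"] = 1.0
        if config.use_shape:
            for s in shape_features(surface, config.collapse_shape):
                feats[f"{tag}{s}"] = 1.0
        if config.use_cluster and lexicon is not None:
            feats[f"{tag}{cluster_feature(surface, lexicon)}"] = 1.0
    return feats


# ---------------------------------------------------------------------------
# cluster induction (distributional stand-in)
# ---------------------------------------------------------------------------


def induce_clusters(corpus: list[AnnotatedDocument], k: int, seed: int = 0,
                    max_types: int = 5000, context_words: int = 200,
                    min_suffix_support: int = 5) -> ClusterLexicon:
    """Induce a cluster lexicon from corpus co-occurrence signatures.

    The ``max_types`` most frequent word types are represented by counts of
    the ``context_words`` most frequent types in their immediate left and
    right neighbour slots, L2-normalised, and clustered with k-means
    (deterministic for a fixed seed).  A word-final k-gram fallback table
    (k = 1..4) maps each suffix seen on at least ``min_suffix_support``
    clustered types to the majority cluster of those types.

    Raises ``ValueError`` if ``k`` exceeds the number of clusterable types.
    """
    if not corpus:
        raise ValueError("empty corpus")
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: Counter[str] = Counter()
    sents: list[list[str]] = []
    for doc in corpus:
        for sent in doc.sentences:
            words = [t.surface for t in sent.tokens]
            sents.append(words)
            counts.update(words)
    types = [w for w, _ in counts.most_common(max_types)]
    if k > len(types):
        raise ValueError(f"k={k} exceeds the {len(types)} clusterable types")
    ctx = [w for w, _ in counts.most_common(context_words)]
    ctx_index = {w: j for j, w in enumerate(ctx)}
    type_index = {w: i for i, w in enumerate(types)}

    X = np.zeros((len(types), 2 * len(ctx)))
    for words in sents:
        for p, w in enumerate(words):
            row = type_index.get(w)
            if row is None:
                continue
            if p > 0 and words[p - 1] in ctx_index:
                X[row, ctx_index[words[p - 1]]] += 1
            if p + 1 < len(words) and words[p + 1] in ctx_index:
                X[row, len(ctx) + ctx_index[words[p + 1]]] += 1
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    X /= norms

    from sklearn.cluster import KMeans

    labels = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(X)
    word2cluster = {w: str(c) for w, c in zip(types, labels)}

    suffix_votes: dict[str, Counter[str]] = defaultdict(Counter)
    for w, c in word2cluster.items():
        for klen in range(1, 5):
            if len(w) >= klen:
                suffix_votes[w[-klen:]][c] += 1
    suffix2cluster = {
        sfx: votes.most_common(1)[0][0]
        for sfx, votes in suffix_votes.items()
        if sum(votes.values()) >= min_suffix_support
    }
    lex = ClusterLexicon(word2cluster, suffix2cluster)
    log.info("induced %d clusters over %d types (%d fallback suffixes)",
             k, len(types), len(suffix2cluster))
    return lex
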