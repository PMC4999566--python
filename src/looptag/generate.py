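"""Deterministic generator of biomedical-like synthetic corpora.

The generator emulates the statistics that make biomedical mention tagging
and relation copying learnable, without any linguistic realism:

* background text is a Zipf-distributed pseudo-word vocabulary (abstracts
  have heavy-tailed unigram distributions);
* entity mentions carry type-specific surface morphology -- a
  characteristic suffix, a capitalization pattern and a digit rate -- which
  is exactly why word-shape and affix features work on real biomedical
  entities, whose shapes differ from ordinary tokens;
* each entity type has a characteristic context cue word that precedes a
  fraction of its mentions, giving distributional cluster induction a
  signal, as induced word clusters do on real text;
* entity surfaces are reused with configurable probability, and previously
  related entity pairs recur in later sentences, so relation-copy
  opportunities arise at a controllable rate;
* a small fraction of background tokens reuse entity surfaces (ambiguity),
  so the tagger's ceiling is below 100 %.

Default inventories: the eight entity types of a clinician-defined
annotation schema (cell, condition, disorder, gene, molecule,
molecular_pathway, protein, substance) and ten relation labels between
them (Equivalent, Protein-component, Subunit-complex, Activator-reactor,
Antibody-antigen, Cell-marker, Cell-variant, DNA-transcript,
Ligand-receptor, Protein-variant).

Alongside the corpus the generator returns hidden ground-truth bookkeeping
(true word classes, planted relation signatures, mention tables) from which
tests compute oracle answers for cluster purity, relation-copy counts and
the tagger ceiling, independently of the library code under test.
"""

from __future__ import annotations

import bisect
import random
from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .corpus_io import (AnnotatedDocument, EntitySpan, RelationInstance,
                        Sentence, Token)

_LETTERS = "abcdefghijklmnopqrstuvwxyz"


@dataclass
class EntityTypeSpec:
    """Surface morphology of one entity type.

    ``caps`` is one of ``lower``, ``capital`` (initial uppercase) or
    ``upper``; ``length_p`` is the success probability of the geometric
    mention-length distribution (high p => mostly single-token mentions);
    ``trigger`` is the context cue word optionally preceding mentions.
    Multi-token mentions are a morphology head followed by type-typical
    tail words (``... pathway``, ``... complex``), the structure real
    multi-word biomedical names have; a type with no tail words only
    produces single-token mentions.
    """

    suffix: str = ""
    caps: str = "lower"
    digit_rate: float = 0.0
    length_p: float = 0.85
    trigger: str = ""
    tail: tuple[str, ...] = ()


def default_entity_types() -> dict[str, EntityTypeSpec]:
    return {
        "cell": EntityTypeSpec("cyte", "lower", 0.0, 0.9, "differentiated",
                               ("cells",)),
        "condition": EntityTypeSpec("emia", "lower", 0.0, 0.9, "chronic",
                                    ("state",)),
        "disorder": EntityTypeSpec("osis", "lower", 0.0, 0.9, "acute",
                                   ("disease",)),
        "gene": EntityTypeSpec("", "upper", 0.8, 0.9, "expressed",
                               ("locus",)),
        "molecule": EntityTypeSpec("ose", "lower", 0.0, 0.9, "soluble",
                                   ("derivative",)),
        "molecular_pathway": EntityTypeSpec("", "capital", 0.0, 0.65,
                                            "canonical",
                                            ("signaling", "pathway", "cascade")),
        "protein": EntityTypeSpec("ase", "capital", 0.2, 0.8, "phosphorylated",
                                  ("complex", "receptor")),
        "substance": EntityTypeSpec("ine", "lower", 0.0, 0.9, "dietary",
                                    ("extract",)),
    }


def default_relation_table() -> dict[tuple[str, str], tuple[str, float]]:
    """(source type, target type) -> (relation label, planting probability)."""
    return {
        ("molecule", "molecule"): ("Equivalent", 0.3),
        ("gene", "protein"): ("Protein-component", 0.5),
        ("molecular_pathway", "protein"): ("Subunit-complex", 0.4),
        ("protein", "molecular_pathway"): ("Activator-reactor", 0.4),
        ("protein", "substance"): ("Antibody-antigen", 0.4),
        ("cell", "protein"): ("Cell-marker", 0.5),
        ("cell", "cell"): ("Cell-variant", 0.4),
        ("gene", "gene"): ("DNA-transcript", 0.4),
        ("protein", "molecule"): ("Ligand-receptor", 0.5),
        ("protein", "protein"): ("Protein-variant", 0.4),
    }


@dataclass
class GeneratorConfig:
    """All dials of the synthetic corpus; same config + seed => same corpus."""

    seed: int = 1
    n_docs: int = 40
    sentences_per_doc: tuple[int, int] = (5, 12)
    sentence_len: tuple[int, int] = (8, 25)
    vocab_size: int = 1500
    zipf_exponent: float = 1.1
    entity_types: dict[str, EntityTypeSpec] = field(default_factory=default_entity_types)
    entity_density: float = 0.10
    ambiguity_rate: float = 0.05
    ambiguous_token_rate: float = 0.01
    trigger_prob: float = 0.6
    surface_reuse: float = 0.5
    relation_table: dict[tuple[str, str], tuple[str, float]] = field(
        default_factory=default_relation_table)
    pair_repeat_rate: float = 0.3
    same_doc_repeat_bias: float = 0.75
    repeat_annotate_prob: float = 0.5

    def validate(self) -> None:
        for name, p in (("entity_density", self.entity_density),
                        ("ambiguity_rate", self.ambiguity_rate),
                        ("ambiguous_token_rate", self.ambiguous_token_rate),
                        ("trigger_prob", self.trigger_prob),
                        ("surface_reuse", self.surface_reuse),
                        ("pair_repeat_rate", self.pair_repeat_rate),
                        ("same_doc_repeat_bias", self.same_doc_repeat_bias),
                        ("repeat_annotate_prob", self.repeat_annotate_prob)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for pair, (label, prob) in self.relation_table.items():
            if not 0.0 <= prob <= 1.0:
                raise ValueError(f"planting probability for {pair} out of [0, 1]")
            for t in pair:
                if t not in self.entity_types:
                    raise ValueError(f"relation table references unknown type {t!r}")
        for name, spec in self.entity_types.items():
            if spec.caps not in ("lower", "capital", "upper"):
                raise ValueError(f"{name}: unknown caps pattern {spec.caps!r}")
            if not 0.0 < spec.length_p <= 1.0:
                raise ValueError(f"{name}: length_p must be in (0, 1]")
        if self.vocab_size < 10:
            raise ValueError("vocab_size too small")


@dataclass
class Mention:
    doc_id: str
    sent_index: int
    tok_begin: int
    tok_end: int
    entity_type: str
    covered_text: str


@dataclass
class Bookkeeping:
    """Hidden ground truth used only by oracle computations, never by the
    library code under test."""

    surface_class: dict[str, str] = field(default_factory=dict)
    mentions: list[Mention] = field(default_factory=list)
    annotated_signatures: Counter = field(default_factory=Counter)
    n_background_tokens: int = 0
    n_ambiguous_tokens: int = 0

    def copy_opportunities(self) -> int:
        """Signature-matching ordered same-sentence span pairs NOT annotated.

        Computed purely from the mention/signature tables: for every
        annotated signature, count ordered mention pairs in one sentence
        whose texts and types match it, then subtract the annotated
        instances themselves.
        """
        per_sent: dict[tuple[str, int], list[Mention]] = defaultdict(list)
        for m in self.mentions:
            per_sent[(m.doc_id, m.sent_index)].append(m)
        total = 0
        for sig, n_annotated in self.annotated_signatures.items():
            _, src_text, src_type, tgt_text, tgt_type = sig
            matches = 0
            for group in per_sent.values():
                srcs = [m for m in group
                        if m.covered_text == src_text and m.entity_type == src_type]
                tgts = [m for m in group
                        if m.covered_text == tgt_text and m.entity_type == tgt_type]
                for a in srcs:
                    for b in tgts:
                        if (a.tok_begin, a.tok_end) != (b.tok_begin, b.tok_end):
                            matches += 1
            total += matches - n_annotated
        return total


class _Zipf:
    """Zipf-distributed sampler over a fixed pseudo-word vocabulary."""

    def __init__(self, rng: random.Random, size: int, exponent: float,
                 forbidden_suffixes: tuple[str, ...]):
        self.words: list[str] = []
        seen = set()
        while len(self.words) < size:
            w = "".join(rng.choice(_LETTERS)
                        for _ in range(rng.randint(2, 9)))
            if w in seen or any(w.endswith(s) for s in forbidden_suffixes if s):
                continue
            seen.add(w)
            self.words.append(w)
        weights = [1.0 / (r ** exponent) for r in range(1, size + 1)]
        total = sum(weights)
        acc = 0.0
        self.cum = []
        for w in weights:
            acc += w / total
            self.cum.append(acc)

    def sample(self, rng: random.Random) -> str:
        return self.words[bisect.bisect_left(self.cum, rng.random())]


def _new_surface(rng: random.Random, spec: EntityTypeSpec) -> list[str]:
    """A fresh entity surface: morphology head plus optional tail words."""
    stem = "".join(rng.choice(_LETTERS) for _ in range(rng.randint(3, 6)))
    head = stem + spec.suffix
    if spec.caps == "capital":
        head = head[0].upper() + head[1:]
    elif spec.caps == "upper":
        head = head.upper()
    if rng.random() < spec.digit_rate:
        head += f"-{rng.randint(1, 9)}"
    tokens = [head]
    if spec.tail:
        while rng.random() > spec.length_p and len(tokens) < 3:
            tokens.append(spec.tail[rng.randrange(len(spec.tail))])
    return tokens


def generate_corpus(config: GeneratorConfig | None = None,
                    ) -> tuple[list[AnnotatedDocument], Bookkeeping]:
    """Generate documents plus hidden ground-truth bookkeeping.

    Deterministic: the same config (including seed) always yields the same
    corpus, byte for byte under IOB serialization.
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = random.Random(config.seed)
    type_names = sorted(config.entity_types)
    suffixes = tuple(s.suffix for s in config.entity_types.values())
    zipf = _Zipf(rng, config.vocab_size, config.zipf_exponent, suffixes)
    book = Bookkeeping()

    # per-type pools of previously used surfaces (token lists)
    pools: dict[str, list[list[str]]] = {t: [] for t in type_names}
    # relation signatures seen so far: globally and in the current document.
    # Pair recurrence is biased toward the current document -- documents
    # discuss the same entity pairs repeatedly, which is what makes
    # same-document relation copying far more productive than copying
    # across independently selected documents.
    sig_history: list[tuple] = []
    ambiguity_pool: list[str] = []

    docs: list[AnnotatedDocument] = []
    for d in range(config.n_docs):
        doc_id = f"syn{d + 1:04d}"
        n_sent = rng.randint(*config.sentences_per_doc)
        sent_token_rows: list[list[str]] = []
        sent_entities: list[list[tuple[int, int, str, str]]] = []
        doc_sigs: list[tuple] = []
        # relation annotations as (sent idx, src ent, tgt ent, label)
        rel_tuples: list[tuple[int, tuple, tuple, str]] = []
        annotated_here: set = set()

        def annotate(si, src_e, tgt_e, label):
            pair = (si, src_e[:2], tgt_e[:2], label)
            if pair in annotated_here or src_e[:2] == tgt_e[:2]:
                return
            annotated_here.add(pair)
            rel_tuples.append((si, src_e, tgt_e, label))
            sig = (label, src_e[3], src_e[2], tgt_e[3], tgt_e[2])
            book.annotated_signatures[sig] += 1
            if sig not in sig_history:
                sig_history.append(sig)
            if sig not in doc_sigs:
                doc_sigs.append(sig)

        for si in range(n_sent):
            target_len = rng.randint(*config.sentence_len)
            words: list[str] = []
            ents: list[tuple[int, int, str, str]] = []  # tok_begin, tok_end, type, text

            def plant(etype: str, tokens: list[str]):
                if rng.random() < config.trigger_prob:
                    spec = config.entity_types[etype]
                    if spec.trigger:
                        words.append(spec.trigger)
                start = len(words)
                words.extend(tokens)
                ents.append((start, len(words), etype, " ".join(tokens)))
                for tok in tokens:
                    book.surface_class.setdefault(tok, etype)

            repeat_sig = None
            if sig_history and rng.random() < config.pair_repeat_rate:
                source = sig_history
                if doc_sigs and rng.random() < config.same_doc_repeat_bias:
                    source = doc_sigs
                repeat_sig = source[rng.randrange(len(source))]
                _, src_text, src_type, tgt_text, tgt_type = repeat_sig
                plant(src_type, src_text.split(" "))
                words.append(zipf.sample(rng))
                plant(tgt_type, tgt_text.split(" "))

            while len(words) < target_len:
                roll = rng.random()
                if roll < config.entity_density:
                    etype = type_names[rng.randrange(len(type_names))]
                    pool = pools[etype]
                    if pool and rng.random() < config.surface_reuse:
                        tokens = pool[rng.randrange(len(pool))]
                    else:
                        tokens = _new_surface(rng, config.entity_types[etype])
                        pool.append(tokens)
                        # a fixed fraction of surfaces is ambiguous: it also
                        # occurs as a plain background word elsewhere
                        if (len(tokens) == 1 and tokens[0].islower()
                                and rng.random() < config.ambiguity_rate):
                            ambiguity_pool.append(tokens[0])
                    plant(etype, tokens)
                elif (roll < config.entity_density + config.ambiguous_token_rate
                      and ambiguity_pool):
                    words.append(ambiguity_pool[rng.randrange(len(ambiguity_pool))])
                    book.n_ambiguous_tokens += 1
                else:
                    words.append(zipf.sample(rng))
                    book.n_background_tokens += 1
            words.append(".")
            sent_token_rows.append(words)
            sent_entities.append(ents)

            # relation annotation decisions for this sentence
            if repeat_sig is not None and rng.random() < config.repeat_annotate_prob:
                label, src_text, src_type, tgt_text, tgt_type = repeat_sig
                srcs = [e for e in ents if e[3] == src_text and e[2] == src_type]
                tgts = [e for e in ents if e[3] == tgt_text and e[2] == tgt_type]
                if srcs and tgts:
                    annotate(si, srcs[0], tgts[-1], label)
            for i, a in enumerate(ents):
                for b in ents[i + 1:]:
                    hit = config.relation_table.get((a[2], b[2]))
                    if hit is not None:
                        if rng.random() < hit[1]:
                            annotate(si, a, b, hit[0])
                        continue
                    hit = config.relation_table.get((b[2], a[2]))
                    if hit is not None and rng.random() < hit[1]:
                        annotate(si, b, a, hit[0])

        doc = _assemble(doc_id, sent_token_rows, sent_entities)
        _materialize_relations(doc, sent_entities, rel_tuples)
        for si, ents in enumerate(sent_entities):
            for (tb, te, etype, text) in ents:
                book.mentions.append(Mention(doc_id, si, tb, te, etype, text))
        doc.validate()
        docs.append(doc)
    return docs, book


def _assemble(doc_id, sent_token_rows, sent_entities) -> AnnotatedDocument:
    sentences: list[Sentence] = []
    spans: list[EntitySpan] = []
    text_parts: list[str] = []
    offset = 0
    nid = 1
    for words, ents in zip(sent_token_rows, sent_entities):
        tokens: list[Token] = []
        pos = offset
        for i, w in enumerate(words):
            tokens.append(Token(w, pos, pos + len(w), i))
            pos += len(w) + 1
        sent = Sentence(tokens)
        tags = ["O"] * len(words)
        for (tb, te, etype, text) in ents:
            spans.append(EntitySpan(
                f"T{nid}", etype, tokens[tb].begin, tokens[te - 1].end, text))
            nid += 1
            tags[tb] = "B-" + etype
            for k in range(tb + 1, te):
                tags[k] = "I-" + etype
        sent.gold_tags = tags
        sentences.append(sent)
        text_parts.append(" ".join(words))
        offset = pos  # accounts for the newline joining sentences
    return AnnotatedDocument(doc_id, "\n".join(text_parts), sentences, spans)


def _materialize_relations(doc, sent_entities, rel_tuples) -> None:
    """Turn (sentence, entity, entity, label) tuples into relation instances."""
    span_at: dict[tuple[int, int, int], EntitySpan] = {}
    cursor = 0
    for si, ents in enumerate(sent_entities):
        for e in ents:
            span_at[(si, e[0], e[1])] = doc.spans[cursor]
            cursor += 1
    for rid, (si, src_e, tgt_e, label) in enumerate(rel_tuples, start=1):
        src = span_at[(si, src_e[0], src_e[1])]
        tgt = span_at[(si, tgt_e[0], tgt_e[1])]
        doc.relations.append(RelationInstance(f"R{rid}", label, src.id, tgt.id))


def corpus_stats(docs: list[AnnotatedDocument]) -> dict:
    """Exact summary counts for a corpus (compared to bookkeeping in tests)."""
    stats = {
        "documents": len(docs),
        "sentences": 0,
        "tokens": 0,
        "spans": 0,
        "relations": 0,
        "spans_per_label": Counter(),
        "relations_per_label": Counter(),
    }
    for doc in docs:
        stats["sentences"] += len(doc.sentences)
        stats["tokens"] += sum(len(s.tokens) for s in doc.sentences)
        stats["spans"] += len(doc.spans)
        stats["relations"] += len(doc.relations)
        for sp in doc.spans:
            stats["spans_per_label"][sp.label] += 1
        for rel in doc.relations:
            stats["relations_per_label"][rel.label] += 1
    return stats


def save_bookkeeping(book: Bookkeeping, path) -> None:
    """Sidecar TSV with the hidden ground truth (synthetic corpora only)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("record\tfields\n")
        for w in sorted(book.surface_class):
            fh.write(f"class\t{w}\t{book.surface_class[w]}\n")
        for m in book.mentions:
            fh.write(f"mention\t{m.doc_id}\t{m.sent_index}\t{m.tok_begin}\t"
                     f"{m.tok_end}\t{m.entity_type}\t{m.covered_text}\n")
        for sig, n in sorted(book.annotated_signatures.items()):
            fh.write("signature\t" + "\t".join(sig) + f"\t{n}\n")
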