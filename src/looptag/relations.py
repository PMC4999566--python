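"""Relation-copy suggestion: re-propose previously annotated relations.

The suggester keeps no statistical model.  It remembers every annotated
relation as a five-field signature -- relation label, source covered text,
source entity label, target covered text, target entity label -- and
proposes a new relation instance wherever an ordered span pair with exactly
matching covered texts and entity labels recurs, in the same or any later
document.  The approach is highly precise but by construction can never
propose a relation type/pair it has not seen annotated.

Matching is exact-string, case- and direction-sensitive by default;
case-insensitive matching of the covered texts is available as a flag.
Candidate pairs are restricted to the same sentence by default (the
combinatorially safe scope); whole-document scope is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

from .corpus_io import (ACCEPTED, GOLD, AnnotatedDocument, DataError,
                        RelationInstance, spans_in_sentence)

log = logging.getLogger(__name__)

SCOPE_SENTENCE = "same_sentence"
SCOPE_DOCUMENT = "same_document"


class RelationKey(NamedTuple):
    """The match signature that drives relation copying (directional)."""

    relation_label: str
    source_text: str
    source_label: str
    target_text: str
    target_label: str


@dataclass
class RelationMemory:
    """Set of seen relation signatures with their provenance lists."""

    keys: dict[RelationKey, list[tuple[str, str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.keys)

    def __contains__(self, key: RelationKey) -> bool:
        return key in self.keys

    def add_document(self, doc: AnnotatedDocument) -> None:
        """Record every gold/accepted relation of ``doc``.  Monotone: keys
        are only ever added, never removed."""
        for rel in doc.relations:
            if rel.provenance not in (GOLD, ACCEPTED):
                continue
            try:
                src = doc.span_by_id(rel.source)
                tgt = doc.span_by_id(rel.target)
            except KeyError as exc:
                raise DataError(
                    f"{doc.doc_id}: relation {rel.id} endpoint {exc.args[0]} "
                    f"missing") from None
            key = RelationKey(rel.label, src.covered_text, src.label,
                              tgt.covered_text, tgt.label)
            self.keys.setdefault(key, []).append((doc.doc_id, rel.id))


def build_memory(documents: Iterable[AnnotatedDocument]) -> RelationMemory:
    """One key per distinct signature across all documents' annotated relations."""
    memory = RelationMemory()
    for doc in documents:
        memory.add_document(doc)
    return memory


@dataclass
class RelationMetrics:
    """Suggestion-yield averages in the layout of the standoff experiments.

    ``per_relation`` is reported to one decimal, ``per_doc`` and
    ``across_docs`` to two, mirroring how these averages are conventionally
    printed.
    """

    docs: int
    suggestions_total: int
    relations_annotated: int
    per_relation: float
    per_doc: float
    across_docs: float

    TSV_HEADER = "Docs\tAll\tRels\tPerrel\tPerdoc\tAcrossdocs"

    def tsv_row(self) -> str:
        return (f"{self.docs}\t{self.suggestions_total}\t"
                f"{self.relations_annotated}\t{self.per_relation}\t"
                f"{self.per_doc}\t{self.across_docs}")


def relation_metrics(docs: int, suggestions_total: int,
                     relations_annotated: int,
                     cross_doc_suggestions: int = 0) -> RelationMetrics:
    """Average suggestions per relation / per document / across documents."""
    if docs < 1 or relations_annotated < 1:
        raise ValueError("need at least one document and one annotated relation")
    return RelationMetrics(
        docs=docs,
        suggestions_total=suggestions_total,
        relations_annotated=relations_annotated,
        per_relation=round(suggestions_total / relations_annotated, 1),
        per_doc=round(suggestions_total / docs, 2),
        across_docs=round(cross_doc_suggestions / relations_annotated, 2),
    )


def _match(memory: RelationMemory, src, tgt, casefold: bool):
    """Memory keys matching this ordered span pair."""
    hits = []
    for key in memory.keys:
        if key.source_label != src.label or key.target_label != tgt.label:
            continue
        if casefold:
            if (key.source_text.casefold() == src.covered_text.casefold()
                    and key.target_text.casefold() == tgt.covered_text.casefold()):
                hits.append(key)
        elif (key.source_text == src.covered_text
              and key.target_text == tgt.covered_text):
            hits.append(key)
    return hits


def suggest_relations(memory: RelationMemory, doc: AnnotatedDocument,
                      scope: str = SCOPE_SENTENCE,
                      case_sensitive: bool = True) -> list[RelationInstance]:
    """Propose one relation per in-scope span pair whose signature is in memory.

    Pairs already related by an existing annotation with the same label are
    skipped.  Output is deterministic, ordered by (source begin, target
    begin, label).  Suggested spans are eligible endpoints, so entity
    suggestions can feed relation suggestions.
    """
    if scope not in (SCOPE_SENTENCE, SCOPE_DOCUMENT):
        raise ValueError(f"unknown scope {scope!r}")
    existing = set()
    for rel in doc.relations:
        existing.add((rel.source, rel.target, rel.label))

    if scope == SCOPE_SENTENCE:
        groups = [spans_in_sentence(sent, doc.spans) for sent in doc.sentences]
    else:
        groups = [list(doc.spans)]

    out: list[RelationInstance] = []
    emitted = set()
    for group in groups:
        for src in group:
            for tgt in group:
                if src.id == tgt.id:
                    continue
                for key in _match(memory, src, tgt, casefold=not case_sensitive):
                    trip = (src.id, tgt.id, key.relation_label)
                    if trip in existing or trip in emitted:
                        continue
                    emitted.add(trip)
                    out.append(RelationInstance(
                        id="", label=key.relation_label, source=src.id,
                        target=tgt.id, provenance="suggested"))
    span_pos = {s.id: (s.begin, s.end) for s in doc.spans}
    out.sort(key=lambda r: (span_pos[r.source], span_pos[r.target], r.label))
    for i, rel in enumerate(out, start=1):
        rel.id = f"SR{i}"
    return out
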