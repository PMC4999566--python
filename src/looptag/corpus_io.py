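"""Corpus readers/writers for the two annotation dialects used by the toolkit.

Two on-disk formats are supported:

* **IOB** -- token-per-line files with at least two whitespace-separated
  columns (token, BIO tag), a blank line terminating each sentence, in the
  style of the BioNLP-NLPBA 2004 shared-task distribution.  A line whose
  first column is ``-DOCSTART-`` marks a document boundary (its optional
  second column is taken as the document id); a file without markers is a
  single document.

* **Standoff** -- a raw UTF-8 ``.txt`` file plus an annotation file with
  ``T``-lines for entity spans and ``R``-lines for binary relations,
  compatible with the BioNLP shared-task entity/relation supporting-task
  layout.  All offsets are 0-based, half-open, in characters.

The module also provides the span<->tag converters (`spans_to_bio`,
`tags_to_spans`) shared by the tagger and the evaluation code.

Conventions enforced throughout:

* offsets are 0-based half-open character offsets into the document text;
* a span's ``covered_text`` always equals the text slice it points at;
* span boundaries coincide with token boundaries;
* overlapping or discontinuous entities are rejected (BIO cannot encode
  them), never silently dropped.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, TextIO

log = logging.getLogger(__name__)

#: provenance values carried by spans and relations
GOLD = "gold"
SUGGESTED = "suggested"
ACCEPTED = "accepted"

PROVENANCES = (GOLD, SUGGESTED, ACCEPTED)


class DataError(ValueError):
    """Raised for malformed corpus input (carries a human-readable location)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Token:
    """A single token anchored in the document text.

    ``begin``/``end`` are character offsets (0-based, half-open) into the
    owning document's text; ``sent_index`` is the ordinal of the token
    within its sentence.
    """

    surface: str
    begin: int
    end: int
    sent_index: int


@dataclass
class Sentence:
    """An ordered, non-overlapping token sequence, optionally gold-tagged."""

    tokens: list[Token]
    gold_tags: list[str] | None = None

    @property
    def begin(self) -> int:
        return self.tokens[0].begin

    @property
    def end(self) -> int:
        return self.tokens[-1].end

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class EntitySpan:
    """A typed, contiguous entity mention (label vocabulary is open)."""

    id: str
    label: str
    begin: int
    end: int
    covered_text: str
    provenance: str = GOLD

    def overlaps(self, other: "EntitySpan") -> bool:
        return self.begin < other.end and other.begin < self.end

    def signature(self) -> tuple[str, int, int]:
        return (self.label, self.begin, self.end)


@dataclass
class RelationInstance:
    """A directed, typed relation between two entity spans (by span id)."""

    id: str
    label: str
    source: str
    target: str
    provenance: str = GOLD


@dataclass
class AnnotatedDocument:
    doc_id: str
    text: str
    sentences: list[Sentence]
    spans: list[EntitySpan] = field(default_factory=list)
    relations: list[RelationInstance] = field(default_factory=list)

    def span_by_id(self, span_id: str) -> EntitySpan:
        for s in self.spans:
            if s.id == span_id:
                return s
        raise KeyError(span_id)

    def validate(self) -> None:
        """Check all structural invariants; raise :class:`DataError` on failure."""
        n = len(self.text)
        for sent in self.sentences:
            prev_end = -1
            for i, tok in enumerate(sent.tokens):
                if not (0 <= tok.begin < tok.end <= n):
                    raise DataError(
                        f"{self.doc_id}: token offsets [{tok.begin},{tok.end}) "
                        f"outside text of length {n}")
                if self.text[tok.begin:tok.end] != tok.surface:
                    raise DataError(
                        f"{self.doc_id}: token surface {tok.surface!r} does not "
                        f"match text slice {self.text[tok.begin:tok.end]!r}")
                if tok.begin < prev_end:
                    raise DataError(f"{self.doc_id}: tokens overlap or unordered")
                if tok.sent_index != i:
                    raise DataError(f"{self.doc_id}: bad sent_index on {tok.surface!r}")
                prev_end = tok.end
            if sent.gold_tags is not None:
                if len(sent.gold_tags) != len(sent.tokens):
                    raise DataError(f"{self.doc_id}: tag/token length mismatch")
                validate_bio(sent.gold_tags)
        ids = set()
        for sp in self.spans:
            if sp.id in ids:
                raise DataError(f"{self.doc_id}: duplicate span id {sp.id}")
            ids.add(sp.id)
            if self.text[sp.begin:sp.end] != sp.covered_text:
                raise DataError(
                    f"{self.doc_id}: span {sp.id} covered_text {sp.covered_text!r} "
                    f"!= text slice {self.text[sp.begin:sp.end]!r}")
        for rel in self.relations:
            if rel.source == rel.target:
                raise DataError(f"{self.doc_id}: relation {rel.id} is reflexive")
            for endpoint in (rel.source, rel.target):
                if endpoint not in ids:
                    raise DataError(
                        f"{self.doc_id}: relation {rel.id} references missing "
                        f"span {endpoint}")


# ---------------------------------------------------------------------------
# BIO tag helpers
# ---------------------------------------------------------------------------

_TAG_RE = re.compile(r"^(O|[BI]-\S+)$")


def parse_tag(tag: str) -> tuple[str, str | None]:
    """Split a BIO tag into (prefix, label); raise DataError if malformed."""
    if tag == "O":
        return "O", None
    if not _TAG_RE.match(tag):
        raise DataError(f"malformed BIO tag {tag!r}")
    return tag[0], tag[2:]


def validate_bio(tags: Iterable[str]) -> None:
    """Raise :class:`DataError` unless ``tags`` is a well-formed BIO sequence."""
    open_label = None
    for tag in tags:
        prefix, lab = parse_tag(tag)
        if prefix == "I" and lab != open_label:
            raise DataError(f"I-{lab} without an open {lab} span")
        open_label = lab if prefix in ("B", "I") else None


def repair_bio(tags: list[str], strict: bool = False,
               where: str = "") -> list[str]:
    """Repair orphan ``I-X`` tags (no preceding ``B-X``/``I-X``) to ``B-X``.

    In strict mode a :class:`DataError` is raised instead; in lenient mode
    (the default) the repair is logged.  Published corpora do contain such
    glitches, hence the lenient default.
    """
    out: list[str] = []
    open_label = None
    for tag in tags:
        prefix, lab = parse_tag(tag)
        if prefix == "I" and lab != open_label:
            if strict:
                raise DataError(f"{where}: I-{lab} without an open {lab} span")
            log.warning("%s: orphan I-%s repaired to B-%s", where or "<input>", lab, lab)
            tag = "B-" + lab
            prefix = "B"
        out.append(tag)
        open_label = lab if prefix in ("B", "I") else None
    return out


# ---------------------------------------------------------------------------
# span <-> tag conversion
# ---------------------------------------------------------------------------


def spans_to_bio(sentence: Sentence, spans: Iterable[EntitySpan]) -> list[str]:
    """Encode token-aligned, non-overlapping spans of one sentence as BIO tags.

    Raises :class:`DataError` if a span is not aligned with token boundaries
    or if two spans overlap (BIO cannot encode either situation).
    """
    starts = {tok.begin: i for i, tok in enumerate(sentence.tokens)}
    ends = {tok.end: i for i, tok in enumerate(sentence.tokens)}
    tags = ["O"] * len(sentence.tokens)
    for span in sorted(spans, key=lambda s: (s.begin, s.end)):
        if span.begin not in starts or span.end not in ends:
            raise DataError(
                f"span {span.id} [{span.begin},{span.end}) is not aligned with "
                f"token boundaries")
        i0, i1 = starts[span.begin], ends[span.end]
        for k in range(i0, i1 + 1):
            if tags[k] != "O":
                raise DataError(
                    f"span {span.id} overlaps another span at token {k}; BIO "
                    f"cannot encode overlapping entities")
        tags[i0] = "B-" + span.label
        for k in range(i0 + 1, i1 + 1):
            tags[k] = "I-" + span.label
    return tags


def tags_to_spans(sentence: Sentence, tags: list[str], text: str | None = None,
                  strict: bool = False, id_prefix: str = "T",
                  id_start: int = 1, provenance: str = GOLD) -> list[EntitySpan]:
    """Decode a BIO tag sequence of one sentence into entity spans.

    ``text`` is the full document text used for ``covered_text``; when absent
    the covered text is reconstructed by single-space joining of the token
    surfaces (the IOB text-reconstruction convention).  Orphan ``I-X`` tags
    are repaired per :func:`repair_bio`.
    """
    if len(tags) != len(sentence.tokens):
        raise DataError(
            f"tag sequence length {len(tags)} != token count {len(sentence.tokens)}")
    tags = repair_bio(list(tags), strict=strict)
    spans: list[EntitySpan] = []
    i = 0
    nid = id_start
    while i < len(tags):
        prefix, lab = parse_tag(tags[i])
        if prefix != "B":
            i += 1
            continue
        j = i + 1
        while j < len(tags) and tags[j] == "I-" + lab:
            j += 1
        begin = sentence.tokens[i].begin
        end = sentence.tokens[j - 1].end
        if text is not None:
            covered = text[begin:end]
        else:
            covered = " ".join(t.surface for t in sentence.tokens[i:j])
        spans.append(EntitySpan(f"{id_prefix}{nid}", lab, begin, end, covered,
                                provenance=provenance))
        nid += 1
        i = j
    return spans


def spans_in_sentence(sentence: Sentence, spans: Iterable[EntitySpan]) -> list[EntitySpan]:
    """Spans fully contained in the sentence's character range."""
    return [s for s in spans if s.begin >= sentence.begin and s.end <= sentence.end]


# ---------------------------------------------------------------------------
# IOB dialect
# ---------------------------------------------------------------------------


def _lines(stream) -> list[str]:
    if isinstance(stream, str):
        return stream.splitlines()
    return [line.rstrip("\n") for line in stream]


def read_iob(stream, strict: bool = False) -> list[AnnotatedDocument]:
    """Parse a token-per-line IOB stream into annotated documents.

    ``stream`` may be a string, an open text file, or any iterable of lines.
    Document text is reconstructed by joining tokens with single spaces and
    sentences with newlines.  Malformed tags raise :class:`DataError` naming
    the offending line; orphan ``I-X`` tags are repaired (lenient, default)
    or rejected (strict).
    """
    docs: list[AnnotatedDocument] = []
    sent_rows: list[list[tuple[str, str, int]]] = []
    cur: list[tuple[str, str, int]] = []
    doc_id: str | None = None
    explicit_doc = False

    def flush_sentence():
        nonlocal cur
        if cur:
            sent_rows.append(cur)
            cur = []

    def flush_doc(next_id: str | None):
        nonlocal sent_rows, doc_id, explicit_doc
        flush_sentence()
        if sent_rows or explicit_doc:
            did = doc_id if doc_id is not None else f"doc{len(docs) + 1}"
            docs.append(_build_iob_doc(did, sent_rows, strict))
        sent_rows = []
        doc_id = next_id

    for lineno, raw in enumerate(_lines(stream), start=1):
        if not raw.strip():
            flush_sentence()
            continue
        cols = raw.split()
        if cols[0] == "-DOCSTART-":
            flush_doc(cols[1] if len(cols) > 1 else None)
            explicit_doc = True
            continue
        if len(cols) < 2:
            raise DataError(f"line {lineno}: expected at least token and tag columns")
        tag = cols[-1]
        if not _TAG_RE.match(tag):
            raise DataError(f"line {lineno}: malformed BIO tag {tag!r}")
        cur.append((cols[0], tag, lineno))
    flush_doc(None)
    return docs


def _build_iob_doc(doc_id: str, sent_rows, strict: bool) -> AnnotatedDocument:
    sentences: list[Sentence] = []
    text_parts: list[str] = []
    offset = 0
    for rows in sent_rows:
        tokens: list[Token] = []
        tags: list[str] = []
        for i, (surface, tag, lineno) in enumerate(rows):
            begin = offset
            end = begin + len(surface)
            tokens.append(Token(surface, begin, end, i))
            tags.append(tag)
            offset = end + 1  # single space / newline separator
        first_line = rows[0][2]
        tags = repair_bio(tags, strict=strict, where=f"line {first_line}")
        sentences.append(Sentence(tokens, gold_tags=tags))
        text_parts.append(" ".join(surface for surface, _, _ in rows))
    text = "\n".join(text_parts)
    doc = AnnotatedDocument(doc_id, text, sentences)
    nid = 1
    for sent in sentences:
        spans = tags_to_spans(sent, sent.gold_tags, text=text, id_start=nid)
        nid += len(spans)
        doc.spans.extend(spans)
    doc.validate()
    return doc


def write_iob(docs: Iterable[AnnotatedDocument]) -> str:
    """Serialize documents as a token-per-line IOB stream (byte-stable).

    Every document is preceded by a ``-DOCSTART-`` marker carrying its id so
    that multi-document files round-trip.  Sentences without gold tags are
    tagged from their (token-aligned, non-overlapping) spans; overlapping
    spans raise :class:`DataError`.
    """
    out: list[str] = []
    for doc in docs:
        out.append(f"-DOCSTART-\t{doc.doc_id}")
        for sent in doc.sentences:
            tags = sent.gold_tags
            if tags is None:
                tags = spans_to_bio(sent, spans_in_sentence(sent, doc.spans))
            for tok, tag in zip(sent.tokens, tags):
                out.append(f"{tok.surface}\t{tag}")
            out.append("")
    return "\n".join(out) + ("\n" if out else "")


# ---------------------------------------------------------------------------
# standoff dialect
# ---------------------------------------------------------------------------

# maximal runs of alphanumerics with internal hyphens; any other non-space
# character is a single-character token
_TOKEN_RE = re.compile(r"[0-9A-Za-z]+(?:-[0-9A-Za-z]+)*|\S")
_SPAN_LINE_RE = re.compile(r"^(T\d+)\t(\S+) (\d+) (\d+)\t(.*)$")
_REL_LINE_RE = re.compile(r"^(R\d+)\t(\S+) Arg1:(\S+) Arg2:(\S+)\s*$")


def tokenize_text(text: str) -> list[Sentence]:
    """Sentence-split on newlines; tokenize with the standoff tokenizer rule."""
    sentences: list[Sentence] = []
    offset = 0
    for line in text.split("\n"):
        tokens = [
            Token(m.group(), offset + m.start(), offset + m.end(), i)
            for i, m in enumerate(_TOKEN_RE.finditer(line))
        ]
        if tokens:
            sentences.append(Sentence(tokens))
        offset += len(line) + 1
    return sentences


def read_standoff(text_stream, ann_stream, doc_id: str = "doc",
                  strict: bool = False) -> AnnotatedDocument:
    """Parse a standoff ``.txt`` + annotation pair into one document.

    Every span's covered text is verified against the text slice it points
    at; mismatches, dangling relation arguments, token-misaligned spans and
    overlapping spans all raise :class:`DataError`.
    """
    text = text_stream.read() if hasattr(text_stream, "read") else str(text_stream)
    sentences = tokenize_text(text)
    starts = {tok.begin for s in sentences for tok in s.tokens}
    ends = {tok.end for s in sentences for tok in s.tokens}

    spans: list[EntitySpan] = []
    raw_relations: list[tuple[str, str, str, str, int]] = []
    for lineno, line in enumerate(_lines(ann_stream), start=1):
        if not line.strip():
            continue
        if line.startswith("T"):
            m = _SPAN_LINE_RE.match(line)
            if not m:
                raise DataError(f"annotation line {lineno}: malformed span line {line!r}")
            sid, label, b, e, covered = m.group(1), m.group(2), int(m.group(3)), int(m.group(4)), m.group(5)
            slice_ = text[b:e]
            if slice_ != covered:
                raise DataError(
                    f"annotation line {lineno}: span {sid} covered text "
                    f"{covered!r} does not match text slice {slice_!r}")
            if b not in starts or e not in ends:
                raise DataError(
                    f"annotation line {lineno}: span {sid} [{b},{e}) is not "
                    f"aligned with token boundaries")
            spans.append(EntitySpan(sid, label, b, e, covered))
        elif line.startswith("R"):
            m = _REL_LINE_RE.match(line)
            if not m:
                raise DataError(f"annotation line {lineno}: malformed relation line {line!r}")
            raw_relations.append((m.group(1), m.group(2), m.group(3), m.group(4), lineno))
        else:
            raise DataError(f"annotation line {lineno}: unrecognised line {line!r}")

    for a in spans:
        for b in spans:
            if a.id < b.id and a.overlaps(b):
                raise DataError(
                    f"overlapping spans {a.id} and {b.id}; overlapping entities "
                    f"are not supported")

    known = {s.id for s in spans}
    relations = []
    for rid, label, arg1, arg2, lineno in raw_relations:
        for arg in (arg1, arg2):
            if arg not in known:
                raise DataError(
                    f"annotation line {lineno}: relation {rid} references "
                    f"unknown span {arg}")
        relations.append(RelationInstance(rid, label, arg1, arg2))

    doc = AnnotatedDocument(doc_id, text, sentences, spans, relations)
    for sent in doc.sentences:
        sent.gold_tags = spans_to_bio(sent, spans_in_sentence(sent, spans))
    doc.validate()
    return doc


def write_standoff(doc: AnnotatedDocument,
                   provenances: tuple[str, ...] = PROVENANCES) -> tuple[str, str]:
    """Serialize a document to (text, annotation) standoff streams.

    Span ids are renumbered ``T1..`` in (begin, end) order and relations
    ``R1..`` follow, so ids are emitted in ascending numeric order and the
    output is byte-stable for a fixed document.
    """
    chosen = [s for s in doc.spans if s.provenance in provenances]
    ordered = sorted(chosen, key=lambda s: (s.begin, s.end, s.label))
    idmap = {s.id: f"T{i}" for i, s in enumerate(ordered, start=1)}
    lines = [
        f"{idmap[s.id]}\t{s.label} {s.begin} {s.end}\t{s.covered_text}"
        for s in ordered
    ]
    rels = [r for r in doc.relations
            if r.provenance in provenances
            and r.source in idmap and r.target in idmap]
    rels.sort(key=lambda r: (int(idmap[r.source][1:]), int(idmap[r.target][1:]), r.label))
    for i, r in enumerate(rels, start=1):
        lines.append(f"R{i}\t{r.label} Arg1:{idmap[r.source]} Arg2:{idmap[r.target]}")
    ann = "\n".join(lines) + ("\n" if lines else "")
    return doc.text, ann


# ---------------------------------------------------------------------------
# structural equality (used by round-trip checks)
# ---------------------------------------------------------------------------


def documents_equal(a: AnnotatedDocument, b: AnnotatedDocument,
                    relations: bool = True) -> bool:
    """Structural identity: tokens, tags, spans, (optionally) relations.

    Ids and provenance are deliberately ignored -- serialization may
    renumber ids without changing the annotation content.
    """
    if len(a.sentences) != len(b.sentences):
        return False
    for sa, sb in zip(a.sentences, b.sentences):
        if [t.surface for t in sa.tokens] != [t.surface for t in sb.tokens]:
            return False
        if (sa.gold_tags or None) != (sb.gold_tags or None):
            return False
    key = lambda s: (s.begin, s.end, s.label, s.covered_text)
    if sorted(map(key, a.spans)) != sorted(map(key, b.spans)):
        return False
    if relations:
        def relkey(doc):
            out = []
            for r in doc.relations:
                src, tgt = doc.span_by_id(r.source), doc.span_by_id(r.target)
                out.append((r.label, key(src), key(tgt)))
            return sorted(out)
        if relkey(a) != relkey(b):
            return False
    return True
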