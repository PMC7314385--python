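"""PubTator corpus I/O and sentence segmentation.

PubTator is the line-oriented annotation format used by the BioCreative V
chemical–disease relation (CDR) corpus: each document block holds a title
line ``<pmid>|t|<title>``, an abstract line ``<pmid>|a|<abstract>``, then
tab-separated mention lines ``pmid TAB start TAB end TAB text TAB type TAB
concept_id`` and relation lines ``pmid TAB type TAB id1 TAB id2``, with
blank lines between blocks.  Character offsets are 0-based half-open over
the string ``title + " " + abstract``.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

CHEMICAL = "chemical"
DISEASE = "disease"
OTHER = "other"

#: concept identifier PubTator uses for mentions the annotators could not normalize
UNNORMALIZED_ID = "-1"


class PubTatorParseError(ValueError):
    """A line in a PubTator stream does not match the dialect."""


class MentionIntegrityError(ValueError):
    """A mention's offsets do not slice the document text to its surface form."""


@dataclass
class Mention:
    """A typed entity mention with character offsets into the document text.

    ``entity_type`` is normalized to ``chemical`` / ``disease`` / ``other``;
    ``source_type`` keeps the raw type string from the file so writing is
    loss-free.  Mentions whose concept could not be normalized (ID ``-1``)
    are demoted to ``other`` and never form target pairs.
    """

    start: int
    end: int
    text: str
    entity_type: str
    concept_id: str
    source_type: str = ""

    def __post_init__(self) -> None:
        if not self.source_type:
            self.source_type = self.entity_type.capitalize()

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass(frozen=True)
class Relation:
    """A document-level gold relation between two concept identifiers."""

    relation_type: str
    concept_id_1: str
    concept_id_2: str


@dataclass
class Document:
    """An annotated title+abstract with mentions and document-level relations."""

    doc_id: str
    title: str
    abstract: str
    mentions: list[Mention] = field(default_factory=list)
    relations: list[Relation] = field(default_factory=list)

    @property
    def text(self) -> str:
        """Title and abstract joined by a single space (offset convention)."""
        if self.abstract:
            return self.title + " " + self.abstract
        return self.title

    def validate(self) -> None:
        """Check offset integrity and mention ordering; raise on violation."""
        text = self.text
        if not text:
            raise MentionIntegrityError(f"document {self.doc_id}: empty text")
        for m in self.mentions:
            if not (0 <= m.start < m.end <= len(text)):
                raise MentionIntegrityError(
                    f"document {self.doc_id}: mention offsets [{m.start},{m.end}) "
                    f"out of range for text of length {len(text)}"
                )
            if text[m.start : m.end] != m.text:
                raise MentionIntegrityError(
                    f"document {self.doc_id}: text at [{m.start},{m.end}) is "
                    f"{text[m.start:m.end]!r}, annotation says {m.text!r}"
                )
        starts = [m.start for m in self.mentions]
        if starts != sorted(starts):
            raise MentionIntegrityError(
                f"document {self.doc_id}: mentions not sorted by start offset"
            )


@dataclass
class SentenceSegmentation:
    """Sentence spans over a document plus a mention→sentence assignment.

    Spans are ascending, non-overlapping [start, end) intervals; every
    mention lies fully inside exactly one span (boundaries that would bisect
    a mention are merged away before assignment).
    """

    spans: list[tuple[int, int]]
    mention_sentence: dict[int, int]

    @property
    def n_sentences(self) -> int:
        return len(self.spans)


def _normalize_type(raw: str, concept_id: str) -> str:
    if concept_id == UNNORMALIZED_ID:
        return OTHER
    low = raw.strip().lower()
    if low == CHEMICAL:
        return CHEMICAL
    if low == DISEASE:
        return DISEASE
    return OTHER


def _as_line_iter(stream: IO[str] | str | Iterable[str]) -> Iterator[str]:
    if isinstance(stream, str):
        return iter(io.StringIO(stream))
    return iter(stream)


def read_pubtator(stream: IO[str] | str | Iterable[str]) -> list[Document]:
    """Parse a PubTator stream into documents.

    Accepts an open text handle, an iterable of lines, or the whole file
    contents as a single string.  Composite concept annotations such as
    ``D001|D002`` are expanded into one mention per identifier sharing the
    same offsets.  Offsets are validated against ``title + " " + abstract``.
    """
    docs: list[Document] = []
    current: Document | None = None
    for lineno, raw in enumerate(_as_line_iter(stream), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            if current is not None:
                current.validate()
                docs.append(current)
                current = None
            continue
        if "|t|" in line or "|a|" in line:
            doc_id, kind, payload = line.split("|", 2)
            if current is None:
                current = Document(doc_id=doc_id, title="", abstract="")
            elif current.doc_id != doc_id:
                raise PubTatorParseError(
                    f"line {lineno}: document id {doc_id!r} inside block of "
                    f"{current.doc_id!r}"
                )
            if kind == "t":
                current.title = payload
            elif kind == "a":
                current.abstract = payload
            else:
                raise PubTatorParseError(f"line {lineno}: unknown line kind {kind!r}")
            continue
        fields = line.split("\t")
        if current is None:
            raise PubTatorParseError(
                f"line {lineno}: annotation line before any title line"
            )
        if len(fields) >= 6 and fields[1].isdigit() and fields[2].isdigit():
            doc_id, start, end, text, raw_type, concept = fields[:6]
            for cid in concept.split("|"):
                cid = cid.strip()
                current.mentions.append(
                    Mention(
                        start=int(start),
                        end=int(end),
                        text=text,
                        entity_type=_normalize_type(raw_type, cid),
                        concept_id=cid,
                        source_type=raw_type,
                    )
                )
        elif len(fields) == 4:
            doc_id, rel_type, id1, id2 = fields
            current.relations.append(Relation(rel_type, id1, id2))
        else:
            raise PubTatorParseError(
                f"line {lineno}: cannot parse annotation line {line!r}"
            )
    if current is not None:
        current.validate()
        docs.append(current)
    for doc in docs:
        doc.mentions.sort(key=lambda m: (m.start, m.end))
    return docs


def write_pubtator(docs: Sequence[Document], sink: IO[str]) -> None:
    """Emit documents in the same PubTator dialect ``read_pubtator`` accepts.

    Mentions that were expanded from a composite concept annotation (same
    offsets and raw type) are re-merged onto one line with ``|``-joined IDs,
    so read→write round-trips byte-stably on well-formed input.
    """
    for doc in docs:
        sink.write(f"{doc.doc_id}|t|{doc.title}\n")
        sink.write(f"{doc.doc_id}|a|{doc.abstract}\n")
        merged: dict[tuple[int, int, str, str], list[str]] = {}
        for m in doc.mentions:
            key = (m.start, m.end, m.text, m.source_type)
            merged.setdefault(key, []).append(m.concept_id)
        for (start, end, text, source_type), cids in merged.items():
            concept = "|".join(cids)
            sink.write(f"{doc.doc_id}\t{start}\t{end}\t{text}\t{source_type}\t{concept}\n")
        for r in doc.relations:
            sink.write(f"{doc.doc_id}\t{r.relation_type}\t{r.concept_id_1}\t{r.concept_id_2}\n")
        sink.write("\n")


# sentence splitting ---------------------------------------------------------

_ABBREVIATIONS = {
    "e.g", "i.e", "etc", "vs", "al", "fig", "figs", "dr", "mr", "mrs", "ms",
    "prof", "inc", "ltd", "st", "no", "approx", "ca", "cf", "resp", "wk",
    "mg", "kg", "ml", "hr", "min", "max", "sec",
}

_BOUNDARY_RE = re.compile(r"[.!?]+[\"')\]]*\s+(?=[A-Z0-9\[\(\"])")


def _candidate_boundaries(text: str) -> list[int]:
    """Offsets where a new sentence may start (first char after the gap)."""
    out = []
    for match in _BOUNDARY_RE.finditer(text):
        prefix = text[: match.start()]
        last_word = prefix.rsplit(None, 1)[-1] if prefix.split() else ""
        bare = last_word.rstrip(".").lower().lstrip("(\"'")
        if bare in _ABBREVIATIONS:
            continue
        # single capital letter before the period is an initial, not an end
        if len(bare) == 1 and last_word[:1].isupper():
            continue
        out.append(match.end())
    return out


def split_sentences(doc: Document) -> SentenceSegmentation:
    """Segment a document into sentences without bisecting any mention.

    Rule-based: terminal punctuation followed by whitespace and a capital
    letter, digit or bracket opens a new sentence, with an abbreviation
    guard.  Any candidate boundary that falls strictly inside a mention is
    dropped, so mention containment always holds; a document that yields no
    boundary is a legal one-sentence segmentation.
    """
    text = doc.text
    boundaries = _candidate_boundaries(text)
    boundaries = [
        b
        for b in boundaries
        if not any(m.start < b < m.end for m in doc.mentions)
    ]
    starts = [0] + boundaries
    ends = boundaries + [len(text)]
    spans: list[tuple[int, int]] = []
    for s, e in zip(starts, ends):
        while s < e and text[s].isspace():
            s += 1
        while e > s and text[e - 1].isspace():
            e -= 1
        if s < e:
            spans.append((s, e))
    if not spans:
        spans = [(0, len(text))]

    mention_sentence: dict[int, int] = {}
    for i, m in enumerate(doc.mentions):
        idx = _containing_span(spans, m)
        if idx is None:
            # mention sticks out of the trimmed span (pathological whitespace):
            # merge the spans it touches
            spans, idx = _merge_spans_for(spans, m)
            mention_sentence = {
                j: _containing_span(spans, doc.mentions[j]) or 0
                for j in range(i)
            }
        mention_sentence[i] = idx
    return SentenceSegmentation(spans=spans, mention_sentence=mention_sentence)


def _containing_span(spans: list[tuple[int, int]], m: Mention) -> int | None:
    for i, (s, e) in enumerate(spans):
        if s <= m.start and m.end <= e:
            return i
    return None


def _merge_spans_for(
    spans: list[tuple[int, int]], m: Mention
) -> tuple[list[tuple[int, int]], int]:
    touched = [i for i, (s, e) in enumerate(spans) if m.start < e and s < m.end]
    if not touched:  # mention in inter-span whitespace; extend nearest span
        touched = [min(range(len(spans)), key=lambda i: abs(spans[i][0] - m.start))]
    lo, hi = touched[0], touched[-1]
    merged = (min(spans[lo][0], m.start), max(spans[hi][1], m.end))
    new_spans = spans[:lo] + [merged] + spans[hi + 1 :]
    return new_spans, lo
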